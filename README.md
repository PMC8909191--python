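# tslecc

Simulation and estimation of **extracorporeal removal of thermosensitive
liposomal doxorubicin (TSL-Dox)** from systemic circulation.

Thermosensitive liposomes release their doxorubicin payload within seconds
at mild hyperthermia (~43 °C). After heat-triggered tumor delivery, most of
the administered drug is still circulating in encapsulated form and drives
off-target toxicity (notably cardiotoxicity). An extracorporeal circuit
(ECC) — pump → in-line heater (releases drug from the liposomes) →
activated-carbon filter (adsorbs the released free drug) → return line —
can strip this remaining drug from the blood. `tslecc` models that system
end to end for a rat-scale scenario:

- **release kinetics** — burst-plus-first-order release,
  *f*(T, t) = b(T) + (1 − b(T))(1 − e^(−k_rel(T)·t)), calibrated per
  temperature and interpolated monotonically;
- **pharmacokinetics** — a compartmental ODE model of encapsulated (L) and
  free (D) drug in plasma, with first-order carrier elimination
  (k_L = ln 2 / t½), a bioavailable leak fraction φ, free-drug elimination
  k_e, an ECC stage with plasma draw F(1 − Hct), in-line release and
  filtration with efficacy η(t), a well-mixed circuit volume V_ECC, and
  irreversible cardiac uptake;
- **estimators** — the measurement-side computations: trapezoid removed
  mass m_Dox = ∫ F(1 − Hct)(c_BF − c_AF) dt, log-linear half-life,
  AUC(0→∞) with λ_z tail extrapolation, circuit transit time, single-pass
  removal;
- **fluorescence monitoring** — standard-curve fitting/inversion and a
  streaming report of circulating concentration, instantaneous filter
  efficacy, and cumulative removed drug;
- **synthetic data** — seeded generators for blood samples, fluorescence
  readings, release assays, and the decaying filter-efficacy profile
  (≈80% → ≈40% over 60 min, 55% time-average), so the whole pipeline is
  testable without external data.

## Worked example

The default `ScenarioConfig()` is the reference scenario: a 250 g rat with
16 mL blood (Hct 0.45), a 7 mg/kg (1750 µg) bolus, carrier plasma
half-life 55 min, and an ECC at 0.35 mL/min starting 30 min post-bolus
with a 4.2 mL priming volume, heater at 43 °C (~5 s dwell) and 60 min of
filtration.

```python
from tslecc import ScenarioConfig, efficacy_sweep

print(efficacy_sweep(ScenarioConfig(), [0.55, 0.80, 1.00]).to_string(index=False))
```

```
 efficacy  removed_percent  auc_ratio  cardiac_ug_per_g  cardiac_reduction
     0.55        32.494173   1.586303          4.492723           1.558102
     0.80        43.789728   1.680483          3.812472           1.836111
     1.00        51.538297   1.754036          3.332009           2.100871
```

Reading: a filter with the 55% average in vivo efficacy removes ~32.5% of
the administered dose within the 60-minute procedure; an ideal filter
removes ~51.5% in the same hour (and ~61% if filtration continues to
plateau). Filtration reduces the plasma AUC(0→∞) ~1.6-fold and cuts the
plateau cardiac drug concentration from ~7 µg/g (no filtration) to
~4.5 µg/g. The same workflows are available from the shell:

```bash
tslecc simulate --out run/                 # one trajectory + summary line
tslecc sweep --efficacies 0.55,1.0 --out sweep.csv
tslecc reproduce-fig4 --out repro/         # control + 55/80/100% arms
tslecc synth --what samples --cv 0.0 --seed 1 --out samples.csv
tslecc estimate-removal --samples samples.csv
```

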