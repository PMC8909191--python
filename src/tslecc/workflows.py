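"""Top-level workflows: the headline reproduction run and efficacy sweeps.

:func:`run_reproduction` drives the full model-prediction workflow: one
no-filtration control plus filtration arms at 55/80/100% constant filter
efficacy, reporting removal percentages, AUC fold-reductions and cardiac
uptake reductions, and writing trajectories, a summary table and a run
manifest sufficient to re-execute the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .calibration import auc_infinity_for, cardiac_plateau_for, removal_percent_for
from .config import ScenarioConfig, simulate_scenario
from .pk import cardiac_concentration, removed_percent
from .release import ReleaseModel

__all__ = ["run_reproduction", "efficacy_sweep", "RunManifest", "package_version"]

DEFAULT_EFFICACIES = (0.55, 0.80, 1.00)


def package_version() -> str:
    try:
        return version("tslecc")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest(dict):
    """Resolved parameters, software version and output inventory of a run."""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self, indent=2, sort_keys=True) + "\n")


def efficacy_sweep(
    config: ScenarioConfig,
    efficacies: Sequence[float] = DEFAULT_EFFICACIES,
    release: Optional[ReleaseModel] = None,
) -> pd.DataFrame:
    """Removal/AUC/cardiac summary over constant filter efficacies."""
    auc_off = auc_infinity_for(config.without_ecc(), release)
    cardiac_off = cardiac_plateau_for(config, release=release)
    rows = []
    for eta in efficacies:
        cfg = config.with_constant_efficacy(eta)
        removed = removal_percent_for(config, eta, release=release)
        auc_on = auc_infinity_for(cfg, release)
        cardiac_on = cardiac_plateau_for(config, eta=eta, release=release)
        rows.append(
            {
                "efficacy": eta,
                "removed_percent": removed,
                "auc_ratio": auc_off / auc_on,
                "cardiac_ug_per_g": cardiac_on,
                "cardiac_reduction": cardiac_off / cardiac_on,
            }
        )
    return pd.DataFrame(rows)


def run_reproduction(
    config: ScenarioConfig,
    output_dir: str | Path,
    efficacies: Sequence[float] = DEFAULT_EFFICACIES,
    release: Optional[ReleaseModel] = None,
) -> RunManifest:
    """Run the no-filtration control and the efficacy arms; write artefacts.

    Writes per-arm trajectory CSVs, ``summary.csv``/``summary.json`` and
    ``manifest.json`` into ``output_dir``.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    traj_off = simulate_scenario(config.without_ecc(), release=release)
    p = outdir / "trajectory_no_ecc.csv"
    traj_off.to_csv(p)
    files.append(p)
    cardiac_off = cardiac_concentration(traj_off).total
    auc_off = auc_infinity_for(config.without_ecc(), release)

    rows = []
    for eta in efficacies:
        cfg = config.with_constant_efficacy(eta)
        traj = simulate_scenario(cfg, release=release)
        p = outdir / f"trajectory_eta{int(round(eta * 100)):03d}.csv"
        traj.to_csv(p)
        files.append(p)
        auc_on = auc_infinity_for(cfg, release)
        cardiac_on = cardiac_plateau_for(config, eta=eta, release=release)
        rows.append(
            {
                "efficacy": eta,
                "removed_percent": removed_percent(traj),
                "auc_ratio": auc_off / auc_on,
                "cardiac_ug_per_g": cardiac_on,
                "cardiac_reduction": cardiac_off / cardiac_on,
            }
        )
    summary = pd.DataFrame(rows)
    p = outdir / "summary.csv"
    summary.to_csv(p, index=False)
    files.append(p)
    summary_json = {
        "no_ecc": {
            "removed_percent": 0.0,
            "auc_ug_min_per_ml": auc_off,
            "cardiac_ug_per_g": cardiac_off,
        },
        "arms": rows,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary_json, indent=2) + "\n")
    files.append(p)

    manifest = RunManifest(
        {
            "tool": "tslecc",
            "version": package_version(),
            "scenario": config.model_dump(mode="json"),
            "efficacies": list(efficacies),
            "release_model": (release.to_dict() if release is not None else "default"),
            "seed": config.noise.seed,
            "outputs": {f.name: _sha256(f) for f in files},
        }
    )
    manifest.write(outdir / "manifest.json")
    return manifest
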