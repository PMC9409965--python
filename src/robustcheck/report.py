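"""Full-pipeline orchestration and report generation.

``run_full_evaluation`` chains the feature screen, the two noise-severity
sweeps and the split study for each configured classifier, and assembles a
summary table (one row per classifier: clean accuracy, accuracy and
variance at full replacement, at maximal Gaussian noise, and across random
splits) together with a robustness verdict: how many of the classifier's
input features the screen flagged as significant, and how the classifier's
accuracy variance compares with the fleet median.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier_zoo import ClassifierSpec
from .dataset_core import OmicsTable, make_split
from .factor_analysis import ScreenConfig, run_factor_analysis
from .robustness_engine import SweepConfig, mc_split_study, severity_sweep

__all__ = ["RunConfig", "run_full_evaluation", "write_report"]

REPORT_COLUMNS = [
    "classifier",
    "accuracy_no_noise",
    "accuracy_p1",
    "variance_p1",
    "accuracy_s1",
    "variance_s1",
    "accuracy_mc_split",
    "variance_mc_split",
    "n_inputs_in_screen",
]


@dataclass(frozen=True)
class RunConfig:
    classifiers: tuple  # ClassifierSpec instances
    seed: int = 0
    reps_per_level: int = 1000
    n_splits: int = 1000
    ratio: float = 0.7
    levels: tuple = tuple(np.round(np.arange(0.0, 1.05, 0.1), 10))
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    track_loocv: bool = False
    run_screen: bool = True


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), default=_json_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_evaluation(table: OmicsTable, config: RunConfig) -> dict:
    """Screen, sweep and split-study every configured classifier.

    Returns a bundle with the screen result, per-classifier sweep and split
    summaries, the report table rows, and provenance (config hash, seed).
    """
    bundle: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "screen": None,
        "classifiers": {},
    }
    screen = None
    if config.run_screen:
        screen = run_factor_analysis(table, config.screen)
        bundle["screen"] = {
            "F_prime": screen.F_prime,
            "F_doubleprime": screen.F_doubleprime,
            "F_star": screen.F_star,
            "fdr": dict(zip(screen.fdr.feature_names, screen.fdr.fdr)),
            "scaled_variances": dict(
                zip(screen.F_doubleprime, screen.scaled_variances)
            ),
        }

    split = make_split(table, ratio=config.ratio, seed=config.seed, stratified=True)
    rows = []
    for spec in config.classifiers:
        entry: dict = {"spec": spec}
        sweeps = {}
        for kind in ("replacement", "gaussian"):
            sweep_cfg = SweepConfig(
                noise_kind=kind,
                levels=config.levels,
                reps_per_level=config.reps_per_level,
                ratio=config.ratio,
                seed=config.seed,
                track_loocv=config.track_loocv,
            )
            sweeps[kind] = severity_sweep(table, spec, sweep_cfg, split=split)
        study = mc_split_study(
            table,
            spec,
            n_splits=config.n_splits,
            ratio=config.ratio,
            seed=config.seed,
            track_loocv=config.track_loocv,
        )
        entry["sweeps"] = sweeps
        entry["split_study"] = study

        rep_last = sweeps["replacement"].summaries[-1]
        gau_last = sweeps["gaussian"].summaries[-1]
        n_in_screen = (
            sum(1 for f in spec.feature_subset if f in screen.F_star)
            if screen is not None
            else None
        )
        rows.append(
            {
                "classifier": spec.algorithm,
                "accuracy_no_noise": sweeps["replacement"].summaries[0].mean_test_accuracy,
                "accuracy_p1": rep_last.mean_test_accuracy,
                "variance_p1": rep_last.var_test_accuracy,
                "accuracy_s1": gau_last.mean_test_accuracy,
                "variance_s1": gau_last.var_test_accuracy,
                "accuracy_mc_split": study.mean_test_accuracy,
                "variance_mc_split": study.var_test_accuracy,
                "n_inputs_in_screen": n_in_screen,
            }
        )
        bundle["classifiers"][spec.algorithm] = entry

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    fleet_median = report["variance_mc_split"].median()
    report["split_variance_vs_fleet_median"] = report["variance_mc_split"] / fleet_median
    bundle["report"] = report
    return bundle


def write_report(bundle: dict, out_dir, formats=("csv", "json")) -> list[Path]:
    """Write the summary table (and screen output) as CSV and/or JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    report: pd.DataFrame = bundle["report"]
    if "csv" in formats:
        path = out_dir / "report.csv"
        report.to_csv(path, index=False)
        written.append(path)
    if "json" in formats:
        payload = {
            "config_hash": bundle["config_hash"],
            "seed": bundle["seed"],
            "screen": bundle["screen"],
            "report": report.to_dict(orient="records"),
        }
        path = out_dir / "report.json"
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
        written.append(path)
    return written
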