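"""Monte Carlo protocols quantifying classifier robustness.

Two studies:

* **Severity sweep** — for each noise level on a grid, corrupt the raw table
  many times (the corruption always precedes standardization), refit the
  classifier on a *fixed* 70/30 split each time, and record the mean and
  variance of test accuracy, of LOOCV training accuracy, and of every
  feature-aligned parameter.  Replacement noise drives any classifier toward
  50% accuracy at p = 1; the decay is approximately linear, which yields a
  closed-form estimate of the noise level a classifier can tolerate while
  staying above a target accuracy.
* **Split study** — refit across many random stratified 70/30 splits of the
  clean table; the spread of test accuracy across splits is a harsher
  robustness probe than the spread of LOOCV accuracy.

Rep r at level index l draws its corruption seed from a counter-derived
stream of (master seed, l, r), so partial or parallel runs reproduce the
serial result exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier_zoo import ClassifierSpec, fit_classifier, loocv_accuracy, predict
from .dataset_core import OmicsTable, TrainTestSplit, make_split, standardize
from .noise_models import NoiseSpec, corrupt

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "LevelSummary",
    "SweepResult",
    "SplitStudyResult",
    "severity_sweep",
    "mc_split_study",
    "tolerable_noise_level",
    "summarize",
]

DEFAULT_LEVELS = tuple(np.round(np.arange(0.0, 1.05, 0.1), 10))


@dataclass(frozen=True)
class SweepConfig:
    """Grid and replication settings for a severity sweep."""

    noise_kind: str = "replacement"
    levels: tuple = DEFAULT_LEVELS
    reps_per_level: int = 1000
    ratio: float = 0.7
    seed: int = 0
    track_loocv: bool = True
    clip_negative: bool | None = None

    def __post_init__(self):
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if any(not 0 <= x <= 1 for x in levels):
            raise ValueError("levels must lie in [0, 1]")
        if list(levels) != sorted(set(levels)):
            raise ValueError("levels must be strictly increasing")
        if self.reps_per_level < 2:
            raise ValueError("need at least 2 reps per level")


@dataclass(frozen=True)
class LevelSummary:
    level: float
    n_reps: int
    mean_test_accuracy: float
    var_test_accuracy: float
    mean_loocv_accuracy: float | None
    var_loocv_accuracy: float | None
    param_means: dict
    param_vars: dict


@dataclass(frozen=True)
class SweepResult:
    spec: ClassifierSpec
    config: SweepConfig
    split: TrainTestSplit
    summaries: tuple
    raw: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class SplitStudyResult:
    spec: ClassifierSpec
    n_splits: int
    test_accuracies: np.ndarray
    loocv_accuracies: np.ndarray
    mean_test_accuracy: float
    var_test_accuracy: float
    mean_loocv_accuracy: float
    var_loocv_accuracy: float
    param_means: dict
    param_vars: dict


def _rep_seed(master: int, level_index: int, rep: int) -> int:
    seq = np.random.SeedSequence([master, level_index, rep])
    return int(seq.generate_state(1)[0] % (2**31))


def _fit_once(
    table: OmicsTable,
    spec: ClassifierSpec,
    split: TrainTestSplit,
    seed: int,
    track_loocv: bool,
):
    """Standardize on the training partition, fit, score test, optional LOOCV."""
    sub = table.select_features(spec.feature_subset) if spec.feature_subset else table
    train = sub.select_samples(split.train_indices)
    test = sub.select_samples(split.test_indices)
    train_z, params = standardize(train)
    test_z, _ = standardize(test, params)
    fit = fit_classifier(spec, train_z.values, train_z.labels, seed=seed)
    acc = float(np.mean(predict(fit, test_z.values) == test_z.labels))
    loocv = (
        loocv_accuracy(spec, train_z.values, train_z.labels, seed=seed)
        if track_loocv
        else None
    )
    return acc, loocv, fit.params


def _aggregate_params(param_list, kind_filter=("coefficient", "importance")):
    """Mean/variance per feature name across a list of ParamVectors."""
    tracked = [p for p in param_list if p is not None and p.kind in kind_filter]
    if not tracked:
        return {}, {}
    names = list(tracked[0].entries)
    stacked = np.array([[p.entries[n] for n in names] for p in tracked])
    means = dict(zip(names, stacked.mean(axis=0)))
    variances = dict(zip(names, stacked.var(axis=0, ddof=1) if len(tracked) > 1 else np.zeros(len(names))))
    return means, variances


def severity_sweep(
    table: OmicsTable,
    spec: ClassifierSpec,
    config: SweepConfig,
    split: TrainTestSplit | None = None,
) -> SweepResult:
    """Noise-severity study on a fixed train/test split.

    For every level on the grid the raw table is corrupted
    ``reps_per_level`` times; each rep re-standardizes on its corrupted
    training partition, refits, and scores the corrupted test partition.
    Level 0 is an identity corruption, so it is evaluated once (zero
    variance by construction).  More than 5% failed reps at a level aborts
    the sweep.
    """
    if split is None:
        split = make_split(table, ratio=config.ratio, seed=config.seed, stratified=True)
    summaries = []
    raw: dict[float, list] = {}
    for li, level in enumerate(config.levels):
        n_reps = 1 if level == 0 else config.reps_per_level
        accs, loocvs, params_list = [], [], []
        failures = 0
        for r in range(n_reps):
            rep_seed = _rep_seed(config.seed, li, r)
            noise = NoiseSpec(
                kind=config.noise_kind,
                level=level,
                clip_negative=config.clip_negative,
                seed=rep_seed,
            )
            try:
                noisy = corrupt(table, noise)
                acc, loocv, params = _fit_once(noisy, spec, split, rep_seed, config.track_loocv)
            except ValueError as exc:
                failures += 1
                logger.warning("rep %d at level %.2f failed: %s", r, level, exc)
                continue
            accs.append(acc)
            loocvs.append(loocv)
            params_list.append(params)
        if failures > 0.05 * n_reps:
            raise RuntimeError(
                f"{failures}/{n_reps} reps failed at level {level}; data too degenerate"
            )
        accs = np.array(accs)
        p_means, p_vars = _aggregate_params(params_list)
        track = config.track_loocv
        summaries.append(
            LevelSummary(
                level=level,
                n_reps=len(accs),
                mean_test_accuracy=float(accs.mean()),
                var_test_accuracy=float(accs.var(ddof=1)) if accs.size > 1 else 0.0,
                mean_loocv_accuracy=float(np.mean(loocvs)) if track else None,
                var_loocv_accuracy=(
                    float(np.var(loocvs, ddof=1)) if track and len(loocvs) > 1 else (0.0 if track else None)
                ),
                param_means=p_means,
                param_vars=p_vars,
            )
        )
        raw[level] = accs
    return SweepResult(spec=spec, config=config, split=split, summaries=tuple(summaries), raw=raw)


def mc_split_study(
    table: OmicsTable,
    spec: ClassifierSpec,
    n_splits: int = 1000,
    ratio: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
    track_loocv: bool = True,
) -> SplitStudyResult:
    """Accuracy spread across many random train/test splits of the clean table."""
    if n_splits < 2:
        raise ValueError("need at least 2 splits")
    accs, loocvs, params_list = [], [], []
    for i in range(n_splits):
        split = make_split(table, ratio=ratio, seed=seed + i, stratified=stratified)
        acc, loocv, params = _fit_once(table, spec, split, seed + i, track_loocv)
        accs.append(acc)
        loocvs.append(loocv if loocv is not None else np.nan)
        params_list.append(params)
    accs = np.array(accs)
    loocvs = np.array(loocvs, dtype=float)
    p_means, p_vars = _aggregate_params(params_list)
    return SplitStudyResult(
        spec=spec,
        n_splits=n_splits,
        test_accuracies=accs,
        loocv_accuracies=loocvs,
        mean_test_accuracy=float(accs.mean()),
        var_test_accuracy=float(accs.var(ddof=1)),
        mean_loocv_accuracy=float(np.nanmean(loocvs)) if track_loocv else float("nan"),
        var_loocv_accuracy=float(np.nanvar(loocvs, ddof=1)) if track_loocv else float("nan"),
        param_means=p_means,
        param_vars=p_vars,
    )


def tolerable_noise_level(
    sweep: SweepResult, target_accuracy: float
) -> dict:
    """Replacement-noise budget for a target accuracy.

    Test accuracy under replacement noise decays approximately linearly from
    its clean baseline acc(0) to chance (0.5) at p = 1, so the level at
    which a target accuracy is crossed is
    ``p* = (acc(0) - target) / (acc(0) - 0.5)``.  The empirical crossing is
    interpolated from the sweep's level grid for comparison.  Targets at or
    above the baseline give p* = 0; targets at or below chance give p* = 1.
    """
    if sweep.config.noise_kind != "replacement":
        raise ValueError("the linear-decay noise budget applies to replacement sweeps")
    acc0 = sweep.summaries[0].mean_test_accuracy
    if target_accuracy >= acc0:
        logger.info("target %.3f at or above the clean baseline; p* = 0", target_accuracy)
        p_star = 0.0
    elif target_accuracy <= 0.5:
        logger.info("target %.3f at or below chance; p* = 1", target_accuracy)
        p_star = 1.0
    else:
        p_star = (acc0 - target_accuracy) / (acc0 - 0.5)

    levels = np.array([s.level for s in sweep.summaries])
    means = np.array([s.mean_test_accuracy for s in sweep.summaries])
    empirical = None
    below = np.flatnonzero(means <= target_accuracy)
    if below.size and below[0] > 0:
        i = below[0]
        x0, x1 = levels[i - 1], levels[i]
        y0, y1 = means[i - 1], means[i]
        empirical = float(x0 + (y0 - target_accuracy) / (y0 - y1) * (x1 - x0))
    elif below.size:
        empirical = float(levels[0])
    return {
        "p_star": float(min(max(p_star, 0.0), 1.0)),
        "empirical_crossing": empirical,
        "baseline_accuracy": float(acc0),
        "target_accuracy": float(target_accuracy),
    }


def summarize(result: SweepResult | SplitStudyResult) -> pd.DataFrame:
    """Tidy one-row-per-condition table of the study's summary statistics."""
    if isinstance(result, SweepResult):
        rows = [
            {
                "classifier": result.spec.algorithm,
                "noise_kind": result.config.noise_kind,
                "level": s.level,
                "n_reps": s.n_reps,
                "mean_test_accuracy": s.mean_test_accuracy,
                "var_test_accuracy": s.var_test_accuracy,
                "mean_loocv_accuracy": s.mean_loocv_accuracy,
                "var_loocv_accuracy": s.var_loocv_accuracy,
            }
            for s in result.summaries
        ]
        return pd.DataFrame(rows)
    if isinstance(result, SplitStudyResult):
        return pd.DataFrame(
            [
                {
                    "classifier": result.spec.algorithm,
                    "n_splits": result.n_splits,
                    "mean_test_accuracy": result.mean_test_accuracy,
                    "var_test_accuracy": result.var_test_accuracy,
                    "mean_loocv_accuracy": result.mean_loocv_accuracy,
                    "var_loocv_accuracy": result.var_loocv_accuracy,
                }
            ]
        )
    raise TypeError(f"cannot summarize {type(result).__name__}")
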