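"""Seeded generator of two-class tabular omics fixtures.

Emulates the statistical structure of a small clinical metabolomics study:
two near-balanced groups (83 cases / 76 controls by default), a couple of
dozen continuous, non-negative measurements, a correlated block of
informative features whose class means differ by a tunable standardized
effect size, and independent null features.  The generator returns the
ground-truth informative set so recovery tests can score the screen and the
wrapper feature selection against it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset_core import OmicsTable, make_split, standardize

__all__ = [
    "SynthConfig",
    "generate_dataset",
    "calibrate_separation",
    "reference_fixture",
    "REFERENCE_EFFECT_SIZE",
]

# Effect size of the canonical fixture, fixed by running calibrate_separation
# against a 94% LDA test-accuracy target on stratified 70/30 splits.
REFERENCE_EFFECT_SIZE = 2.47


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for a synthetic two-class measurement table.

    ``effect_size`` is the standardized mean difference (case minus control,
    in units of the within-class standard deviation) applied to every
    informative feature.  ``correlation`` is the pairwise correlation within
    the informative block; null features are mutually independent.
    ``non_negative`` shifts each feature to a concentration-like positive
    support and clips residual negatives at zero.
    """

    n_case: int = 83
    n_control: int = 76
    n_features: int = 24
    n_informative: int = 5
    effect_size: float = 1.0
    correlation: float = 0.5
    noise_sd: float = 1.0
    non_negative: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each class needs at least 2 samples")


def generate_dataset(config: SynthConfig) -> tuple[OmicsTable, list[str]]:
    """Draw a table from the config; returns (table, informative feature names).

    Informative features share an equicorrelated Gaussian block (correlation
    ``rho``) and a class-mean shift of ``effect_size * noise_sd``; null
    features are independent draws from the same marginal family with zero
    shift.  With ``non_negative`` on, every feature is translated so that
    less than 0.1% of its mass falls below zero (3.1 marginal SDs plus the
    class shift), then clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    f = config.n_features
    k = config.n_informative

    labels = np.concatenate([np.ones(config.n_case, int), np.zeros(config.n_control, int)])

    x = np.empty((n, f))
    if k > 0:
        # equicorrelated block via a shared factor: x = sqrt(rho)*g + sqrt(1-rho)*e
        rho = config.correlation
        shared = rng.standard_normal((n, 1))
        unique = rng.standard_normal((n, k))
        x[:, :k] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * unique
        x[:, :k] += config.effect_size * labels[:, None]
    if f > k:
        x[:, k:] = rng.standard_normal((n, f - k))
    x *= config.noise_sd

    if config.non_negative:
        shift = 3.1 * config.noise_sd + config.effect_size * config.noise_sd
        x = np.clip(x + shift, 0.0, None)

    perm = rng.permutation(n)  # interleave classes so row order carries no signal
    table = OmicsTable(
        values=x[perm],
        sample_ids=tuple(f"S{i:03d}" for i in range(n)),
        feature_names=tuple(
            [f"M{j + 1:02d}_inf" for j in range(k)] + [f"M{j + 1:02d}" for j in range(k, f)]
        ),
        labels=labels[perm],
        metadata={"synthetic": True, "config": config},
    )
    return table, list(table.feature_names[:k])


def _mean_split_accuracy(
    table: OmicsTable, algorithm: str, n_splits: int, seed: int
) -> float:
    """Mean test accuracy of `algorithm` over seeded stratified 70/30 splits."""
    from .classifier_zoo import ClassifierSpec, fit_classifier, predict

    spec = ClassifierSpec(algorithm=algorithm, feature_subset=list(table.feature_names))
    accs = []
    for i in range(n_splits):
        split = make_split(table, ratio=0.7, seed=seed + i, stratified=True)
        train = table.select_samples(split.train_indices)
        test = table.select_samples(split.test_indices)
        train_z, params = standardize(train)
        test_z, _ = standardize(test, params)
        fit = fit_classifier(spec, train_z.values, train_z.labels, seed=seed + i)
        accs.append(float(np.mean(predict(fit, test_z.values) == test_z.labels)))
    return float(np.mean(accs))


def calibrate_separation(
    config: SynthConfig,
    target_accuracy: float,
    algorithm: str = "LDA",
    tolerance: float = 0.02,
    seed: int = 0,
    n_splits: int = 25,
    max_iter: int = 25,
    bracket: tuple[float, float] = (0.05, 6.0),
) -> tuple[float, float]:
    """Bisect the effect size until mean test accuracy matches ``target_accuracy``.

    Accuracy is a monotone (up to Monte Carlo jitter) function of the effect
    size, so a bisection on a fixed batch of seeded splits converges; returns
    ``(effect_size, achieved_accuracy)``.
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie strictly between 0.5 and 1")

    def acc_at(d: float) -> float:
        table, _ = generate_dataset(replace(config, effect_size=d))
        return _mean_split_accuracy(table, algorithm, n_splits, seed)

    lo, hi = bracket
    acc_lo, acc_hi = acc_at(lo), acc_at(hi)
    if not acc_lo < target_accuracy < acc_hi:
        raise ValueError(
            f"target {target_accuracy} not bracketed: accuracy spans "
            f"[{acc_lo:.3f}, {acc_hi:.3f}] over effect sizes {bracket}"
        )
    mid, acc_mid = lo, acc_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        acc_mid = acc_at(mid)
        if abs(acc_mid - target_accuracy) <= tolerance:
            return mid, acc_mid
        if acc_mid < target_accuracy:
            lo = mid
        else:
            hi = mid
    return mid, acc_mid


def reference_fixture(seed: int = 42) -> tuple[OmicsTable, list[str]]:
    """The canonical fixture: 159 x 24, 83/76 balance, 5 informative features.

    The effect size is pinned to :data:`REFERENCE_EFFECT_SIZE` so the LDA
    baseline test accuracy sits near 94% on a stratified 70/30 split.
    """
    config = SynthConfig(effect_size=REFERENCE_EFFECT_SIZE, seed=seed)
    return generate_dataset(config)
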