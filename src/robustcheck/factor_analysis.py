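"""Feature-significance screen for two-class measurement tables.

Three stages, each only removing features:

1. **Stability-of-significance FDR filter.**  For every feature, a two-group
   significance test is run on every leave-one-out (and, at depth 2, every
   leave-two-out) subsample.  The feature's FDR is the fraction of those
   p-values above 0.05 — a stability score, not the Benjamini–Hochberg
   procedure.  Features with FDR > 0.1 are dropped, leaving ``F'``.
2. **Loading-cluster pruning.**  PCA on the surviving features, component
   retention by Horn's parallel analysis, factor loadings ``A = P V^(-1/2)``,
   k-means on the loading rows with k chosen by the mean per-cluster
   silhouette ``s_c = (b_c - a_c) / max(a_c, b_c)``.  Tight clusters
   (``s_c`` above a threshold) contribute only their three most central
   members, removing near-duplicate features and leaving ``F''``.
3. **Logistic variance screen.**  A logistic model on ``F''`` gives weights
   ``w``; each feature's influence is probed by pushing standard-normal draws
   through its weight alone and measuring the output variance.  Variances are
   rescaled so the largest is 8 (±2.82 SD covers ~99.76% of a standard
   normal); features scoring below 2 are dropped, leaving ``F*``.

The result is a reference set of statistically meaningful features, to be
compared against a classifier's inputs — not a replacement for feature
subset selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .dataset_core import OmicsTable, standardize

__all__ = [
    "FdrResult",
    "LoadingMatrix",
    "ClusterSolution",
    "ScreenResult",
    "ScreenConfig",
    "choose_significance_test",
    "compute_feature_fdr",
    "filter_by_fdr",
    "horns_parallel",
    "pca_eigendecomposition",
    "compute_loadings",
    "cluster_loadings",
    "prune_tight_clusters",
    "logistic_variance_screen",
    "run_factor_analysis",
]


# ---------------------------------------------------------------------------
# rationale of the 0-8 variance scale


def variance_scale_sd(scale_max: float = 8.0) -> float:
    """Standard deviation corresponding to the top of the variance scale.

    The screen rescales output variances so the largest is 8; a variance of
    8 corresponds to sqrt(8) ~ 2.82 standard deviations.
    """
    return float(np.sqrt(scale_max))


def normal_coverage(n_sd: float) -> float:
    """Fraction of a standard normal below ``n_sd`` standard deviations.

    ``normal_coverage(sqrt(8))`` ~ 0.9976 — the coverage argument behind
    capping the variance scale at 8.
    """
    return float(stats.norm.cdf(n_sd))


# ---------------------------------------------------------------------------
# significance-test triage


def choose_significance_test(group_a, group_b, alpha: float = 0.05):
    """Pick and run the two-group test appropriate for the data at hand.

    Triage: Shapiro–Wilk normality on both groups at ``alpha``; if both pass,
    Levene's test decides between Student's (equal-variance) and Welch's
    t-test; any non-normal group falls through to the Mann–Whitney U test.
    A zero-variance group cannot take the parametric branch and is routed to
    the rank-based test as well.  Returns ``(test_name, two_sided_p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")

    def _normal(x):
        if np.ptp(x) == 0:
            return False  # degenerate group: route to the rank-based branch
        if x.size < 3:
            return True  # too few values for Shapiro-Wilk; normality not rejected
        return stats.shapiro(x).pvalue > alpha

    if _normal(a) and _normal(b):
        if stats.levene(a, b).pvalue > alpha:
            return "student_t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return "welch_t", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if np.ptp(np.concatenate([a, b])) == 0:
        return "mann_whitney_u", 1.0  # all values identical: no evidence either way
    return "mann_whitney_u", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# stage 1: leave-out FDR


@dataclass(frozen=True)
class FdrResult:
    """Per-feature stability-of-significance scores."""

    feature_names: tuple
    fdr: np.ndarray  # fraction of leave-out p-values > 0.05, in [0, 1]
    n_above: np.ndarray  # integer count of p-values > 0.05
    n_total: np.ndarray  # integer count of p-values computed
    leave_out_depth: int = 2


def compute_feature_fdr(
    table: OmicsTable,
    max_leave_out: int = 2,
    alpha: float = 0.05,
    max_pairs: int | None = None,
    seed: int = 0,
) -> FdrResult:
    """Leave-out significance stability per feature.

    For each feature the two-class test from :func:`choose_significance_test`
    is evaluated on every leave-one-out subsample (N p-values) and, at depth
    2, every leave-two-out subsample (N·(N−1)/2 more).  ``FDR_f`` is the
    exact ratio (# p-values > ``alpha``) / (total # p-values).  A leave-out
    set that empties a class is skipped and the total decremented.
    ``max_pairs`` subsamples the leave-two-out pairs (seeded) for large N.
    """
    if max_leave_out not in (1, 2):
        raise ValueError("max_leave_out must be 1 or 2")
    n = table.n_samples
    leave_outs: list[tuple[int, ...]] = [(i,) for i in range(n)]
    if max_leave_out == 2:
        pairs = list(combinations(range(n), 2))
        if max_pairs is not None and len(pairs) > max_pairs:
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(keep)]
        leave_outs.extend(pairs)

    labels = table.labels
    class_sizes = {c: int((labels == c).sum()) for c in (0, 1)}
    n_above = np.zeros(table.n_features, dtype=int)
    n_total = np.zeros(table.n_features, dtype=int)
    for left_out in leave_outs:
        dropped = {c: sum(1 for i in left_out if labels[i] == c) for c in (0, 1)}
        if any(class_sizes[c] - dropped[c] < 2 for c in (0, 1)):
            continue  # subsample would empty (or near-empty) a class
        mask = np.ones(n, dtype=bool)
        mask[list(left_out)] = False
        sub_labels = labels[mask]
        sub_values = table.values[mask]
        case = sub_labels == 1
        for j in range(table.n_features):
            _, p = choose_significance_test(sub_values[case, j], sub_values[~case, j])
            n_total[j] += 1
            if p > alpha:
                n_above[j] += 1
    if (n_total == 0).any():
        raise ValueError("no valid leave-out subsamples; classes too small")
    return FdrResult(
        feature_names=table.feature_names,
        fdr=n_above / n_total,
        n_above=n_above,
        n_total=n_total,
        leave_out_depth=max_leave_out,
    )


def filter_by_fdr(fdr: FdrResult, threshold: float = 0.1) -> list[str]:
    """Features with FDR at or below ``threshold`` (strictly greater removed)."""
    kept = [name for name, v in zip(fdr.feature_names, fdr.fdr) if v <= threshold]
    if not kept:
        raise ValueError(
            f"no significant features: every FDR exceeds {threshold}"
        )
    return kept


# ---------------------------------------------------------------------------
# stage 2: PCA, Horn's parallel analysis, loading clustering


def pca_eigendecomposition(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and matching eigenvectors of the feature
    covariance matrix of a standardized data matrix."""
    cov = np.cov(values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def horns_parallel(
    values: np.ndarray,
    n_iter: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Number of principal components whose eigenvalues beat random data.

    Observed eigenvalues are compared rank-by-rank against the chosen
    percentile of eigenvalues from ``n_iter`` same-shape standard-normal
    matrices; components are retained from the top while they exceed the
    null.  Raises if no component survives (no structure beyond noise).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100 for a stable percentile")
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    observed, _ = pca_eigendecomposition(values)
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, m))
    for i in range(n_iter):
        null[i], _ = pca_eigendecomposition(rng.standard_normal((n, m)))
    thresholds = np.percentile(null, percentile, axis=0)
    k = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            k += 1
        else:
            break
    if k == 0:
        raise ValueError(
            "parallel analysis retained no components: the data show no "
            "structure beyond same-shape random noise"
        )
    return k


@dataclass(frozen=True)
class LoadingMatrix:
    """Factor loadings of m features on k retained components."""

    A: np.ndarray  # m x k loadings
    P: np.ndarray  # m x k eigenvectors (columns orthonormal)
    V: np.ndarray  # k eigenvalues (diagonal of the eigenvalue matrix)
    exponent_convention: float = -0.5


def compute_loadings(
    eigvals: np.ndarray,
    eigvecs: np.ndarray,
    k: int,
    exponent_convention: float = -0.5,
) -> LoadingMatrix:
    """Loadings of the first ``k`` components: ``A = P V^exponent``.

    The default exponent is −1/2 (eigenvector columns shrunk by the root
    eigenvalue); the conventional factor-loading definition uses +1/2 and is
    available via ``exponent_convention=+0.5``.  Either way the column sign
    pattern of ``A`` matches ``P`` since ``V^(±1/2)`` is a positive diagonal.
    """
    if exponent_convention not in (-0.5, 0.5):
        raise ValueError("exponent_convention must be -0.5 or +0.5")
    v = np.asarray(eigvals, dtype=float)[:k]
    if (v <= 0).any():
        raise ValueError("all retained eigenvalues must be strictly positive")
    p = np.asarray(eigvecs, dtype=float)[:, :k]
    a = p * v**exponent_convention
    return LoadingMatrix(A=a, P=p, V=v, exponent_convention=exponent_convention)


@dataclass(frozen=True)
class ClusterSolution:
    """k-means grouping of loading rows with per-cluster silhouettes."""

    k: int
    labels: np.ndarray  # cluster id per feature, 0..k-1
    silhouettes: np.ndarray  # s_c per cluster
    within: np.ndarray  # a_c: mean pairwise distance within cluster c
    neighbor: np.ndarray  # b_c: mean distance to the nearest other cluster
    centers: np.ndarray = field(repr=False, default=None)


def _cluster_silhouettes(points: np.ndarray, labels: np.ndarray, k: int):
    """Per-cluster a_c, b_c and s_c = (b_c - a_c) / max(a_c, b_c)."""
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    a = np.zeros(k)
    b = np.zeros(k)
    s = np.zeros(k)
    for c in range(k):
        inside = np.flatnonzero(labels == c)
        if inside.size > 1:
            sub = dist[np.ix_(inside, inside)]
            a[c] = sub[np.triu_indices(inside.size, 1)].mean()
        cross = [
            dist[np.ix_(inside, np.flatnonzero(labels == other))].mean()
            for other in range(k)
            if other != c and (labels == other).any()
        ]
        b[c] = min(cross) if cross else 0.0
        denom = max(a[c], b[c])
        s[c] = (b[c] - a[c]) / denom if denom > 0 else 0.0
    return a, b, s


def cluster_loadings(
    loadings: LoadingMatrix | np.ndarray,
    k_range=None,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterSolution:
    """Group loading rows by k-means, choosing k by mean per-cluster silhouette.

    Points are the m rows of the loading matrix.  For each candidate k the
    best of ``n_restarts`` seeded k-means runs (by inertia) is scored by the
    mean of the per-cluster silhouettes; the highest-scoring k wins, ties to
    the smaller k.  Requires m >= 3 points.
    """
    points = loadings.A if isinstance(loadings, LoadingMatrix) else np.asarray(loadings, float)
    if points.ndim == 1:
        points = points[:, None]
    m = points.shape[0]
    if m < 3:
        raise ValueError("clustering needs at least 3 features")
    if k_range is None:
        k_range = range(2, min(10, m - 1) + 1)
    best = None
    for k in k_range:
        if not 2 <= k <= m - 1:
            raise ValueError(f"k={k} outside the valid range [2, {m - 1}]")
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(points)
        a, b, s = _cluster_silhouettes(points, labels, k)
        score = s.mean()
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels, a, b, s, km.cluster_centers_)
    _, k, labels, a, b, s, centers = best
    return ClusterSolution(k=k, labels=labels, silhouettes=s, within=a, neighbor=b, centers=centers)


def prune_tight_clusters(
    clusters: ClusterSolution,
    loadings: LoadingMatrix | np.ndarray,
    feature_names,
    silhouette_threshold: float = 0.5,
    keep_per_cluster: int = 3,
) -> list[str]:
    """Drop near-duplicate members of tight loading clusters.

    A cluster whose silhouette is at or above the threshold contributes only
    its ``keep_per_cluster`` members closest to the cluster centroid (ties
    broken by lowest feature index); looser clusters contribute everything.
    The returned list preserves the input feature order.
    """
    points = loadings.A if isinstance(loadings, LoadingMatrix) else np.asarray(loadings, float)
    if points.ndim == 1:
        points = points[:, None]
    feature_names = list(feature_names)
    keep = np.zeros(len(feature_names), dtype=bool)
    for c in range(clusters.k):
        members = np.flatnonzero(clusters.labels == c)
        if clusters.silhouettes[c] >= silhouette_threshold and members.size > keep_per_cluster:
            centroid = points[members].mean(axis=0)
            d = np.linalg.norm(points[members] - centroid, axis=1)
            order = np.lexsort((members, d))  # distance, then feature index
            members = members[order[:keep_per_cluster]]
        keep[members] = True
    return [name for name, k in zip(feature_names, keep) if k]


# ---------------------------------------------------------------------------
# stage 3: logistic variance screen


def logistic_variance_screen(
    values: np.ndarray,
    labels: np.ndarray,
    feature_names,
    n_draws: int = 100_000,
    seed: int = 0,
    variance_cut: float = 2.0,
    scale_max: float = 8.0,
):
    """Influence screen through a logistic model's weight vector.

    Fits logistic regression on the standardized features, then probes each
    feature f by drawing ``n_draws`` standard-normal values for f with every
    other feature zeroed and recording the variance of the continuous output
    ``w · x`` (analytically ``w_f^2``).  Variances are rescaled so the
    largest equals ``scale_max`` (8, i.e. ±2.82 SD of a standard normal);
    features below ``variance_cut`` (2) on that scale are deemed
    uninformative.  Returns ``(weights, scaled_variances, kept_features)``.
    """
    values = np.asarray(values, dtype=float)
    feature_names = list(feature_names)
    model = LogisticRegression(solver="saga", max_iter=5000, random_state=seed)
    model.fit(values, labels)
    w = model.coef_[0]
    if np.allclose(w, 0):
        raise ValueError("logistic model produced an all-zero weight vector")
    rng = np.random.default_rng(seed)
    raw = np.array([np.var(wf * rng.standard_normal(n_draws), ddof=1) for wf in w])
    scaled = scale_max * raw / raw.max()
    kept = [name for name, v in zip(feature_names, scaled) if v >= variance_cut]
    return w, scaled, kept


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class ScreenConfig:
    fdr_threshold: float = 0.1
    max_leave_out: int = 2
    alpha: float = 0.05
    max_pairs: int | None = None
    horn_iter: int = 1000
    horn_percentile: float = 95.0
    exponent_convention: float = -0.5
    silhouette_threshold: float = 0.5
    keep_per_cluster: int = 3
    n_draws: int = 100_000
    seed: int = 0


@dataclass(frozen=True)
class ScreenResult:
    """Everything the screen computed, stage by stage."""

    F_prime: list
    F_doubleprime: list
    F_star: list
    fdr: FdrResult
    loadings: LoadingMatrix | None
    clusters: ClusterSolution | None
    weights: np.ndarray
    scaled_variances: np.ndarray
    config: ScreenConfig

    def __post_init__(self):
        if not set(self.F_star) <= set(self.F_doubleprime) <= set(self.F_prime):
            raise ValueError("screen stages must be nested: F* ⊆ F'' ⊆ F'")


def run_factor_analysis(table: OmicsTable, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Run the full three-stage screen on a labelled table."""
    try:
        z_table, _ = standardize(table)
    except ValueError as exc:
        raise ValueError(f"standardization stage: {exc}") from exc

    try:
        fdr = compute_feature_fdr(
            z_table,
            max_leave_out=config.max_leave_out,
            alpha=config.alpha,
            max_pairs=config.max_pairs,
            seed=config.seed,
        )
        f_prime = filter_by_fdr(fdr, threshold=config.fdr_threshold)
    except ValueError as exc:
        raise ValueError(f"FDR stage: {exc}") from exc

    sub = z_table.select_features(f_prime)
    loadings = None
    clusters = None
    if len(f_prime) < 3:
        f_doubleprime = list(f_prime)  # too few features to cluster; pass through
    else:
        try:
            eigvals, eigvecs = pca_eigendecomposition(sub.values)
            k = horns_parallel(
                sub.values,
                n_iter=config.horn_iter,
                percentile=config.horn_percentile,
                seed=config.seed,
            )
            loadings = compute_loadings(
                eigvals, eigvecs, k, exponent_convention=config.exponent_convention
            )
            clusters = cluster_loadings(loadings, seed=config.seed)
            f_doubleprime = prune_tight_clusters(
                clusters,
                loadings,
                f_prime,
                silhouette_threshold=config.silhouette_threshold,
                keep_per_cluster=config.keep_per_cluster,
            )
        except ValueError as exc:
            raise ValueError(f"loading-cluster stage: {exc}") from exc

    sub2 = z_table.select_features(f_doubleprime)
    try:
        w, scaled, f_star = logistic_variance_screen(
            sub2.values,
            sub2.labels,
            f_doubleprime,
            n_draws=config.n_draws,
            seed=config.seed,
        )
    except ValueError as exc:
        raise ValueError(f"logistic variance stage: {exc}") from exc

    return ScreenResult(
        F_prime=f_prime,
        F_doubleprime=f_doubleprime,
        F_star=f_star,
        fdr=fdr,
        loadings=loadings,
        clusters=clusters,
        weights=w,
        scaled_variances=scaled,
        config=config,
    )
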