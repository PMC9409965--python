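"""Core data model for tabular omics measurements.

An :class:`OmicsTable` holds an N-samples x F-features matrix of continuous
measurements (e.g. metabolite concentrations) together with a binary class
label per sample (case = 1, control = 0).  All downstream stages — the
feature-significance screen, the noise engines and the Monte Carlo
protocols — consume and return this container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsTable",
    "StandardizationParams",
    "TrainTestSplit",
    "read_table",
    "write_table",
    "standardize",
    "make_split",
]


@dataclass(frozen=True)
class OmicsTable:
    """Samples-by-features measurement matrix with binary class labels.

    Parameters
    ----------
    values
        ``(N, F)`` float array of measurements.
    sample_ids
        ``N`` unique sample identifiers.
    feature_names
        ``F`` unique feature identifiers.
    labels
        ``N`` binary class indicators (case = 1, control = 0).
    metadata
        Free-form provenance dictionary (label coding, corruption specs, ...).
    """

    values: np.ndarray
    sample_ids: tuple
    feature_names: tuple
    labels: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples-by-features matrix")
        n, f = values.shape
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if f < 1:
            raise ValueError("need at least 1 feature")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.feature_names)) != f:
            raise ValueError("feature_names must be unique")
        if labels.shape != (n,):
            raise ValueError("labels length does not match row count")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "missing or non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )
        if set(np.unique(labels)) != {0, 1}:
            raise ValueError("labels must contain both classes coded as 0 and 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def select_features(self, names) -> "OmicsTable":
        """Restrict the table to the given features, preserving their order."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            values=self.values[:, idx],
            feature_names=tuple(names),
        )

    def select_samples(self, indices) -> "OmicsTable":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            labels=self.labels[idx],
        )

    def with_values(self, values: np.ndarray, **metadata) -> "OmicsTable":
        meta = dict(self.metadata)
        meta.update(metadata)
        return replace(self, values=np.asarray(values, dtype=float), metadata=meta)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "sample_id", list(self.sample_ids))
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale used to z-score a table (mu_f, sigma_f)."""

    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        stds = np.asarray(self.stds, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "stds", stds)
        if means.shape != stds.shape or means.ndim != 1:
            raise ValueError("means and stds must be 1-D arrays of equal length")
        if not (stds > 0).all():
            bad = int(np.argmin(stds))
            raise ValueError(
                f"constant feature (zero standard deviation) at column index {bad}; "
                "remove it before standardizing"
            )


@dataclass(frozen=True)
class TrainTestSplit:
    """Disjoint train/test index sets covering all samples."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float = 0.7
    seed: int = 0

    def __post_init__(self):
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        n = tr.size + te.size
        if set(tr) & set(te):
            raise ValueError("train and test indices overlap")
        if sorted(np.concatenate([tr, te])) != list(range(n)):
            raise ValueError("train and test indices must partition 0..N-1")
        if abs(tr.size - self.ratio * n) > 1 + 1e-9:
            raise ValueError("train size deviates from the requested ratio by more than one sample")


def read_table(path, label_column: str, delimiter: str | None = None) -> OmicsTable:
    """Load a CSV/TSV measurement table into an :class:`OmicsTable`.

    The file must have a header row, one sample per row, and a binary label
    column.  The delimiter is inferred from the extension (``.tsv``/``.txt``
    -> tab, otherwise comma) unless given explicitly.  An optional
    ``sample_id`` column supplies sample identifiers; otherwise row numbers
    are used.  Labels with two distinct values are coerced to {0, 1} by
    mapping the lexicographically smaller value to 0; the mapping is recorded
    in ``metadata['label_coding']``.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")

    raw_labels = df[label_column]
    distinct = sorted(raw_labels.astype(str).unique())
    if len(distinct) != 2:
        raise ValueError(
            f"label column {label_column!r} must have exactly two distinct values, "
            f"found {distinct}"
        )
    coding = {distinct[0]: 0, distinct[1]: 1}
    labels = raw_labels.astype(str).map(coding).to_numpy()

    if "sample_id" in df.columns:
        sample_ids = tuple(df["sample_id"].astype(str))
        feature_df = df.drop(columns=[label_column, "sample_id"])
    else:
        sample_ids = tuple(str(i) for i in range(len(df)))
        feature_df = df.drop(columns=[label_column])

    for col in feature_df.columns:
        numeric = pd.to_numeric(feature_df[col], errors="coerce")
        bad = numeric.isna() & feature_df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {feature_df[col][row]!r} at sample "
                f"{sample_ids[row]!r}, feature {col!r}"
            )
        na = numeric.isna()
        if na.any():
            row = int(na.idxmax())
            raise ValueError(f"missing value at sample {sample_ids[row]!r}, feature {col!r}")
        feature_df[col] = numeric

    return OmicsTable(
        values=feature_df.to_numpy(dtype=float),
        sample_ids=sample_ids,
        feature_names=tuple(str(c) for c in feature_df.columns),
        labels=labels,
        metadata={"label_coding": coding, "source": path, "label_column": label_column},
    )


def write_table(table: OmicsTable, path, label_column: str = "label") -> None:
    """Write a table as CSV/TSV (delimiter inferred from the extension)."""
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    table.to_frame(label_column=label_column).to_csv(path, sep=sep, index=False)


def standardize(
    table: OmicsTable, params: StandardizationParams | None = None
) -> tuple[OmicsTable, StandardizationParams]:
    """Z-score each feature column.

    When ``params`` is omitted, per-feature means and standard deviations
    (ddof=1) are computed from ``table`` itself; otherwise the supplied
    parameters are applied unchanged — this is how train-fitted scaling is
    carried onto a test partition without leakage.
    """
    if params is None:
        means = table.values.mean(axis=0)
        stds = table.values.std(axis=0, ddof=1)
        if not (stds > 0).all():
            bad = int(np.argmin(stds))
            raise ValueError(
                f"feature {table.feature_names[bad]!r} is constant; cannot standardize"
            )
        params = StandardizationParams(means=means, stds=stds)
    elif params.means.size != table.n_features:
        raise ValueError("standardization parameter length does not match feature count")
    z = (table.values - params.means) / params.stds
    return table.with_values(z, standardized=True), params


def make_split(
    table: OmicsTable, ratio: float = 0.7, seed: int = 0, stratified: bool = True
) -> TrainTestSplit:
    """Draw a seeded train/test split of the sample indices.

    Stratified mode (the default) allocates each class separately so the
    train partition preserves class proportions to within one sample per
    class.  In non-stratified mode a class absent from one partition is
    possible on small tables; that is logged as a warning, not an error.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = table.n_samples
    n_train = int(round(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)

    if stratified:
        train_parts = []
        # larger class allocated first so per-class rounding cancels overall
        classes = sorted(np.unique(table.labels), key=lambda c: -(table.labels == c).sum())
        remaining = n_train
        for i, c in enumerate(classes):
            idx = np.flatnonzero(table.labels == c)
            if i == len(classes) - 1:
                take = remaining
            else:
                take = int(round(ratio * idx.size))
            take = min(max(take, 1), idx.size - 1)
            train_parts.append(rng.choice(idx, size=take, replace=False))
            remaining -= take
        train = np.sort(np.concatenate(train_parts))
    else:
        train = np.sort(rng.choice(n, size=n_train, replace=False))

    test = np.setdiff1d(np.arange(n), train)
    for name, part in (("train", train), ("test", test)):
        if np.unique(table.labels[part]).size < 2:
            msg = f"{name} partition contains a single class (seed={seed})"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
    return TrainTestSplit(train_indices=train, test_indices=test, ratio=ratio, seed=seed)
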