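"""Feature-level corruption engines.

Two noise models for continuous measurement tables, both operating on the
raw (pre-standardization) scale:

* **replacement noise** — a proportion ``p`` of each column's values is
  replaced by draws from a normal fitted to that column's clean values
  (``N(mu_f, sigma_f^2)``).  At ``p = 1`` the column carries no class
  information and any classifier decays to chance.
* **dampened Gaussian noise** — zero-mean additive noise with standard
  deviation ``s * sigma_f`` per column, ``s`` the dampening factor; models
  systematic measurement error.  Negative corrupted values are clipped to
  zero for concentration data.

Column statistics always come from the uncorrupted input, with the
sample (N-1) standard deviation.  Each (seed, column) pair gets an
independent random stream so sweeps are reproducible rep-by-rep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset_core import OmicsTable

logger = logging.getLogger(__name__)

__all__ = ["NoiseSpec", "replacement_corrupt", "gaussian_corrupt", "corrupt"]


@dataclass(frozen=True)
class NoiseSpec:
    """A corruption recipe.

    ``level`` is the replacement proportion ``p`` for kind ``"replacement"``
    or the dampening factor ``s`` for kind ``"gaussian"``.  ``clip_negative``
    clips corrupted values at zero (concentration data); it defaults on for
    Gaussian noise and off for replacement noise, where the fitted-normal
    draws are left untouched unless requested.
    """

    kind: str
    level: float
    clip_negative: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("replacement", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0 <= self.level <= 1:
            raise ValueError("noise level must lie in [0, 1]")


def _column_streams(seed: int, n_columns: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n_columns)]


def replacement_corrupt(table: OmicsTable, p: float, seed: int = 0,
                        clip_negative: bool = False) -> OmicsTable:
    """Replace a proportion ``p`` of each column with fitted-normal draws.

    Per column ``f``: fit ``mu_f`` and ``sigma_f`` (ddof=1) on the clean
    values, round ``v = p * N`` half-to-even, pick ``v`` row positions
    uniformly without replacement, and overwrite them with independent
    ``N(mu_f, sigma_f^2)`` draws.  Labels, identifiers and shape are
    untouched; ``p = 0`` returns the input values bit-exactly.
    """
    if not 0 <= p <= 1:
        raise ValueError("replacement proportion p must lie in [0, 1]")
    values = table.values.copy()
    n, f = values.shape
    v = int(np.round(p * n))  # round-half-to-even, constant across columns
    if v == 0:
        return table.with_values(values, noise={"kind": "replacement", "level": p, "seed": seed})
    streams = _column_streams(seed, f)
    mus = table.values.mean(axis=0)
    sigmas = table.values.std(axis=0, ddof=1)
    for j in range(f):
        rng = streams[j]
        rows = rng.choice(n, size=v, replace=False)
        if sigmas[j] == 0:
            logger.info("constant column %r: replacement draws equal its mean", table.feature_names[j])
            values[rows, j] = mus[j]
        else:
            values[rows, j] = rng.normal(mus[j], sigmas[j], size=v)
    if clip_negative:
        np.clip(values, 0.0, None, out=values)
    return table.with_values(values, noise={"kind": "replacement", "level": p, "seed": seed})


def gaussian_corrupt(table: OmicsTable, s: float, clip_negative: bool = True,
                     seed: int = 0) -> OmicsTable:
    """Add zero-mean Gaussian noise with per-column SD ``s * sigma_f``.

    With ``clip_negative`` on, corrupted values below zero are set to zero.
    ``s = 0`` returns the input values bit-exactly.
    """
    if s < 0:
        raise ValueError("dampening factor s must be non-negative")
    values = table.values.copy()
    n, f = values.shape
    if s == 0:
        return table.with_values(values, noise={"kind": "gaussian", "level": s, "seed": seed})
    sigmas = table.values.std(axis=0, ddof=1)
    streams = _column_streams(seed, f)
    for j in range(f):
        values[:, j] += streams[j].normal(0.0, s * sigmas[j], size=n)
    if clip_negative:
        np.clip(values, 0.0, None, out=values)
    return table.with_values(values, noise={"kind": "gaussian", "level": s, "seed": seed})


def corrupt(table: OmicsTable, spec: NoiseSpec) -> OmicsTable:
    """Dispatch a :class:`NoiseSpec` to the matching engine."""
    if spec.kind == "replacement":
        clip = False if spec.clip_negative is None else spec.clip_negative
        return replacement_corrupt(table, spec.level, seed=spec.seed, clip_negative=clip)
    if spec.kind == "gaussian":
        clip = True if spec.clip_negative is None else spec.clip_negative
        return gaussian_corrupt(table, spec.level, clip_negative=clip, seed=spec.seed)
    raise ValueError(f"unknown noise kind {spec.kind!r}")
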