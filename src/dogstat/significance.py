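"""Empirical null distributions and p-values.

Two routes to a null distribution of an outlier statistic:

* **Simulation panel** — a large set of genes that are null by construction
  (no planted outliers); the statistic over the panel *is* the null sample.
* **Control resampling** — for real data, new control and experimental
  replicates are drawn with replacement from each gene's control values only
  (assumed outlier-free), 100 rounds per gene by default, and pooled across
  genes.

A gene's empirical p-value is the proportion of null statistics that strictly
exceed its observed statistic; p = 0 is representable when the observed value
tops the whole pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datamodel import DegenerateScaleError, ExpressionDataset

__all__ = [
    "NullDistribution",
    "null_from_panel",
    "null_from_control_resampling",
    "empirical_pvalues",
]

StatFn = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class NullDistribution:
    """A pool of null statistic values."""

    values: np.ndarray
    source: str  # "simulation_panel" or "control_resampling"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("null distribution must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("null statistics must be finite")

    @property
    def n(self) -> int:
        return self.values.size


def _safe_stat(stat_fn: StatFn, x: np.ndarray, y: np.ndarray, what: str) -> float:
    try:
        out = stat_fn(x, y)
    except DegenerateScaleError:
        warnings.warn(f"degenerate scale on {what}; statistic set to 0", stacklevel=3)
        return 0.0
    return float(getattr(out, "statistic", out))


def null_from_panel(panel: ExpressionDataset, stat_fn: StatFn) -> NullDistribution:
    """Null statistics from a panel of by-construction null genes.

    ``stat_fn(x, y)`` may return a float or any object with a ``statistic``
    attribute.  Genes with a degenerate scale contribute 0 with a warning.
    """
    values = np.array(
        [_safe_stat(stat_fn, p.x, p.y, f"panel gene {gid}")
         for gid, p in panel.iter_genes()]
    )
    return NullDistribution(values=values, source="simulation_panel")


def null_from_control_resampling(
    ds: ExpressionDataset,
    stat_fn: StatFn,
    n_resample: int = 100,
    seed: int | None = None,
) -> NullDistribution:
    """Null statistics by resampling each gene's controls with replacement.

    Per gene and round, fresh control and experimental vectors of the
    original sizes are drawn from that gene's control values only, and the
    statistic recomputed; all genes × rounds are pooled.
    """
    rng = np.random.default_rng(seed)
    n_x, n_y = ds.n_control, ds.n_experimental
    values = np.empty(ds.n_genes * n_resample)
    pos = 0
    for gid, pair in ds.iter_genes():
        draws = rng.choice(pair.x, size=(n_resample, n_x + n_y), replace=True)
        for r in range(n_resample):
            values[pos] = _safe_stat(
                stat_fn, draws[r, :n_x], draws[r, n_x:], f"gene {gid} resample {r}"
            )
            pos += 1
    return NullDistribution(values=values, source="control_resampling")


def empirical_pvalues(
    observed: np.ndarray, null: NullDistribution | np.ndarray
) -> np.ndarray:
    """p_g = #{null > observed_g} / n (strict exceedance; ties do not count)."""
    null_values = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    null_sorted = np.sort(null_values)
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    exceed = null_sorted.size - np.searchsorted(null_sorted, observed, side="right")
    return exceed / null_sorted.size
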