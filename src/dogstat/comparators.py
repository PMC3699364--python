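"""Classical outlier statistics for two-group expression data.

Implements the five cancer-outlier-profile statistics used as baselines for
hDEG detection:

* **COPA** — (q_r(y) − λ)/σ, the distance of the r-th percentile of the
  experimental samples from the pooled median, in robust-scale units.
* **OS** (outlier sum) — sum of standardized experimental values exceeding
  q75 + IQR of the *pooled* samples.
* **ORT** (outlier robust t) — the same sum with the threshold computed from
  the *control* samples only.
* **MOST** (maximum ordered subset t) — the ordered-subset sum S_k over the
  top-k experimental values, normalized by its null mean and SD and maximized
  over k.
* **LSOSS** (least sum of ordered subset squares) — k(ȳ(k) − x̄)/S where k
  minimizes the within-cluster variance of the two-way split of the sorted
  experimental values and S is the pooled standard deviation of the resulting
  groups.

Throughout, λ is the pooled median and σ = 1.4826 × MAD about λ.  All
percentiles use linear interpolation between order statistics
(h = (n − 1)p + 1, numpy's default).  Per-gene functions raise
:class:`~dogstat.datamodel.DegenerateScaleError` on zero scale; the matrix
variants used for large panels set such genes to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .datamodel import DegenerateScaleError, ExpressionDataset

MAD_CONSTANT = 1.4826  # Gaussian consistency factor for the MAD

COMPARATOR_NAMES = ("copa", "os", "ort", "most", "lsoss")

__all__ = [
    "COMPARATOR_NAMES",
    "MAD_CONSTANT",
    "MonteCarloSpec",
    "OutlierStatResult",
    "location_scale",
    "copa_stat",
    "os_stat",
    "ort_stat",
    "most_stat",
    "lsoss_stat",
    "comparator_matrix",
    "apply_comparator",
]


@dataclass(frozen=True)
class MonteCarloSpec:
    """Monte-Carlo settings for MOST's null normalization constants."""

    n_draws: int = 2000
    seed: int = 20130305


@dataclass
class OutlierStatResult:
    """Outcome of one outlier statistic on a single gene.

    ``outlier_indices`` index into the experimental vector ``y`` (empty for
    COPA, which names no outliers); ``k`` is the chosen subset size for
    MOST/LSOSS, ``None`` otherwise.
    """

    statistic: float
    outlier_indices: np.ndarray
    k: int | None = None


def location_scale(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled median λ and MAD scale σ = 1.4826 × med|z − λ|, z = x ∪ y."""
    z = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    if z.size < 4:
        raise ValueError("need a combined sample of at least 4 values")
    lam = float(np.median(z))
    sigma = MAD_CONSTANT * float(np.median(np.abs(z - lam)))
    if sigma == 0.0:
        raise DegenerateScaleError("pooled MAD is zero (constant-median data)")
    return lam, sigma


def copa_stat(x: np.ndarray, y: np.ndarray, r: float = 90.0) -> OutlierStatResult:
    """COPA: (q_r(y) − λ)/σ.  ``r`` is a percentile in (0, 100)."""
    if not 0.0 < r < 100.0:
        raise ValueError("percentile r must lie in (0, 100)")
    lam, sigma = location_scale(x, y)
    qr = float(np.percentile(np.asarray(y, float), r))
    return OutlierStatResult(
        statistic=(qr - lam) / sigma, outlier_indices=np.empty(0, dtype=int)
    )


def _outlier_sum(
    y: np.ndarray, lam: float, sigma: float, threshold: float
) -> OutlierStatResult:
    y = np.asarray(y, float)
    idx = np.nonzero(y > threshold)[0]
    stat = float(((y[idx] - lam) / sigma).sum()) if idx.size else 0.0
    return OutlierStatResult(statistic=stat, outlier_indices=idx)


def os_stat(x: np.ndarray, y: np.ndarray) -> OutlierStatResult:
    """Outlier sum with the pooled q75 + IQR outlier threshold."""
    lam, sigma = location_scale(x, y)
    z = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    q25, q75 = np.percentile(z, [25.0, 75.0])
    return _outlier_sum(y, lam, sigma, float(q75 + (q75 - q25)))


def ort_stat(x: np.ndarray, y: np.ndarray) -> OutlierStatResult:
    """Outlier sum with the control-only q75 + IQR threshold."""
    lam, sigma = location_scale(x, y)
    x = np.asarray(x, float)
    q25, q75 = np.percentile(x, [25.0, 75.0])
    return _outlier_sum(y, lam, sigma, float(q75 + (q75 - q25)))


@lru_cache(maxsize=32)
def _most_null_moments(
    n_x: int, n_y: int, n_draws: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Null mean m_k and SD s_k of the ordered-subset sums S_k, k = 1..n_y.

    Estimated once per sample-size pair by drawing standard-normal
    pseudo-samples and replaying the S_k computation.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, n_x + n_y))
    lam = np.median(z, axis=1, keepdims=True)
    sigma = MAD_CONSTANT * np.median(np.abs(z - lam), axis=1, keepdims=True)
    y_desc = np.sort(z[:, n_x:], axis=1)[:, ::-1]
    s = np.cumsum((y_desc - lam) / sigma, axis=1)
    return s.mean(axis=0), s.std(axis=0, ddof=1)


def most_stat(
    x: np.ndarray, y: np.ndarray, mc: MonteCarloSpec = MonteCarloSpec()
) -> OutlierStatResult:
    """MOST: max over k of the normalized ordered-subset sum (S_k − m_k)/s_k."""
    lam, sigma = location_scale(x, y)
    y = np.asarray(y, float)
    order = np.argsort(y)[::-1]
    s_k = np.cumsum((y[order] - lam) / sigma)
    m, s = _most_null_moments(len(x), len(y), mc.n_draws, mc.seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (s_k - m) / s
    if (s == 0).any():
        warnings.warn("excluding subset sizes with zero null SD", stacklevel=2)
        norm = np.where(s == 0, -np.inf, norm)
    k = int(np.argmax(norm)) + 1
    return OutlierStatResult(
        statistic=float(norm[k - 1]), outlier_indices=np.sort(order[:k]), k=k
    )


def lsoss_stat(x: np.ndarray, y: np.ndarray) -> OutlierStatResult:
    """LSOSS: k(ȳ(k) − x̄)/S with k minimizing the within-cluster variance.

    The sorted experimental vector is split into a top-k part and the rest;
    k ∈ 1..len(y)−1 is chosen to minimize the total within-group sum of
    squares.  S is the pooled SD (df = n₁ + n₂ − 2) of the group
    {controls ∪ non-outlier experimentals} versus {top-k experimentals}.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.size < 2:
        raise ValueError("LSOSS needs at least 2 experimental samples")
    order = np.argsort(y)[::-1]
    y_desc = y[order]
    ks = np.arange(1, y.size)
    c1 = np.cumsum(y_desc)
    c2 = np.cumsum(y_desc**2)
    tot1, tot2 = c1[-1], c2[-1]
    ss_top = c2[:-1] - c1[:-1] ** 2 / ks
    n_bot = y.size - ks
    ss_bot = (tot2 - c2[:-1]) - (tot1 - c1[:-1]) ** 2 / n_bot
    k = int(np.argmin(ss_top + ss_bot)) + 1

    top = y_desc[:k]
    rest = np.concatenate([x, y_desc[k:]])
    ss1 = float(((rest - rest.mean()) ** 2).sum())
    ss2 = float(((top - top.mean()) ** 2).sum())
    df = rest.size + top.size - 2
    pooled_sd = np.sqrt((ss1 + ss2) / df)
    if pooled_sd == 0.0:
        raise DegenerateScaleError("pooled SD is zero")
    stat = k * (top.mean() - x.mean()) / pooled_sd
    return OutlierStatResult(
        statistic=float(stat), outlier_indices=np.sort(order[:k]), k=k
    )


# ---------------------------------------------------------------------------
# Vectorized matrix variants — same definitions applied row-wise, used for
# large simulated panels where per-gene Python dispatch would dominate.
# Degenerate-scale genes get statistic 0 with a warning instead of an error.
# ---------------------------------------------------------------------------


def _location_scale_matrix(X: np.ndarray, Y: np.ndarray):
    Z = np.hstack([X, Y])
    lam = np.median(Z, axis=1)
    sigma = MAD_CONSTANT * np.median(np.abs(Z - lam[:, None]), axis=1)
    bad = sigma == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero MAD scale; statistic set to 0",
            stacklevel=3,
        )
        sigma = np.where(bad, 1.0, sigma)
    return lam, sigma, bad


def _copa_matrix(X, Y, r=90.0):
    lam, sigma, bad = _location_scale_matrix(X, Y)
    qr = np.percentile(Y, r, axis=1)
    return np.where(bad, 0.0, (qr - lam) / sigma)


def _sum_above(Y, lam, sigma, thr):
    excess = np.where(Y > thr[:, None], Y - lam[:, None], 0.0)
    return excess.sum(axis=1) / sigma


def _os_matrix(X, Y):
    lam, sigma, bad = _location_scale_matrix(X, Y)
    Z = np.hstack([X, Y])
    q25, q75 = np.percentile(Z, [25.0, 75.0], axis=1)
    return np.where(bad, 0.0, _sum_above(Y, lam, sigma, q75 + (q75 - q25)))


def _ort_matrix(X, Y):
    lam, sigma, bad = _location_scale_matrix(X, Y)
    q25, q75 = np.percentile(X, [25.0, 75.0], axis=1)
    return np.where(bad, 0.0, _sum_above(Y, lam, sigma, q75 + (q75 - q25)))


def _most_matrix(X, Y, mc: MonteCarloSpec = MonteCarloSpec()):
    lam, sigma, bad = _location_scale_matrix(X, Y)
    y_desc = np.sort(Y, axis=1)[:, ::-1]
    s_k = np.cumsum((y_desc - lam[:, None]) / sigma[:, None], axis=1)
    m, s = _most_null_moments(X.shape[1], Y.shape[1], mc.n_draws, mc.seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(s > 0, (s_k - m) / s, -np.inf)
    return np.where(bad, 0.0, norm.max(axis=1))


def _lsoss_matrix(X, Y):
    y_desc = np.sort(Y, axis=1)[:, ::-1]
    n_y = Y.shape[1]
    ks = np.arange(1, n_y)
    c1 = np.cumsum(y_desc, axis=1)
    c2 = np.cumsum(y_desc**2, axis=1)
    ss_top = c2[:, :-1] - c1[:, :-1] ** 2 / ks
    ss_bot = (c2[:, -1:] - c2[:, :-1]) - (c1[:, -1:] - c1[:, :-1]) ** 2 / (n_y - ks)
    k = np.argmin(ss_top + ss_bot, axis=1) + 1

    rows = np.arange(Y.shape[0])
    top_sum = c1[rows, k - 1]
    top_sq = c2[rows, k - 1]
    top_mean = top_sum / k
    ss2 = top_sq - top_sum**2 / k
    rest_sum = X.sum(axis=1) + (c1[:, -1] - top_sum)
    rest_sq = (X**2).sum(axis=1) + (c2[:, -1] - top_sq)
    n1 = X.shape[1] + n_y - k
    ss1 = rest_sq - rest_sum**2 / n1
    pooled_sd = np.sqrt(np.maximum(ss1 + ss2, 0.0) / (n1 + k - 2))
    bad = pooled_sd == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero pooled SD; statistic set to 0",
            stacklevel=2,
        )
        pooled_sd = np.where(bad, 1.0, pooled_sd)
    stat = k * (top_mean - X.mean(axis=1)) / pooled_sd
    return np.where(bad, 0.0, stat)


_MATRIX_FNS = {
    "copa": _copa_matrix,
    "os": _os_matrix,
    "ort": _ort_matrix,
    "most": _most_matrix,
    "lsoss": _lsoss_matrix,
}

_GENE_FNS = {
    "copa": copa_stat,
    "os": os_stat,
    "ort": ort_stat,
    "most": most_stat,
    "lsoss": lsoss_stat,
}


def comparator_matrix(name: str, X: np.ndarray, Y: np.ndarray, **params) -> np.ndarray:
    """Row-wise statistic over control matrix ``X`` and experimental matrix ``Y``."""
    if name not in _MATRIX_FNS:
        raise ValueError(f"unknown statistic {name!r}; choose from {COMPARATOR_NAMES}")
    return _MATRIX_FNS[name](np.asarray(X, float), np.asarray(Y, float), **params)


def apply_comparator(name: str, ds: ExpressionDataset, **params) -> np.ndarray:
    """Apply one comparator statistic to every gene of a dataset."""
    mask = ds.control_mask
    return comparator_matrix(name, ds.values[:, mask], ds.values[:, ~mask], **params)
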