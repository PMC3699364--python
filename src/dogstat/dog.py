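"""DOG — detecting outliers via gap.

A heterogeneously differentially expressed gene (hDEG) shows high expression
in only a few experimental samples (the outliers) while the remaining
experimental and all control samples form a tight low-expression cluster.
DOG detects the outliers sequentially instead of modelling them:

1. *Candidate split.* The pooled values z = x ∪ y are divided at a cutoff —
   the control maximum by default, or a control percentile ς when the
   controls themselves may be contaminated — into the ascending candidate
   list z⁺ and the tight-cluster seed z⁻.
2. *Tight-cluster fit.* The cluster is modelled as Gaussian N(μ, 1/β) with
   conjugate priors μ ~ N(μ₀, 1/β₀) and σ² = 1/β ~ InvGamma(a, b).  The MAP
   estimate is obtained by cycling the three update equations

       1/β  = (Σ (z_j − μ)² + 2b) / (n + 2a + 2)
       μ    = (β Σ z_j + β₀ μ₀) / (β n + β₀)
       1/β₀ = ((μ − μ₀)²/2 + b) / (a + 1)

   over the current z⁻ until a fixed point, with μ₀ = med(z⁻).
3. *Detection / absorption.* The smallest remaining candidate z₁⁺ is tested
   with t = (z₁⁺ − μ)√β.  If t exceeds the critical threshold t_α the
   algorithm stops and the whole remaining z⁺ is declared outliers;
   otherwise z₁⁺ is absorbed into z⁻ and the cluster is refitted.  By
   default t_α is the upper-α quantile of the *maximum* of n standard-normal
   draws, Φ⁻¹((1−α)^{1/n}) with n the current cluster size (≈ 3.14 at
   α = 0.05, n = 60): the candidate is declared an outlier only if it would
   be surprising as the largest member of a cluster that big, which holds
   the per-gene false-detection rate near α regardless of cluster size.
   The plain upper-α normal or Student-t quantiles are available as options.

A gene with non-empty final z⁺ is classified as an hDEG; its summary
statistic is the mean of the standardized outlier values, which favours
hDEGs with few but extreme outliers.

The prior scale ``b`` is shared across a dataset: the maximum per-gene
pooled sample variance (a deliberately heavy-tailed variance prior — large
``b`` with a = 1 keeps absorption permissive so that only clear gaps fire).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import ExpressionDataset, GenePair, ResultTable

__all__ = [
    "DogHyper",
    "TightClusterState",
    "DogResult",
    "ConvergenceError",
    "split_candidates",
    "update_tight_cluster",
    "dog_detect",
    "run_dog_dataset",
    "dog_statistics",
    "max_gene_variance",
]


class ConvergenceError(RuntimeError):
    """MAP fixed-point iteration failed to converge; carries the last state."""

    def __init__(self, msg: str, state: "TightClusterState"):
        super().__init__(msg)
        self.state = state


@dataclass(frozen=True)
class DogHyper:
    """Hyperparameters of the DOG tight-cluster model.

    Parameters
    ----------
    alpha
        Tail probability for the outlier test; t_α is the upper-α quantile.
    a, b
        Inverse-gamma prior on the cluster variance.  ``b=None`` means
        "derive from the data": the maximum per-gene pooled sample variance
        of the analyzed dataset (for a single gene, that gene's variance).
    beta0_init
        Initial precision of the prior on μ; β₀ is then updated recursively
        and carried across absorption steps within a gene.
    mode
        ``max_control``: candidate cutoff is max(x).  ``control_percentile``:
        cutoff is the ``control_percentile``-th percentile of x, letting
        contaminated controls contribute candidates too.
    t_dist
        Reference distribution for the critical threshold t_α, with
        n = current tight-cluster size:
        ``max_normal`` (default) — upper-α quantile of the maximum of n
        standard-normal draws, Φ⁻¹((1−α)^{1/n});
        ``normal`` — plain standard-normal upper-α quantile;
        ``student`` — Student-t upper-α quantile with n − 1 df.
    """

    alpha: float = 0.05
    a: float = 1.0
    b: float | None = None
    beta0_init: float = 0.1
    mode: str = "max_control"
    control_percentile: float = 90.0
    t_dist: str = "max_normal"
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.a <= 0 or (self.b is not None and self.b <= 0) or self.beta0_init <= 0:
            raise ValueError("a, b and beta0_init must be positive")
        if self.mode not in ("max_control", "control_percentile"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "control_percentile" and not 0 < self.control_percentile < 100:
            raise ValueError("control_percentile must lie in (0, 100)")
        if self.t_dist not in ("max_normal", "normal", "student"):
            raise ValueError(f"unknown t_dist {self.t_dist!r}")

    def threshold(self, n: int) -> float:
        """Critical threshold t_α for a cluster of size n."""
        if self.t_dist == "student":
            return float(stats.t.ppf(1.0 - self.alpha, df=max(n - 1, 1)))
        if self.t_dist == "max_normal":
            return float(stats.norm.ppf((1.0 - self.alpha) ** (1.0 / max(n, 1))))
        return float(stats.norm.ppf(1.0 - self.alpha))

    def threshold_table(self, n_max: int) -> np.ndarray:
        """t_α for every cluster size 0..n_max (index = n)."""
        return np.array([self.threshold(n) for n in range(n_max + 1)])


@dataclass
class TightClusterState:
    """Posterior state of the non-outlier cluster."""

    mu: float
    beta: float
    beta0: float
    mu0: float
    n: int

    @property
    def sigma2(self) -> float:
        return 1.0 / self.beta


@dataclass
class DogResult:
    """Per-gene DOG outcome."""

    z_plus: np.ndarray
    outlier_sample_indices: np.ndarray
    z_minus_size: int
    M: int
    t_values: np.ndarray
    statistic: float
    is_hdeg: bool
    state: TightClusterState | None
    trace: list[tuple[float, float, str]] = field(default_factory=list)


def max_gene_variance(*datasets: ExpressionDataset) -> float:
    """Maximum pooled per-gene sample variance (ddof=1) across datasets."""
    out = 0.0
    for ds in datasets:
        out = max(out, float(np.var(ds.values, axis=1, ddof=1).max()))
    if out <= 0:
        raise ValueError("all genes are constant; variance prior b would be 0")
    return out


def split_candidates(
    pair: GenePair, hyper: DogHyper
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition z = x ∪ y into the tight-cluster seed and candidate outliers.

    Returns ``(z_minus, z_plus, z_plus_indices)`` with z⁺ ascending and its
    companion array giving positions into the pooled vector (controls first).
    Values strictly above the cutoff are candidates.
    """
    z = pair.z
    if hyper.mode == "max_control":
        cutoff = float(pair.x.max())
    else:
        cutoff = float(np.percentile(pair.x, hyper.control_percentile))
    plus_mask = z > cutoff
    if plus_mask.all():
        raise ValueError("all values above the candidate cutoff; empty tight cluster")
    idx = np.nonzero(plus_mask)[0]
    order = np.argsort(z[idx], kind="stable")
    return z[~plus_mask], z[idx[order]], idx[order]


def _map_fit(
    n: int,
    s1: float,
    s2: float,
    mu0: float,
    beta0: float,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
) -> tuple[float, float, float, bool]:
    """MAP fixed point for (μ, β, β₀) given Σz, Σz² of the cluster.

    Cycles β → μ → β₀ starting from μ = μ₀ and the carried β₀, until the
    largest absolute change is below ``tol``.
    """
    mu = mu0
    prev_mu = mu0
    prev_beta = math.inf
    prev_beta0 = beta0
    denom = n + 2.0 * a + 2.0
    for _ in range(max_iter):
        beta = denom / (s2 - 2.0 * mu * s1 + n * mu * mu + 2.0 * b)
        mu = (beta * s1 + beta0 * mu0) / (beta * n + beta0)
        beta0 = (a + 1.0) / ((mu - mu0) ** 2 / 2.0 + b)
        if (
            abs(mu - prev_mu) < tol
            and abs(beta - prev_beta) < tol
            and abs(beta0 - prev_beta0) < tol
        ):
            return mu, beta, beta0, True
        prev_mu, prev_beta, prev_beta0 = mu, beta, beta0
    return mu, beta, beta0, False


def update_tight_cluster(
    z_minus: np.ndarray,
    hyper: DogHyper,
    state: TightClusterState | None = None,
    b: float | None = None,
) -> TightClusterState:
    """Fit the tight-cluster posterior on ``z_minus`` by MAP iteration.

    μ₀ is the median of ``z_minus``; β₀ starts from the previous state when
    given (absorption carries it forward) or from ``hyper.beta0_init``.
    """
    z_minus = np.asarray(z_minus, dtype=float)
    if z_minus.size == 0:
        raise ValueError("tight cluster must be non-empty")
    if b is None:
        b = hyper.b
    if b is None:
        raise ValueError("prior scale b is required (see max_gene_variance)")
    mu0 = float(np.median(z_minus))
    beta0 = state.beta0 if state is not None else hyper.beta0_init
    mu, beta, beta0, ok = _map_fit(
        z_minus.size,
        float(z_minus.sum()),
        float((z_minus**2).sum()),
        mu0,
        beta0,
        hyper.a,
        b,
        hyper.tol,
        hyper.max_iter,
    )
    new = TightClusterState(mu=mu, beta=beta, beta0=beta0, mu0=mu0, n=z_minus.size)
    if not ok:
        raise ConvergenceError(
            f"MAP iteration did not converge in {hyper.max_iter} steps", new
        )
    return new


def _median_of_prefix(sorted_values: np.ndarray, n: int) -> float:
    """Median of the first n entries of an ascending array."""
    half = n >> 1
    if n & 1:
        return float(sorted_values[half])
    return 0.5 * (float(sorted_values[half - 1]) + float(sorted_values[half]))


def dog_detect(
    pair: GenePair, hyper: DogHyper, b: float | None = None, keep_trace: bool = True
) -> DogResult:
    """Run DOG on a single gene.

    ``b`` overrides ``hyper.b``; when both are None the gene's own pooled
    sample variance is used (single-gene analysis).
    """
    if b is None:
        b = hyper.b
    if b is None:
        b = float(np.var(pair.z, ddof=1))
        if b <= 0:
            raise ValueError("constant gene; variance prior b would be 0")
    z_minus, z_plus, z_plus_idx = split_candidates(pair, hyper)
    zm_sorted = np.sort(z_minus)
    # all candidates exceed the cutoff ≥ every tight value, so the
    # concatenation is globally ascending and prefix medians are O(1)
    allv = np.concatenate([zm_sorted, z_plus])
    n = zm_sorted.size
    s1 = float(zm_sorted.sum())
    s2 = float((zm_sorted**2).sum())
    beta0 = hyper.beta0_init
    trace: list[tuple[float, float, str]] = []
    state: TightClusterState | None = None

    for i in range(z_plus.size):
        mu0 = _median_of_prefix(allv, n)
        mu, beta, beta0, ok = _map_fit(
            n, s1, s2, mu0, beta0, hyper.a, b, hyper.tol, hyper.max_iter
        )
        state = TightClusterState(mu=mu, beta=beta, beta0=beta0, mu0=mu0, n=n)
        if not ok:
            raise ConvergenceError(
                f"MAP iteration did not converge in {hyper.max_iter} steps", state
            )
        cand = float(z_plus[i])
        t = (cand - mu) * math.sqrt(beta)
        if t > hyper.threshold(n):
            if keep_trace:
                trace.append((cand, t, "detect"))
            t_values = (z_plus[i:] - mu) * math.sqrt(beta)
            return DogResult(
                z_plus=z_plus[i:].copy(),
                outlier_sample_indices=z_plus_idx[i:].copy(),
                z_minus_size=n,
                M=int(z_plus.size - i),
                t_values=t_values,
                statistic=float(t_values.mean()),
                is_hdeg=True,
                state=state,
                trace=trace,
            )
        if keep_trace:
            trace.append((cand, t, "absorb"))
        n += 1
        s1 += cand
        s2 += cand * cand

    return DogResult(
        z_plus=np.empty(0),
        outlier_sample_indices=np.empty(0, dtype=int),
        z_minus_size=n,
        M=0,
        t_values=np.empty(0),
        statistic=0.0,
        is_hdeg=False,
        state=state,
        trace=trace,
    )


def _dog_row(
    row_sorted: np.ndarray,
    n_minus: int,
    b: float,
    thresholds: np.ndarray,
    a: float,
    beta0_init: float,
    tol: float,
    max_iter: int,
) -> tuple[float, int]:
    """Fast path: statistic and M for one gene from its ascending pooled values.

    ``thresholds[n]`` is t_α for cluster size n (see ``DogHyper.threshold``).
    """
    n = n_minus
    zm = row_sorted[:n]
    s1 = float(zm.sum())
    s2 = float((zm * zm).sum())
    beta0 = beta0_init
    total = row_sorted.size
    for i in range(n_minus, total):
        mu0 = _median_of_prefix(row_sorted, n)
        mu, beta, beta0, ok = _map_fit(n, s1, s2, mu0, beta0, a, b, tol, max_iter)
        if not ok:
            raise ConvergenceError(
                f"MAP iteration did not converge in {max_iter} steps",
                TightClusterState(mu=mu, beta=beta, beta0=beta0, mu0=mu0, n=n),
            )
        cand = float(row_sorted[i])
        sqb = math.sqrt(beta)
        t = (cand - mu) * sqb
        if t > thresholds[n]:
            t_values = (row_sorted[i:] - mu) * sqb
            return float(t_values.mean()), total - i
        n += 1
        s1 += cand
        s2 += cand * cand
    return 0.0, 0


def dog_statistics(
    ds: ExpressionDataset, hyper: DogHyper, b: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """DOG summary statistic and outlier count M for every gene of a dataset.

    ``b`` defaults to ``hyper.b`` or, failing that, the maximum per-gene
    pooled variance of ``ds`` itself.
    """
    if b is None:
        b = hyper.b if hyper.b is not None else max_gene_variance(ds)
    mask = ds.control_mask
    X = ds.values[:, mask]
    if hyper.mode == "max_control":
        cutoffs = X.max(axis=1)
    else:
        cutoffs = np.percentile(X, hyper.control_percentile, axis=1)
    pooled_max = ds.values.max(axis=1)
    row_sorted = np.sort(ds.values, axis=1)
    thresholds = hyper.threshold_table(ds.n_samples)

    stats_out = np.zeros(ds.n_genes)
    m_out = np.zeros(ds.n_genes, dtype=int)
    for i in range(ds.n_genes):
        if pooled_max[i] <= cutoffs[i]:
            continue  # no candidates; statistic 0, M 0
        rs = row_sorted[i]
        n_minus = int(np.searchsorted(rs, cutoffs[i], side="right"))
        if n_minus == 0:
            raise ValueError(
                f"gene {ds.gene_ids[i]}: all values above the candidate cutoff"
            )
        stats_out[i], m_out[i] = _dog_row(
            rs,
            n_minus,
            b,
            thresholds,
            hyper.a,
            hyper.beta0_init,
            hyper.tol,
            hyper.max_iter,
        )
    return stats_out, m_out


def run_dog_dataset(
    ds: ExpressionDataset,
    hyper: DogHyper = DogHyper(),
    b: float | None = None,
    p_values: np.ndarray | None = None,
) -> ResultTable:
    """Apply DOG to every gene with a shared variance prior b.

    By default b is the maximum pooled per-gene sample variance of ``ds``
    (computed once per dataset); pass ``b`` explicitly to include e.g. a
    simulated null panel in its computation.
    """
    stat, m = dog_statistics(ds, hyper, b=b)
    return ResultTable.from_arrays(ds.gene_ids, stat, M=m, p_value=p_values)
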