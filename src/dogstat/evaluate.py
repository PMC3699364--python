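"""Benchmark metrics and the simulation harness.

Metrics: confusion counts at a critical p-value, the Matthews correlation
coefficient (MCC), its integral over critical p-values in (0, p*] (the
cumulative MCC), the total classification accuracy (TP + TN)/total, and ROC
analysis with a 5%-truncated partial AUC rescaled so a perfect classifier
scores 1.

:func:`run_benchmark` ties everything together: it simulates repetitions of
a scenario, scores every gene with each requested statistic, calibrates
empirical p-values against the per-repetition null panel and averages the
metrics over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .comparators import COMPARATOR_NAMES, comparator_matrix
from .datamodel import ExpressionDataset
from .dog import DogHyper, dog_statistics, max_gene_variance
from .significance import empirical_pvalues
from .simulate import SimSpec, simulate_study

ALL_ALGORITHMS = ("copa", "os", "ort", "most", "lsoss", "dog")

__all__ = [
    "ALL_ALGORITHMS",
    "ConfusionCounts",
    "BenchmarkSummary",
    "confusion_at",
    "mcc",
    "cmcc",
    "total_accuracy",
    "roc_partial_auc",
    "run_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts at one critical p-value."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_at(
    truth: np.ndarray, pvals: np.ndarray, p_crit: float
) -> ConfusionCounts:
    """Call a gene positive when its p-value ≤ ``p_crit``; tally against truth."""
    truth = np.asarray(truth, dtype=bool)
    pvals = np.asarray(pvals, dtype=float)
    if truth.shape != pvals.shape:
        raise ValueError("truth and p-values must have equal length")
    called = pvals <= p_crit
    return ConfusionCounts(
        TP=int((called & truth).sum()),
        TN=int((~called & ~truth).sum()),
        FP=int((called & ~truth).sum()),
        FN=int((~called & truth).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)


def total_accuracy(c: ConfusionCounts) -> float:
    """(TN + TP) / total gene count."""
    return (c.TN + c.TP) / c.total


def cmcc(
    truth: np.ndarray, pvals: np.ndarray, p_star: float = 0.01, grid: int = 100
) -> float:
    """Cumulative MCC: ∫₀^{p*} ρ_p dp by the trapezoid rule on a uniform grid.

    ρ is evaluated at ``grid`` nodes p* i/grid, i = 1..grid; its value at the
    open left endpoint 0 is taken as the right-limit (the first node's value).
    """
    if not 0.0 < p_star <= 1.0:
        raise ValueError("p_star must lie in (0, 1]")
    nodes = p_star * np.arange(1, grid + 1) / grid
    rho = np.array([mcc(confusion_at(truth, pvals, p)) for p in nodes])
    xs = np.concatenate([[0.0], nodes])
    ys = np.concatenate([[rho[0]], rho])
    return float(np.trapezoid(ys, xs))


def roc_partial_auc(
    truth: np.ndarray, scores: np.ndarray, fpr_max: float = 0.05
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and scaled partial AUC over FPR ∈ [0, fpr_max].

    Positives are high scores.  The area is trapezoidal with linear
    interpolation of the curve at ``fpr_max`` and is divided by ``fpr_max``
    so a perfect ranking scores 1.  Returns ``((fpr, tpr), pauc)``.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present")
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError("fpr_max must lie in (0, 1]")
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, float), drop_intermediate=False)
    right = np.interp(fpr_max, fpr, tpr)
    keep = fpr < fpr_max
    xs = np.concatenate([fpr[keep], [fpr_max]])
    ys = np.concatenate([tpr[keep], [right]])
    return (fpr, tpr), float(np.trapezoid(ys, xs) / fpr_max)


@dataclass
class BenchmarkSummary:
    """Mean metrics per algorithm for one simulated condition.

    ``table`` rows are algorithms; columns: mean_p (mean hDEG p-value),
    mean_M (DOG's mean detected outlier count, NaN otherwise),
    classification_rate (total accuracy at ``p_crit``), cmcc, partial_auc
    (mean of per-repetition areas), reps.
    """

    scenario: str
    k: int
    reps: int
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def _scores(
    algorithm: str,
    eval_ds: ExpressionDataset,
    panel: ExpressionDataset,
    dog_hyper: DogHyper,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Statistic vectors on evaluation genes and the panel (+ M for DOG)."""
    if algorithm == "dog":
        b = max_gene_variance(eval_ds, panel)
        s_eval, m_eval = dog_statistics(eval_ds, dog_hyper, b=b)
        s_panel, _ = dog_statistics(panel, dog_hyper, b=b)
        return s_eval, s_panel, m_eval
    cm, em = eval_ds.control_mask, panel.control_mask
    s_eval = comparator_matrix(
        algorithm, eval_ds.values[:, cm], eval_ds.values[:, ~cm]
    )
    s_panel = comparator_matrix(algorithm, panel.values[:, em], panel.values[:, ~em])
    return s_eval, s_panel, None


def run_benchmark(
    scenario: str,
    k: int = 1,
    reps: int = 100,
    seed: int | None = None,
    algorithms: tuple[str, ...] = ALL_ALGORITHMS,
    *,
    delta_mean: float = 2.0,
    cluster_model: str = "gaussian",
    control_outliers: int = 0,
    n_null_panel: int = 10_000,
    p_crit: float = 0.01,
    p_star: float = 0.01,
    cmcc_grid: int = 100,
    fpr_max: float = 0.05,
    dog_hyper: DogHyper | None = None,
) -> BenchmarkSummary:
    """Simulate a scenario and score each algorithm against the truth.

    ``scenario`` is ``"scenario1"`` (single hDEG; variable-distance, mixture
    and contaminated-control variants via keywords) or ``"scenario2"``
    (50 hDEGs + 50 non-DEGs).  Per repetition, a fresh dataset and null
    panel are generated; the shared DOG variance prior b is the maximum
    per-gene variance over both; empirical p-values come from the panel.
    All metrics, the partial AUC included, are averaged over repetitions
    (statistic scales are only comparable within a repetition, so ROC
    curves are summarized by vertical averaging rather than score pooling).
    """
    unknown = set(algorithms) - set(ALL_ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    if scenario == "scenario1":
        spec = SimSpec(
            n_outliers=k,
            delta_mean=delta_mean,
            cluster_model=cluster_model,
            control_outliers=control_outliers,
            n_hdeg=1,
            n_nondeg=0,
            n_null_panel=n_null_panel,
        )
    elif scenario == "scenario2":
        spec = SimSpec(
            n_outliers=k,
            delta_mean=delta_mean,
            cluster_model=cluster_model,
            control_outliers=control_outliers,
            n_hdeg=50,
            n_nondeg=50,
            n_null_panel=n_null_panel,
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if dog_hyper is None:
        dog_hyper = DogHyper(
            mode="control_percentile" if control_outliers > 0 else "max_control"
        )

    acc: dict[str, dict[str, list]] = {
        alg: {"p": [], "M": [], "rate": [], "cmcc": [], "pauc": []}
        for alg in algorithms
    }
    for child in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child)
        study = simulate_study(spec, rng)
        truth = study.dataset.truth_labels
        for alg in algorithms:
            s_eval, s_panel, m_eval = _scores(alg, study.dataset, study.panel, dog_hyper)
            pvals = empirical_pvalues(s_eval, s_panel)
            rec = acc[alg]
            rec["p"].append(float(pvals[truth].mean()))
            if m_eval is not None:
                rec["M"].append(float(m_eval[truth].mean()))
            if truth.any() and not truth.all():
                rec["rate"].append(total_accuracy(confusion_at(truth, pvals, p_crit)))
                rec["cmcc"].append(cmcc(truth, pvals, p_star, cmcc_grid))
                rec["pauc"].append(roc_partial_auc(truth, s_eval, fpr_max)[1])

    rows = {}
    for alg in algorithms:
        rec = acc[alg]
        rows[alg] = {
            "mean_p": float(np.mean(rec["p"])),
            "mean_M": float(np.mean(rec["M"])) if rec["M"] else np.nan,
            "classification_rate": float(np.mean(rec["rate"])) if rec["rate"] else np.nan,
            "cmcc": float(np.mean(rec["cmcc"])) if rec["cmcc"] else np.nan,
            "partial_auc": float(np.mean(rec["pauc"])) if rec["pauc"] else np.nan,
            "reps": reps,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(algorithms)]
    table.index.name = "algorithm"
    return BenchmarkSummary(scenario=scenario, k=k, reps=reps, table=table)
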