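"""Synthetic two-group expression data with planted hDEGs.

The generative model: control and non-outlier experimental expressions are
i.i.d. draws from a tight-cluster distribution — N(10, 1) by default, or the
Gaussian mixture 0.5·N(9,1) + 0.5·N(10,1) to probe non-Gaussianity — with 30
replicates per group.  Each outlier is placed at the maximum of the gene's
tight cluster plus an independent gap drawn from N(δ, 0.2²) with δ = 2 by
default, so outliers sit strictly above the cluster by a controlled marginal
null-outlier distance.  Optionally the same construction contaminates the
control group.

Two benchmark designs are provided:

* **Scenario 1** — a single hDEG per repetition, with the number of planted
  outliers varied; used to study p-values and the estimated outlier count.
* **Scenario 2** — 50 hDEGs and 50 non-DEGs per repetition; used for
  classification metrics.

Both come with a large panel of null genes (10,000 by default) drawn from
the same tight-cluster model, which supplies the empirical null statistics
for p-value calibration.  A master seed spawns independent per-repetition
streams, so any repetition is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import CONTROL, EXPERIMENTAL, ExpressionDataset

__all__ = [
    "SimSpec",
    "SimulatedStudy",
    "simulate_gene",
    "simulate_dataset",
    "simulate_study",
    "simulate_scenario1",
    "simulate_scenario2",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the per-gene generative model and study layout."""

    n_control: int = 30
    n_experimental: int = 30
    n_outliers: int = 0
    delta_mean: float = 2.0
    delta_sd: float = 0.2
    cluster_model: str = "gaussian"  # or "mixture"
    control_outliers: int = 0
    n_hdeg: int = 1
    n_nondeg: int = 0
    n_null_panel: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_outliers >= self.n_experimental:
            raise ValueError("n_outliers must be smaller than n_experimental")
        if self.control_outliers >= self.n_control:
            raise ValueError("control_outliers must be smaller than n_control")
        if self.delta_sd <= 0:
            raise ValueError("delta_sd must be positive")
        if min(self.n_outliers, self.control_outliers, self.n_hdeg,
               self.n_nondeg, self.n_null_panel) < 0:
            raise ValueError("counts must be non-negative")
        if self.cluster_model not in ("gaussian", "mixture"):
            raise ValueError(f"unknown cluster model {self.cluster_model!r}")


@dataclass
class SimulatedStudy:
    """One simulated repetition: evaluation genes plus the null panel."""

    dataset: ExpressionDataset  # labelled genes (truth_labels set)
    panel: ExpressionDataset  # null genes for p-value calibration
    spec: SimSpec

    def combined(self) -> ExpressionDataset:
        return self.dataset.concat(self.panel)


def _draw_cluster(spec: SimSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    if spec.cluster_model == "mixture":
        means = np.where(rng.random(size) < 0.5, 9.0, 10.0)
        return rng.normal(means, 1.0)
    return rng.normal(10.0, 1.0, size)


def simulate_gene(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw one gene; returns (x, y, truth).

    The tight cluster is the union of all non-outlier values; every planted
    outlier equals max(tight cluster) + d with d ~ N(delta_mean, delta_sd²),
    drawn independently per outlier.  Outlier positions are shuffled within
    their group.  ``truth`` records the outlier sample indices per group.
    """
    k = spec.n_outliers
    c = spec.control_outliers
    n_tight = spec.n_control - c + spec.n_experimental - k
    tight = _draw_cluster(spec, n_tight, rng)
    top = float(tight.max())
    gaps = rng.normal(spec.delta_mean, spec.delta_sd, k + c)

    y = np.concatenate([tight[: spec.n_experimental - k], top + gaps[:k]])
    x = np.concatenate([tight[spec.n_experimental - k:], top + gaps[k:]])
    perm_y = rng.permutation(spec.n_experimental)
    perm_x = rng.permutation(spec.n_control)
    y_out = np.nonzero(perm_y >= spec.n_experimental - k)[0]
    x_out = np.nonzero(perm_x >= spec.n_control - c)[0]
    return x[perm_x], y[perm_y], {
        "is_hdeg": k > 0,
        "outlier_indices_y": np.sort(y_out),
        "outlier_indices_x": np.sort(x_out),
    }


def simulate_dataset(
    spec: SimSpec,
    n_hdeg: int,
    n_null: int,
    rng: np.random.Generator,
    prefix: str = "gene",
) -> ExpressionDataset:
    """A dataset of ``n_hdeg`` planted hDEGs followed by ``n_null`` null genes."""
    null_spec = replace(spec, n_outliers=0, control_outliers=0)
    n_genes = n_hdeg + n_null
    values = np.empty((n_genes, spec.n_control + spec.n_experimental))
    truth = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        g = spec if i < n_hdeg else null_spec
        x, y, info = simulate_gene(g, rng)
        values[i] = np.concatenate([x, y])
        truth[i] = info["is_hdeg"]
    labels = [CONTROL] * spec.n_control + [EXPERIMENTAL] * spec.n_experimental
    ids = [f"{prefix}_{i + 1}" for i in range(n_genes)]
    return ExpressionDataset(ids, values, labels, truth_labels=truth)


def simulate_study(spec: SimSpec, rng: np.random.Generator) -> SimulatedStudy:
    """One repetition: ``n_hdeg`` hDEGs + ``n_nondeg`` nulls to evaluate, and
    an ``n_null_panel``-gene null panel for calibration."""
    dataset = simulate_dataset(spec, spec.n_hdeg, spec.n_nondeg, rng, prefix="eval")
    panel = simulate_dataset(
        replace(spec, n_outliers=0, control_outliers=0),
        0,
        spec.n_null_panel,
        rng,
        prefix="null",
    )
    return SimulatedStudy(dataset=dataset, panel=panel, spec=spec)


def _spawn(seed: int | None, reps: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(reps)]


def simulate_scenario1(
    k: int,
    reps: int,
    seed: int | None = None,
    *,
    delta_mean: float = 2.0,
    cluster_model: str = "gaussian",
    control_outliers: int = 0,
    n_null_panel: int = 10_000,
) -> list[SimulatedStudy]:
    """Single-hDEG repetitions with ``k`` planted outliers each.

    The variable-distance, mixture-cluster and contaminated-control
    extensions are reached through the keyword arguments.
    """
    spec = SimSpec(
        n_outliers=k,
        delta_mean=delta_mean,
        cluster_model=cluster_model,
        control_outliers=control_outliers,
        n_hdeg=1,
        n_nondeg=0,
        n_null_panel=n_null_panel,
        seed=seed,
    )
    return [simulate_study(spec, rng) for rng in _spawn(seed, reps)]


def simulate_scenario2(
    k: int,
    reps: int,
    seed: int | None = None,
    *,
    n_hdeg: int = 50,
    n_nondeg: int = 50,
    n_null_panel: int = 10_000,
) -> list[SimulatedStudy]:
    """Mixed repetitions: ``n_hdeg`` hDEGs (k outliers each) + ``n_nondeg`` nulls."""
    spec = SimSpec(
        n_outliers=k,
        n_hdeg=n_hdeg,
        n_nondeg=n_nondeg,
        n_null_panel=n_null_panel,
        seed=seed,
    )
    return [simulate_study(spec, rng) for rng in _spawn(seed, reps)]
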