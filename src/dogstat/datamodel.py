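"""Core data containers and tab-delimited IO for two-group expression studies.

The central object is :class:`ExpressionDataset`, a genes × samples matrix of
(log2) expression values with a binary control/experimental annotation per
sample.  Per-gene work is done on :class:`GenePair` — the control vector ``x``
and experimental vector ``y`` of a single gene.  Ranked per-gene output is an
:class:`ResultTable` wrapper around a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
EXPERIMENTAL = "experimental"

__all__ = [
    "CONTROL",
    "EXPERIMENTAL",
    "ExpressionDataset",
    "GenePair",
    "ResultTable",
    "DegenerateScaleError",
    "read_expression_table",
    "write_expression_table",
    "write_results",
]


class DegenerateScaleError(ValueError):
    """Raised when a scale estimate (MAD, pooled SD, ...) is exactly zero."""


@dataclass
class GenePair:
    """Expression of one gene: control vector ``x`` and experimental vector ``y``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size < 2 or self.y.size < 2:
            raise ValueError("need at least 2 control and 2 experimental samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("expression values must be finite")

    @property
    def z(self) -> np.ndarray:
        """Pooled vector z = x ∪ y (controls first)."""
        return np.concatenate([self.x, self.y])


@dataclass
class ExpressionDataset:
    """A genes × samples expression matrix with a two-group sample annotation.

    Parameters
    ----------
    gene_ids
        Unique gene (or probe-set) identifiers, one per row.
    values
        Real matrix, shape ``(n_genes, n_samples)``; assumed log2 scale.
    group_labels
        Per-column label, each ``"control"`` or ``"experimental"``.
    truth_labels
        Optional per-gene boolean, True for simulated hDEGs.  Simulation only.
    """

    gene_ids: list[str]
    values: np.ndarray
    group_labels: list[str]
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.group_labels = list(self.group_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × samples matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")
        if len(self.group_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.group_labels)} group labels for "
                f"{self.values.shape[1]} sample columns"
            )
        bad = sorted(set(self.group_labels) - {CONTROL, EXPERIMENTAL})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = {g for g in self.gene_ids if g in seen or seen.add(g)}
            raise ValueError(f"duplicate gene ids: {sorted(dups)}")
        if np.isnan(self.values).any():
            rows, cols = np.nonzero(np.isnan(self.values))
            where = ", ".join(
                f"(gene {self.gene_ids[r]}, sample {c})"
                for r, c in list(zip(rows, cols))[:5]
            )
            raise ValueError(f"missing values are not supported; first at {where}")
        if self.n_control < 2 or self.n_experimental < 2:
            raise ValueError("need at least 2 control and 2 experimental samples")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=bool)
            if self.truth_labels.shape != (self.n_genes,):
                raise ValueError("truth_labels must have one entry per gene")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([g == CONTROL for g in self.group_labels])

    @property
    def n_control(self) -> int:
        return int(self.control_mask.sum())

    @property
    def n_experimental(self) -> int:
        return self.n_samples - self.n_control

    def gene(self, index: int) -> GenePair:
        """Return the :class:`GenePair` for one gene row."""
        mask = self.control_mask
        row = self.values[index]
        return GenePair(x=row[mask], y=row[~mask])

    def iter_genes(self):
        """Yield ``(gene_id, GenePair)`` in row order."""
        mask = self.control_mask
        for gid, row in zip(self.gene_ids, self.values):
            yield gid, GenePair(x=row[mask], y=row[~mask])

    def concat(self, other: "ExpressionDataset") -> "ExpressionDataset":
        """Stack two datasets with identical sample annotations gene-wise."""
        if self.group_labels != other.group_labels:
            raise ValueError("sample annotations differ")
        truth = None
        if self.truth_labels is not None and other.truth_labels is not None:
            truth = np.concatenate([self.truth_labels, other.truth_labels])
        return ExpressionDataset(
            gene_ids=self.gene_ids + other.gene_ids,
            values=np.vstack([self.values, other.values]),
            group_labels=self.group_labels,
            truth_labels=truth,
        )


@dataclass
class ResultTable:
    """Ranked per-gene results.

    Columns: ``gene_id``, ``statistic``, ``M`` (detected outlier count, 0 for
    statistics that do not estimate one), ``p_value`` (may be NaN when no null
    distribution was supplied) and ``rank``.  Ranks are 1..n by decreasing
    statistic, ties broken by gene_id order.
    """

    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        statistic: np.ndarray,
        M: np.ndarray | None = None,
        p_value: np.ndarray | None = None,
    ) -> "ResultTable":
        statistic = np.asarray(statistic, dtype=float)
        n = len(statistic)
        if len(gene_ids) != n:
            raise ValueError("gene_ids and statistic lengths differ")
        if M is None:
            M = np.zeros(n, dtype=int)
        if p_value is None:
            p_value = np.full(n, np.nan)
        frame = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "statistic": statistic,
                "M": np.asarray(M, dtype=int),
                "p_value": np.asarray(p_value, dtype=float),
            }
        )
        # stable sort on gene_id first, then on -statistic, implements the
        # "decreasing statistic, ties by gene_id order" rule
        order = frame.sort_values(
            ["statistic", "gene_id"], ascending=[False, True], kind="mergesort"
        ).index
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        frame["rank"] = ranks
        return cls(frame=frame)

    def __len__(self) -> int:
        return len(self.frame)

    def sorted(self) -> pd.DataFrame:
        return self.frame.sort_values("rank").reset_index(drop=True)


def read_expression_table(
    path: str | Path,
    group_spec: Sequence[str] | str | Path,
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix.

    The file must have a header row of sample identifiers and gene ids in the
    first column.  ``group_spec`` is either a sequence of per-sample labels
    (``"control"``/``"experimental"``, in column order) or a path to a
    two-column tab-delimited file ``sample_id<TAB>label`` (header optional,
    order taken from the expression table's columns when sample ids match,
    otherwise file order).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if isinstance(group_spec, (str, Path)):
        lab = pd.read_csv(group_spec, sep="\t", header=None, comment="#")
        if lab.shape[1] >= 2:
            first = str(lab.iloc[0, 1]).strip().lower()
            if first not in (CONTROL, EXPERIMENTAL):  # header row present
                lab = lab.iloc[1:]
            mapping = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
            try:
                labels = [mapping[str(c)] for c in frame.columns]
            except KeyError as exc:
                raise ValueError(f"sample {exc} missing from the label file") from exc
        else:
            labels = [str(v) for v in lab.iloc[:, 0]]
    else:
        labels = [str(v) for v in group_spec]
    labels = [s.strip().lower() for s in labels]
    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        values=frame.to_numpy(dtype=float),
        group_labels=labels,
    )


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as tab-delimited text (gene ids in the first column)."""
    cols = [f"{g[:4]}_{i + 1}" for i, g in enumerate(ds.group_labels)]
    frame = pd.DataFrame(ds.values, index=ds.gene_ids, columns=cols)
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_results(results: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as tab-delimited text ordered by rank.

    Absent p-values are serialized as ``NA``.
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty result table")
    frame = results.sorted()[["gene_id", "statistic", "M", "p_value", "rank"]]
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
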