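"""Single-cell transcriptional noise and its young/aged comparison.

Transcriptional noise of a cell is (1 - r) * 100 where r is the Pearson
correlation between the cell's log-CPM profile and the mean log-CPM profile
of the young cells, optionally restricted to a gene stratum (all genes,
CGI+, CGI-). Cells with fewer than 1,000 detected genes or fewer than 1e5
reads are dropped first, and a dataset is rejected outright when any group
retains fewer than 10 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CgiClass, ExpressionMatrix
from .shift_stats import rank_sum_test

__all__ = [
    "GroupSizeError",
    "NoiseResult",
    "qc_cells",
    "log_cpm",
    "transcriptional_noise",
    "compare_noise",
    "noise_table",
]


class GroupSizeError(ValueError):
    """Raised when a group retains fewer individuals than required."""

    def __init__(self, group: str, n: int, minimum: int):
        self.group = group
        super().__init__(
            f"group {group!r} has {n} individuals after QC "
            f"(minimum {minimum}); dataset rejected"
        )


@dataclass(frozen=True)
class NoiseResult:
    cell_id: str
    group: str
    stratum: str
    noise: float


def qc_cells(
    matrix: ExpressionMatrix,
    min_genes: int = 1000,
    min_reads: float = 1e5,
    min_group_n: int = 10,
) -> ExpressionMatrix:
    """Drop low-quality cells; reject the dataset on group-size failure.

    Cells with detected genes < ``min_genes`` (strict) or total reads <
    ``min_reads`` (strict) are removed. If the number of distinct
    individuals surviving in any group of the metadata drops below
    ``min_group_n``, a :class:`GroupSizeError` names the failing group.
    """
    if matrix.layer != "raw":
        raise ValueError("qc_cells expects raw counts")
    counts = matrix.values
    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep = (detected >= min_genes) & (totals >= min_reads)
    kept = [s for s, k in zip(matrix.sample_ids, keep) if k]
    filtered = matrix.subset_samples(kept)
    for group in sorted(matrix.meta["group"].unique()):
        surviving = filtered.meta.loc[
            filtered.meta["group"] == group, "individual"
        ].nunique()
        if surviving < min_group_n:
            raise GroupSizeError(group, int(surviving), min_group_n)
    return filtered


def log_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log10(1 + 1e6 * count / cell_total) per cell."""
    if matrix.layer != "raw":
        raise ValueError("log_cpm expects raw counts")
    totals = matrix.values.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total cells: {bad}")
    cpm = matrix.values * (1e6 / totals)
    return ExpressionMatrix(np.log10(1.0 + cpm), matrix.meta, layer="log")


def transcriptional_noise(
    cell: np.ndarray, young_mean: np.ndarray, subset=None
) -> float:
    """(1 - Pearson r between cell and young-mean log-CPM) * 100."""
    cell = np.asarray(cell, dtype=float)
    young_mean = np.asarray(young_mean, dtype=float)
    if cell.shape != young_mean.shape:
        raise ValueError("cell and reference must be aligned")
    if subset is not None:
        subset = np.asarray(subset)
        cell, young_mean = cell[subset], young_mean[subset]
    if cell.size < 3:
        raise ValueError("stratum must contain >= 3 genes")
    if np.ptp(cell) == 0 or np.ptp(young_mean) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    r = np.corrcoef(cell, young_mean)[0, 1]
    return float((1.0 - r) * 100.0)


def compare_noise(
    young_noises: Sequence[float], aged_noises: Sequence[float]
) -> tuple[float, int]:
    """Two-sided rank-sum p and the sign of the aged-young median change."""
    young = np.asarray(young_noises, dtype=float)
    aged = np.asarray(aged_noises, dtype=float)
    if young.size == 0 or aged.size == 0:
        raise ValueError("both groups must be nonempty")
    p = rank_sum_test(aged, young)
    direction = int(np.sign(np.median(aged) - np.median(young)))
    return p, direction


def noise_table(
    log_matrix: ExpressionMatrix,
    classes: Mapping[str, CgiClass] | None = None,
    young_group: str = "young",
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Per-cell noise for every stratum, against the young mean profile.

    The young reference Y is the mean log-CPM profile over the young cells
    of the full gene set; strata subset that shared reference. By default a
    young cell is scored against the mean of the *other* young cells
    (leave-one-out): including the cell in its own reference biases the
    reference group's noise down by cov(X_i, Y) = var/n and makes any
    non-member group look noisier even under identical dispersion.
    ``leave_one_out=False`` gives the literal shared mean.
    """
    if log_matrix.layer != "log":
        raise ValueError("noise_table expects the log layer (see log_cpm)")
    meta = log_matrix.meta
    young_ids = [s for s in log_matrix.sample_ids if meta.loc[s, "group"] == young_group]
    if not young_ids:
        raise ValueError(f"no cells in young group {young_group!r}")
    if leave_one_out and len(young_ids) < 2:
        raise ValueError("leave-one-out reference needs >= 2 young cells")
    young_sum = log_matrix.values[young_ids].sum(axis=1).to_numpy()
    n_young = len(young_ids)
    young_mean = young_sum / n_young
    gene_ids = log_matrix.gene_ids
    strata: dict[str, np.ndarray] = {"all": np.ones(len(gene_ids), dtype=bool)}
    if classes is not None:
        labels = np.array(
            [str(classes.get(g, CgiClass.UNCLASSIFIED)) for g in gene_ids]
        )
        strata["CGI_PLUS"] = labels == str(CgiClass.CGI_PLUS)
        strata["CGI_MINUS"] = labels == str(CgiClass.CGI_MINUS)
    rows = []
    values = log_matrix.values.to_numpy()
    young_set = set(young_ids)
    for j, cell_id in enumerate(log_matrix.sample_ids):
        if leave_one_out and cell_id in young_set:
            reference = (young_sum - values[:, j]) / (n_young - 1)
        else:
            reference = young_mean
        for stratum, mask in strata.items():
            if not mask.any():
                continue
            rows.append({
                "cell_id": cell_id,
                "group": meta.loc[cell_id, "group"],
                "stratum": stratum,
                "noise": transcriptional_noise(values[:, j], reference, mask),
            })
    return pd.DataFrame(rows)
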