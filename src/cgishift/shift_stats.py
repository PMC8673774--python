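"""Distribution shift and net expression change (dAUC).

The pipeline's central question is whether a sample's whole expression
distribution has moved relative to a young reference, rather than whether
individual genes changed. Two complementary quantities capture this, per
stratum of genes (all genes, CGI+ genes, CGI- genes):

* distribution shift -- a two-sided Wilcoxon rank-sum test between the
  log10 expression values of the sample and the reference over the gene
  subset; the shift score is -log10(p).

* net expression change (dAUC) -- the difference in area under the sorted
  log10-expression curve when both axes are scaled to 0-10, times 100:

      dAUC = (sum_i log10 Exp_i^S - sum_i log10 Exp_i^R)
             / (n * log10 Exp_max^Both) * 100

  where n is the number of genes used and Exp_max^Both the maximum value
  over both vectors. Positive dAUC means global up-regulation.

Genes expressed in neither vector are excluded; remaining zeros are handled
with a pseudocount (default 1) before the log transform. Aged samples are
called AFFECTED / UNAFFECTED / INTERMEDIATE from the all-genes shift score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CgiClass, ExpressionMatrix, GeneModel

__all__ = [
    "ShiftResult",
    "AgingStatus",
    "Status",
    "ReferenceProfile",
    "normalize_counts",
    "reference_profile",
    "rank_sum_test",
    "distribution_shift",
    "net_expression_change",
    "classify_status",
    "all_pairs_shift",
    "paired_strata_test",
    "fold_change_fractions",
    "shift_table",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ShiftResult:
    stratum: str  # "all" | "CGI_PLUS" | "CGI_MINUS"
    p_value: float
    shift_score: float
    delta_auc: float
    n_genes: int
    pct_up: float
    pct_down: float


class Status(str, Enum):
    AFFECTED = "AFFECTED"
    UNAFFECTED = "UNAFFECTED"
    INTERMEDIATE = "INTERMEDIATE"


@dataclass(frozen=True)
class AgingStatus:
    sample_id: str
    status: Status
    score_used: float


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-gene median of normalized expression across the young samples."""

    values: pd.Series
    young_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# normalization & reference


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization (size factors as in bulk RNA-seq).

    Size factor of a sample = median over genes of count / geometric-mean
    across samples, computed on genes with no zero anywhere; each column is
    divided by its factor.
    """
    if matrix.layer != "raw":
        raise ValueError("normalize_counts expects a raw-count matrix")
    counts = matrix.values.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    zero_cols = counts.sum(axis=0) == 0
    if zero_cols.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero_cols) if z]
        raise ValueError(f"all-zero samples: {bad}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    normalized = matrix.values / factors
    return ExpressionMatrix(normalized, matrix.meta, layer="normalized")


def reference_profile(
    matrix: ExpressionMatrix, young_ids: Sequence[str]
) -> ReferenceProfile:
    """Per-gene median across the young samples (the young reference)."""
    if len(young_ids) == 0:
        raise ValueError("need at least one young sample")
    unknown = [s for s in young_ids if s not in matrix.values.columns]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")
    med = matrix.values[list(young_ids)].median(axis=1)
    return ReferenceProfile(med, tuple(young_ids))


# ---------------------------------------------------------------------------
# the two core statistics


def _used_genes(
    sample: np.ndarray, reference: np.ndarray, subset=None
) -> tuple[np.ndarray, np.ndarray]:
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.shape != reference.shape:
        raise ValueError("sample and reference must be aligned vectors")
    if subset is not None:
        subset = np.asarray(subset)
        sample, reference = sample[subset], reference[subset]
    keep = (sample > 0) | (reference > 0)  # expressed in at least one
    return sample[keep], reference[keep]


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both sizes <= 25 and there are no ties across
    the pooled values; otherwise the normal approximation with tie-corrected
    variance and continuity correction. All values tied -> p = 1 by
    contract.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty vector in rank-sum test")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    untied = np.unique(pooled).size == pooled.size
    if untied and x.size <= 25 and y.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def distribution_shift(
    sample: np.ndarray,
    reference: np.ndarray,
    subset=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """(two-sided rank-sum p, shift score = -log10 p) on log10 values."""
    s, r = _used_genes(sample, reference, subset)
    if s.size == 0:
        raise ValueError("no genes left after exclusion")
    p = rank_sum_test(np.log10(s + pseudocount), np.log10(r + pseudocount))
    return p, float(-np.log10(p))


def net_expression_change(
    sample: np.ndarray,
    reference: np.ndarray,
    subset=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Net expression change (dAUC) on the printed x100 scale."""
    s, r = _used_genes(sample, reference, subset)
    if s.size == 0:
        raise ValueError("no genes left after exclusion")
    s = s + pseudocount
    r = r + pseudocount
    max_both = max(s.max(), r.max())
    log_max = np.log10(max_both)
    if log_max <= 0:
        raise ValueError(
            f"degenerate scale: max pseudocounted value {max_both} gives "
            "log10 <= 0"
        )
    n = s.size
    return float(
        (np.log10(s).sum() - np.log10(r).sum()) / (n * log_max) * 100.0
    )


def fold_change_fractions(
    sample: np.ndarray,
    reference: np.ndarray,
    subset=None,
    fold: float = 2.0,
) -> tuple[float, float]:
    """Percent of used genes up / down by >= ``fold`` (inclusive).

    Comparisons are on the raw values after excluding genes expressed in
    neither vector; a gene with reference 0 and any expression counts as
    up, and symmetrically for down.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    s, r = _used_genes(sample, reference, subset)
    if s.size == 0:
        raise ValueError("no genes left after exclusion")
    n = s.size
    pct_up = 100.0 * np.count_nonzero(s >= fold * r) / n
    pct_down = 100.0 * np.count_nonzero(r >= fold * s) / n
    return float(pct_up), float(pct_down)


def classify_status(
    shift_score: float,
    t_affected: float = 0.5,
    t_unaffected: float = 0.25,
    sample_id: str = "",
) -> AgingStatus:
    """AFFECTED if score > t_affected, UNAFFECTED if < t_unaffected."""
    if not t_unaffected < t_affected:
        raise ValueError("require t_unaffected < t_affected")
    if shift_score > t_affected:
        status = Status.AFFECTED
    elif shift_score < t_unaffected:
        status = Status.UNAFFECTED
    else:
        status = Status.INTERMEDIATE
    return AgingStatus(sample_id, status, float(shift_score))


# ---------------------------------------------------------------------------
# harnesses


def _strata_masks(
    gene_ids: Sequence[str], classes: Mapping[str, CgiClass] | None
) -> dict[str, np.ndarray]:
    masks = {"all": np.ones(len(gene_ids), dtype=bool)}
    if classes is not None:
        labels = np.array(
            [str(classes.get(g, CgiClass.UNCLASSIFIED)) for g in gene_ids]
        )
        masks["CGI_PLUS"] = labels == str(CgiClass.CGI_PLUS)
        masks["CGI_MINUS"] = labels == str(CgiClass.CGI_MINUS)
    return masks


def shift_table(
    sample: np.ndarray,
    reference: np.ndarray,
    gene_ids: Sequence[str],
    classes: Mapping[str, CgiClass] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fold: float = 2.0,
) -> list[ShiftResult]:
    """Full per-stratum ShiftResult list for one sample-vs-reference pair."""
    out = []
    for stratum, mask in _strata_masks(gene_ids, classes).items():
        if not mask.any():
            continue
        p, score = distribution_shift(sample, reference, mask, pseudocount)
        dauc = net_expression_change(sample, reference, mask, pseudocount)
        s, r = _used_genes(sample, reference, mask)
        up, down = fold_change_fractions(sample, reference, mask, fold)
        out.append(ShiftResult(stratum, p, score, dauc, s.size, up, down))
    return out


def all_pairs_shift(
    group_a: ExpressionMatrix,
    group_b: ExpressionMatrix,
    classes: Mapping[str, CgiClass] | None = None,
    genes: Sequence[GeneModel] | None = None,
    depth_ratio_max: float = 1.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """All-pairs shift testing between two comparison groups.

    Both matrices must be normalized and share the gene universe; sample
    metadata must provide ``sex`` and ``total_mapped_reads``. Sexes are
    analyzed separately; pairs whose mapped-read totals differ by more than
    ``depth_ratio_max``-fold (strictly) are excluded and returned in the
    second element; Y-chromosome genes are dropped when ``genes`` provides
    coordinates.

    Returns a tidy DataFrame with one row per (sample_a, sample_b, stratum)
    plus the list of depth-excluded pairs.
    """
    if list(group_a.values.index) != list(group_b.values.index):
        raise ValueError("groups must share an identically ordered gene universe")
    gene_ids = list(group_a.values.index)
    keep = np.ones(len(gene_ids), dtype=bool)
    if genes is not None:
        chrom_of = {g.gene_id: g.interval.chrom for g in genes}
        keep = np.array(
            [chrom_of.get(g, "") not in ("chrY", "Y") for g in gene_ids]
        )
    gene_ids_used = [g for g, k in zip(gene_ids, keep) if k]

    rows = []
    excluded: list[tuple[str, str]] = []
    sexes = sorted(
        set(group_a.meta["sex"]).union(group_b.meta["sex"])
    )
    for sex in sexes:
        ids_a = [s for s in group_a.sample_ids if group_a.meta.loc[s, "sex"] == sex]
        ids_b = [s for s in group_b.sample_ids if group_b.meta.loc[s, "sex"] == sex]
        if not ids_a or not ids_b:
            logger.warning("sex split %r skipped: a group is empty", sex)
            continue
        for sa, sb in product(ids_a, ids_b):
            da = float(group_a.meta.loc[sa, "total_mapped_reads"])
            db = float(group_b.meta.loc[sb, "total_mapped_reads"])
            ratio = max(da, db) / min(da, db)
            if ratio > depth_ratio_max:
                logger.info(
                    "pair (%s, %s) excluded: depth ratio %.3f > %.2f",
                    sa, sb, ratio, depth_ratio_max,
                )
                excluded.append((sa, sb))
                continue
            b_vals = group_b.values[sb].to_numpy()[keep]
            a_vals = group_a.values[sa].to_numpy()[keep]
            for res in shift_table(
                b_vals, a_vals, gene_ids_used, classes, pseudocount
            ):
                rows.append({
                    "sample_a": sa, "sample_b": sb, "sex": sex,
                    "stratum": res.stratum, "p_value": res.p_value,
                    "shift_score": res.shift_score, "delta_auc": res.delta_auc,
                    "n_genes": res.n_genes, "pct_up": res.pct_up,
                    "pct_down": res.pct_down,
                })
    return pd.DataFrame(rows), excluded


def paired_strata_test(
    delta_auc_minus: Sequence[float], delta_auc_plus: Sequence[float]
) -> float:
    """One-tailed paired t test that CGI- dAUC exceeds CGI+ dAUC."""
    a = np.asarray(delta_auc_minus, dtype=float)
    b = np.asarray(delta_auc_plus, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 aligned dAUC pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue)
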