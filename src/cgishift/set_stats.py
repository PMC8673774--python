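"""Supporting set statistics and QC filters.

Hypergeometric term enrichment/depletion, a permutation test for gene-set
overlap, the fold-change rules used for meta-analysis differential
expression and tissue-specific gene definition, Benjamini-Hochberg
adjustment, and the ChIP-seq signal-to-noise / coverage quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cgi_annotation import merge_intervals
from .io_formats import GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "EnrichmentRecord",
    "SnrResult",
    "hypergeom_enrichment",
    "overlap_permutation",
    "tissue_specific_genes",
    "fold_change_de",
    "bh_adjust",
    "chip_snr",
]

SIGNIFICANCE_CUTOFF = 1e-6


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    k: int  # overlap
    K: int  # term size
    n: int  # query size
    N: int  # universe size
    p_enriched: float
    p_depleted: float
    significant: bool


@dataclass(frozen=True)
class SnrResult:
    snr: float  # inf when no signal falls outside peaks
    coverage_frac: float
    reads: int
    passed: bool


def hypergeom_enrichment(
    query: set[str],
    term_sets: Mapping[str, set[str]],
    universe: set[str],
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment/depletion of ``query`` in each term set.

    p_enriched = P(X >= k), p_depleted = P(X <= k) for
    X ~ Hypergeom(N=|universe|, K=|term|, n=|query|).
    """
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    out = []
    for term_id, term in term_sets.items():
        term = term & universe
        K = len(term)
        k = len(query & term)
        dist = stats.hypergeom(M=N, n=K, N=n)
        p_enr = float(dist.sf(k - 1))
        p_dep = float(dist.cdf(k))
        out.append(
            EnrichmentRecord(
                term_id, k, K, n, N, p_enr, p_dep,
                significant=min(p_enr, p_dep) < cutoff,
            )
        )
    return out


def overlap_permutation(
    set_a: set[str],
    set_b: set[str],
    universe: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical p for the overlap of two gene sets.

    Draws ``n_perm`` uniform subsets of size |set_a| from the universe,
    holding set_b fixed; p = (1 + #{permutation overlap >= observed}) /
    (n_perm + 1), so p is never 0.
    """
    universe = list(universe)
    uniset = set(universe)
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s - uniset
        if stray:
            raise ValueError(f"{name} has genes outside universe: {sorted(stray)[:5]}")
    if len(set_a) > len(universe):
        raise ValueError("set_a larger than universe")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = len(set_a & set_b)
    in_b = np.array([g in set_b for g in universe])
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(universe), size=len(set_a), replace=False)
        if int(in_b[idx].sum()) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def tissue_specific_genes(
    mean_expr: pd.DataFrame, fold: float = 5.0
) -> dict[str, list[str]]:
    """Tissue-specific genes by the fivefold-over-any-other-tissue rule.

    ``mean_expr`` is genes x tissues (mean expression per tissue). Gene g is
    t-specific iff expr(g, t) >= fold * max over all other tissues
    (inclusive); when no other tissue expresses g at all, g is t-specific
    iff expr(g, t) > 0.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if mean_expr.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    vals = mean_expr.to_numpy(dtype=float)
    out: dict[str, list[str]] = {t: [] for t in mean_expr.columns}
    for j, tissue in enumerate(mean_expr.columns):
        others = np.delete(vals, j, axis=1).max(axis=1)
        own = vals[:, j]
        specific = np.where(
            others > 0, own >= fold * others, own > 0
        )
        out[tissue] = list(mean_expr.index[specific])
    return out


def fold_change_de(
    group_a: pd.DataFrame, group_b: pd.DataFrame, fold: float = 2.0
) -> tuple[set[str], set[str]]:
    """Meta-analysis differential-expression rule on group means.

    Gene up in b iff mean_b >= fold * mean_a (inclusive) and mean_b > 0;
    down symmetric. Matrices are genes x samples over a shared universe.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if list(group_a.index) != list(group_b.index):
        raise ValueError("groups must share an identically ordered gene universe")
    mean_a = group_a.mean(axis=1).to_numpy()
    mean_b = group_b.mean(axis=1).to_numpy()
    genes = np.asarray(group_a.index)
    up = set(genes[(mean_b >= fold * mean_a) & (mean_b > 0)])
    down = set(genes[(mean_a >= fold * mean_b) & (mean_a > 0)])
    return up, down


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(p_values, float), method="bh")


def _overlap_bp(track: SignalTrack, regions: list[GenomicInterval]) -> np.ndarray:
    """Per-track-interval bp of overlap with the (merged) regions."""
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = np.zeros(len(track.data), dtype=float)
    for i, row in enumerate(track.data.itertuples()):
        for iv in by_chrom.get(row.chrom, ()):
            out[i] += max(0, min(row.end, iv.end) - max(row.start, iv.start))
    return out


def chip_snr(
    track: SignalTrack,
    peaks: list[GenomicInterval],
    genes: Sequence[GeneModel],
    raw_reads: int,
    snr_min: float = 0.01,
    coverage_min: float = 0.999,
    reads_min: float = 1e7,
    flank: int = 500,
) -> SnrResult:
    """ChIP-seq quality filter: signal-to-noise, gene coverage, read depth.

    snr = (AUC of signal inside peak regions) / (AUC outside); a zero
    outside-integral flags snr as infinite and the pass decision falls to
    the remaining criteria. coverage_frac is the fraction of genes whose
    [flank bp strandwise upstream, gene end] span overlaps any nonzero
    signal. Boundary semantics: snr strictly > ``snr_min``; coverage and
    reads inclusive (>=).
    """
    inside_bp = _overlap_bp(track, peaks) if peaks else np.zeros(len(track.data))
    lengths = (track.data["end"] - track.data["start"]).to_numpy(dtype=float)
    values = track.data["value"].to_numpy(dtype=float)
    inside = float((values * inside_bp).sum())
    outside = float((values * (lengths - inside_bp)).sum())
    snr = float("inf") if outside == 0 else inside / outside

    nonzero = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in track.data.itertuples() if r.value > 0
    ]
    covered = 0
    for g in genes:
        span = g.body_with_upstream(flank)
        if any(span.overlaps(iv) for iv in nonzero):
            covered += 1
    coverage = covered / len(genes) if genes else float("nan")

    snr_ok = snr > snr_min  # inf passes
    passed = bool(
        snr_ok and coverage >= coverage_min and raw_reads >= reads_min
    )
    return SnrResult(snr, coverage, int(raw_reads), passed)
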