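"""CpG-island calling and CGI+/CGI- gene classification.

A CpG island (CGI) is called wherever the sequence is CpG-dense: GC content
>= 50%, length > 200 bp and observed/expected CpG ratio > 0.6, the classic
sequence criteria. The caller is declarative: its output is the set of
maximal merged intervals covered by *any* window satisfying all three
criteria, which makes it directly checkable against an exhaustive
all-window scan.

Gene classification uses dual evidence: a gene is CGI+ only when both a
sequence-called CGI and a consensus CxxC-binding region (experimentally
validated unmethylated CpG-rich DNA) sit within +/-500 bp of its TSS, and
CGI- only when neither element touches the span from 500 bp upstream
(strandwise) through the gene body. Everything else is left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CgiClass, GeneModel, GenomicInterval

__all__ = [
    "CgiCall",
    "ConsensusRegion",
    "call_cgis",
    "consensus_regions",
    "classify_genes",
    "merge_intervals",
]


@dataclass(frozen=True)
class CgiCall:
    interval: GenomicInterval
    gc_frac: float
    obs_exp: float
    length: int


@dataclass(frozen=True)
class ConsensusRegion:
    interval: GenomicInterval
    support: int


_VALID = set("ACGTN")


def _composition_stats(seq: str, start: int, end: int):
    """(gc_frac, obs_exp, n_frac) on seq[start:end]; N bases count toward
    length only."""
    sub = seq[start:end]
    length = end - start
    nc = sub.count("C")
    ng = sub.count("G")
    nn = sub.count("N")
    ncpg = sub.count("CG")
    gc = (nc + ng) / length
    obs_exp = (ncpg * length) / (nc * ng) if nc and ng else 0.0
    return gc, obs_exp, nn / length


def call_cgis(
    sequence: str,
    min_len: int = 201,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    max_n_frac: float = 0.5,
    chrom: str = "seq",
) -> list[CgiCall]:
    """Call CpG islands on a sequence.

    A window [s, e) qualifies when e - s >= ``min_len``, GC fraction >=
    ``min_gc``, observed/expected CpG = (N_CpG * L) / (N_C * N_G) >
    ``min_obs_exp`` and its N fraction is <= ``max_n_frac``. Calls are the
    maximal merged intervals of the union of all qualifying windows, with
    per-call statistics recomputed on each merged interval.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    L = len(seq)
    if L < min_len:
        return []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    # prefix sums: C[i] = count in seq[:i]; P[i] = CpG pair starts in seq[:i]
    C = np.concatenate([[0], np.cumsum(is_c)]).astype(np.int32)
    G = np.concatenate([[0], np.cumsum(is_g)]).astype(np.int32)
    N = np.concatenate([[0], np.cumsum(is_n)]).astype(np.int32)
    pair = is_c[:-1] & is_g[1:]
    # P[e] = number of CpG pair starts in seq[:e-1] (pairs fully inside [0,e))
    P = np.concatenate([[0, 0], np.cumsum(pair)]).astype(np.int32)

    # For each window start s, the union of qualifying windows [s, e) is
    # [s, e_max(s)); coverage is the union over s. Starts are processed in
    # blocks, ends vectorised.
    cover_start = np.full(L, -1, dtype=np.int64)  # e_max per start, -1 if none
    ends_all = np.arange(L + 1, dtype=np.int32)
    block = max(16, int(4e6 // max(L, 1)))  # cap working-set size
    for s0 in range(0, L - min_len + 1, block):
        s1 = min(s0 + block, L - min_len + 1)
        starts = np.arange(s0, s1, dtype=np.int32)[:, None]
        ends = ends_all[None, s0 + min_len:]
        lens = ends - starts  # may be <= 0 for late starts/early ends
        nc = C[ends] - C[starts]
        ng = G[ends] - G[starts]
        nn = N[ends] - N[starts]
        # pairs fully inside [s,e) start in [s, e-1): count = P[e] - P[s+1]
        ncpg = P[ends] - P[starts + 1]
        gc_ok = (nc + ng) >= min_gc * lens
        n_ok = nn <= max_n_frac * lens
        oe_ok = ncpg.astype(np.int64) * lens > min_obs_exp * (
            nc.astype(np.int64) * ng
        )
        oe_ok &= (nc > 0) & (ng > 0)
        qual = (lens >= min_len) & gc_ok & n_ok & oe_ok
        any_q = qual.any(axis=1)
        if any_q.any():
            # last qualifying end per start
            last = qual.shape[1] - 1 - np.argmax(qual[:, ::-1], axis=1)
            emax = ends_all[s0 + min_len:][last]
            idx = np.arange(s0, s1)[any_q]
            cover_start[idx] = emax[any_q]

    intervals = [
        (int(s), int(e)) for s, e in zip(np.flatnonzero(cover_start >= 0),
                                         cover_start[cover_start >= 0])
    ]
    merged = _merge_tuples(intervals)
    calls = []
    for s, e in merged:
        gc, oe, _ = _composition_stats(seq, s, e)
        calls.append(
            CgiCall(GenomicInterval(chrom, s, e), gc, oe, e - s)
        )
    return calls


def _merge_tuples(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_tuples(by_chrom[chrom]):
            out.append(GenomicInterval(chrom, s, e))
    return out


def consensus_regions(
    peak_sets: list[list[GenomicInterval]], min_support: int | None = None
) -> list[ConsensusRegion]:
    """Maximal intervals covered by at least one peak in every input set.

    With ``min_support`` (default: all sets), intervals covered by at least
    that many sets are returned instead.
    """
    if not peak_sets:
        raise ValueError("consensus requires at least one peak set")
    k = len(peak_sets)
    if min_support is None:
        min_support = k
    if not (1 <= min_support <= k):
        raise ValueError(f"min_support must be in [1, {k}]")

    # coverage-count sweep over merged per-set intervals
    events: dict[str, list[tuple[int, int]]] = {}
    for peaks in peak_sets:
        for iv in merge_intervals(peaks):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out: list[ConsensusRegion] = []
    for chrom in sorted(events):
        depth = 0
        region_start = None
        for pos, delta in sorted(events[chrom]):
            new_depth = depth + delta
            if depth < min_support <= new_depth and region_start is None:
                region_start = pos
            elif region_start is not None and new_depth < min_support:
                if pos > region_start:
                    out.append(
                        ConsensusRegion(GenomicInterval(chrom, region_start, pos), k)
                    )
                region_start = None
            depth = new_depth
    return out


def classify_genes(
    genes: list[GeneModel],
    cgi_calls: list[CgiCall],
    consensus: list[ConsensusRegion],
    flank: int = 500,
) -> list[GeneModel]:
    """Assign each gene a CGI class by the dual-evidence rule.

    CGI_PLUS: both a CGI call and a consensus CxxC region overlap the
    (2*flank + 1)-bp window centred on the TSS. CGI_MINUS: neither element
    overlaps the span from ``flank`` bp strandwise-upstream of the TSS
    through the gene end. Otherwise UNCLASSIFIED.
    """
    cgi_ivs = [c.interval for c in cgi_calls]
    con_ivs = [c.interval for c in consensus]

    def _any_overlap(window: GenomicInterval, ivs: list[GenomicInterval]) -> bool:
        return any(window.overlaps(iv) for iv in ivs)

    out = []
    for g in genes:
        tss_window = GenomicInterval(
            g.interval.chrom, max(0, g.tss - flank), g.tss + flank + 1
        )
        span = g.body_with_upstream(flank)
        cgi_at_tss = _any_overlap(tss_window, cgi_ivs)
        con_at_tss = _any_overlap(tss_window, con_ivs)
        cgi_in_span = _any_overlap(span, cgi_ivs)
        con_in_span = _any_overlap(span, con_ivs)
        if cgi_at_tss and con_at_tss:
            label = CgiClass.CGI_PLUS
        elif not cgi_in_span and not con_in_span:
            label = CgiClass.CGI_MINUS
        else:
            label = CgiClass.UNCLASSIFIED
        out.append(g.with_class(label))
    return out
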