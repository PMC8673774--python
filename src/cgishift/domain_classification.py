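"""Consensus chromatin-domain classification from Hi-C PC1 tracks.

At 50-kb resolution, a genomic bin is constitutively euchromatic (cEu) when
at least 95% of surveyed cell/tissue types have a positive Hi-C PC1 value
there, constitutively heterochromatic (cHet) when at least 95% are
non-positive, and interconvertible (Eu-Het) otherwise. One representative
dataset per cell type (the one with the most aligned reads) feeds the
consensus. PC1 == 0 counts as non-positive; bins missing in more than half
of the cell types are left unlabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CgiClass, GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "BIN_SIZE",
    "Pc1Matrix",
    "DomainCall",
    "select_representative",
    "pc1_matrix_from_tracks",
    "classify_domains",
    "assign_gene_domain",
    "stratified_up_fraction",
]

BIN_SIZE = 50_000
LABELS = ("cEu", "cHet", "EuHet")


@dataclass
class Pc1Matrix:
    """PC1 values per (50-kb bin, cell type); NaN marks missing bins."""

    bins: pd.DataFrame  # columns chrom, start, end
    pc1: pd.DataFrame  # rows align with bins, one column per cell type

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.pc1):
            raise ValueError("bins and pc1 must have equal row counts")
        off = (self.bins["start"] % BIN_SIZE != 0) | (
            self.bins["end"] - self.bins["start"] != BIN_SIZE
        )
        if off.any():
            row = self.bins[off].iloc[0]
            raise ValueError(
                f"bin {row['chrom']}:{row['start']}-{row['end']} not aligned "
                f"to the {BIN_SIZE}-bp grid"
            )
        if self.pc1.columns.duplicated().any():
            raise ValueError("duplicate cell-type ids")

    @property
    def celltypes(self) -> list[str]:
        return list(self.pc1.columns)


@dataclass(frozen=True)
class DomainCall:
    bin: GenomicInterval
    label: str | None  # cEu | cHet | EuHet | None when unlabeled
    frac_positive: float


def select_representative(
    datasets: Mapping[str, Mapping[str, int]]
) -> dict[str, str]:
    """Pick per cell type the dataset with the most aligned reads.

    ``datasets`` maps cell type -> {dataset id -> aligned read count}. Ties
    break to the lexicographically first id, with a warning.
    """
    out: dict[str, str] = {}
    for celltype, counts in datasets.items():
        if not counts:
            raise ValueError(f"cell type {celltype!r} has no datasets")
        best = max(counts.values())
        winners = sorted(d for d, c in counts.items() if c == best)
        if len(winners) > 1:
            warnings.warn(
                f"cell type {celltype!r}: aligned-read tie between "
                f"{winners}; keeping {winners[0]}", stacklevel=2,
            )
        out[celltype] = winners[0]
    return out


def pc1_matrix_from_tracks(tracks: Mapping[str, SignalTrack]) -> Pc1Matrix:
    """Assemble per-cell-type PC1 bedGraph tracks into a Pc1Matrix.

    Track intervals must be 50-kb bins; bins absent from a track are NaN
    for that cell type.
    """
    if not tracks:
        raise ValueError("no tracks given")
    frames = {}
    for celltype, track in tracks.items():
        d = track.data
        off = (d["start"] % BIN_SIZE != 0) | (d["end"] - d["start"] != BIN_SIZE)
        if off.any():
            raise ValueError(
                f"track {celltype!r} has bins off the {BIN_SIZE}-bp grid"
            )
        frames[celltype] = d.set_index(
            pd.MultiIndex.from_frame(d[["chrom", "start"]])
        )["value"]
    pc1 = pd.DataFrame(frames).sort_index()
    bins = pd.DataFrame(
        {
            "chrom": pc1.index.get_level_values(0),
            "start": pc1.index.get_level_values(1),
        }
    )
    bins["end"] = bins["start"] + BIN_SIZE
    return Pc1Matrix(bins.reset_index(drop=True), pc1.reset_index(drop=True))


def classify_domains(
    pc1: Pc1Matrix, consensus: float = 0.95, exclude_y: bool = True
) -> list[DomainCall]:
    """Call cEu / cHet / Eu-Het per bin from the cross-cell-type consensus.

    ``frac_positive`` is computed over the non-missing cell types of each
    bin ("at least 95%" is inclusive). PC1 == 0 counts as non-positive.
    """
    if pc1.pc1.shape[1] < 2:
        raise ValueError("need at least 2 cell types for a consensus")
    vals = pc1.pc1.to_numpy(dtype=float)
    n_celltypes = vals.shape[1]
    informative = ~np.isnan(vals)
    n_inf = informative.sum(axis=1)
    n_pos = np.nansum(vals > 0, axis=1)
    calls: list[DomainCall] = []
    for i, row in enumerate(pc1.bins.itertuples()):
        if exclude_y and row.chrom in ("chrY", "Y"):
            continue
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        if n_inf[i] == 0 or n_inf[i] < 0.5 * n_celltypes:
            calls.append(DomainCall(iv, None, float("nan")))
            continue
        frac_pos = n_pos[i] / n_inf[i]
        if frac_pos >= consensus:
            label = "cEu"
        elif (1.0 - frac_pos) >= consensus:
            label = "cHet"
        else:
            label = "EuHet"
        calls.append(DomainCall(iv, label, float(frac_pos)))
    return calls


def assign_gene_domain(
    genes: Sequence[GeneModel], calls: Sequence[DomainCall]
) -> dict[str, str | None]:
    """Map each gene to the domain label of its TSS bin.

    If the TSS bin is unlabeled (or absent), the labeled bin with the
    largest gene-body overlap is used instead (ties to the leftmost bin);
    genes with no labeled overlap are recorded as None.
    """
    by_bin: dict[tuple[str, int], DomainCall] = {
        (c.bin.chrom, c.bin.start): c for c in calls
    }
    out: dict[str, str | None] = {}
    for g in genes:
        tss_bin = by_bin.get((g.interval.chrom, g.tss // BIN_SIZE * BIN_SIZE))
        if tss_bin is not None and tss_bin.label is not None:
            out[g.gene_id] = tss_bin.label
            continue
        # gene-body majority among labeled bins
        best_label, best_overlap = None, 0
        start_bin = g.interval.start // BIN_SIZE * BIN_SIZE
        for bs in range(start_bin, g.interval.end, BIN_SIZE):
            call = by_bin.get((g.interval.chrom, bs))
            if call is None or call.label is None:
                continue
            ov = g.interval.overlap_length(call.bin)
            if ov > best_overlap:
                best_label, best_overlap = call.label, ov
        out[g.gene_id] = best_label
    return out


def stratified_up_fraction(
    gene_domains: Mapping[str, str | None],
    cgi_classes: Mapping[str, CgiClass],
    up_genes: set[str],
) -> pd.DataFrame:
    """Percent up-regulated genes per (domain x CGI class) stratum.

    Returns a tidy table with, per stratum, the number of genes, the percent
    of them in ``up_genes`` (NaN for an empty stratum) and the stratum's
    share of its CGI class (the polar-angle quantity of a radial plot).
    """
    rows = []
    class_totals = {
        cls: sum(
            1 for g, c in cgi_classes.items()
            if c == cls and gene_domains.get(g) in LABELS
        )
        for cls in (CgiClass.CGI_PLUS, CgiClass.CGI_MINUS)
    }
    for cls in (CgiClass.CGI_PLUS, CgiClass.CGI_MINUS):
        for label in LABELS:
            stratum = [
                g for g, c in cgi_classes.items()
                if c == cls and gene_domains.get(g) == label
            ]
            n = len(stratum)
            pct_up = 100.0 * len(up_genes.intersection(stratum)) / n if n else float("nan")
            share = (
                100.0 * n / class_totals[cls] if class_totals[cls] else float("nan")
            )
            rows.append({
                "cgi_class": str(cls.value), "domain": label, "n_genes": n,
                "pct_up": pct_up, "pct_of_class": share,
            })
    return pd.DataFrame(rows)
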