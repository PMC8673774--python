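"""Synthetic pipeline inputs with planted, recorded ground truth.

Every generator is a pure function of its parameters and a seed, so each
stage of the pipeline can be tested end-to-end against a recorded truth
object without any external data. The defaults encode the study regime the
analysis targets: a configurable fraction of CGI- genes up-regulated 2-4x
in aged bulk samples, single-cell data with age-dependent cell-to-cell
dispersion, PC1 tracks over constitutive and interconvertible 50-kb
domains, and ChIP-like pileups with known inside/outside peak rates.

Seeding: a global seed expands to per-component child streams as
``numpy.random.default_rng([seed, component_code])`` with fixed codes
(bulk=1, sc=2, pc1=3, pileup=4, genome=5), so partial re-runs of one
generator reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CgiClass,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SignalTrack,
)

__all__ = [
    "BulkTruth",
    "SingleCellTruth",
    "Pc1Truth",
    "PileupTruth",
    "DomainSpec",
    "simulate_bulk",
    "simulate_single_cell",
    "simulate_pc1_tracks",
    "simulate_pileup",
    "simulate_genome_sequence",
    "default_domain_layout",
]

_COMPONENT_CODES = {"bulk": 1, "sc": 2, "pc1": 3, "pileup": 4, "genome": 5}

BIN_SIZE = 50_000


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _COMPONENT_CODES[component]])


# ---------------------------------------------------------------------------
# bulk RNA-seq


@dataclass(frozen=True)
class BulkTruth:
    seed: int
    frac_cgi_minus: float
    frac_up: float
    fc_low: float
    fc_high: float
    baseline_log10_mean: float
    baseline_log10_sd: float
    dispersion: float
    gene_classes: dict[str, CgiClass]
    planted_fc: dict[str, float]  # gene id -> fold change applied to aged mean
    baseline: dict[str, float]  # gene id -> expected normalized expression


def simulate_bulk(
    n_genes: int = 6000,
    n_young: int = 8,
    n_aged: int = 8,
    frac_cgi_minus: float = 0.25,
    frac_up: float = 0.3,
    fc_low: float = 2.0,
    fc_high: float = 4.0,
    baseline_log10_mean: float = 1.5,
    baseline_log10_sd: float = 0.7,
    dispersion: float = 0.05,
    depth_sd: float = 0.1,
    sex: str = "F",
    tissue: str = "synthetic",
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[GeneModel], BulkTruth]:
    """Simulate a young/aged bulk count matrix with planted up-regulation.

    Gene baselines are log-normal (log10 mean/sd as given); raw counts are
    negative binomial around each sample's expected value (gamma-Poisson
    with the given dispersion). A fraction ``frac_up`` of the CGI- genes is
    planted up-regulated in aged samples by fold changes drawn log-uniform
    on [fc_low, fc_high]. Genes receive synthetic coordinates, one gene per
    consecutive 50-kb bin of "chr1", so a domain layout over the same bins
    applies directly.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if min(n_young, n_aged) < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= frac_cgi_minus <= 1 and 0 <= frac_up <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if frac_up > 0 and frac_cgi_minus == 0:
        raise ValueError("frac_up > 0 with no CGI- genes: nothing to up-regulate")
    if fc_low < 1 or fc_high < fc_low:
        raise ValueError("require 1 <= fc_low <= fc_high")

    rng = _rng(seed, "bulk")
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    genes = [
        GeneModel.from_interval(
            gid,
            GenomicInterval("chr1", i * BIN_SIZE + 10_000, i * BIN_SIZE + 12_000, "+"),
        )
        for i, gid in enumerate(gene_ids)
    ]

    n_minus = int(round(frac_cgi_minus * n_genes))
    order = rng.permutation(n_genes)
    minus_idx = np.sort(order[:n_minus])
    minus_set = set(minus_idx.tolist())
    classes = {
        gid: (CgiClass.CGI_MINUS if i in minus_set else CgiClass.CGI_PLUS)
        for i, gid in enumerate(gene_ids)
    }
    genes = [g.with_class(classes[g.gene_id]) for g in genes]

    baseline = 10.0 ** rng.normal(baseline_log10_mean, baseline_log10_sd, n_genes)

    n_planted = int(round(frac_up * n_minus))
    planted_idx = np.sort(rng.choice(minus_idx, size=n_planted, replace=False))
    fc = np.ones(n_genes)
    drawn = np.exp(rng.uniform(np.log(fc_low), np.log(fc_high), n_planted))
    fc[planted_idx] = drawn

    n_samples = n_young + n_aged
    depth = np.exp(rng.normal(0.0, depth_sd, n_samples))
    mu = baseline[:, None] * depth[None, :]
    mu[:, n_young:] *= fc[:, None]
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    sample_ids = [f"young{i:02d}" for i in range(n_young)] + [
        f"aged{i:02d}" for i in range(n_aged)
    ]
    values = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "age_group": ["young"] * n_young + ["aged"] * n_aged,
            "sex": sex,
            "tissue": tissue,
            "total_mapped_reads": values.sum(axis=0).to_numpy(),
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(values, meta, layer="raw")
    truth = BulkTruth(
        seed=seed,
        frac_cgi_minus=frac_cgi_minus,
        frac_up=frac_up,
        fc_low=fc_low,
        fc_high=fc_high,
        baseline_log10_mean=baseline_log10_mean,
        baseline_log10_sd=baseline_log10_sd,
        dispersion=dispersion,
        gene_classes=classes,
        planted_fc={gene_ids[i]: float(f) for i, f in zip(planted_idx, drawn)},
        baseline={g: float(b) for g, b in zip(gene_ids, baseline)},
    )
    return matrix, genes, truth


# ---------------------------------------------------------------------------
# single-cell RNA-seq


@dataclass(frozen=True)
class SingleCellTruth:
    seed: int
    dispersion_young: float
    dispersion_aged: float
    frac_cgi_minus: float
    cgi_minus_only: bool
    gene_classes: dict[str, CgiClass]


def simulate_single_cell(
    n_genes: int = 2000,
    cells_per_group: int = 60,
    dispersion_young: float = 0.15,
    dispersion_aged: float = 0.30,
    n_individuals: int = 12,
    frac_cgi_minus: float = 0.3,
    cgi_minus_only: bool = False,
    mean_library: float = 3e5,
    baseline_log10_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SingleCellTruth]:
    """Simulate young/aged single-cell counts with group-level dispersion.

    Each cell's expected profile is a shared log-normal baseline times a
    cell-specific log-normal perturbation whose log10 sd is the group's
    dispersion; counts are Poisson around the expected profile scaled to a
    variable library size. With ``cgi_minus_only`` the aged group's extra
    dispersion applies only to CGI- genes (CGI+ genes keep the young
    dispersion), which is the stratum-confined noise scenario.
    """
    if cells_per_group < 10:
        raise ValueError("cells_per_group must be >= 10")
    if dispersion_young <= 0 or dispersion_aged <= 0:
        raise ValueError("dispersions must be > 0")

    rng = _rng(seed, "sc")
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_minus = int(round(frac_cgi_minus * n_genes))
    order = rng.permutation(n_genes)
    minus_mask = np.zeros(n_genes, dtype=bool)
    minus_mask[order[:n_minus]] = True
    classes = {
        gid: (CgiClass.CGI_MINUS if m else CgiClass.CGI_PLUS)
        for gid, m in zip(gene_ids, minus_mask)
    }

    baseline = 10.0 ** rng.normal(0.0, baseline_log10_sd, n_genes)
    cells, groups, individuals = [], [], []
    profiles = np.empty((n_genes, 2 * cells_per_group))
    col = 0
    for group, disp in (("young", dispersion_young), ("aged", dispersion_aged)):
        for c in range(cells_per_group):
            sd = np.full(n_genes, disp)
            if cgi_minus_only and group == "aged":
                sd = np.where(minus_mask, disp, dispersion_young)
            # mean-one log-normal: dispersion changes variability, not the
            # expected composition (E[10^(sd Z)] = 10^(sd^2 ln10 / 2))
            perturb = 10.0 ** (rng.normal(0.0, sd) - sd**2 * np.log(10.0) / 2.0)
            profiles[:, col] = baseline * perturb
            cells.append(f"{group}_c{c:03d}")
            groups.append(group)
            individuals.append(f"{group}_i{c % n_individuals:02d}")
            col += 1
    libraries = np.exp(rng.normal(np.log(mean_library), 0.2, 2 * cells_per_group))
    expected = profiles / profiles.sum(axis=0, keepdims=True) * libraries
    counts = rng.poisson(expected).astype(np.int64)

    values = pd.DataFrame(counts, index=gene_ids, columns=cells)
    meta = pd.DataFrame(
        {"group": groups, "individual": individuals}, index=cells
    )
    truth = SingleCellTruth(
        seed, dispersion_young, dispersion_aged, frac_cgi_minus,
        cgi_minus_only, classes,
    )
    return ExpressionMatrix(values, meta, layer="raw"), truth


# ---------------------------------------------------------------------------
# Hi-C PC1 tracks


@dataclass(frozen=True)
class DomainSpec:
    """One layout entry: a 50-kb-aligned interval, its true label, and, for
    Eu-Het intervals, the per-cell-type probability of a positive sign."""

    interval: GenomicInterval
    label: str  # cEu | cHet | EuHet
    p_positive: float = 0.5


@dataclass(frozen=True)
class Pc1Truth:
    seed: int
    flip_prob: float
    n_celltypes: int
    layout: tuple[DomainSpec, ...]


def default_domain_layout(
    n_bins: int,
    frac_ceu: float = 0.4,
    frac_chet: float = 0.4,
    chrom: str = "chr1",
) -> list[DomainSpec]:
    """A simple block layout: cEu bins first, then cHet, then Eu-Het."""
    n_ceu = int(round(frac_ceu * n_bins))
    n_chet = int(round(frac_chet * n_bins))
    out = []
    for i in range(n_bins):
        label = "cEu" if i < n_ceu else ("cHet" if i < n_ceu + n_chet else "EuHet")
        out.append(
            DomainSpec(
                GenomicInterval(chrom, i * BIN_SIZE, (i + 1) * BIN_SIZE), label
            )
        )
    return out


def simulate_pc1_tracks(
    domain_layout: Sequence[DomainSpec],
    n_celltypes: int = 30,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, SignalTrack], Pc1Truth]:
    """Per-cell-type PC1 tracks over a known domain layout.

    Each cell type's PC1 sign on a constitutive bin equals the true label's
    sign (cEu -> +, cHet -> -), flipped independently with ``flip_prob``;
    Eu-Het bins are positive with the layout entry's ``p_positive``.
    Magnitudes are uniform on [0.2, 1.5].
    """
    if n_celltypes < 1:
        raise ValueError("need >= 1 cell type")
    if not (0 <= flip_prob <= 1):
        raise ValueError("flip_prob must be in [0, 1]")
    bins: list[tuple[str, int, str, float]] = []
    for spec in domain_layout:
        iv = spec.interval
        if iv.start % BIN_SIZE or iv.end % BIN_SIZE:
            raise ValueError(
                f"layout interval {iv.chrom}:{iv.start}-{iv.end} is not "
                f"{BIN_SIZE}-bp aligned"
            )
        if spec.label not in ("cEu", "cHet", "EuHet"):
            raise ValueError(f"unknown layout label {spec.label!r}")
        for bs in range(iv.start, iv.end, BIN_SIZE):
            bins.append((iv.chrom, bs, spec.label, spec.p_positive))

    rng = _rng(seed, "pc1")
    n_bins = len(bins)
    tracks: dict[str, SignalTrack] = {}
    for t in range(n_celltypes):
        magnitude = rng.uniform(0.2, 1.5, n_bins)
        u = rng.random(n_bins)
        sign = np.empty(n_bins)
        for i, (_, _, label, p_pos) in enumerate(bins):
            if label == "cEu":
                sign[i] = -1.0 if u[i] < flip_prob else 1.0
            elif label == "cHet":
                sign[i] = 1.0 if u[i] < flip_prob else -1.0
            else:
                sign[i] = 1.0 if u[i] < p_pos else -1.0
        tracks[f"celltype{t:02d}"] = SignalTrack.from_arrays(
            [b[0] for b in bins],
            [b[1] for b in bins],
            [b[1] + BIN_SIZE for b in bins],
            magnitude * sign,
            signed=True,
        )
    truth = Pc1Truth(seed, flip_prob, n_celltypes, tuple(domain_layout))
    return tracks, truth


# ---------------------------------------------------------------------------
# ChIP-like pileup


@dataclass(frozen=True)
class PileupTruth:
    seed: int
    rate_in: float
    rate_out: float
    peak_bp: int
    nonpeak_bp: int


def simulate_pileup(
    genome_length: int,
    peaks: Sequence[GenomicInterval],
    rate_in: float,
    rate_out: float,
    bin_size: int = 50,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[SignalTrack, list[GenomicInterval], PileupTruth]:
    """A pileup track with Poisson signal at known inside/outside rates.

    The expected track integral equals rate_in * peak bp inside peaks and
    rate_out * non-peak bp outside (each bin's value is a Poisson draw with
    mean rate * bin length, divided by the bin length).
    """
    if rate_in < 0 or rate_out < 0:
        raise ValueError("rates must be >= 0")
    for iv in peaks:
        if iv.start < 0 or iv.end > genome_length:
            raise ValueError(
                f"peak {iv.start}-{iv.end} outside genome [0, {genome_length})"
            )
    from .cgi_annotation import merge_intervals

    merged = merge_intervals(
        [GenomicInterval(chrom, p.start, p.end) for p in peaks]
    )
    # segment the genome at peak boundaries
    boundaries = sorted({0, genome_length, *(p.start for p in merged),
                         *(p.end for p in merged)})
    inside = {}
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        inside[(s, e)] = any(p.start <= s and e <= p.end for p in merged)

    rng = _rng(seed, "pileup")
    starts, ends, values = [], [], []
    for (s, e), is_peak in inside.items():
        rate = rate_in if is_peak else rate_out
        for bs in range(s, e, bin_size):
            be = min(bs + bin_size, e)
            length = be - bs
            values.append(rng.poisson(rate * length) / length)
            starts.append(bs)
            ends.append(be)
    track = SignalTrack.from_arrays([chrom] * len(starts), starts, ends, values)
    peak_bp = sum(len(p) for p in merged)
    truth = PileupTruth(seed, rate_in, rate_out, peak_bp, genome_length - peak_bp)
    return track, merged, truth


# ---------------------------------------------------------------------------
# genome sequence with planted CpG islands


def simulate_genome_sequence(
    length: int,
    planted_cgis: Sequence[tuple[int, int]],
    gc_background: float = 0.3,
    cpg_suppression: float = 0.15,
    seed: int = 0,
    chrom: str = "chrS",
):
    """A synthetic chromosome: CpG-poor background, CpG-rich planted islands.

    The background is a first-order Markov chain at the given GC content
    with the C->G transition down-weighted by ``cpg_suppression`` (so its
    observed/expected CpG ratio is well below the island-calling cutoff).
    Planted intervals (each >= 250 bp, pairwise gaps >= 500 bp,
    non-overlapping) are rewritten with a CpG-rich emitter (GC ~0.83,
    obs/exp ~1.5). Returns a Bio.SeqRecord and the truth intervals.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    ivs = sorted((int(s), int(e)) for s, e in planted_cgis)
    for s, e in ivs:
        if not (0 <= s < e <= length):
            raise ValueError(f"planted interval [{s}, {e}) outside genome")
        if e - s < 250:
            raise ValueError(f"planted interval [{s}, {e}) shorter than 250 bp")
    for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
        if s2 < e1:
            raise ValueError(f"planted intervals overlap at [{s2}, {e1})")
        if s2 - e1 < 500:
            raise ValueError(
                f"gap between planted intervals [{e1}, {s2}) is under 500 bp"
            )

    rng = _rng(seed, "genome")
    bases = np.array(list("ACGT"))
    at = (1.0 - gc_background) / 2.0
    gc = gc_background / 2.0
    base_p = np.array([at, gc, gc, at])
    after_c = base_p.copy()
    after_c[2] *= cpg_suppression  # suppress CpG dinucleotides
    after_c /= after_c.sum()
    cum_base = np.cumsum(base_p)
    cum_after_c = np.cumsum(after_c)
    u = rng.random(length)
    seq = np.empty(length, dtype="<U1")
    prev_c = False
    for i in range(length):
        cum = cum_after_c if prev_c else cum_base
        j = int(np.searchsorted(cum, u[i], side="right"))
        j = min(j, 3)
        seq[i] = bases[j]
        prev_c = j == 1

    island_singles = np.array(list("ACGT"))
    single_p = np.array([0.2, 0.3, 0.3, 0.2])
    for s, e in ivs:
        chunk: list[str] = []
        while len(chunk) < e - s:
            if rng.random() < 0.4:
                chunk.extend("CG")
            else:
                chunk.append(str(rng.choice(island_singles, p=single_p)))
        seq[s:e] = chunk[: e - s]

    record = SeqRecord(Seq("".join(seq)), id=chrom, description="synthetic")
    truth = [GenomicInterval(chrom, s, e) for s, e in ivs]
    return record, truth
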