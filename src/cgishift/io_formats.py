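"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive GTF convention happens only at the I/O boundary.
Chromosome names are matched exactly (no "chr" stripping).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CgiClass",
    "GeneModel",
    "ExpressionMatrix",
    "SignalTrack",
    "parse_gene_models",
    "write_gene_models",
    "parse_signal",
    "write_signal",
    "parse_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_mtx",
    "write_matrix_mtx",
    "read_metadata",
    "write_metadata",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class CgiClass(str, Enum):
    CGI_PLUS = "CGI_PLUS"
    CGI_MINUS = "CGI_MINUS"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class GeneModel:
    """A gene: coordinates, strand-aware TSS and CpG-island class.

    The TSS is forced by the half-open convention: ``interval.start`` for a
    '+' gene and ``interval.end - 1`` for a '-' gene.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    cgi_class: CgiClass = CgiClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.interval.strand == "+":
            expected = self.interval.start
        elif self.interval.strand == "-":
            expected = self.interval.end - 1
        else:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.interval.strand} strand interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @classmethod
    def from_interval(
        cls, gene_id: str, interval: GenomicInterval,
        cgi_class: CgiClass = CgiClass.UNCLASSIFIED,
    ) -> "GeneModel":
        tss = interval.start if interval.strand == "+" else interval.end - 1
        return cls(gene_id, interval, tss, cgi_class)

    def with_class(self, cgi_class: CgiClass) -> "GeneModel":
        return replace(self, cgi_class=cgi_class)

    def body_with_upstream(self, flank: int = 500) -> GenomicInterval:
        """Strandwise [5'-most point - flank, gene end] span (half-open)."""
        iv = self.interval
        if iv.strand == "+":
            return GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end, "+")
        return GenomicInterval(iv.chrom, iv.start, iv.end + flank, "-")


# ---------------------------------------------------------------------------
# expression matrices


class MetadataError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples (bulk) or genes x cells (single-cell) values.

    ``values`` is a DataFrame indexed by gene id with sample/cell ids as
    columns; ``meta`` is indexed by sample/cell id. Bulk metadata must carry
    age_group, sex and total_mapped_reads; single-cell metadata a group and
    an individual id.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    layer: str = "raw"

    _LAYERS = ("raw", "normalized", "log")

    def __post_init__(self) -> None:
        if self.layer not in self._LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.layer != "log" and (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise MetadataError(
                f"samples missing from metadata: {missing}"
            )
        # keep metadata aligned and restricted to the matrix's samples
        self.meta = self.meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.meta, self.layer)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.meta.loc[list(sample_ids)], self.layer
        )


# ---------------------------------------------------------------------------
# signal tracks (bedGraph)


class OverlapError(ValueError):
    pass


@dataclass
class SignalTrack:
    """Non-overlapping per-interval signal (bedGraph semantics).

    Pileup-like tracks are non-negative by default; ``signed=True`` admits
    signed signals such as Hi-C PC1 eigenvector tracks.
    """

    data: pd.DataFrame  # columns chrom, start, end, value
    signed: bool = False

    COLUMNS = ("chrom", "start", "end", "value")

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != list(self.COLUMNS):
            df = df[list(self.COLUMNS)]
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if not self.signed and (df["value"] < 0).any():
            bad = df[df["value"] < 0].iloc[0]
            raise ValueError(
                f"negative signal value {bad['value']} at "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        overlap = same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0]) + 1
            row = df.iloc[i]
            raise OverlapError(
                f"overlapping intervals at {row['chrom']}:{row['start']}-{row['end']}"
            )
        self.data = df

    @classmethod
    def from_arrays(cls, chrom, start, end, value, signed: bool = False) -> "SignalTrack":
        return cls(pd.DataFrame({
            "chrom": chrom, "start": np.asarray(start, dtype=int),
            "end": np.asarray(end, dtype=int),
            "value": np.asarray(value, dtype=float),
        }), signed=signed)

    @classmethod
    def empty(cls) -> "SignalTrack":
        return cls(pd.DataFrame({
            "chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
            "end": pd.Series(dtype=int), "value": pd.Series(dtype=float),
        }))

    def __len__(self) -> int:
        return len(self.data)

    def integral(self) -> float:
        """Sum of value x length over all intervals (the track's AUC)."""
        if not len(self.data):
            return 0.0
        d = self.data
        return float(((d["end"] - d["start"]) * d["value"]).sum())

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.data.itertuples()
        ]


# ---------------------------------------------------------------------------
# GTF


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def parse_gene_models(gtf_source, feature: str = "gene") -> list[GeneModel]:
    """Parse gene records from a GTF stream or path.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention and the strand-aware TSS is computed.
    Records with strand '.' are skipped with a warning; malformed lines
    raise a ``ValueError`` naming the line number. For duplicate gene ids
    the first record wins (warned).
    """
    handle, close = _open_text(gtf_source)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"GTF parse error at line {lineno}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feat, start, end, _score, strand, _frame, attrs = fields[:9]
            if feat != feature:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"GTF parse error at line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                warnings.warn(
                    f"GTF line {lineno}: missing strand, record skipped",
                    stacklevel=2,
                )
                continue
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ValueError(
                    f"GTF parse error at line {lineno}: no gene_id attribute"
                )
            if gene_id in seen:
                warnings.warn(
                    f"GTF line {lineno}: duplicate gene_id {gene_id}, first "
                    "record kept", stacklevel=2,
                )
                continue
            seen.add(gene_id)
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            genes.append(GeneModel.from_interval(gene_id, iv))
    finally:
        if close:
            handle.close()
    return genes


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def write_gene_models(genes: Iterable[GeneModel], dest) -> None:
    """Write gene models as minimal GTF (1-based inclusive coordinates)."""
    handle, close = _open_text(dest, "w")
    try:
        for g in genes:
            iv = g.interval
            handle.write(
                "\t".join([
                    iv.chrom, "cgishift", "gene", str(iv.start + 1), str(iv.end),
                    ".", iv.strand, ".", f'gene_id "{g.gene_id}";',
                ]) + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# bedGraph / BED


def parse_signal(bedgraph_source, signed: bool = False) -> SignalTrack:
    """Parse a bedGraph stream/path into a :class:`SignalTrack`.

    Overlapping intervals are rejected; negative values too unless
    ``signed=True`` (e.g. PC1 eigenvector tracks).
    """
    handle, close = _open_text(bedgraph_source)
    chroms, starts, ends, values = [], [], [], []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"bedGraph parse error at line {lineno}: expected 4 fields"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(
                    f"bedGraph parse error at line {lineno}"
                ) from exc
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
    finally:
        if close:
            handle.close()
    if not chroms:
        return SignalTrack.empty()
    return SignalTrack.from_arrays(chroms, starts, ends, values, signed=signed)


def write_signal(track: SignalTrack, dest) -> None:
    handle, close = _open_text(dest, "w")
    try:
        for r in track.data.itertuples():
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")
    finally:
        if close:
            handle.close()


def parse_bed(bed_source) -> list[GenomicInterval]:
    """Parse BED3/BED6 (0-based half-open) into intervals."""
    handle, close = _open_text(bed_source)
    out: list[GenomicInterval] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"BED parse error at line {lineno}: expected >=3 fields"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    finally:
        if close:
            handle.close()
    return out


def write_bed(intervals: Iterable[GenomicInterval], dest, names=None) -> None:
    handle, close = _open_text(dest, "w")
    try:
        for i, iv in enumerate(intervals):
            if names is not None:
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n"
                )
            else:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# count matrices + metadata


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, meta: pd.DataFrame, layer: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = None
    df.columns.name = None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in matrix: {list(dups)[:5]}")
    return ExpressionMatrix(df, meta, layer)


def write_matrix_mtx(matrix: ExpressionMatrix, prefix) -> None:
    """Write MTX triplet: <prefix>.mtx, <prefix>.genes.tsv, <prefix>.samples.tsv."""
    from scipy import io as spio
    from scipy import sparse

    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", sparse.coo_matrix(matrix.values.to_numpy()))
    with open(prefix + ".genes.tsv", "w") as fh:
        fh.write("\n".join(matrix.gene_ids) + "\n")
    with open(prefix + ".samples.tsv", "w") as fh:
        fh.write("\n".join(matrix.sample_ids) + "\n")


def read_matrix_mtx(prefix, meta: pd.DataFrame, layer: str = "raw") -> ExpressionMatrix:
    from scipy import io as spio

    prefix = str(prefix)
    mat = spio.mmread(prefix + ".mtx").toarray()
    with open(prefix + ".genes.tsv") as fh:
        genes = fh.read().split()
    with open(prefix + ".samples.tsv") as fh:
        samples = fh.read().split()
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in MTX companion file")
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionMatrix(df, meta, layer)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
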