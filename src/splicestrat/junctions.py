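"""Splice-junction parsing, count matrices, and isoform quantification.

Alternative first exons of a gene are distinguished by the intron each one
splices out: a read spanning an isoform-unique donor--acceptor pair counts
for that isoform alone.  This module parses junction coordinate strings,
reads junction count tables (plain TSV or per-sample STAR ``SJ.out.tab``
files), and sums the reads on each isoform's discriminating junctions into
per-sample raw and log10(x + pseudocount) expression values.

Coordinates are 1-based, fully closed intron intervals (first and last
intronic base), matching recount3-style junction exports.  Junction matching
is by exact (chrom, start, end, strand) key -- no positional overlap -- and
strand must agree for a row to count.

The two PIK3R1 junctions used throughout are exported as module constants:
``P85A_JUNCTION`` (full-length regulatory isoform p85alpha,
chr5:68281007-68292258:+) and ``P55A_JUNCTION`` (the shorter
alternative-first-exon isoform p55alpha, chr5:68290835-68292258:+), which
share their acceptor coordinate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DefinitionError,
    FormatError,
    ParseError,
    UsageError,
)

__all__ = [
    "GenomicJunction",
    "JunctionMatrix",
    "IsoformDefinition",
    "ExpressionTable",
    "parse_junction_region",
    "read_junction_matrix",
    "quantify_isoforms",
    "write_expression_csv",
    "read_expression_csv",
    "P85A_JUNCTION",
    "P55A_JUNCTION",
    "default_isoform_definitions",
]

# Separators tolerated between start and end: ASCII hyphen, en dash,
# em dash, figure dash, non-breaking hyphen, minus sign.
_SPAN_SEP = "-‐‑‒–—−"
_STRAND_MAP = {"+": "+", "-": "-", "−": "-", "‐": "-", "–": "-"}


@dataclass(frozen=True, order=True)
class GenomicJunction:
    """A splice junction as a closed intronic interval.

    ``start`` and ``end`` are the first and last intronic base (1-based,
    both inclusive); ``strand`` is ``+`` or ``-``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("junction chromosome name must be non-empty")
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise DataError(
                f"junction start must be < end, got [{self.start}, {self.end}]"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


#: Discriminating junction of the full-length p85alpha isoform (hg38).
P85A_JUNCTION = GenomicJunction("chr5", 68281007, 68292258, "+")
#: Discriminating junction of the alternative-first-exon p55alpha isoform.
P55A_JUNCTION = GenomicJunction("chr5", 68290835, 68292258, "+")


def parse_junction_region(text: str) -> GenomicJunction:
    """Parse ``chrom:start-end:strand`` into a :class:`GenomicJunction`.

    Digit-grouping commas are stripped and the start-end separator may be a
    hyphen or any common dash.  An interval printed with start > end (the
    5'->3' convention for minus-strand transcripts) is normalized by
    swapping, with a warning.

    >>> parse_junction_region("chr5:68281007-68292258:+").start
    68281007
    """
    if not isinstance(text, str):
        raise ParseError(f"expected a junction string, got {type(text).__name__}")
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ParseError(
            f"malformed junction {text!r}: expected 'chrom:start-end:strand'"
        )
    chrom, span, strand_tok = (p.strip() for p in parts)
    if not chrom:
        raise ParseError(f"malformed junction {text!r}: empty chromosome token")
    strand = _STRAND_MAP.get(strand_tok)
    if strand is None:
        raise ParseError(f"malformed junction {text!r}: bad strand token {strand_tok!r}")
    m = re.fullmatch(rf"([\d,]+)[{_SPAN_SEP}]([\d,]+)", span)
    if m is None:
        raise ParseError(f"malformed junction {text!r}: bad coordinate span {span!r}")
    start = int(m.group(1).replace(",", ""))
    end = int(m.group(2).replace(",", ""))
    if start == end:
        raise ParseError(f"invalid interval in {text!r}: start == end == {start}")
    if start > end:
        warnings.warn(
            f"junction {text!r} has start > end; swapping to {end}-{start}",
            UserWarning,
            stacklevel=2,
        )
        start, end = end, start
    return GenomicJunction(chrom, start, end, strand)


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering so chr2 sorts before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class JunctionMatrix:
    """Junction-by-sample matrix of non-negative integer read counts."""

    junctions: list[GenomicJunction]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.junctions)} junctions x {len(self.samples)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise DataError("junction counts must be non-negative")
        keys = [j.key for j in self.junctions]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise DataError(f"duplicate junction keys: {sorted(dupes)}")
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sorted(self) -> "JunctionMatrix":
        """Return a copy in canonical (chrom, start, end, strand) order."""
        order = sorted(
            range(len(self.junctions)),
            key=lambda i: (
                _chrom_sort_key(self.junctions[i].chrom),
                self.junctions[i].start,
                self.junctions[i].end,
                self.junctions[i].strand,
            ),
        )
        return JunctionMatrix(
            [self.junctions[i] for i in order], list(self.samples), self.counts[order]
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "chrom": [j.chrom for j in self.junctions],
                "start": [j.start for j in self.junctions],
                "end": [j.end for j in self.junctions],
                "strand": [j.strand for j in self.junctions],
            }
        )
        counts = pd.DataFrame(self.counts, columns=list(self.samples))
        return pd.concat([meta, counts], axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _read_junction_tsv(path: str | Path) -> JunctionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "start", "end", "strand"]
    if list(df.columns[:4]) != required:
        raise FormatError(
            f"{path}: header must start with {required}, got {list(df.columns[:4])}"
        )
    samples = list(df.columns[4:])
    junctions: list[GenomicJunction] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        j = GenomicJunction(str(row.chrom), int(row.start), int(row.end), str(row.strand))
        if j.key in seen:
            raise FormatError(
                f"{path}: duplicate junction key {j} at row {i} "
                f"(first seen at row {seen[j.key]})"
            )
        seen[j.key] = i
        junctions.append(j)
    counts = df[samples].to_numpy()
    if counts.size and counts.min() < 0:
        bad = int(np.argwhere(counts < 0)[0][0])
        raise FormatError(f"{path}: negative count at data row {bad + 2}")
    return JunctionMatrix(junctions, samples, counts).sorted()


_STAR_STRAND = {1: "+", 2: "-"}


def _read_star_sj(path: str | Path, count_column: str) -> dict[tuple, int]:
    """One STAR SJ.out.tab file -> {junction key: count}.

    Columns: chrom, intron start, intron end, strand code (0 undefined,
    1 ``+``, 2 ``-``), motif, annotated, unique reads, multimapping reads,
    max overhang.  ``count_column`` selects ``unique`` (column 7, default)
    or ``total`` (unique + multimapping).
    """
    out: dict[tuple, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            strand_code = int(fields[3])
            if strand_code == 0:
                warnings.warn(
                    f"{path}:{lineno}: undefined-strand junction skipped",
                    UserWarning,
                    stacklevel=3,
                )
                continue
            strand = _STAR_STRAND.get(strand_code)
            if strand is None:
                raise FormatError(f"{path}:{lineno}: bad strand code {strand_code}")
            unique, multi = int(fields[6]), int(fields[7])
            if unique < 0 or multi < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            count = unique if count_column == "unique" else unique + multi
            key = (fields[0], int(fields[1]), int(fields[2]), strand)
            if key in out:
                raise FormatError(
                    f"{path}:{lineno}: duplicate junction key "
                    f"{key[0]}:{key[1]}-{key[2]}:{key[3]}"
                )
            out[key] = count
    return out


def read_junction_matrix(
    path: str | Path | Sequence[str | Path],
    format: str = "tsv",
    count_column: str = "unique",
    sample_names: Sequence[str] | None = None,
) -> JunctionMatrix:
    """Read a junction count matrix.

    ``format="tsv"`` reads one table (header ``chrom start end strand`` then
    one column per sample barcode).  ``format="star_sj"`` reads one
    9-column ``SJ.out.tab`` file per sample and merges them by junction key;
    a junction missing from a sample's file gets count 0.  Sample names
    default to the file stems.  ``count_column`` ("unique" or "total")
    selects which STAR read counter is used.
    """
    if format == "tsv":
        if not isinstance(path, (str, Path)):
            raise UsageError("tsv format expects a single file path")
        return _read_junction_tsv(path)
    if format != "star_sj":
        raise UsageError(f"unknown junction matrix format {format!r}")
    if count_column not in ("unique", "total"):
        raise UsageError(f"count_column must be 'unique' or 'total', got {count_column!r}")
    paths = [path] if isinstance(path, (str, Path)) else list(path)
    if not paths:
        raise UsageError("star_sj format requires at least one file")
    if sample_names is None:
        sample_names = [Path(p).stem for p in paths]
    if len(sample_names) != len(paths):
        raise UsageError("sample_names length must match the number of files")
    per_sample = [_read_star_sj(p, count_column) for p in paths]
    all_keys = sorted(
        {k for d in per_sample for k in d},
        key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3]),
    )
    counts = np.zeros((len(all_keys), len(paths)), dtype=np.int64)
    for col, d in enumerate(per_sample):
        for row, k in enumerate(all_keys):
            counts[row, col] = d.get(k, 0)
    junctions = [GenomicJunction(*k) for k in all_keys]
    return JunctionMatrix(junctions, list(sample_names), counts)


@dataclass(frozen=True)
class IsoformDefinition:
    """A named isoform and the junction(s) unique to it."""

    name: str
    gene: str
    junctions: tuple[GenomicJunction, ...]

    def __post_init__(self) -> None:
        if not self.junctions:
            raise DefinitionError(f"isoform {self.name!r} has no junctions")


def default_isoform_definitions() -> list[IsoformDefinition]:
    """The two PIK3R1 alternative-first-exon isoforms (hg38)."""
    return [
        IsoformDefinition("p85a", "PIK3R1", (P85A_JUNCTION,)),
        IsoformDefinition("p55a", "PIK3R1", (P55A_JUNCTION,)),
    ]


@dataclass
class ExpressionTable:
    """Per-sample raw and log10(raw + pseudocount) expression per isoform."""

    samples: list[str]
    isoforms: list[str]
    raw: pd.DataFrame  # samples x isoforms, int
    pseudocount: float
    sample_type: pd.Series | None = None  # tumor/normal per sample

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise DataError("raw isoform counts must be non-negative")

    @property
    def log(self) -> pd.DataFrame:
        return np.log10(self.raw + self.pseudocount)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.samples, name="sample_barcode"))
        df["sample_type"] = (
            self.sample_type.reindex(self.samples)
            if self.sample_type is not None
            else pd.NA
        )
        log = self.log
        for iso in self.isoforms:
            df[f"{iso}_raw"] = self.raw[iso]
            df[f"{iso}_log"] = log[iso]
        return df


def quantify_isoforms(
    jm: JunctionMatrix,
    defs: Sequence[IsoformDefinition],
    pseudocount: float = 1.0,
    sample_type: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionTable:
    """Sum each isoform's discriminating-junction reads per sample.

    Matching is by exact (chrom, start, end, strand) key; a defined junction
    absent from ``jm`` contributes 0.  ``pseudocount`` (> 0) is added before
    the log10 transform.
    """
    if not defs:
        raise UsageError("at least one isoform definition is required")
    if pseudocount <= 0:
        raise UsageError(f"pseudocount must be positive, got {pseudocount}")
    for gene in {d.gene for d in defs}:
        seen: dict[tuple, str] = {}
        for d in defs:
            if d.gene != gene:
                continue
            for j in d.junctions:
                if j.key in seen:
                    raise DefinitionError(
                        f"junction {j} appears in both {seen[j.key]!r} and "
                        f"{d.name!r} of gene {gene}"
                    )
                seen[j.key] = d.name
    index = {j.key: i for i, j in enumerate(jm.junctions)}
    raw = pd.DataFrame(
        0, index=pd.Index(jm.samples, name="sample_barcode"),
        columns=[d.name for d in defs], dtype=np.int64,
    )
    for d in defs:
        for j in d.junctions:
            row = index.get(j.key)
            if row is not None:
                raw[d.name] += jm.counts[row]
    st = None
    if sample_type is not None:
        st = pd.Series(sample_type).reindex(jm.samples)
    return ExpressionTable(
        samples=list(jm.samples),
        isoforms=[d.name for d in defs],
        raw=raw,
        pseudocount=pseudocount,
        sample_type=st,
    )


def write_expression_csv(et: ExpressionTable, path: str | Path) -> None:
    """Write sample_barcode, sample_type, <iso>_raw, <iso>_log columns.

    Log values are written with enough digits that a read-back reproduces
    them to 12 decimal places; raw counts round-trip exactly.
    """
    if not et.samples:
        raise UsageError("cannot write an expression table with zero samples")
    et.to_frame().to_csv(path, float_format="%.15g")


def read_expression_csv(path: str | Path, pseudocount: float = 1.0) -> ExpressionTable:
    """Read a CSV produced by :func:`write_expression_csv`."""
    df = pd.read_csv(path, index_col="sample_barcode", comment="#")
    isoforms = [c[: -len("_raw")] for c in df.columns if c.endswith("_raw")]
    raw = df[[f"{i}_raw" for i in isoforms]].copy()
    raw.columns = isoforms
    st = df["sample_type"] if "sample_type" in df else None
    if st is not None and st.isna().all():
        st = None
    return ExpressionTable(
        samples=list(df.index),
        isoforms=isoforms,
        raw=raw.astype(np.int64),
        pseudocount=pseudocount,
        sample_type=st,
    )
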