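"""Variant region classification, consequence tallies, and coding-SNV annotation.

The two PIK3R1 isoform regions used for population-variant analysis are the
GRCh38 intervals ``5:68,281,006-68,290,834`` (p85alpha; printed 5'->3' of
the transcript and normalized here to start <= end) and
``5:68,290,834-68,292,259`` (p55alpha).  They overlap at the single
coordinate 68,290,834, so a "shared" variant sits exactly on that boundary.

Variants are read from plain VCF (via pysam) or a gnomAD-export-style TSV,
classified by closed-interval containment into {region-A only, region-B
only, shared, outside}, and tallied per consequence class and region.  A
small coding-SNV annotator translates reference and substituted codons by
the standard genetic code and emits HGVS p. notation (three-letter amino
acid codes), e.g. the PIK3R1 missense rs144312303 c.18G>T -> p.Trp6Cys.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .errors import DataError, ParseError, UsageError

__all__ = [
    "CONSEQUENCE_CLASSES",
    "VariantRecord",
    "RegionSet",
    "ConsequenceTally",
    "ProteinConsequence",
    "read_variants",
    "classify_region",
    "tally_consequences",
    "annotate_coding_snv",
    "default_pik3r1_regions",
]

#: Frozen consequence-class vocabulary (gnomAD-style).
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "5_prime_UTR",
    "3_prime_UTR",
    "intron",
    "splice_region",
    "splice_donor",
    "splice_acceptor",
    "missense",
    "start_lost",
    "start_gained",
    "stop_gained",
    "frameshift",
    "synonymous",
    "inframe_insertion",
    "other",
)

_CONSEQUENCE_SYNONYMS = {
    "5' utr": "5_prime_UTR",
    "5_prime_utr_variant": "5_prime_UTR",
    "5 prime utr": "5_prime_UTR",
    "3' utr": "3_prime_UTR",
    "3_prime_utr_variant": "3_prime_UTR",
    "3 prime utr": "3_prime_UTR",
    "intron_variant": "intron",
    "intronic": "intron",
    "splice_region_variant": "splice_region",
    "splice region": "splice_region",
    "splice_donor_variant": "splice_donor",
    "splice donor": "splice_donor",
    "splice_acceptor_variant": "splice_acceptor",
    "splice acceptor": "splice_acceptor",
    "missense_variant": "missense",
    "start_lost": "start_lost",
    "start lost": "start_lost",
    "start_gained": "start_gained",
    "start gained": "start_gained",
    "stop_gained": "stop_gained",
    "stop gained": "stop_gained",
    "stop": "stop_gained",
    "frameshift_variant": "frameshift",
    "synonymous_variant": "synonymous",
    "inframe_insertion": "inframe_insertion",
    "in-frame insertion": "inframe_insertion",
    "in_frame_insertion": "inframe_insertion",
}


def normalize_consequence(text: object) -> str:
    """Map a consequence string onto the fixed vocabulary (unknown -> other)."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return "other"
    s = str(text).strip()
    if s in CONSEQUENCE_CLASSES:
        return s
    mapped = _CONSEQUENCE_SYNONYMS.get(s.lower())
    if mapped is None:
        warnings.warn(
            f"unknown consequence class {s!r} mapped to 'other'",
            UserWarning,
            stacklevel=3,
        )
        return "other"
    return mapped


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    consequence: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise DataError(
                f"ref and alt identical ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise DataError(f"unknown consequence class {self.consequence!r}")


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class RegionSet:
    """Two named closed genomic intervals on one chromosome."""

    chrom: str
    name_a: str
    start_a: int
    end_a: int
    name_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        for name, start, end in (
            (self.name_a, self.start_a, self.end_a),
            (self.name_b, self.start_b, self.end_b),
        ):
            if start > end:
                raise DataError(
                    f"region {name!r} has start {start} > end {end}; "
                    "normalize before constructing the RegionSet"
                )

    @classmethod
    def from_bounds(
        cls, chrom: str, name_a: str, bounds_a: tuple[int, int],
        name_b: str, bounds_b: tuple[int, int],
    ) -> "RegionSet":
        """Build a RegionSet, swapping reversed (5'->3'-printed) bounds."""
        def norm(name, bounds):
            start, end = bounds
            if start > end:
                warnings.warn(
                    f"region {name!r} bounds reversed ({start} > {end}); swapping",
                    UserWarning,
                    stacklevel=3,
                )
                start, end = end, start
            return start, end

        a = norm(name_a, bounds_a)
        b = norm(name_b, bounds_b)
        return cls(chrom, name_a, *a, name_b, *b)


def default_pik3r1_regions() -> RegionSet:
    """The GRCh38 PIK3R1 isoform regions used for variant classification."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p85a bounds are printed reversed
        return RegionSet.from_bounds(
            "5", "p85a", (68_290_834, 68_281_006), "p55a", (68_290_834, 68_292_259)
        )


def classify_region(v: VariantRecord, regions: RegionSet) -> str:
    """Closed-interval membership: ``<a>_only`` | ``<b>_only`` | shared | outside."""
    if _strip_chr(v.chrom) != _strip_chr(regions.chrom):
        warnings.warn(
            f"variant chromosome {v.chrom!r} does not match region "
            f"chromosome {regions.chrom!r}; classified outside",
            UserWarning,
            stacklevel=2,
        )
        return "outside"
    in_a = regions.start_a <= v.pos <= regions.end_a
    in_b = regions.start_b <= v.pos <= regions.end_b
    if in_a and in_b:
        return "shared"
    if in_a:
        return f"{regions.name_a}_only"
    if in_b:
        return f"{regions.name_b}_only"
    return "outside"


@dataclass
class ConsequenceTally:
    """Per-region consequence-class counts plus shared rsIDs.

    A shared variant (inside both intervals) is counted in both regions,
    mirroring how a variant table reports each isoform's total.
    """

    counts: pd.DataFrame  # index = consequence class, columns = region names
    shared_rsids: list[str]
    n_outside: int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.loc["total"] = self.totals
        out.index.name = "consequence_class"
        out.to_csv(path)


def tally_consequences(
    variants: Iterable[VariantRecord], regions: RegionSet
) -> ConsequenceTally:
    """Count variants per consequence class and region (Table-style shape)."""
    names = [regions.name_a, regions.name_b]
    counts = pd.DataFrame(0, index=list(CONSEQUENCE_CLASSES), columns=names)
    shared: list[str] = []
    outside = 0
    for v in variants:
        where = classify_region(v, regions)
        if where == "outside":
            outside += 1
            continue
        if where == "shared":
            counts.loc[v.consequence, names[0]] += 1
            counts.loc[v.consequence, names[1]] += 1
            if v.rsid:
                shared.append(v.rsid)
        else:
            region = where[: -len("_only")]
            counts.loc[v.consequence, region] += 1
    return ConsequenceTally(counts=counts, shared_rsids=shared, n_outside=outside)


# ---------------------------------------------------------------- file readers


def _read_variants_vcf(path: str | Path, consequence_key: str) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            cons_raw = rec.info.get(consequence_key) if consequence_key in rec.info else None
            if isinstance(cons_raw, tuple):
                cons_raw = cons_raw[0]
            cons = normalize_consequence(cons_raw)
            rsid = rec.id if rec.id not in (None, ".") else None
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        rsid=rsid,
                        consequence=cons,
                    )
                )
    return records


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: variant TSV must contain columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records: list[VariantRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(
                VariantRecord(
                    chrom=str(d.get("chrom", "?")),
                    pos=int(d["pos"]),
                    ref=d["ref"],
                    alt=d["alt"],
                    rsid=d.get("rsid") if pd.notna(d.get("rsid")) else None,
                    consequence=normalize_consequence(d.get("consequence")),
                )
            )
        except (TypeError, ValueError, DataError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def read_variants(
    path: str | Path, format: str = "tsv", consequence_key: str = "Consequence"
) -> list[VariantRecord]:
    """Read variants from VCF 4.x or a gnomAD-export-style TSV.

    Multi-allelic VCF rows are split into one record per alternate allele;
    consequence strings are normalized onto the fixed vocabulary (unknowns
    become ``other`` with a warning).  For VCF input the consequence is
    taken from the INFO field named ``consequence_key``.
    """
    if format == "vcf":
        return _read_variants_vcf(path, consequence_key)
    if format == "tsv":
        return _read_variants_tsv(path)
    raise UsageError(f"unknown variant format {format!r}")


# ------------------------------------------------------------ coding-SNV HGVS

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


def _translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    try:
        return _CODON_TABLE[codon]
    except KeyError as exc:
        raise DataError(f"untranslatable codon {codon!r}") from exc


@dataclass(frozen=True)
class ProteinConsequence:
    hgvs_p: str
    category: str  # synonymous | missense | stop_gained | start_lost
    codon_index: int
    ref_aa: str
    alt_aa: str


def annotate_coding_snv(
    cds: str, coding_pos: int, ref: str, alt: str
) -> ProteinConsequence:
    """Protein consequence of a single-nucleotide substitution in a CDS.

    ``cds`` must start with ATG and have length a multiple of 3;
    ``coding_pos`` is the 1-based c. position of the substituted base and
    must carry the ``ref`` allele.  The affected codon (index
    ``ceil(coding_pos / 3)``) is translated before and after substitution
    by the standard genetic code; the HGVS p. string uses three-letter
    amino acid codes ("Ter" for a gained stop, "p.(=)" for synonymous,
    "p.Met1?" for a lost start).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise UsageError(f"CDS length {len(cds)} is not a multiple of 3")
    if not cds.startswith("ATG"):
        raise UsageError("CDS must start with the ATG initiator codon")
    if not 1 <= coding_pos <= len(cds):
        raise UsageError(
            f"coding position {coding_pos} outside CDS of length {len(cds)}"
        )
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise UsageError("ref and alt must be single, distinct nucleotides")
    found = cds[coding_pos - 1]
    if found != ref:
        raise DataError(
            f"reference mismatch at c.{coding_pos}: expected {ref!r}, found {found!r}"
        )
    codon_index = (coding_pos + 2) // 3  # ceil(coding_pos / 3)
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    offset = coding_pos - 1 - codon_start
    alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if codon_index == 1 and alt_aa != "M":
        return ProteinConsequence("p.Met1?", "start_lost", 1, "M", alt_aa)
    if ref_aa == alt_aa:
        return ProteinConsequence("p.(=)", "synonymous", codon_index, ref_aa, alt_aa)
    if alt_aa == "*":
        return ProteinConsequence(
            f"p.{seq3(ref_aa)}{codon_index}Ter", "stop_gained", codon_index, ref_aa, "*"
        )
    return ProteinConsequence(
        f"p.{seq3(ref_aa)}{codon_index}{seq3(alt_aa)}",
        "missense",
        codon_index,
        ref_aa,
        alt_aa,
    )
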