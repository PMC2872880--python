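"""Variant contexts: polarization, exon models, and sequence extraction.

A variant is anchored to its host exon, its alleles are polarized into
ancestral/derived using two agreeing outgroup bases, and a
strand-normalized (transcript orientation) sequence context is built
around it. Inclusion filters reject nonsense variants, variants 3 bp or
less from a splice junction, and variants in terminal exons.

Coordinates are 1-based inclusive in all I/O (VCF convention) and
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

__all__ = [
    "Variant",
    "PolarizedVariant",
    "PolarizationRejection",
    "ExonModel",
    "VariantContext",
    "FilterRules",
    "FilterDecision",
    "polarize",
    "extract_context",
    "filter_variant",
    "find_host_exon",
    "read_variant_table",
    "read_vcf",
    "read_bed12",
    "read_gff3_exons",
]

_BASES = set("ACGT")
_STOP_CODONS = set(standard_dna_table.stop_codons)


class ReferenceMismatchError(ValueError):
    """FASTA base disagrees with the variant's wild-type allele."""


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant with unordered alleles."""

    chrom: str
    pos: int  # 1-based genomic position
    allele_a: str
    allele_b: str
    id: str | None = None

    def __post_init__(self) -> None:
        a, b = self.allele_a.upper(), self.allele_b.upper()
        if a not in _BASES or b not in _BASES:
            raise ValueError(f"alleles must be single ACGT bases, got {a!r}/{b!r}")
        if a == b:
            raise ValueError(f"alleles must differ, got {a}/{b}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)


class PolarizationRejection(str, Enum):
    MISSING_ALIGNMENT = "MISSING_ALIGNMENT"
    OUTGROUP_DISAGREE = "OUTGROUP_DISAGREE"
    NO_ALLELE_MATCH = "NO_ALLELE_MATCH"


@dataclass(frozen=True)
class PolarizedVariant:
    """A variant with ancestral/derived assignment and its evidence."""

    variant: Variant
    ancestral: str
    derived: str
    polarization_evidence: tuple[str, str]

    def __post_init__(self) -> None:
        if {self.ancestral, self.derived} != {self.variant.allele_a, self.variant.allele_b}:
            raise ValueError("ancestral/derived must be the variant's alleles")

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos


def polarize(
    variant: Variant, out1: str | None, out2: str | None
) -> PolarizedVariant | PolarizationRejection:
    """Assign ancestral/derived alleles from two outgroup bases.

    Accepted only when both outgroup bases are present, agree with each
    other, and match one of the two alleles; that allele is ancestral.
    Rejections are returned as values, not raised.
    """
    o1 = out1.upper() if isinstance(out1, str) and out1.strip() else None
    o2 = out2.upper() if isinstance(out2, str) and out2.strip() else None
    if o1 in {"-", "N", "."}:
        o1 = None
    if o2 in {"-", "N", "."}:
        o2 = None
    if o1 is None or o2 is None:
        return PolarizationRejection.MISSING_ALIGNMENT
    if o1 != o2:
        return PolarizationRejection.OUTGROUP_DISAGREE
    if o1 == variant.allele_a:
        anc, der = variant.allele_a, variant.allele_b
    elif o1 == variant.allele_b:
        anc, der = variant.allele_b, variant.allele_a
    else:
        return PolarizationRejection.NO_ALLELE_MATCH
    return PolarizedVariant(variant, anc, der, (o1, o2))


@dataclass(frozen=True)
class ExonModel:
    """An exon with its genomic interval, frame, and intron context.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    ``phase`` follows the GFF convention: the number of bases at the
    transcript-orientation start of the exon that complete the previous
    codon (0 means the exon starts on a codon boundary). Intron lengths
    are in transcript orientation (upstream = toward the transcript 5'
    end).
    """

    chrom: str
    start: int
    end: int
    strand: str
    phase: int = 0
    transcript_id: str = ""
    exon_index: int = 0  # 0-based index in transcript orientation
    n_exons: int = 1
    upstream_intron_length: int = 0
    downstream_intron_length: int = 0
    alternative: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("exon length must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.phase not in {0, 1, 2}:
            raise ValueError("phase must be 0, 1 or 2")
        if min(self.upstream_intron_length, self.downstream_intron_length) < 0:
            raise ValueError("intron lengths must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_internal(self) -> bool:
        return 0 < self.exon_index < self.n_exons - 1

    def contains(self, pos: int) -> bool:
        """Whether a 1-based genomic position lies inside the exon."""
        return self.start < pos <= self.end

    def exon_offset(self, pos: int) -> int:
        """0-based transcript-orientation offset of a 1-based position."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside exon {self.start}-{self.end}")
        genomic_off = pos - 1 - self.start
        return genomic_off if self.strand == "+" else self.length - 1 - genomic_off

    def genomic_pos(self, offset: int) -> int:
        """Inverse of :meth:`exon_offset` (returns a 1-based position)."""
        if not 0 <= offset < self.length:
            raise ValueError(f"offset {offset} outside exon of length {self.length}")
        if self.strand == "+":
            return self.start + offset + 1
        return self.end - offset


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    UNKNOWN = "unknown"  # codon spans an exon boundary


@dataclass(frozen=True)
class VariantContext:
    """Strand-normalized sequence context of a polarized exonic variant.

    All sequences are transcript orientation; ``var_offset`` indexes the
    variant inside ``exon_seq``. Junction distances count the edge base
    as distance 1.
    """

    variant: PolarizedVariant
    exon: ExonModel
    exon_seq: str  # wild-type (ancestral) exon sequence
    var_offset: int
    ancestral_base: str  # transcript orientation
    derived_base: str
    upstream_intron_seq: str
    downstream_intron_seq: str
    codon_position: int | None  # 1..3 within the codon, None if unknown
    wild_codon: str | None
    derived_codon: str | None
    consequence: Consequence

    @property
    def derived_exon_seq(self) -> str:
        s = self.exon_seq
        return s[: self.var_offset] + self.derived_base + s[self.var_offset + 1 :]

    @property
    def dist_to_upstream_junction(self) -> int:
        """Exonic distance to the transcript-5' exon edge (edge base = 1)."""
        return self.var_offset + 1

    @property
    def dist_to_downstream_junction(self) -> int:
        return len(self.exon_seq) - self.var_offset

    @property
    def min_junction_distance(self) -> int:
        return min(self.dist_to_upstream_junction, self.dist_to_downstream_junction)

    def window(self, flank: int) -> tuple[str, str, int]:
        """Exon-truncated window of +/- ``flank`` bases around the variant.

        Returns ``(wild, derived, offset_of_variant_in_window)``.
        """
        lo = max(0, self.var_offset - flank)
        hi = min(len(self.exon_seq), self.var_offset + flank + 1)
        return (
            self.exon_seq[lo:hi],
            self.derived_exon_seq[lo:hi],
            self.var_offset - lo,
        )


def _codon_of(exon_seq: str, offset: int, phase: int) -> tuple[str | None, int | None]:
    """Codon containing an exon offset, or None if it spans a boundary."""
    codon_pos = (offset - phase) % 3  # 0-based position inside the codon
    codon_start = offset - codon_pos
    if codon_start < 0 or codon_start + 3 > len(exon_seq):
        return None, None
    return exon_seq[codon_start : codon_start + 3], codon_pos + 1


def extract_context(
    genome,
    exon: ExonModel,
    variant: PolarizedVariant,
    intron_flank: int = 120,
) -> VariantContext:
    """Build a :class:`VariantContext` from an indexed FASTA.

    ``genome`` is any mapping of chromosome name to a sliceable
    sequence (e.g. a :class:`pyfaidx.Fasta`). ``intron_flank`` bases of
    intronic sequence are attached on each side (truncated to the
    annotated intron lengths) for splice-site window scanning.

    Raises :class:`ReferenceMismatchError` when the FASTA base at the
    variant position does not equal the ancestral (wild-type) allele.
    """
    if not exon.contains(variant.pos):
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} outside exon "
            f"{exon.chrom}:{exon.start}-{exon.end}"
        )
    chrom_seq = genome[variant.chrom]
    exon_seq_plus = str(chrom_seq[exon.start : exon.end]).upper()
    up_len = min(intron_flank, exon.upstream_intron_length)
    down_len = min(intron_flank, exon.downstream_intron_length)
    if exon.strand == "+":
        left = str(chrom_seq[exon.start - up_len : exon.start]).upper()
        right = str(chrom_seq[exon.end : exon.end + down_len]).upper()
        exon_seq, up_seq, down_seq = exon_seq_plus, left, right
    else:
        left = str(chrom_seq[exon.start - down_len : exon.start]).upper()
        right = str(chrom_seq[exon.end : exon.end + up_len]).upper()
        exon_seq = reverse_complement(exon_seq_plus)
        up_seq = reverse_complement(right)
        down_seq = reverse_complement(left)

    offset = exon.exon_offset(variant.pos)
    anc, der = variant.ancestral, variant.derived
    if exon.strand == "-":
        anc, der = reverse_complement(anc), reverse_complement(der)
    ref_base = exon_seq[offset]
    if ref_base != anc:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: FASTA base {ref_base!r} (transcript"
            f" orientation) != wild-type allele {anc!r}"
        )
    derived_exon = exon_seq[:offset] + der + exon_seq[offset + 1 :]
    wild_codon, codon_pos = _codon_of(exon_seq, offset, exon.phase)
    derived_codon, _ = _codon_of(derived_exon, offset, exon.phase)
    if wild_codon is None or derived_codon is None:
        consequence = Consequence.UNKNOWN
    elif derived_codon in _STOP_CODONS:
        consequence = Consequence.NONSENSE
    elif standard_dna_table.forward_table.get(wild_codon) == standard_dna_table.forward_table.get(
        derived_codon
    ) and wild_codon not in _STOP_CODONS:
        consequence = Consequence.SYNONYMOUS
    else:
        consequence = Consequence.MISSENSE
    return VariantContext(
        variant=variant,
        exon=exon,
        exon_seq=exon_seq,
        var_offset=offset,
        ancestral_base=anc,
        derived_base=der,
        upstream_intron_seq=up_seq,
        downstream_intron_seq=down_seq,
        codon_position=codon_pos,
        wild_codon=wild_codon,
        derived_codon=derived_codon,
        consequence=consequence,
    )


@dataclass(frozen=True)
class FilterRules:
    """Inclusion rules for cohort construction.

    ``min_junction_distance`` is the smallest retained distance; the
    default of 4 excludes variants 3 bp or less from either junction,
    with the exon edge base counted as distance 1.
    """

    min_junction_distance: int = 4
    exclude_nonsense: bool = True
    internal_exons_only: bool = True


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None


def filter_variant(ctx: VariantContext, rules: FilterRules = FilterRules()) -> FilterDecision:
    """Apply cohort inclusion filters to a built context."""
    if rules.exclude_nonsense and ctx.consequence is Consequence.NONSENSE:
        return FilterDecision(False, "NONSENSE")
    if ctx.min_junction_distance < rules.min_junction_distance:
        return FilterDecision(False, "NEAR_JUNCTION")
    if rules.internal_exons_only and not ctx.exon.is_internal:
        return FilterDecision(False, "NON_INTERNAL_EXON")
    return FilterDecision(True, None)


def find_host_exon(exons: Iterable[ExonModel], variant: Variant) -> ExonModel | None:
    """Largest exon containing the variant; ties broken by transcript id."""
    hosts = [e for e in exons if e.chrom == variant.chrom and e.contains(variant.pos)]
    if not hosts:
        return None
    return min(hosts, key=lambda e: (-e.length, e.transcript_id))


# ---------------------------------------------------------------------------
# Readers


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited variant table.

    Required columns: chrom, pos, allele_a, allele_b. Optional: id,
    outgroup1, outgroup2 (for polarization), plus any extra metadata
    columns, which are passed through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = {"chrom", "pos", "allele_a", "allele_b"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} missing columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read SNV records from a VCF into the variant-table layout.

    Outgroup bases may be carried in INFO keys ``OUT1``/``OUT2``.
    Non-SNV records are ignored.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                if rec.ref.upper() not in _BASES or alt.upper() not in _BASES:
                    continue
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "id": rec.id,
                        "allele_a": rec.ref.upper(),
                        "allele_b": alt.upper(),
                        "outgroup1": rec.info.get("OUT1", None),
                        "outgroup2": rec.info.get("OUT2", None),
                    }
                )
    return pd.DataFrame(rows)


def _transcript_exons(
    chrom: str,
    strand: str,
    blocks: Sequence[tuple[int, int]],
    transcript_id: str,
    alternative: bool | None = None,
) -> list[ExonModel]:
    """Build :class:`ExonModel` rows from genomic blocks of one transcript."""
    blocks = sorted(blocks)
    n = len(blocks)
    order = range(n) if strand == "+" else range(n - 1, -1, -1)
    exons: list[ExonModel] = []
    phase = 0
    for tx_index, gi in enumerate(order):
        start, end = blocks[gi]
        if strand == "+":
            up = start - blocks[gi - 1][1] if gi > 0 else 0
            down = blocks[gi + 1][0] - end if gi < n - 1 else 0
        else:
            up = blocks[gi + 1][0] - end if gi < n - 1 else 0
            down = start - blocks[gi - 1][1] if gi > 0 else 0
        exons.append(
            ExonModel(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                phase=phase,
                transcript_id=transcript_id,
                exon_index=tx_index,
                n_exons=n,
                upstream_intron_length=up,
                downstream_intron_length=down,
                alternative=alternative,
            )
        )
        phase = (3 - ((end - start - phase) % 3)) % 3
    return exons


def read_bed12(path: str | Path) -> list[ExonModel]:
    """Read exon models from BED12 (one transcript per line).

    Blocks are taken as coding exons; reading frame is accumulated
    across exons in transcript order starting in phase 0.
    """
    exons: list[ExonModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 needs 12 columns (line {lineno} of {path})")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"BED12 block count mismatch (line {lineno} of {path})")
            blocks = [
                (chrom_start + s, chrom_start + s + size) for s, size in zip(starts, sizes)
            ]
            exons.extend(_transcript_exons(chrom, strand, blocks, name))
    return exons


def read_gff3_exons(path: str | Path) -> list[ExonModel]:
    """Read CDS exon models from GFF3, grouped by Parent transcript."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_tx: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "tx"])
        for parent in parents:
            by_tx.setdefault(parent, []).append(cds)
    exons: list[ExonModel] = []
    for tx, features in sorted(by_tx.items()):
        features.sort(key=lambda c: c.start)
        chrom = features[0].seqid
        strand = features[0].strand
        blocks = [(c.start - 1, c.end) for c in features]
        exons.extend(_transcript_exons(chrom, strand, blocks, tx))
    return exons
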