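"""Shared construction helpers for tests."""

from __future__ import annotations

import numpy as np

from savscan.variants import (
    Consequence,
    ExonModel,
    PolarizedVariant,
    Variant,
    VariantContext,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_exon(
    length: int,
    chrom: str = "chrT",
    start: int = 1000,
    strand: str = "+",
    phase: int = 0,
    up_intron: int = 300,
    down_intron: int = 300,
    internal: bool = True,
) -> ExonModel:
    return ExonModel(
        chrom=chrom,
        start=start,
        end=start + length,
        strand=strand,
        phase=phase,
        transcript_id="txT",
        exon_index=1 if internal else 0,
        n_exons=3 if internal else 2,
        upstream_intron_length=up_intron,
        downstream_intron_length=down_intron,
    )


def make_ctx(
    exon_seq: str,
    offset: int,
    derived: str,
    up_intron_seq: str = "",
    down_intron_seq: str = "",
    phase: int = 0,
    chrom: str = "chrT",
    pos: int | None = None,
) -> VariantContext:
    """Hand-build a VariantContext without FASTA plumbing."""
    exon_seq = exon_seq.upper()
    anc = exon_seq[offset]
    derived = derived.upper()
    assert derived != anc
    pos = pos if pos is not None else 1001 + offset
    variant = Variant(chrom=chrom, pos=pos, allele_a=anc, allele_b=derived, id="v")
    pv = PolarizedVariant(variant, anc, derived, (anc, anc))
    exon = make_exon(
        len(exon_seq),
        chrom=chrom,
        up_intron=max(len(up_intron_seq), 0),
        down_intron=max(len(down_intron_seq), 0),
    )
    return VariantContext(
        variant=pv,
        exon=exon,
        exon_seq=exon_seq,
        var_offset=offset,
        ancestral_base=anc,
        derived_base=derived,
        upstream_intron_seq=up_intron_seq.upper(),
        downstream_intron_seq=down_intron_seq.upper(),
        codon_position=None,
        wild_codon=None,
        derived_codon=None,
        consequence=Consequence.UNKNOWN,
    )
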