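"""Shared helper for the examples: build a VariantContext by hand."""

from savscan.variants import (
    Consequence,
    ExonModel,
    PolarizedVariant,
    Variant,
    VariantContext,
)


def toy_context(exon_seq: str, offset: int, derived: str,
                up_intron: str = "", down_intron: str = "") -> VariantContext:
    exon_seq = exon_seq.upper()
    anc = exon_seq[offset]
    variant = Variant("chrT", 1001 + offset, anc, derived.upper(), id="example")
    pv = PolarizedVariant(variant, anc, derived.upper(), (anc, anc))
    exon = ExonModel(
        "chrT", 1000, 1000 + len(exon_seq), "+",
        transcript_id="tx", exon_index=1, n_exons=3,
        upstream_intron_length=max(len(up_intron), 300),
        downstream_intron_length=max(len(down_intron), 300),
    )
    return VariantContext(
        variant=pv, exon=exon, exon_seq=exon_seq, var_offset=offset,
        ancestral_base=anc, derived_base=derived.upper(),
        upstream_intron_seq=up_intron.upper(), downstream_intron_seq=down_intron.upper(),
        codon_position=None, wild_codon=None, derived_codon=None,
        consequence=Consequence.UNKNOWN,
    )
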