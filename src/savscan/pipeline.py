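"""End-to-end per-variant scoring: the batch report behind the CLI.

Given variants, a genome, exon models and the configured motif
resources, each variant is polarized, anchored to its host exon,
filtered, and scored for every feature family: ESR change profile per
motif set (with extent bin), PWM site changes, regulatory-constraint
score, the delta-SS ectopic block, exon position section, and the host
exon's definition features. Variants that cannot be scored yield a
rejection record with a reason code instead of aborting the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .changes import change_profile, extent_bin
from .cohort_stats import junction_distance_bin
from .constraint import CodonConstraintMatrix, MafIndex, variant_rc
from .exons import exon_feature_profile, exon_position_section
from .motifs import ESRMotifSet, PWMSet
from .splice import delta_ss, ectopic_assessment
from .variants import (
    ExonModel,
    FilterRules,
    PolarizationRejection,
    Variant,
    VariantContext,
    extract_context,
    filter_variant,
    find_host_exon,
    polarize,
    ReferenceMismatchError,
)

__all__ = ["ScoreConfig", "ScoreResult", "score_variants", "build_contexts"]


@dataclass(frozen=True)
class ScoreConfig:
    """Batch scoring configuration."""

    filter_rules: FilterRules = FilterRules()
    intron_flank: int = 120
    rc_flank: int = 5
    dss_threshold: float = 1.0
    batch_cap: int | None = 200  # mirrors the web tool's batch limit; None = unlimited
    apply_filters: bool = True


@dataclass
class ScoreResult:
    """Per-variant feature table plus the rejection report."""

    report: pd.DataFrame
    rejections: pd.DataFrame
    contexts: list[VariantContext] = field(default_factory=list)

    @property
    def counters(self) -> dict[str, int]:
        out = {"input": len(self.report) + len(self.rejections), "scored": len(self.report)}
        if len(self.rejections):
            for reason, n in self.rejections["reason"].value_counts().items():
                out[f"rejected_{reason}"] = int(n)
        return out


def _iter_variant_rows(variants: pd.DataFrame):
    for _, row in variants.iterrows():
        yield row


def build_contexts(
    variants: pd.DataFrame,
    genome,
    exons: Sequence[ExonModel],
    config: ScoreConfig = ScoreConfig(),
) -> tuple[list[VariantContext], list[dict]]:
    """Polarize, anchor and filter a variant table into contexts.

    Returns the kept contexts and a list of rejection records
    (``{"id", "chrom", "pos", "reason"}``).
    """
    kept: list[VariantContext] = []
    rejected: list[dict] = []
    exons_by_chrom: dict[str, list[ExonModel]] = {}
    for e in exons:
        exons_by_chrom.setdefault(e.chrom, []).append(e)

    for row in _iter_variant_rows(variants):
        vid = str(row.get("id", "") or f"{row['chrom']}:{row['pos']}")
        rec = {"id": vid, "chrom": str(row["chrom"]), "pos": int(row["pos"])}
        try:
            variant = Variant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele_a=str(row["allele_a"]),
                allele_b=str(row["allele_b"]),
                id=vid,
            )
        except ValueError:
            rejected.append({**rec, "reason": "MALFORMED_VARIANT"})
            continue
        pol = polarize(variant, row.get("outgroup1"), row.get("outgroup2"))
        if isinstance(pol, PolarizationRejection):
            rejected.append({**rec, "reason": pol.value})
            continue
        exon = find_host_exon(exons_by_chrom.get(variant.chrom, ()), variant)
        if exon is None:
            rejected.append({**rec, "reason": "NO_HOST_EXON"})
            continue
        try:
            ctx = extract_context(genome, exon, pol, intron_flank=config.intron_flank)
        except ReferenceMismatchError:
            rejected.append({**rec, "reason": "REFERENCE_MISMATCH"})
            continue
        if config.apply_filters:
            decision = filter_variant(ctx, config.filter_rules)
            if not decision.keep:
                rejected.append({**rec, "reason": decision.reason})
                continue
        kept.append(ctx)
    return kept, rejected


def score_variants(
    variants: pd.DataFrame,
    genome,
    exons: Sequence[ExonModel],
    motif_sets: Sequence[ESRMotifSet],
    pwms: PWMSet | None = None,
    splice_model=None,
    maf: MafIndex | None = None,
    rc_matrix: CodonConstraintMatrix | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> ScoreResult:
    """Score a variant table; one report row per scorable variant."""
    if config.batch_cap is not None and len(variants) > config.batch_cap:
        raise ValueError(
            f"batch of {len(variants)} exceeds cap {config.batch_cap}; "
            "raise batch_cap (or set it to None) for large cohorts"
        )
    contexts, rejected = build_contexts(variants, genome, exons, config)

    exon_cache: dict[str, dict] = {}
    rows = []
    for ctx in contexts:
        exon = ctx.exon
        profile = change_profile(ctx, motif_sets, pwms)
        section, peripheral = exon_position_section(len(ctx.exon_seq), ctx.var_offset)
        row: dict = {
            "id": ctx.variant.variant.id,
            "chrom": ctx.variant.chrom,
            "pos": ctx.variant.pos,
            "ancestral": ctx.variant.ancestral,
            "derived": ctx.variant.derived,
            "transcript": exon.transcript_id,
            "exon_index": exon.exon_index,
            "strand": exon.strand,
            "exon_length": exon.length,
            "consequence": ctx.consequence.value,
            "codon_position": ctx.codon_position,
            "min_junction_distance": ctx.min_junction_distance,
            "junction_distance_bin": junction_distance_bin(ctx.min_junction_distance),
            "exon_section": section,
            "peripheral": peripheral,
        }
        for set_name, counts in profile.per_set.items():
            p = f"{set_name}_"
            if counts.unlabeled:
                row[p + "esr_loss"] = counts.esr_loss
                row[p + "esr_gain"] = counts.esr_gain
                row[p + "esr_alteration"] = counts.esr_alteration
            else:
                row[p + "ese_loss"] = counts.ese_loss
                row[p + "ese_gain"] = counts.ese_gain
                row[p + "ese_alteration"] = counts.ese_alteration
                row[p + "ess_loss"] = counts.ess_loss
                row[p + "ess_gain"] = counts.ess_gain
                row[p + "ess_alteration"] = counts.ess_alteration
                row[p + "ese_to_ess"] = counts.ese_to_ess
                row[p + "ess_to_ese"] = counts.ess_to_ese
            row[p + "combined_extent"] = counts.combined_extent
            row[p + "extent_bin"] = extent_bin(profile, set_name)
            row[p + "n_windows"] = counts.n_windows
        if pwms is not None:
            pc = profile.pwm_counts()
            row["pwm_lost"] = pc["lost"]
            row["pwm_gained"] = pc["gained"]
            row["pwm_altered"] = pc["altered"]
            row["pwm_lost_positions"] = ",".join(
                str(c.variant_pos_in_motif) for c in profile.pwm_changes if c.kind == "lost"
            )
        if maf is not None and rc_matrix is not None:
            rc = variant_rc(rc_matrix, maf, ctx, flank=config.rc_flank)
            row["rc_score"] = rc.score
            row["rc_unscored_reason"] = rc.reason
            row["rc_n_columns"] = rc.n_columns
        if splice_model is not None:
            dss = delta_ss(splice_model, ctx)
            assess = ectopic_assessment(dss, ctx, threshold=config.dss_threshold)
            row["delta_5ss"] = dss.donor.delta
            row["delta_3ss"] = dss.acceptor.delta
            row["delta_ss"] = dss.delta_ss
            row["natural_donor_score"] = dss.natural_donor_score
            row["natural_acceptor_score"] = dss.natural_acceptor_score
            row["ectopic_like"] = assess.ectopic_like
            row["ectopic_side"] = assess.side
            row["best_ectopic_score"] = assess.best_ectopic_score
            row["ectopic_ge_natural"] = assess.ectopic_ge_natural
            row["ectopic_same_half"] = assess.same_half_as_site
        exon_key = f"{exon.transcript_id}:exon{exon.exon_index}"
        row["exon_id"] = exon_key
        if exon_key not in exon_cache:
            exon_cache[exon_key] = exon_feature_profile(
                genome, exon, motif_sets, pwms, splice_model
            ).to_row()
        for k, v in exon_cache[exon_key].items():
            if k != "exon_id":
                row[f"host_{k}"] = v
        rows.append(row)
    report = pd.DataFrame(rows)
    rejections = pd.DataFrame(rejected, columns=["id", "chrom", "pos", "reason"])
    return ScoreResult(report=report, rejections=rejections, contexts=contexts)
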