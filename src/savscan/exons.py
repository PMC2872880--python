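"""Exon- and intron-level features of exon definition.

Well-defined exons pair strong splice sites with a high density of
enhancer motifs and a low density of silencers, while their flanking
introns show the opposite profile. This module measures those
features: sliding-window ESR densities over the exon, densities over
the 100 intronic bases flanking each junction (excluding the GT/AG
dinucleotides; exons with a flanking intron shorter than 102 bp are
excluded), the six-section position of a variant within its exon, the
ESE/ESS occupancy profile around junctions across an exon cohort, the
natural splice-site strengths, and a simple exon-length model for the
probability of an exon harbouring a variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .motifs import ESRMotifSet, Label, PWMSet, scan_pwm_hits
from .splice import ACCEPTOR_EXONIC, ACCEPTOR_WIDTH, DONOR_EXONIC, DONOR_WIDTH
from .variants import ExonModel

__all__ = [
    "esr_density",
    "esefinder_density",
    "intron_flank_density",
    "FlankDensities",
    "exon_position_section",
    "expected_snp_exon_length_dist",
    "junction_occupancy_profile",
    "splice_site_strengths",
    "SpliceSiteScores",
    "exon_sequences",
    "ExonFeatureProfile",
    "exon_feature_profile",
    "qualifies_exon_length",
]

_BASES = set("ACGT")


def _density_states(motif_set: ESRMotifSet) -> tuple[Label, ...]:
    if motif_set.unlabeled:
        return (Label.UNLABELED_ESR,)
    return (Label.ESE, Label.ESS)


def esr_density(motif_set: ESRMotifSet, sequence: str) -> dict[Label, float] | None:
    """Per-label fraction of k-mer windows scoring as that label.

    The denominator is the total number of windows (L - k + 1);
    windows containing non-ACGT bases never count as hits. Returns
    None (unscored) when the sequence is shorter than k.
    """
    sequence = sequence.upper()
    k = motif_set.k
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        return None
    counts = {state: 0 for state in _density_states(motif_set)}
    for start in range(n_windows):
        window = sequence[start : start + k]
        try:
            label = motif_set.classify(window)
        except ValueError:
            continue
        if label in counts:
            counts[label] += 1
    return {state: c / n_windows for state, c in counts.items()}


def esefinder_density(pwms: PWMSet, sequence: str) -> float | None:
    """Sum over matrices of (threshold-crossing windows / windows).

    Matrices have differing widths, so each is windowed separately and
    the per-matrix densities are summed into one overall density.
    Returns None when the sequence is shorter than every matrix.
    """
    sequence = sequence.upper()
    total = None
    for pwm in pwms.matrices:
        n_windows = len(sequence) - pwm.width + 1
        if n_windows < 1:
            continue
        hits = 0
        for start in range(n_windows):
            window = sequence[start : start + pwm.width]
            if any(b not in _BASES for b in window):
                continue
            if pwm.score(window) >= pwm.threshold:
                hits += 1
        total = (total or 0.0) + hits / n_windows
    return total


@dataclass(frozen=True)
class FlankDensities:
    upstream: dict[Label, float]
    downstream: dict[Label, float]


# bases of flanking intron measured, after the 2-base junction dinucleotide
FLANK_BP = 100
MIN_FLANK_INTRON = FLANK_BP + 2


def intron_flank_density(
    motif_set: ESRMotifSet, genome, exon: ExonModel
) -> FlankDensities | None:
    """ESR densities on the 100 intronic bases flanking each junction.

    The conserved GT/AG splice-site dinucleotides are excluded, so the
    measured bases are intronic positions 3..102 from each junction
    (transcript orientation). Exons with either flanking intron
    shorter than 102 bp are excluded (returns None).
    """
    if (
        exon.upstream_intron_length < MIN_FLANK_INTRON
        or exon.downstream_intron_length < MIN_FLANK_INTRON
    ):
        return None
    up, _, down = exon_sequences(genome, exon, intron_flank=MIN_FLANK_INTRON)
    up_flank = up[:-2][-FLANK_BP:]  # drop the AG, keep the 100 bases before it
    down_flank = down[2 : 2 + FLANK_BP]  # drop the GT
    du = esr_density(motif_set, up_flank)
    dd = esr_density(motif_set, down_flank)
    assert du is not None and dd is not None
    return FlankDensities(upstream=du, downstream=dd)


def exon_position_section(exon_length: int, var_offset: int) -> tuple[int, bool]:
    """Six-equal-section bin of a variant within its exon.

    ``var_offset`` is the 0-based transcript-orientation offset.
    Sections are half-open: section = floor(6 * offset / length) + 1,
    clamped to 6. Peripheral means section 1 or 6.
    """
    if not 0 <= var_offset < exon_length:
        raise ValueError(f"offset {var_offset} outside exon of length {exon_length}")
    section = min(6, (6 * var_offset) // exon_length + 1)
    return section, section in (1, 6)


def expected_snp_exon_length_dist(
    exon_lengths: Mapping[int, int],
    p_snp: float = 0.001,
    length_weighted: bool = False,
) -> dict[int, float]:
    """Expected frequency of variant-containing exons per exon length.

    The base model is ``fr(n) = p_snp * obs(n)`` with ``obs(n)`` the
    observed number of exons of length n. With ``length_weighted`` the
    per-base placement model ``fr(n) = p_snp * n * obs(n)`` is used
    instead, which is the mode under which longer exons are more likely
    to contain a variant (see docs/methods.md for the distinction).
    """
    if not exon_lengths:
        raise ValueError("empty exon length histogram")
    return {
        n: p_snp * (n if length_weighted else 1) * obs
        for n, obs in sorted(exon_lengths.items())
    }


def exon_sequences(genome, exon: ExonModel, intron_flank: int) -> tuple[str, str, str]:
    """(upstream intron, exon, downstream intron), transcript orientation.

    Intron pieces are truncated to the annotated intron lengths.
    """
    chrom_seq = genome[exon.chrom]
    up_len = min(intron_flank, exon.upstream_intron_length)
    down_len = min(intron_flank, exon.downstream_intron_length)
    exon_seq = str(chrom_seq[exon.start : exon.end]).upper()
    if exon.strand == "+":
        up = str(chrom_seq[exon.start - up_len : exon.start]).upper()
        down = str(chrom_seq[exon.end : exon.end + down_len]).upper()
        return up, exon_seq, down
    left = str(chrom_seq[exon.start - down_len : exon.start]).upper()
    right = str(chrom_seq[exon.end : exon.end + up_len]).upper()
    return (
        reverse_complement(right),
        reverse_complement(exon_seq),
        reverse_complement(left),
    )


OCCUPANCY_INTRON_BP = 100
OCCUPANCY_EXON_BP = 50


def junction_occupancy_profile(
    motif_set: ESRMotifSet,
    genome,
    exons: Sequence[ExonModel],
    min_exon_length: int = 100,
    min_intron_length: int = 200,
) -> pd.DataFrame:
    """Fraction of exons with an ESE/ESS motif starting at each position.

    For each junction, a hexamer (or k-mer) slides across 100 bp of
    flanking intron plus the adjacent 50 bp of exon; each profile
    position is the first base of the k-mer, labelled as a signed
    offset from the junction (negative toward the transcript 5' side,
    so intronic bases are negative at the acceptor and positive at the
    donor; there is no position 0).
    Only exons of at least ``min_exon_length`` with both flanking
    introns of at least ``min_intron_length`` contribute, so profiles
    are not contaminated by signal from neighbouring exons.
    """
    k = motif_set.k
    qualifying = [
        e
        for e in exons
        if e.length >= min_exon_length
        and e.upstream_intron_length >= min_intron_length
        and e.downstream_intron_length >= min_intron_length
    ]
    if not qualifying:
        raise ValueError("no exons qualify for the junction occupancy profile")
    span = OCCUPANCY_INTRON_BP + OCCUPANCY_EXON_BP
    n_starts = span - k + 1
    states = _density_states(motif_set)
    tallies = {
        junction: {state: [0] * n_starts for state in states}
        for junction in ("acceptor", "donor")
    }
    for exon in qualifying:
        up, exon_seq, down = exon_sequences(genome, exon, OCCUPANCY_INTRON_BP)
        regions = {
            "acceptor": up + exon_seq[:OCCUPANCY_EXON_BP],
            "donor": exon_seq[-OCCUPANCY_EXON_BP:] + down,
        }
        for junction, region in regions.items():
            for start in range(n_starts):
                try:
                    label = motif_set.classify(region[start : start + k])
                except ValueError:
                    continue
                if label in states:
                    tallies[junction][label][start] += 1
    n = len(qualifying)
    rows = []
    for junction in ("acceptor", "donor"):
        for start in range(n_starts):
            if junction == "acceptor":
                pos = start - OCCUPANCY_INTRON_BP  # negative = intronic
            else:
                pos = start - OCCUPANCY_EXON_BP  # negative = exonic
            if pos >= 0:
                pos += 1  # no position zero; first base across the junction is +/-1
            row = {"junction": junction, "position": pos}
            for state in states:
                key = "esr" if state is Label.UNLABELED_ESR else state.value.lower()
                row[f"{key}_fraction"] = tallies[junction][state][start] / n
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpliceSiteScores:
    donor: float | None
    acceptor: float | None
    donor_dinucleotide: str | None
    acceptor_dinucleotide: str | None

    @property
    def canonical(self) -> bool | None:
        if self.donor_dinucleotide is None or self.acceptor_dinucleotide is None:
            return None
        return self.donor_dinucleotide == "GT" and self.acceptor_dinucleotide == "AG"


def splice_site_strengths(model, genome, exon: ExonModel) -> SpliceSiteScores:
    """Natural 5'/3' splice-site scores of an exon's annotated junctions.

    Non-canonical (non-GT/AG) junctions are scored anyway; the
    dinucleotides are reported so a canonical-only filter can flag
    them.
    """
    intron_need = max(DONOR_WIDTH - DONOR_EXONIC, ACCEPTOR_WIDTH - ACCEPTOR_EXONIC)
    up, exon_seq, down = exon_sequences(genome, exon, intron_need)
    donor = acceptor = None
    donor_din = acceptor_din = None
    if len(down) >= DONOR_WIDTH - DONOR_EXONIC and len(exon_seq) >= DONOR_EXONIC:
        window = exon_seq[-DONOR_EXONIC:] + down[: DONOR_WIDTH - DONOR_EXONIC]
        donor_din = down[:2]
        try:
            donor = model.score(window, "5p")
        except ValueError:
            donor = None
    if len(up) >= ACCEPTOR_WIDTH - ACCEPTOR_EXONIC and len(exon_seq) >= ACCEPTOR_EXONIC:
        window = up[-(ACCEPTOR_WIDTH - ACCEPTOR_EXONIC) :] + exon_seq[:ACCEPTOR_EXONIC]
        acceptor_din = up[-2:]
        try:
            acceptor = model.score(window, "3p")
        except ValueError:
            acceptor = None
    return SpliceSiteScores(donor, acceptor, donor_din, acceptor_din)


def qualifies_exon_length(exon: ExonModel, lo: int = 20, hi: int = 1000) -> bool:
    """Inclusion bounds for exon-level cohorts (20..1000 bp)."""
    return lo <= exon.length <= hi


@dataclass
class ExonFeatureProfile:
    """Exon-definition feature vector for one exon."""

    exon_id: str
    length: int
    donor_score: float | None
    acceptor_score: float | None
    canonical: bool | None
    densities: dict[str, dict[Label, float]]  # per motif-set exon densities
    pwm_density: float | None
    flank_densities: dict[str, FlankDensities | None]
    alternative: bool | None

    def to_row(self) -> dict:
        row = {
            "exon_id": self.exon_id,
            "exon_length": self.length,
            "donor_score": self.donor_score,
            "acceptor_score": self.acceptor_score,
            "canonical_junctions": self.canonical,
            "pwm_density": self.pwm_density,
            "alternative": self.alternative,
        }
        for set_name, dens in self.densities.items():
            for state, value in dens.items():
                key = "esr" if state is Label.UNLABELED_ESR else state.value.lower()
                row[f"{set_name}_{key}_density"] = value
        for set_name, flanks in self.flank_densities.items():
            if flanks is None:
                row[f"{set_name}_flank_excluded"] = True
                continue
            row[f"{set_name}_flank_excluded"] = False
            for side, dens in (("upstream", flanks.upstream), ("downstream", flanks.downstream)):
                for state, value in dens.items():
                    key = "esr" if state is Label.UNLABELED_ESR else state.value.lower()
                    row[f"{set_name}_{side}_{key}_density"] = value
        return row


def exon_feature_profile(
    genome,
    exon: ExonModel,
    motif_sets: Sequence[ESRMotifSet],
    pwms: PWMSet | None = None,
    splice_model=None,
) -> ExonFeatureProfile:
    """Assemble the full exon-definition feature vector for one exon."""
    _, exon_seq, _ = exon_sequences(genome, exon, 0)
    densities = {}
    flanks = {}
    for ms in motif_sets:
        d = esr_density(ms, exon_seq)
        if d is not None:
            densities[ms.name] = d
        flanks[ms.name] = intron_flank_density(ms, genome, exon)
    pwm_density = esefinder_density(pwms, exon_seq) if pwms is not None else None
    if splice_model is not None:
        ss = splice_site_strengths(splice_model, genome, exon)
        donor, acceptor, canonical = ss.donor, ss.acceptor, ss.canonical
    else:
        donor = acceptor = canonical = None
    exon_id = f"{exon.transcript_id}:exon{exon.exon_index}"
    return ExonFeatureProfile(
        exon_id=exon_id,
        length=exon.length,
        donor_score=donor,
        acceptor_score=acceptor,
        canonical=canonical,
        densities=densities,
        pwm_density=pwm_density,
        flank_densities=flanks,
        alternative=exon.alternative,
    )
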