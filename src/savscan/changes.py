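"""ESR changes induced by a variant across all motif windows it touches.

Every k-mer window overlapping the variant (at most k of them, fewer
near an exon boundary) is classified in the wild-type and derived
alleles, and the pair of states maps onto one of nine change
categories: three same-state "alterations" (ESE~ESE, Neutral~Neutral,
ESS~ESS), four single-step transitions (ESE loss/gain, ESS loss/gain)
and two direct conversions (ESE->ESS, ESS->ESE). Collections whose
motifs carry no ESE/ESS direction use a reduced two-state scheme with
four categories.

Loss and gain tallies are inclusive of direct conversions: a window
whose wild-type hexamer is an ESE and whose derived hexamer is an ESS
counts both as an ESE loss and as an ESS gain (and once as a direct
conversion); the combined extent of change sums ESE losses and ESS
gains, so such a window contributes twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .motifs import ESRMotifSet, Label, PWMSet
from .variants import VariantContext

__all__ = [
    "ChangeCategory",
    "NINE_CATEGORIES",
    "FOUR_CATEGORIES",
    "SetChangeCounts",
    "PWMChange",
    "ESRChangeProfile",
    "variant_windows",
    "classify_change_pair",
    "change_profile",
    "extent_bin",
    "EXTENT_BINS",
]

_ARROW = "→"  # ->
_STATE_NAMES = {
    Label.ESE: "ESE",
    Label.ESS: "ESS",
    Label.UNLABELED_ESR: "ESR",
    Label.NEUTRAL: "Neutral",
}


@dataclass(frozen=True)
class ChangeCategory:
    """An ordered (wild-type state, derived state) pair."""

    wild: Label
    derived: Label

    @property
    def label(self) -> str:
        w, d = _STATE_NAMES[self.wild], _STATE_NAMES[self.derived]
        return f"{w}~{w}" if self.wild is self.derived else f"{w}{_ARROW}{d}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChangeCategory({self.label})"


_THREE_STATES = (Label.ESE, Label.NEUTRAL, Label.ESS)
NINE_CATEGORIES: tuple[ChangeCategory, ...] = tuple(
    ChangeCategory(w, d) for w in _THREE_STATES for d in _THREE_STATES
)
_TWO_STATES = (Label.UNLABELED_ESR, Label.NEUTRAL)
FOUR_CATEGORIES: tuple[ChangeCategory, ...] = tuple(
    ChangeCategory(w, d) for w in _TWO_STATES for d in _TWO_STATES
)


def variant_windows(
    ctx: VariantContext, k: int, pad_into_introns: bool = False
) -> list[tuple[str, str, int]]:
    """All k-mer windows containing the variant, 5'->3'.

    Returns ``(wild_kmer, derived_kmer, variant_position_in_kmer)``
    triples, the position being 1-based (the first window has the
    variant at position k, the last at position 1). Windows are
    truncated at the exon boundary by default: ESRs are exonic, so a
    window crossing into the intron is dropped rather than padded.
    With ``pad_into_introns`` the available intronic flank is appended
    for exploratory scanning.
    """
    if pad_into_introns:
        wild = ctx.upstream_intron_seq + ctx.exon_seq + ctx.downstream_intron_seq
        derived = ctx.upstream_intron_seq + ctx.derived_exon_seq + ctx.downstream_intron_seq
        offset = len(ctx.upstream_intron_seq) + ctx.var_offset
    else:
        wild, derived, offset = ctx.exon_seq, ctx.derived_exon_seq, ctx.var_offset
    out = []
    for start in range(max(0, offset - k + 1), min(len(wild) - k, offset) + 1):
        out.append((wild[start : start + k], derived[start : start + k], offset - start + 1))
    return out


def classify_change_pair(
    motif_set: ESRMotifSet, wild_kmer: str, derived_kmer: str
) -> ChangeCategory:
    """Change category of one window from its wild/derived k-mers."""
    if len(wild_kmer) != motif_set.k or len(derived_kmer) != motif_set.k:
        raise ValueError(
            f"k-mers must have length {motif_set.k}, got "
            f"{len(wild_kmer)}/{len(derived_kmer)}"
        )
    return ChangeCategory(motif_set.classify(wild_kmer), motif_set.classify(derived_kmer))


@dataclass
class SetChangeCounts:
    """Per-motif-set window tallies for one variant.

    ``counts`` maps each change category to its window count; the
    derived properties aggregate them into the loss/gain/alteration
    vocabulary. For unlabeled (direction-free) sets only the ESR
    properties are meaningful.
    """

    set_name: str
    unlabeled: bool
    counts: dict[ChangeCategory, int] = field(default_factory=dict)
    n_windows: int = 0
    n_unscorable_windows: int = 0  # windows containing non-ACGT bases

    def _get(self, wild: Label, derived: Label) -> int:
        return self.counts.get(ChangeCategory(wild, derived), 0)

    # -- directional sets -------------------------------------------------
    @property
    def ese_to_ess(self) -> int:
        return self._get(Label.ESE, Label.ESS)

    @property
    def ess_to_ese(self) -> int:
        return self._get(Label.ESS, Label.ESE)

    @property
    def ese_loss(self) -> int:
        """Windows whose wild k-mer is an ESE and derived k-mer is not."""
        return self._get(Label.ESE, Label.NEUTRAL) + self.ese_to_ess

    @property
    def ese_gain(self) -> int:
        return self._get(Label.NEUTRAL, Label.ESE) + self.ess_to_ese

    @property
    def ese_alteration(self) -> int:
        return self._get(Label.ESE, Label.ESE)

    @property
    def ess_loss(self) -> int:
        return self._get(Label.ESS, Label.NEUTRAL) + self.ess_to_ese

    @property
    def ess_gain(self) -> int:
        return self._get(Label.NEUTRAL, Label.ESS) + self.ese_to_ess

    @property
    def ess_alteration(self) -> int:
        return self._get(Label.ESS, Label.ESS)

    # -- unlabeled sets ---------------------------------------------------
    @property
    def esr_loss(self) -> int:
        return self._get(Label.UNLABELED_ESR, Label.NEUTRAL)

    @property
    def esr_gain(self) -> int:
        return self._get(Label.NEUTRAL, Label.UNLABELED_ESR)

    @property
    def esr_alteration(self) -> int:
        return self._get(Label.UNLABELED_ESR, Label.UNLABELED_ESR)

    @property
    def combined_extent(self) -> int:
        """ESE losses + ESS gains (direct conversions count in both)."""
        if self.unlabeled:
            return self.esr_loss + self.esr_gain
        return self.ese_loss + self.ess_gain


@dataclass(frozen=True)
class PWMChange:
    """A threshold-crossing change of one PWM site window."""

    matrix_name: str
    start: int  # window start relative to the exon-truncated scan region
    kind: str  # "lost" | "gained" | "altered"
    wild_score: float
    derived_score: float
    variant_pos_in_motif: int  # 1-based position of the variant in the motif


@dataclass
class ESRChangeProfile:
    """All motif-level changes induced by one variant."""

    variant_id: str
    per_set: dict[str, SetChangeCounts] = field(default_factory=dict)
    pwm_changes: list[PWMChange] = field(default_factory=list)

    def pwm_counts(self) -> dict[str, int]:
        out = {"lost": 0, "gained": 0, "altered": 0}
        for c in self.pwm_changes:
            out[c.kind] += 1
        return out


def _profile_one_set(ctx: VariantContext, motif_set: ESRMotifSet) -> SetChangeCounts:
    counts = SetChangeCounts(set_name=motif_set.name, unlabeled=motif_set.unlabeled)
    for wild, derived, _pos in variant_windows(ctx, motif_set.k):
        try:
            cat = classify_change_pair(motif_set, wild, derived)
        except ValueError:
            counts.n_unscorable_windows += 1
            continue
        counts.counts[cat] = counts.counts.get(cat, 0) + 1
        counts.n_windows += 1
    return counts


def _profile_pwms(ctx: VariantContext, pwms: PWMSet) -> list[PWMChange]:
    changes: list[PWMChange] = []
    for pwm in pwms.matrices:
        for wild, derived, pos in variant_windows(ctx, pwm.width):
            try:
                ws, ds = pwm.score(wild), pwm.score(derived)
            except ValueError:
                continue
            wild_site, derived_site = ws >= pwm.threshold, ds >= pwm.threshold
            if wild_site and not derived_site:
                kind = "lost"
            elif derived_site and not wild_site:
                kind = "gained"
            elif wild_site and derived_site and ws != ds:
                kind = "altered"
            else:
                continue
            start = ctx.var_offset - (pos - 1)
            changes.append(PWMChange(pwm.name, start, kind, ws, ds, pos))
    return changes


def change_profile(
    ctx: VariantContext,
    sets: Iterable[ESRMotifSet],
    pwms: PWMSet | None = None,
) -> ESRChangeProfile:
    """Aggregate window change categories over motif sets and PWMs.

    A PWM site is lost when a window scores at or above threshold in
    the wild-type allele and the corresponding window falls below it in
    the derived allele, gained for the reverse, and altered when both
    alleles score as sites with different scores. For each lost site
    the variant's 1-based position within the motif is recorded.
    """
    profile = ESRChangeProfile(variant_id=ctx.variant.variant.id or f"{ctx.variant.chrom}:{ctx.variant.pos}")
    for motif_set in sets:
        profile.per_set[motif_set.name] = _profile_one_set(ctx, motif_set)
    if pwms is not None:
        profile.pwm_changes = _profile_pwms(ctx, pwms)
    return profile


EXTENT_BINS = ("0", "1", "2", "3", ">=4")


def extent_bin(profile: ESRChangeProfile, set_name: str) -> str:
    """Bin a variant's combined extent of change into {0,1,2,3,>=4}."""
    if set_name not in profile.per_set:
        raise KeyError(f"profile has no motif set {set_name!r}")
    extent = profile.per_set[set_name].combined_extent
    return EXTENT_BINS[extent] if extent < 4 else ">=4"
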