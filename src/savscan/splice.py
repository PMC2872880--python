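"""Splice-site strength scoring and the delta-SS ectopic-creation metric.

Donor (5') sites are scored on 9-base windows (3 exonic + 6 intronic)
and acceptor (3') sites on 23-base windows (20 intronic + 3 exonic),
through a pluggable scoring backend. The shipped backend is a
position-weight log-odds model trainable from a set of true junction
windows against a background (pseudocount 0.5, log base 2); its
parameters round-trip through a plain-text file so externally derived
per-position weight models can be supplied instead.

The ectopic-creation metric considers every window placement in which
the variant could play a role (sliding 1 bp at a time, including
placements that put the putative junction inside the exon -- that is
what an ectopic site is), scores wild-type and derived alleles, and
takes the maximal score increase per side:

    deltaSS = max(delta5'SS, delta3'SS),   delta5'SS = max_w (ME_var - ME_wt)

Large positive values flag creation of a candidate de novo splice
site, which is then compared against the exon's natural site on the
same side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .variants import VariantContext

__all__ = [
    "DONOR_WIDTH",
    "ACCEPTOR_WIDTH",
    "DONOR_EXONIC",
    "ACCEPTOR_EXONIC",
    "PositionWeightSpliceModel",
    "SideDelta",
    "DeltaSSResult",
    "EctopicAssessment",
    "score_splice_site",
    "delta_ss",
    "ectopic_assessment",
    "select_ectopic_like_controls",
]

DONOR_WIDTH = 9
ACCEPTOR_WIDTH = 23
DONOR_EXONIC = 3  # exonic bases in a donor window
ACCEPTOR_EXONIC = 3  # exonic bases in an acceptor window

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_WIDTHS = {"5p": DONOR_WIDTH, "3p": ACCEPTOR_WIDTH}


def _counts(windows: Sequence[str], width: int) -> np.ndarray:
    counts = np.zeros((4, width))
    for w in windows:
        w = w.upper()
        if len(w) != width:
            raise ValueError(f"training window {w!r} has length {len(w)}, expected {width}")
        for j, base in enumerate(w):
            counts[_BASE_INDEX[base], j] += 1
    return counts


@dataclass(frozen=True)
class PositionWeightSpliceModel:
    """Log-odds per-position weight model for donor and acceptor sites.

    ``donor_weights`` is 4x9 and ``acceptor_weights`` 4x23, rows in
    A,C,G,T order; a window's score is the sum of the weights of its
    observed bases. Deterministic by construction.
    """

    donor_weights: np.ndarray
    acceptor_weights: np.ndarray
    backend: str = "log-odds-wmm"

    def __post_init__(self) -> None:
        d = np.asarray(self.donor_weights, dtype=float)
        a = np.asarray(self.acceptor_weights, dtype=float)
        if d.shape != (4, DONOR_WIDTH):
            raise ValueError(f"donor weights must be 4x{DONOR_WIDTH}, got {d.shape}")
        if a.shape != (4, ACCEPTOR_WIDTH):
            raise ValueError(f"acceptor weights must be 4x{ACCEPTOR_WIDTH}, got {a.shape}")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(a))):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "donor_weights", d)
        object.__setattr__(self, "acceptor_weights", a)

    def score(self, window: str, side: str) -> float:
        window = window.upper()
        if side not in _WIDTHS:
            raise ValueError(f"side must be '5p' or '3p', got {side!r}")
        width = _WIDTHS[side]
        if len(window) != width:
            raise ValueError(f"{side} window must be {width} bases, got {len(window)}")
        weights = self.donor_weights if side == "5p" else self.acceptor_weights
        total = 0.0
        for j, base in enumerate(window):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {base!r} in splice-site window")
            total += weights[_BASE_INDEX[base], j]
        return float(total)

    @classmethod
    def train(
        cls,
        donor_windows: Sequence[str],
        acceptor_windows: Sequence[str],
        donor_background: Sequence[str] | None = None,
        acceptor_background: Sequence[str] | None = None,
        pseudocount: float = 0.5,
    ) -> "PositionWeightSpliceModel":
        """Fit log2-odds weights from true junction windows.

        Per position, the foreground base probability is
        ``(count + pseudocount) / (n + 4 * pseudocount)``; the
        background is estimated the same way from the background
        windows, or is uniform 0.25 when none are given. The weight is
        ``log2(foreground / background)``.
        """

        def freq(windows: Sequence[str], width: int) -> np.ndarray:
            c = _counts(windows, width)
            return (c + pseudocount) / (c.sum(axis=0, keepdims=True) + 4 * pseudocount)

        def bg(windows: Sequence[str] | None, width: int) -> np.ndarray:
            if windows is None:
                return np.full((4, width), 0.25)
            return freq(windows, width)

        if not donor_windows or not acceptor_windows:
            raise ValueError("training requires at least one window per side")
        donor = np.log2(freq(donor_windows, DONOR_WIDTH) / bg(donor_background, DONOR_WIDTH))
        acceptor = np.log2(
            freq(acceptor_windows, ACCEPTOR_WIDTH) / bg(acceptor_background, ACCEPTOR_WIDTH)
        )
        return cls(donor, acceptor)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# splice-site position-weight model (rows A,C,G,T)\n")
            for section, weights in (("DONOR", self.donor_weights), ("ACCEPTOR", self.acceptor_weights)):
                fh.write(f">{section}\n")
                for i, base in enumerate(_BASES):
                    fh.write(f"{base}: " + " ".join(repr(float(x)) for x in weights[i]) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PositionWeightSpliceModel":
        sections: dict[str, dict[str, list[float]]] = {}
        current: dict[str, list[float]] | None = None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0].upper()
                    current = sections.setdefault(name, {})
                elif current is not None and ":" in line:
                    base, _, rest = line.partition(":")
                    current[base.strip().upper()] = [float(x) for x in rest.split()]
                else:
                    raise ValueError(f"malformed model file line {lineno} of {path}")
        for name in ("DONOR", "ACCEPTOR"):
            if name not in sections or sorted(sections[name]) != ["A", "C", "G", "T"]:
                raise ValueError(f"model file {path} missing complete {name} section")
        donor = np.array([sections["DONOR"][b] for b in _BASES])
        acceptor = np.array([sections["ACCEPTOR"][b] for b in _BASES])
        return cls(donor, acceptor, backend=f"file:{Path(path).name}")


def score_splice_site(model, window: str, side: str) -> float:
    """Score one junction window (side '5p' = 9 bases, '3p' = 23)."""
    return model.score(window, side)


@dataclass(frozen=True)
class SideDelta:
    """Per-side result of the variant-window scan (None = no window)."""

    delta: float | None
    best_start: int | None  # start of the best derived-allele window, relative to variant
    best_derived_score: float | None
    n_windows: int


@dataclass(frozen=True)
class DeltaSSResult:
    donor: SideDelta
    acceptor: SideDelta
    natural_donor_score: float | None
    natural_acceptor_score: float | None

    @property
    def delta_ss(self) -> float | None:
        deltas = [s.delta for s in (self.donor, self.acceptor) if s.delta is not None]
        return max(deltas) if deltas else None

    @property
    def best_side(self) -> str | None:
        """Side of the strongest derived-allele (putative ectopic) site."""
        cands = [("5p", self.donor), ("3p", self.acceptor)]
        cands = [(s, d) for s, d in cands if d.best_derived_score is not None]
        if not cands:
            return None
        return max(cands, key=lambda sd: sd[1].best_derived_score)[0]


def _scan_side(model, wild: str, derived: str, vpos: int, side: str) -> SideDelta:
    width = _WIDTHS[side]
    lo = max(0, vpos - width + 1)
    hi = min(len(wild) - width, vpos)
    best_delta = None
    best_start = None
    best_score = None
    n = 0
    for start in range(lo, hi + 1):
        try:
            ws = model.score(wild[start : start + width], side)
            ds = model.score(derived[start : start + width], side)
        except ValueError:
            continue  # window contains unscorable bases
        n += 1
        d = ds - ws
        if best_delta is None or d > best_delta:
            best_delta = d
        if best_score is None or ds > best_score:
            best_score, best_start = ds, start - vpos
    return SideDelta(best_delta, best_start, best_score, n)


def delta_ss(model, ctx: VariantContext) -> DeltaSSResult:
    """Maximal splice-site score change over all variant windows.

    The scan region is the transcript-orientation concatenation of the
    available upstream intron, the exon, and the downstream intron, so
    placements may put the putative junction anywhere around the
    variant. Natural-site scores are read at the annotated junctions
    with the same backend (donor: last 3 exonic + first 6 intronic
    bases; acceptor: last 20 intronic + first 3 exonic bases); they are
    None when the flanking intron is too short.
    """
    wild = ctx.upstream_intron_seq + ctx.exon_seq + ctx.downstream_intron_seq
    derived = ctx.upstream_intron_seq + ctx.derived_exon_seq + ctx.downstream_intron_seq
    vpos = len(ctx.upstream_intron_seq) + ctx.var_offset
    donor = _scan_side(model, wild, derived, vpos, "5p")
    acceptor = _scan_side(model, wild, derived, vpos, "3p")

    natural_donor = None
    if len(ctx.downstream_intron_seq) >= DONOR_WIDTH - DONOR_EXONIC and len(ctx.exon_seq) >= DONOR_EXONIC:
        window = ctx.exon_seq[-DONOR_EXONIC:] + ctx.downstream_intron_seq[: DONOR_WIDTH - DONOR_EXONIC]
        try:
            natural_donor = model.score(window, "5p")
        except ValueError:
            natural_donor = None
    natural_acceptor = None
    intronic = ACCEPTOR_WIDTH - ACCEPTOR_EXONIC
    if len(ctx.upstream_intron_seq) >= intronic and len(ctx.exon_seq) >= ACCEPTOR_EXONIC:
        window = ctx.upstream_intron_seq[-intronic:] + ctx.exon_seq[:ACCEPTOR_EXONIC]
        try:
            natural_acceptor = model.score(window, "3p")
        except ValueError:
            natural_acceptor = None
    return DeltaSSResult(donor, acceptor, natural_donor, natural_acceptor)


@dataclass(frozen=True)
class EctopicAssessment:
    ectopic_like: bool  # deltaSS at or above the threshold
    ectopic_ge_natural: bool | None  # best ectopic score >= same-side natural score
    side: str | None  # side of the best putative ectopic site
    best_ectopic_score: float | None
    natural_score_same_side: float | None
    variant_half: str  # "acceptor_half" (5' half of exon) or "donor_half"
    same_half_as_site: bool | None  # variant in the exon half adjacent to the created site


def ectopic_assessment(
    result: DeltaSSResult, ctx: VariantContext, threshold: float = 1.0
) -> EctopicAssessment:
    """Flag ectopic-site creation and compare to the natural site.

    ``ectopic_like`` requires deltaSS >= threshold (default 1).
    ``ectopic_ge_natural`` compares the best derived-allele window
    score with the natural score of the same side (the natural site the
    new site would compete with). The variant's exon half is recorded:
    an ectopic donor created in the donor-proximal half mirrors the
    true-positive pattern, the opposite-half pattern is typical of
    computational ectopic-like lookalikes.
    """
    ds = result.delta_ss
    ectopic_like = ds is not None and ds >= threshold
    side = result.best_side
    half = "acceptor_half" if ctx.var_offset < len(ctx.exon_seq) / 2 else "donor_half"
    if side is None:
        return EctopicAssessment(ectopic_like, None, None, None, None, half, None)
    side_delta = result.donor if side == "5p" else result.acceptor
    natural = result.natural_donor_score if side == "5p" else result.natural_acceptor_score
    ge = None
    if natural is not None and side_delta.best_derived_score is not None:
        ge = side_delta.best_derived_score >= natural
    same_half = (side == "5p") == (half == "donor_half")
    return EctopicAssessment(
        ectopic_like, ge, side, side_delta.best_derived_score, natural, half, same_half
    )


def select_ectopic_like_controls(
    scored: Sequence[tuple[object, DeltaSSResult]],
    n: int,
    threshold: float = 1.0,
) -> list[tuple[object, DeltaSSResult]]:
    """Top-n qualifying variants by best putative ectopic site score.

    Filters to deltaSS >= threshold, ranks by the best derived-allele
    window score descending (ties broken by the key's natural order),
    and returns the first n. Returns all qualifiers with a warning when
    fewer than n qualify.
    """
    qualifying = []
    for key, res in scored:
        ds = res.delta_ss
        if ds is None or ds < threshold:
            continue
        side = res.best_side
        best = (res.donor if side == "5p" else res.acceptor).best_derived_score if side else None
        if best is None:
            continue
        qualifying.append((key, res, best))
    qualifying.sort(key=lambda t: (-t[2], str(t[0])))
    if len(qualifying) < n:
        warnings.warn(
            f"only {len(qualifying)} variants reach deltaSS >= {threshold}, requested {n}",
            stacklevel=2,
        )
    return [(k, r) for k, r, _ in qualifying[:n]]
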