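"""Exonic splicing regulatory (ESR) motif collections.

Two kinds of motif resources are supported:

* plain k-mer sets (hexamer or octamer lists) in which each motif is
  labelled as an exonic splicing enhancer (ESE), silencer (ESS), or --
  for collections whose elements were not assigned a direction -- as an
  unlabelled ESR;
* position weight matrices (PWMs) with per-matrix score thresholds, in
  the style of SR-protein binding-site models, where a sequence window
  "scores" as a site when its summed weight reaches the threshold.

File formats are small line-oriented text dialects documented in
``docs/formats.md`` so that any published motif collection can be
dropped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Label",
    "ESRMotifSet",
    "PWM",
    "PWMSet",
    "PWMHit",
    "PWMScanResult",
    "load_motif_set",
    "write_motif_set",
    "load_pwm_set",
    "write_pwm_set",
    "scan_pwm_hits",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class Label(str, Enum):
    """Functional label of a motif or of an n-mer classification."""

    ESE = "ESE"
    ESS = "ESS"
    UNLABELED_ESR = "UNLABELED_ESR"
    NEUTRAL = "NEUTRAL"


class MotifParseError(ValueError):
    """Raised for malformed motif or PWM files."""


def _check_kmer(kmer: str, k: int, where: str = "") -> str:
    kmer = kmer.upper()
    if len(kmer) != k:
        raise MotifParseError(f"motif {kmer!r} has length {len(kmer)}, expected {k}{where}")
    if any(b not in _BASE_INDEX for b in kmer):
        raise MotifParseError(f"motif {kmer!r} contains non-ACGT characters{where}")
    return kmer


@dataclass(frozen=True)
class ESRMotifSet:
    """A labelled collection of fixed-length DNA motifs.

    Parameters
    ----------
    name : str
        Identifier of the collection (e.g. ``"toy-ni"``).
    k : int
        Motif length in bases (6 for hexamer sets, 8 for octamer sets).
    motifs : mapping
        Uppercase k-mer -> :class:`Label` (ESE, ESS or UNLABELED_ESR).
    source_note : str
        Free-text provenance note.
    """

    name: str
    k: int
    motifs: Mapping[str, Label]
    source_note: str = ""

    def __post_init__(self) -> None:
        for kmer, label in self.motifs.items():
            if len(kmer) != self.k or any(b not in _BASE_INDEX for b in kmer):
                raise ValueError(f"invalid motif {kmer!r} for k={self.k}")
            if kmer != kmer.upper():
                raise ValueError(f"motif {kmer!r} must be uppercase")
            if label is Label.NEUTRAL:
                raise ValueError("NEUTRAL is a classification outcome, not a stored label")
        labels = set(self.motifs.values())
        if Label.UNLABELED_ESR in labels and labels != {Label.UNLABELED_ESR}:
            raise ValueError(
                f"set {self.name!r} mixes UNLABELED_ESR with directional labels"
            )

    @property
    def unlabeled(self) -> bool:
        """True for collections whose motifs carry no ESE/ESS direction."""
        return any(l is Label.UNLABELED_ESR for l in self.motifs.values())

    def __len__(self) -> int:
        return len(self.motifs)

    def count(self, label: Label) -> int:
        return sum(1 for l in self.motifs.values() if l is label)

    def classify(self, nmer: str) -> Label:
        """Classify an n-mer as ESE, ESS, UNLABELED_ESR or NEUTRAL.

        N-mers absent from the collection are splicing-neutral. The
        query is uppercased first; ambiguity codes (N etc.) are a data
        gap, not a biological claim, and raise.
        """
        nmer = nmer.upper()
        if len(nmer) != self.k:
            raise ValueError(f"n-mer length {len(nmer)} != k={self.k}")
        if any(b not in _BASE_INDEX for b in nmer):
            raise ValueError(f"n-mer {nmer!r} contains non-ACGT characters; unscorable")
        return self.motifs.get(nmer, Label.NEUTRAL)


def classify_nmer(motif_set: ESRMotifSet, nmer: str) -> Label:
    """Functional alias for :meth:`ESRMotifSet.classify`."""
    return motif_set.classify(nmer)


def load_motif_set(
    path: str | Path,
    k: int,
    default_label: Label | str | None = None,
    name: str | None = None,
) -> ESRMotifSet:
    """Load a motif set from a one-motif-per-line text file.

    Each non-comment line is ``KMER`` or ``KMER<TAB>LABEL``. Lines
    without a label use ``default_label``. Duplicate identical lines
    collapse; the same k-mer with two different labels is a validation
    error.
    """
    path = Path(path)
    if default_label is not None:
        default_label = Label(default_label)
    motifs: dict[str, Label] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            where = f" (line {lineno} of {path})"
            kmer = _check_kmer(parts[0], k, where)
            if len(parts) >= 2:
                try:
                    label = Label(parts[1].strip().upper())
                except ValueError as exc:
                    raise MotifParseError(f"unknown label {parts[1]!r}{where}") from exc
                if label is Label.NEUTRAL:
                    raise MotifParseError(f"NEUTRAL cannot be a stored label{where}")
            elif default_label is not None:
                label = default_label
            else:
                raise MotifParseError(f"no label and no default_label{where}")
            if kmer in motifs and motifs[kmer] is not label:
                raise MotifParseError(
                    f"conflicting labels for {kmer}: {motifs[kmer].value} vs {label.value}{where}"
                )
            motifs[kmer] = label
    return ESRMotifSet(name=name or path.stem, k=k, motifs=motifs)


def write_motif_set(motif_set: ESRMotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# motif set {motif_set.name} (k={motif_set.k})\n")
        for kmer in sorted(motif_set.motifs):
            fh.write(f"{kmer}\t{motif_set.motifs[kmer].value}\n")


# ---------------------------------------------------------------------------
# Position weight matrices


@dataclass(frozen=True)
class PWM:
    """A 4xL weight matrix with a site-calling threshold.

    Rows are fixed in A, C, G, T order. A window of width L scores as
    the sum over positions of the weight of the observed base, and is a
    site when score >= threshold.
    """

    name: str
    weights: np.ndarray  # shape (4, L)
    threshold: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4 or w.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r} must be 4xL with L >= 1, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"PWM {self.name!r} has non-finite weights")
        if not math.isfinite(self.threshold):
            raise ValueError(f"PWM {self.name!r} threshold must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return int(self.weights.shape[1])

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != width {self.width}")
        total = 0.0
        for j, base in enumerate(window):
            try:
                total += self.weights[_BASE_INDEX[base], j]
            except KeyError as exc:
                raise ValueError(f"unscorable base {base!r} in window") from exc
        return float(total)


@dataclass(frozen=True)
class PWMSet:
    """A named collection of threshold-bearing PWMs."""

    name: str
    matrices: tuple[PWM, ...]

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def min_width(self) -> int:
        return min(m.width for m in self.matrices)


@dataclass(frozen=True)
class PWMHit:
    motif_name: str
    start: int  # 0-based window start
    score: float


@dataclass(frozen=True)
class PWMScanResult:
    hits: tuple[PWMHit, ...]
    skipped_windows: int  # windows overlapping unscorable bases (N etc.)

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def scan_pwm_hits(pwms: PWMSet, sequence: str) -> PWMScanResult:
    """Score every window of every matrix; return threshold-crossing hits.

    Hits are sorted by start, then motif name. Windows overlapping a
    non-ACGT base are skipped and counted in ``skipped_windows``.
    """
    sequence = sequence.upper()
    if len(sequence) < pwms.min_width:
        raise ValueError(
            f"sequence length {len(sequence)} < minimum matrix width {pwms.min_width}"
        )
    hits: list[PWMHit] = []
    skipped = 0
    for pwm in pwms.matrices:
        for start in range(len(sequence) - pwm.width + 1):
            window = sequence[start : start + pwm.width]
            if any(b not in _BASE_INDEX for b in window):
                skipped += 1
                continue
            score = pwm.score(window)
            if score >= pwm.threshold:
                hits.append(PWMHit(pwm.name, start, score))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return PWMScanResult(tuple(hits), skipped)


def load_pwm_set(path: str | Path, name: str | None = None) -> PWMSet:
    """Load PWMs from the text dialect in ``docs/formats.md``.

    Each matrix is a ``>NAME threshold=X`` header followed by exactly
    four rows ``A:``, ``C:``, ``G:``, ``T:`` of equal length.
    """
    path = Path(path)
    matrices: list[PWM] = []
    header: tuple[str, float] | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        mname, threshold = header
        if sorted(rows) != ["A", "C", "G", "T"]:
            raise MotifParseError(
                f"matrix {mname!r} has rows {sorted(rows)}, need exactly A,C,G,T"
                f" (before line {lineno} of {path})"
            )
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise MotifParseError(f"matrix {mname!r} has ragged rows {widths}")
        weights = np.array([rows[b] for b in _BASES], dtype=float)
        matrices.append(PWM(mname, weights, threshold))
        header, rows = None, {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split()
                if not fields:
                    raise MotifParseError(f"empty matrix header (line {lineno} of {path})")
                mname = fields[0]
                thr = None
                for tok in fields[1:]:
                    if tok.startswith("threshold="):
                        thr = float(tok.split("=", 1)[1])
                if thr is None:
                    raise MotifParseError(
                        f"matrix {mname!r} missing threshold= (line {lineno} of {path})"
                    )
                header = (mname, thr)
            else:
                if header is None:
                    raise MotifParseError(f"row outside a matrix (line {lineno} of {path})")
                if ":" not in line:
                    raise MotifParseError(f"malformed row (line {lineno} of {path})")
                base, _, rest = line.partition(":")
                base = base.strip().upper()
                if base not in _BASE_INDEX:
                    raise MotifParseError(f"unknown row {base!r} (line {lineno} of {path})")
                if base in rows:
                    raise MotifParseError(f"duplicate row {base!r} (line {lineno} of {path})")
                rows[base] = [float(x) for x in rest.split()]
    flush(-1)
    if not matrices:
        raise MotifParseError(f"no matrices found in {path}")
    return PWMSet(name=name or path.stem, matrices=tuple(matrices))


def write_pwm_set(pwms: PWMSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# PWM set {pwms.name}\n")
        for pwm in pwms.matrices:
            fh.write(f">{pwm.name} threshold={pwm.threshold!r}\n")
            for i, base in enumerate(_BASES):
                vals = " ".join(repr(float(x)) for x in pwm.weights[i])
                fh.write(f"{base}: {vals}\n")
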