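"""Regulatory (non-coding) evolutionary constraint in coding sequence.

Constraint on splicing-regulatory sequence inside coding exons has to
be decoupled from protein-level constraint. The approach: measure, in
genome-wide multi-species alignments of internal coding exons, the
proportion of alignment columns fully conserved for each of the 192
(codon, codon position) cells, and weight each cell by
``(1 - Pr) * 10`` so the score is inversely proportional to its
genome-wide conservation. Synonymous positions (and hypermutable CpG
third positions in particular) get the highest weights. The regulatory
constraint (RC) score of a window is then the weight-sum of its fully
conserved columns divided by the window length:

    RC = ( sum_i S_i * delta_ci ) / N

where N is the number of columns, S_i is 1 when column i is identical
across all species and 0 otherwise, and delta_ci is the matrix weight
of the human codon position at column i. High RC means conservation
exactly where genome-wide coding sequence is free to drift -- the
signature of an overlapping regulatory element.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .variants import ExonModel, VariantContext

__all__ = [
    "CodonConstraintMatrix",
    "AlignmentWindow",
    "MafIndex",
    "RCResult",
    "build_codon_matrix",
    "rc_score",
    "variant_rc",
    "exon_conservation",
    "non_overlapping_contexts",
]

_BASES = set("ACGT")
ALL_CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))


class UndefinedCellError(KeyError):
    """A (codon, position) cell with no genome-wide observations."""


@dataclass
class CodonConstraintMatrix:
    """Scores for the 192 (codon, codon-position) cells.

    ``observed[cell]`` is the number of genome-wide alignment columns
    contributing to the cell and ``conserved[cell]`` how many of those
    were identical across all species. The score of a cell is
    ``(1 - conserved/observed) * 10``; cells never observed are
    undefined and raise :class:`UndefinedCellError` when used.
    """

    observed: dict[tuple[str, int], int] = field(default_factory=dict)
    conserved: dict[tuple[str, int], int] = field(default_factory=dict)

    @staticmethod
    def cells() -> tuple[tuple[str, int], ...]:
        return tuple((codon, pos) for codon in ALL_CODONS for pos in (1, 2, 3))

    def pr(self, codon: str, position: int) -> float:
        """Proportion of fully conserved columns for a cell."""
        key = (codon.upper(), position)
        n = self.observed.get(key, 0)
        if n == 0:
            raise UndefinedCellError(f"no observations for codon {key[0]} position {position}")
        return self.conserved.get(key, 0) / n

    def score(self, codon: str, position: int) -> float:
        """Cell weight ``(1 - Pr) * 10`` in [0, 10]."""
        return (1.0 - self.pr(codon, position)) * 10.0

    def defined(self, codon: str, position: int) -> bool:
        return self.observed.get((codon.upper(), position), 0) > 0

    @property
    def max_score(self) -> float:
        best = 0.0
        for codon, pos in self.cells():
            if self.defined(codon, pos):
                best = max(best, self.score(codon, pos))
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for codon, pos in self.cells():
            n = self.observed.get((codon, pos), 0)
            c = self.conserved.get((codon, pos), 0)
            rows.append(
                {
                    "codon": codon,
                    "position": pos,
                    "observed": n,
                    "conserved": c,
                    "pr_conserved": c / n if n else float("nan"),
                    "score": (1.0 - c / n) * 10.0 if n else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonConstraintMatrix":
        df = pd.read_csv(path, sep="\t")
        m = cls()
        for _, row in df.iterrows():
            key = (str(row["codon"]).upper(), int(row["position"]))
            m.observed[key] = int(row["observed"])
            m.conserved[key] = int(row["conserved"])
        return m


@dataclass(frozen=True)
class AlignmentWindow:
    """An ungapped multi-species window in transcript orientation.

    ``rows`` holds per-species sequences, reference first; ``keys``
    gives each column's (codon, position) matrix key, or None for
    columns outside a complete codon (which are unweighted and thus
    contribute S_i * 0 -- they still count toward N).
    """

    rows: tuple[str, ...]
    keys: tuple[tuple[str, int] | None, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 3:
            raise ValueError("alignment window needs the reference plus >= 2 other species")
        n = len(self.rows[0])
        if n < 1:
            raise ValueError("alignment window must have >= 1 column")
        if any(len(r) != n for r in self.rows):
            raise ValueError("ragged alignment rows")
        if any("-" in r for r in self.rows):
            raise ValueError("alignment window must be ungapped")
        if len(self.keys) != n:
            raise ValueError("one codon key per column required")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def conservation_flags(self) -> tuple[int, ...]:
        return tuple(
            1 if len({row[i].upper() for row in self.rows}) == 1 else 0
            for i in range(self.n_columns)
        )


def rc_score(matrix: CodonConstraintMatrix, window: AlignmentWindow) -> float:
    """RC = (sum of cell weights over fully conserved columns) / N."""
    if window.n_columns == 0:
        raise ValueError("empty alignment window")
    total = 0.0
    for flag, key in zip(window.conservation_flags(), window.keys):
        if flag and key is not None:
            total += matrix.score(*key)  # raises UndefinedCellError on empty cells
    return total / window.n_columns


# ---------------------------------------------------------------------------
# MAF access


class MafIndex:
    """Reference-anchored access to ungapped-reference MAF blocks.

    Blocks are indexed by the reference species' chromosome interval.
    ``src`` fields are expected as ``species.chrom``; the reference
    species name identifies the anchor row, which must be on the +
    strand.
    """

    def __init__(self, path: str | Path, reference: str):
        self.reference = reference
        self._blocks: dict[str, list[tuple[int, int, list[tuple[str, str]]]]] = {}
        for aln in AlignIO.parse(str(path), "maf"):
            ref_rec = None
            rows: list[tuple[str, str]] = []
            for rec in aln:
                species, _, chrom = rec.id.partition(".")
                rows.append((species, str(rec.seq).upper()))
                if species == reference:
                    ref_rec = (chrom, rec)
            if ref_rec is None:
                continue
            chrom, rec = ref_rec
            if rec.annotations.get("strand", 1) != 1:
                raise ValueError("reference rows must be + strand")
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            # order rows with the reference first, others in file order
            rows.sort(key=lambda r: r[0] != reference)
            self._blocks.setdefault(chrom, []).append((start, start + size, rows))
        for blocks in self._blocks.values():
            blocks.sort()

    def fetch(self, chrom: str, start: int, end: int) -> list[tuple[str, str]] | None:
        """Per-species columns for a 0-based half-open reference interval.

        Returns ``(species, subsequence)`` rows (reference first, which
        is ungapped by construction of the column mapping) or None when
        no single block fully covers the interval. Gap characters in
        non-reference rows are preserved.
        """
        for b_start, b_end, rows in self._blocks.get(chrom, []):
            if b_start <= start and end <= b_end:
                ref_seq = rows[0][1]
                # map reference coordinates to alignment columns
                cols = []
                ref_pos = b_start
                for j, base in enumerate(ref_seq):
                    if base != "-":
                        if start <= ref_pos < end:
                            cols.append(j)
                        ref_pos += 1
                return [(sp, "".join(seq[j] for j in cols)) for sp, seq in rows]
        return None


def _codon_keys(exon_seq: str, phase: int) -> list[tuple[str, int] | None]:
    """Matrix key per exon position (transcript orientation)."""
    keys: list[tuple[str, int] | None] = [None] * len(exon_seq)
    start = phase
    while start + 3 <= len(exon_seq):
        codon = exon_seq[start : start + 3].upper()
        if all(b in _BASES for b in codon):
            for i in range(3):
                keys[start + i] = (codon, i + 1)
        start += 3
    return keys


def _transcript_rows(rows: Sequence[tuple[str, str]], strand: str) -> list[str]:
    seqs = [seq for _, seq in rows]
    if strand == "-":
        seqs = [reverse_complement(s) for s in seqs]
    return seqs


def build_codon_matrix(
    maf: MafIndex, exons: Iterable[ExonModel], min_species: int = 3
) -> CodonConstraintMatrix:
    """Tally conserved/observed columns per (codon, position) cell.

    For each exon covered by an alignment with at least the reference
    plus two other species, every gap-free column inside a complete
    reference codon increments the cell's observed count, and its
    conserved count when identical across all rows.
    """
    matrix = CodonConstraintMatrix()
    for exon in exons:
        rows = maf.fetch(exon.chrom, exon.start, exon.end)
        if rows is None or len(rows) < min_species:
            continue
        seqs = _transcript_rows(rows, exon.strand)
        keys = _codon_keys(seqs[0], exon.phase)
        for i, key in enumerate(keys):
            if key is None:
                continue
            column = [s[i].upper() for s in seqs]
            if any(b not in _BASES for b in column):
                continue  # gap or ambiguous base: column not observed
            matrix.observed[key] = matrix.observed.get(key, 0) + 1
            if len(set(column)) == 1:
                matrix.conserved[key] = matrix.conserved.get(key, 0) + 1
    return matrix


@dataclass(frozen=True)
class RCResult:
    score: float | None
    reason: str | None = None  # set when unscored
    n_columns: int = 0

    @property
    def scored(self) -> bool:
        return self.score is not None


def variant_rc(
    matrix: CodonConstraintMatrix,
    maf: MafIndex,
    ctx: VariantContext,
    flank: int = 5,
    min_species: int = 3,
) -> RCResult:
    """RC score of the window ``flank`` bases either side of a variant.

    The default 5-base flank makes an 11-column window covering every
    hexamer containing the variant; the window truncates at the exon
    boundary. Unscorable cases (no alignment, fewer than two
    non-reference species, gapped columns, undefined matrix cells)
    return an :class:`RCResult` with a reason instead of raising.
    """
    lo = max(0, ctx.var_offset - flank)
    hi = min(len(ctx.exon_seq), ctx.var_offset + flank + 1)
    exon = ctx.exon
    if exon.strand == "+":
        g_start, g_end = exon.start + lo, exon.start + hi
    else:
        g_start, g_end = exon.end - hi, exon.end - lo
    rows = maf.fetch(exon.chrom, g_start, g_end)
    if rows is None:
        return RCResult(None, "MISSING_ALIGNMENT")
    if len(rows) < min_species:
        return RCResult(None, "TOO_FEW_SPECIES")
    seqs = _transcript_rows(rows, exon.strand)
    if any("-" in s for s in seqs):
        return RCResult(None, "GAPPED")
    keys = _codon_keys(ctx.exon_seq, exon.phase)[lo:hi]
    try:
        window = AlignmentWindow(tuple(seqs), tuple(keys))
        score = rc_score(matrix, window)
    except UndefinedCellError:
        return RCResult(None, "UNDEFINED_MATRIX_CELL")
    except ValueError as exc:
        return RCResult(None, str(exc))
    return RCResult(score, None, window.n_columns)


def non_overlapping_contexts(
    ctxs: Sequence[VariantContext], flank: int = 5
) -> list[VariantContext]:
    """Drop variants whose RC windows overlap, keeping the first by coordinate."""
    kept: list[VariantContext] = []
    last: dict[str, int] = {}
    for ctx in sorted(ctxs, key=lambda c: (c.variant.chrom, c.variant.pos)):
        lo = ctx.variant.pos - flank
        hi = ctx.variant.pos + flank
        if ctx.variant.chrom in last and lo <= last[ctx.variant.chrom]:
            continue
        kept.append(ctx)
        last[ctx.variant.chrom] = hi
    return kept


def _zero_fold(codon: str, position: int) -> bool:
    """True when every base change at this codon position is non-synonymous."""
    aa = standard_dna_table.forward_table.get(codon)
    if codon in standard_dna_table.stop_codons:
        aa = "*"
    i = position - 1
    for alt in "ACGT":
        if alt == codon[i]:
            continue
        mutant = codon[:i] + alt + codon[i + 1 :]
        alt_aa = "*" if mutant in standard_dna_table.stop_codons else standard_dna_table.forward_table.get(mutant)
        if alt_aa == aa:
            return False
    return True


def exon_conservation(
    rows: Sequence[str], phase: int
) -> tuple[float, float | None]:
    """Percent identity of an exon alignment, overall and at 0-fold sites.

    ``rows`` are transcript-orientation ungapped per-species sequences
    (reference first). Returns percentages in [0, 100]; the second
    value is None when the exon contains no 0-fold (strictly
    non-synonymous) position.
    """
    if len(rows) < 2:
        raise ValueError("need at least two species")
    n = len(rows[0])
    if any(len(r) != n for r in rows) or any("-" in r for r in rows):
        raise ValueError("rows must be ungapped and equal length")
    keys = _codon_keys(rows[0].upper(), phase)
    conserved_all = 0
    ns_total = 0
    ns_conserved = 0
    for i in range(n):
        cons = len({r[i].upper() for r in rows}) == 1
        conserved_all += cons
        key = keys[i]
        if key is not None and _zero_fold(*key):
            ns_total += 1
            ns_conserved += cons
    overall = 100.0 * conserved_all / n
    nonsyn = 100.0 * ns_conserved / ns_total if ns_total else None
    return overall, nonsyn
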