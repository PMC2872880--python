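"""Deterministic synthetic fixtures emulating the analysis inputs.

Everything the scoring framework consumes is generated at toy scale
from a single seed: a multi-gene genome FASTA with realistic splice
junctions, BED12 transcript models, hexamer ESR motif sets (a labelled
ESE/ESS collection and an unlabelled one), a set of threshold-bearing
PWMs, four-species MAF alignments whose per-column substitution rates
depend on codon position (third positions, and CpG third positions in
particular, drift fastest), a trained splice-site weight model, and
variant cohorts:

* a "skipping" cohort planted to destroy ESE hexamers and create ESS
  hexamers, preferentially near exon edges, inside fully conserved
  alignment windows;
* an "inclusion" cohort with the mirrored planting (ESS loss / ESE
  gain);
* an "ectopic" cohort whose derived alleles complete a splice-site
  consensus inside the exon;
* a large splicing-neutral control cohort and a smaller verified-
  neutral cohort with no planted effects.

Cohort sizes default to the study conditions (87 skipping, 80 verified
neutral, 20 inclusion, 54 ectopic); the control pool is a scaled-down
stand-in for a genome-wide common-SNP set. A JSON manifest records the
seed, the configuration, and the planted ground truth per variant.
Regeneration from the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .motifs import ESRMotifSet, Label, PWM, PWMSet, write_motif_set, write_pwm_set
from .splice import ACCEPTOR_WIDTH, DONOR_WIDTH, PositionWeightSpliceModel

__all__ = ["FixtureConfig", "FixtureBundle", "simulate_fixtures"]

_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_CPG_CODONS = {"TCG", "ACG", "CCG", "GCG"}

# per-position base probabilities for donor (9) and acceptor (23) windows
_DONOR_PROFILE = [
    {"A": 0.30, "C": 0.40, "G": 0.20, "T": 0.10},  # exon -3
    {"A": 0.60, "C": 0.10, "G": 0.20, "T": 0.10},  # exon -2
    {"A": 0.10, "C": 0.05, "G": 0.80, "T": 0.05},  # exon -1
    {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0},  # intron +1 (G of GT)
    {"A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0},  # intron +2 (T of GT)
    {"A": 0.60, "C": 0.05, "G": 0.30, "T": 0.05},
    {"A": 0.70, "C": 0.10, "G": 0.10, "T": 0.10},
    {"A": 0.10, "C": 0.05, "G": 0.80, "T": 0.05},
    {"A": 0.20, "C": 0.15, "G": 0.15, "T": 0.50},
]
_ACCEPTOR_PROFILE = (
    [{"A": 0.10, "C": 0.35, "G": 0.10, "T": 0.45}] * 16  # polypyrimidine tract
    + [
        {"A": 0.25, "C": 0.30, "G": 0.15, "T": 0.30},
        {"A": 0.05, "C": 0.65, "G": 0.05, "T": 0.25},
        {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0},  # A of AG
        {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0},  # G of AG
        {"A": 0.25, "C": 0.125, "G": 0.50, "T": 0.125},  # exon +1
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    ]
)
assert len(_DONOR_PROFILE) == DONOR_WIDTH and len(_ACCEPTOR_PROFILE) == ACCEPTOR_WIDTH


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the fixture generator; defaults are the study conditions."""

    # genome structure
    n_genes: int = 60
    exons_per_gene: int = 5
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (250, 400)
    gene_flank: int = 150
    intergenic: int = 150
    n_chromosomes: int = 2
    # motif sets (totals include planted motifs)
    n_ese: int = 979
    n_ess: int = 496
    n_unlabeled: int = 285
    # cohorts
    n_skipping: int = 87
    n_neutral_verified: int = 80
    n_inclusion: int = 20
    n_ectopic: int = 54
    n_control: int = 1000
    # planted effect structure
    sav_ese_loss_choices: tuple[int, ...] = (1, 2, 3)
    sav_ese_loss_probs: tuple[float, ...] = (0.3, 0.4, 0.3)
    sav_ess_gain_choices: tuple[int, ...] = (0, 1, 2)
    sav_ess_gain_probs: tuple[float, ...] = (0.3, 0.4, 0.3)
    sav_peripheral_prob: float = 0.7
    ectopic_donor_prob: float = 0.7
    ectopic_same_half_prob: float = 0.75
    ectopic_ess_gain_prob: float = 0.5
    # alignment simulation: per-species substitution rate by codon position
    sub_rate_pos1: float = 0.04
    sub_rate_pos2: float = 0.02
    sub_rate_pos3: float = 0.15
    sub_rate_cpg3: float = 0.45
    sub_rate_noncoding: float = 0.10
    # control-cohort polarization noise
    p_outgroup_missing: float = 0.01
    p_outgroup_disagree: float = 0.01
    min_variant_spacing: int = 12  # keeps hexamer and RC windows disjoint


@dataclass
class FixtureBundle:
    """Paths of one generated fixture set plus its manifest."""

    root: Path
    genome: Path
    transcripts_bed: Path
    ni_like_motifs: Path
    ast_like_motifs: Path
    pwms: Path
    splice_model: Path
    maf: Path
    cohorts: dict[str, Path]
    manifest_path: Path
    manifest: dict


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, n)]


def _sample_profile(rng: np.random.Generator, profile) -> str:
    out = []
    for probs in profile:
        p = np.array([probs[b] for b in _BASES])
        out.append(_BASES[rng.choice(4, p=p / p.sum())])
    return "".join(out)


def _consensus(profile) -> str:
    return "".join(max(p, key=p.get) for p in profile)


@dataclass
class _Gene:
    gid: str
    strand: str
    chrom: str
    exons: list[list[str]]  # mutable per-exon transcript-orientation sequence
    introns: list[str]
    flank5: str
    flank3: str
    phases: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        phase = 0
        for exon in self.exons:
            self.phases.append(phase)
            phase = (3 - ((len(exon) - phase) % 3)) % 3

    def exon_tx_start(self, idx: int) -> int:
        off = len(self.flank5)
        for i in range(idx):
            off += len(self.exons[i]) + len(self.introns[i])
        return off

    def tx_seq(self) -> str:
        parts = [self.flank5]
        for i, exon in enumerate(self.exons):
            parts.append("".join(exon))
            if i < len(self.introns):
                parts.append(self.introns[i])
        parts.append(self.flank3)
        return "".join(parts)


@dataclass
class _PlannedVariant:
    vid: str
    cohort: str
    gene: _Gene
    exon_idx: int
    offset: int  # transcript-orientation offset within the exon
    derived_tx: str  # derived base, transcript orientation
    planted_ese_loss: int = 0
    planted_ess_gain: int = 0
    planted_ess_loss: int = 0
    planted_ese_gain: int = 0
    peripheral_planted: bool = False
    ectopic_side: str | None = None
    force_conserved: bool = False


def _codon_of(seq: str, offset: int, phase: int) -> tuple[str, int] | None:
    pos = (offset - phase) % 3
    start = offset - pos
    if start < 0 or start + 3 > len(seq):
        return None
    return seq[start : start + 3], pos


def _is_nonsense(exon_seq: str, phase: int, offset: int, alt: str) -> bool:
    info = _codon_of(exon_seq, offset, phase)
    if info is None:
        return False
    codon, pos = info
    mutant = codon[:pos] + alt + codon[pos + 1 :]
    return mutant in _STOPS


class _Placer:
    """Tracks used offsets per exon so variant windows stay disjoint."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self.used: dict[tuple[str, int], list[int]] = {}

    def free(self, gene: _Gene, exon_idx: int, offset: int) -> bool:
        return all(
            abs(offset - u) >= self.spacing
            for u in self.used.get((gene.gid, exon_idx), [])
        )

    def claim(self, gene: _Gene, exon_idx: int, offset: int) -> None:
        self.used.setdefault((gene.gid, exon_idx), []).append(offset)


def _choose_offset(
    rng: np.random.Generator,
    gene: _Gene,
    exon_idx: int,
    placer: _Placer,
    peripheral: bool | None = None,
    attempts: int = 40,
) -> int | None:
    """An offset with junction distance >= 4, spaced from earlier variants."""
    length = len(gene.exons[exon_idx])
    lo, hi = 3, length - 4  # inclusive; distance-to-edge >= 4 on both sides
    if hi < lo:
        return None
    for _ in range(attempts):
        if peripheral:
            sixth = length // 6
            if rng.random() < 0.5:
                a, b = lo, min(hi, max(lo, sixth - 1))
            else:
                a, b = max(lo, length - sixth), hi
            if b < a:
                a, b = lo, hi
        else:
            a, b = lo, hi
        offset = int(rng.integers(a, b + 1))
        if placer.free(gene, exon_idx, offset):
            return offset
    return None


class _Labeler:
    """Hexamer label registry honouring planted-guarantee exclusions."""

    def __init__(self) -> None:
        self.labels: dict[str, Label] = {}
        self.forbidden: dict[str, set[Label]] = {}

    def can_set(self, kmer: str, label: Label) -> bool:
        if label in self.forbidden.get(kmer, set()):
            return False
        return self.labels.get(kmer, label) is label

    def set(self, kmer: str, label: Label) -> None:
        self.labels[kmer] = label

    def forbid(self, kmer: str, label: Label) -> bool:
        """Forbid a label on a k-mer; False if it already carries it."""
        if self.labels.get(kmer) is label:
            return False
        self.forbidden.setdefault(kmer, set()).add(label)
        return True


def _plant_skipping(
    rng: np.random.Generator,
    labeler: _Labeler,
    exon_seq: str,
    offset: int,
    derived: str,
    n_loss: int,
    n_gain: int,
    loss_label: Label,
    gain_label: Label,
) -> tuple[int, int]:
    """Label wild/derived hexamers around a variant to plant changes.

    Returns the numbers of guaranteed (loss_label loss, gain_label
    gain) windows actually planted after conflict checks.
    """
    derived_seq = exon_seq[:offset] + derived + exon_seq[offset + 1 :]
    starts = list(range(max(0, offset - 5), min(len(exon_seq) - 6, offset) + 1))
    rng.shuffle(starts)
    planted_loss = planted_gain = 0
    for s in starts:
        if planted_loss >= n_loss:
            break
        wild, der = exon_seq[s : s + 6], derived_seq[s : s + 6]
        if labeler.can_set(wild, loss_label) and labeler.forbid(der, loss_label):
            labeler.set(wild, loss_label)
            planted_loss += 1
    for s in starts:
        if planted_gain >= n_gain:
            break
        wild, der = exon_seq[s : s + 6], derived_seq[s : s + 6]
        if labeler.can_set(der, gain_label) and labeler.forbid(wild, gain_label):
            labeler.set(der, gain_label)
            planted_gain += 1
    return planted_loss, planted_gain


# ---------------------------------------------------------------------------
# main generator


def simulate_fixtures(
    out_dir: str | Path,
    seed: int = 7,
    config: FixtureConfig = FixtureConfig(),
) -> FixtureBundle:
    """Generate the full fixture bundle under ``out_dir``."""
    cfg = config
    if cfg.n_genes < 1 or cfg.exons_per_gene < 3:
        raise ValueError("need at least one gene with three exons")
    if cfg.exon_length[0] < 40:
        raise ValueError("exons must be at least 40 bp for ectopic planting")
    if not 0 <= cfg.sav_peripheral_prob <= 1:
        raise ValueError("sav_peripheral_prob must be a probability")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # -- genes in transcript space -----------------------------------------
    genes: list[_Gene] = []
    for g in range(cfg.n_genes):
        strand = "+" if int(rng.integers(0, 2)) == 0 else "-"
        chrom = f"chr{g % cfg.n_chromosomes + 1}"
        exons = [
            _random_seq(rng, int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)))
            for _ in range(cfg.exons_per_gene)
        ]
        introns = [
            "".join(_random_seq(rng, int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))))
            for _ in range(cfg.exons_per_gene - 1)
        ]
        # impose junction consensus: donor at each exon end, acceptor at each start
        for i in range(len(introns)):
            donor = _sample_profile(rng, _DONOR_PROFILE)
            exons[i][-3:] = list(donor[:3])
            acceptor = _sample_profile(rng, _ACCEPTOR_PROFILE)
            introns[i] = donor[3:] + introns[i][9:-22] + acceptor[:20]
            exons[i + 1][:3] = list(acceptor[20:])
        genes.append(
            _Gene(
                gid=f"tx{g:03d}",
                strand=strand,
                chrom=chrom,
                exons=exons,
                introns=introns,
                flank5="".join(_random_seq(rng, cfg.gene_flank)),
                flank3="".join(_random_seq(rng, cfg.gene_flank)),
            )
        )

    internal = [(g, i) for g in genes for i in range(1, cfg.exons_per_gene - 1)]
    placer = _Placer(cfg.min_variant_spacing)
    labeler = _Labeler()
    planned: list[_PlannedVariant] = []

    def host(rng: np.random.Generator) -> tuple[_Gene, int]:
        g, i = internal[int(rng.integers(0, len(internal)))]
        return g, i

    def pick_derived(gene: _Gene, exon_idx: int, offset: int, rng) -> str | None:
        seq = "".join(gene.exons[exon_idx])
        ref = seq[offset]
        alts = [b for b in _BASES if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            if not _is_nonsense(seq, gene.phases[exon_idx], offset, alt):
                return alt
        return None

    # ectopic cohort first: it rewrites exon sequence
    donor_cons = _consensus(_DONOR_PROFILE)
    acceptor_cons = _consensus(_ACCEPTOR_PROFILE)
    for v in range(cfg.n_ectopic):
        for _attempt in range(200):
            gene, ei = host(rng)
            exon = gene.exons[ei]
            length = len(exon)
            side = "5p" if rng.random() < cfg.ectopic_donor_prob else "3p"
            width = DONOR_WIDTH if side == "5p" else ACCEPTOR_WIDTH
            cons = donor_cons if side == "5p" else acceptor_cons
            lo, hi = 3, length - width - 3
            if hi < lo:
                continue
            same_half = rng.random() < cfg.ectopic_same_half_prob
            if side == "5p":
                a, b = (max(lo, length // 2), hi) if same_half else (lo, min(hi, length // 2))
            else:
                a, b = (lo, min(hi, length // 2)) if same_half else (max(lo, length // 2), hi)
            if b < a:
                a, b = lo, hi
            s = int(rng.integers(a, b + 1))
            v_in = int(rng.integers(3, 5)) if side == "5p" else int(rng.integers(18, 20))
            offset = s + v_in
            # claim the whole rewrite region so no later variant or rewrite
            # can touch the engineered window
            claims = sorted({*range(s, s + width, 6), s + width - 1, offset})
            if not all(placer.free(gene, ei, c) for c in claims):
                continue
            derived = cons[v_in]
            wild_base = str(rng.choice([b for b in _BASES if b != derived]))
            new = cons[:v_in] + wild_base + cons[v_in + 1 :]
            trial = list(exon)
            trial[s : s + width] = list(new)
            if _is_nonsense("".join(trial), gene.phases[ei], offset, derived):
                continue
            exon[s : s + width] = list(new)
            for c in claims:
                placer.claim(gene, ei, c)
            pv = _PlannedVariant(
                vid=f"ect{v:04d}",
                cohort="ectopic",
                gene=gene,
                exon_idx=ei,
                offset=offset,
                derived_tx=derived,
                ectopic_side=side,
            )
            if rng.random() < cfg.ectopic_ess_gain_prob:
                _, g = _plant_skipping(
                    rng, labeler, "".join(exon), offset, derived, 0, 1, Label.ESE, Label.ESS
                )
                pv.planted_ess_gain = g
            planned.append(pv)
            break
        else:
            raise RuntimeError("could not place an ectopic variant; enlarge the genome")

    # skipping cohort: ESE-loss / ESS-gain planting near exon edges
    for v in range(cfg.n_skipping):
        for _attempt in range(200):
            gene, ei = host(rng)
            peripheral = bool(rng.random() < cfg.sav_peripheral_prob)
            offset = _choose_offset(rng, gene, ei, placer, peripheral=peripheral)
            if offset is None:
                continue
            derived = pick_derived(gene, ei, offset, rng)
            if derived is None:
                continue
            placer.claim(gene, ei, offset)
            n_loss = int(rng.choice(cfg.sav_ese_loss_choices, p=cfg.sav_ese_loss_probs))
            n_gain = int(rng.choice(cfg.sav_ess_gain_choices, p=cfg.sav_ess_gain_probs))
            loss, gain = _plant_skipping(
                rng, labeler, "".join(gene.exons[ei]), offset, derived,
                n_loss, n_gain, Label.ESE, Label.ESS,
            )
            planned.append(
                _PlannedVariant(
                    vid=f"sav{v:04d}",
                    cohort="skipping",
                    gene=gene,
                    exon_idx=ei,
                    offset=offset,
                    derived_tx=derived,
                    planted_ese_loss=loss,
                    planted_ess_gain=gain,
                    peripheral_planted=peripheral,
                    force_conserved=True,
                )
            )
            break
        else:
            raise RuntimeError("could not place a skipping variant; enlarge the genome")

    # inclusion cohort: mirrored planting (ESS loss / ESE gain)
    for v in range(cfg.n_inclusion):
        for _attempt in range(200):
            gene, ei = host(rng)
            offset = _choose_offset(rng, gene, ei, placer)
            if offset is None:
                continue
            derived = pick_derived(gene, ei, offset, rng)
            if derived is None:
                continue
            placer.claim(gene, ei, offset)
            loss, gain = _plant_skipping(
                rng, labeler, "".join(gene.exons[ei]), offset, derived,
                2, 1, Label.ESS, Label.ESE,
            )
            planned.append(
                _PlannedVariant(
                    vid=f"inc{v:04d}",
                    cohort="inclusion",
                    gene=gene,
                    exon_idx=ei,
                    offset=offset,
                    derived_tx=derived,
                    planted_ess_loss=loss,
                    planted_ese_gain=gain,
                )
            )
            break
        else:
            raise RuntimeError("could not place an inclusion variant")

    # neutral cohorts: no planting
    for cohort, n, prefix in (
        ("control", cfg.n_control, "ctl"),
        ("neutral_verified", cfg.n_neutral_verified, "neu"),
    ):
        for v in range(n):
            for _attempt in range(400):
                gene, ei = host(rng)
                offset = _choose_offset(rng, gene, ei, placer)
                if offset is None:
                    continue
                derived = pick_derived(gene, ei, offset, rng)
                if derived is None:
                    continue
                placer.claim(gene, ei, offset)
                planned.append(
                    _PlannedVariant(
                        vid=f"{prefix}{v:04d}",
                        cohort=cohort,
                        gene=gene,
                        exon_idx=ei,
                        offset=offset,
                        derived_tx=derived,
                    )
                )
                break
            else:
                raise RuntimeError(f"could not place a {cohort} variant; enlarge the genome")

    # -- motif sets ----------------------------------------------------------
    def fill_background(target: int, label: Label) -> None:
        have = sum(1 for l in labeler.labels.values() if l is label)
        guard = 0
        while have < target:
            kmer = "".join(_BASES[i] for i in rng.integers(0, 4, 6))
            guard += 1
            if guard > 500_000:
                raise RuntimeError("motif space exhausted")
            if kmer in labeler.labels or label in labeler.forbidden.get(kmer, set()):
                continue
            labeler.set(kmer, label)
            have += 1

    fill_background(cfg.n_ese, Label.ESE)
    fill_background(cfg.n_ess, Label.ESS)
    ni_like = ESRMotifSet("ni_like", 6, dict(sorted(labeler.labels.items())), "synthetic")

    unlabeled: dict[str, Label] = {}
    while len(unlabeled) < cfg.n_unlabeled:
        kmer = "".join(_BASES[i] for i in rng.integers(0, 4, 6))
        unlabeled[kmer] = Label.UNLABELED_ESR
    ast_like = ESRMotifSet("ast_like", 6, dict(sorted(unlabeled.items())), "synthetic")

    # -- PWMs (SR-protein-binding-site style, arbitrary thresholds) --------
    pwm_list = []
    for name, width in (("SRM1", 7), ("SRM2", 8), ("SRM3", 7), ("SRM4", 6)):
        cons_idx = rng.integers(0, 4, width)
        weights = rng.normal(-0.8, 0.2, size=(4, width))
        for j, ci in enumerate(cons_idx):
            weights[ci, j] = rng.normal(1.0, 0.1)
        best = float(weights.max(axis=0).sum())
        pwm_list.append(PWM(name, np.round(weights, 4), threshold=round(best - 1.5, 4)))
    pwms = PWMSet("sr_pwms", tuple(pwm_list))

    # -- genome assembly ----------------------------------------------------
    chrom_parts: dict[str, list[str]] = {f"chr{i+1}": [] for i in range(cfg.n_chromosomes)}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_parts}
    gene_start: dict[str, int] = {}
    spacer = "".join(_random_seq(rng, cfg.intergenic))
    for gene in genes:
        parts = chrom_parts[gene.chrom]
        parts.append(spacer)
        chrom_len[gene.chrom] += len(spacer)
        tx = gene.tx_seq()
        gseq = tx if gene.strand == "+" else reverse_complement(tx)
        gene_start[gene.gid] = chrom_len[gene.chrom]
        parts.append(gseq)
        chrom_len[gene.chrom] += len(gseq)
    for c in chrom_parts:
        tail = "".join(_random_seq(rng, cfg.intergenic))
        chrom_parts[c].append(tail)
        chrom_len[c] += len(tail)
    chromosomes = {c: "".join(parts) for c, parts in chrom_parts.items()}

    def tx_to_genomic(gene: _Gene, tx_pos: int) -> int:
        """0-based genomic coordinate of a transcript-space position."""
        g0 = gene_start[gene.gid]
        n = len(gene.tx_seq())
        return g0 + tx_pos if gene.strand == "+" else g0 + n - 1 - tx_pos

    def exon_genomic_interval(gene: _Gene, idx: int) -> tuple[int, int]:
        s = gene.exon_tx_start(idx)
        e = s + len(gene.exons[idx])
        a, b = tx_to_genomic(gene, s), tx_to_genomic(gene, e - 1)
        return (a, b + 1) if a <= b else (b, a + 1)

    # -- files ---------------------------------------------------------------
    genome_path = out / "genome.fa"
    with open(genome_path, "w") as fh:
        for c in sorted(chromosomes):
            fh.write(f">{c}\n")
            seq = chromosomes[c]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    bed_path = out / "transcripts.bed"
    with open(bed_path, "w") as fh:
        for gene in genes:
            ivals = sorted(exon_genomic_interval(gene, i) for i in range(len(gene.exons)))
            start, end = ivals[0][0], ivals[-1][1]
            sizes = ",".join(str(b - a) for a, b in ivals)
            starts = ",".join(str(a - start) for a, b in ivals)
            fh.write(
                f"{gene.chrom}\t{start}\t{end}\t{gene.gid}\t0\t{gene.strand}\t{start}\t{end}"
                f"\t0\t{len(ivals)}\t{sizes},\t{starts},\n"
            )

    ni_path = out / "ni_like_motifs.tsv"
    write_motif_set(ni_like, ni_path)
    ast_path = out / "ast_like_motifs.tsv"
    write_motif_set(ast_like, ast_path)
    pwm_path = out / "sr_pwms.tsv"
    write_pwm_set(pwms, pwm_path)

    # splice model trained on this genome's own junction windows
    donor_windows, acceptor_windows = [], []
    for gene in genes:
        for i in range(len(gene.exons) - 1):
            exon, nxt, intron = gene.exons[i], gene.exons[i + 1], gene.introns[i]
            donor_windows.append("".join(exon[-3:]) + intron[:6])
            acceptor_windows.append(intron[-20:] + "".join(nxt[:3]))
    model = PositionWeightSpliceModel.train(donor_windows, acceptor_windows)
    model_path = out / "splice_model.tsv"
    model.to_file(model_path)

    # -- alignments ----------------------------------------------------------
    forced: dict[tuple[str, int], set[int]] = {}
    for pv in planned:
        if pv.force_conserved:
            key = (pv.gene.gid, pv.exon_idx)
            lo = max(0, pv.offset - 5)
            hi = min(len(pv.gene.exons[pv.exon_idx]), pv.offset + 6)
            forced.setdefault(key, set()).update(range(lo, hi))

    maf_path = out / "alignments.maf"
    species = ("hum", "mus", "rat", "caf")
    with open(maf_path, "w") as fh:
        fh.write("##maf version=1 scoring=synthetic\n\n")
        for gene in genes:
            for ei in range(1, len(gene.exons) - 1):
                exon_seq = "".join(gene.exons[ei])
                phase = gene.phases[ei]
                rates = []
                start = phase
                keyed = [None] * len(exon_seq)
                while start + 3 <= len(exon_seq):
                    codon = exon_seq[start : start + 3]
                    for k in range(3):
                        keyed[start + k] = (codon, k + 1)
                    start += 3
                for i, key in enumerate(keyed):
                    if key is None:
                        rates.append(cfg.sub_rate_noncoding)
                    elif key[1] == 3:
                        rates.append(cfg.sub_rate_cpg3 if key[0] in _CPG_CODONS else cfg.sub_rate_pos3)
                    elif key[1] == 1:
                        rates.append(cfg.sub_rate_pos1)
                    else:
                        rates.append(cfg.sub_rate_pos2)
                force = forced.get((gene.gid, ei), set())
                rows_tx = [exon_seq]
                for _sp in species[1:]:
                    row = list(exon_seq)
                    for i, q in enumerate(rates):
                        if i in force:
                            continue
                        if rng.random() < q:
                            row[i] = rng.choice([b for b in _BASES if b != exon_seq[i]])
                    rows_tx.append("".join(row))
                g_start, g_end = exon_genomic_interval(gene, ei)
                if gene.strand == "+":
                    rows = rows_tx
                else:
                    rows = [reverse_complement(r) for r in rows_tx]
                fh.write("a score=0.0\n")
                src_size = chrom_len[gene.chrom]
                for sp, row in zip(species, rows):
                    fh.write(
                        f"s {sp}.{gene.chrom} {g_start} {g_end - g_start} + {src_size} {row}\n"
                    )
                fh.write("\n")

    # -- variant cohorts -----------------------------------------------------
    cohort_paths: dict[str, Path] = {}
    manifest_variants = []
    by_cohort: dict[str, list[_PlannedVariant]] = {}
    for pv in planned:
        by_cohort.setdefault(pv.cohort, []).append(pv)
    for cohort in ("skipping", "neutral_verified", "inclusion", "ectopic", "control"):
        path = out / f"variants_{cohort}.tsv"
        cohort_paths[cohort] = path
        with open(path, "w") as fh:
            fh.write(
                "# synthetic cohort table (generated fixture, not curated data)\n"
                "chrom\tpos\tid\tallele_a\tallele_b\toutgroup1\toutgroup2\n"
            )
            for pv in by_cohort.get(cohort, []):
                gene = pv.gene
                tx_pos = gene.exon_tx_start(pv.exon_idx) + pv.offset
                gpos = tx_to_genomic(gene, tx_pos)  # 0-based
                anc_tx = gene.exons[pv.exon_idx][pv.offset]
                anc = anc_tx if gene.strand == "+" else reverse_complement(anc_tx)
                der = pv.derived_tx if gene.strand == "+" else reverse_complement(pv.derived_tx)
                assert chromosomes[gene.chrom][gpos] == anc
                o1 = o2 = anc
                if cohort == "control":
                    r = rng.random()
                    if r < cfg.p_outgroup_missing:
                        o1 = "N"
                    elif r < cfg.p_outgroup_missing + cfg.p_outgroup_disagree:
                        o2 = rng.choice([b for b in _BASES if b != anc])
                a, b = (anc, der) if rng.random() < 0.5 else (der, anc)
                fh.write(f"{gene.chrom}\t{gpos + 1}\t{pv.vid}\t{a}\t{b}\t{o1}\t{o2}\n")
                manifest_variants.append(
                    {
                        "id": pv.vid,
                        "cohort": cohort,
                        "chrom": gene.chrom,
                        "pos": gpos + 1,
                        "transcript": gene.gid,
                        "exon_index": pv.exon_idx,
                        "strand": gene.strand,
                        "exon_offset": pv.offset,
                        "planted_ese_loss": pv.planted_ese_loss,
                        "planted_ess_gain": pv.planted_ess_gain,
                        "planted_ess_loss": pv.planted_ess_loss,
                        "planted_ese_gain": pv.planted_ese_gain,
                        "peripheral_planted": pv.peripheral_planted,
                        "ectopic_side": pv.ectopic_side,
                        "force_conserved": pv.force_conserved,
                    }
                )

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "n_variants": len(manifest_variants),
        "variants": manifest_variants,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return FixtureBundle(
        root=out,
        genome=genome_path,
        transcripts_bed=bed_path,
        ni_like_motifs=ni_path,
        ast_like_motifs=ast_path,
        pwms=pwm_path,
        splice_model=model_path,
        maf=maf_path,
        cohorts=cohort_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )
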