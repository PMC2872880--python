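# Methods

`savscan` scores exonic single-nucleotide variants for the sequence
and exon-context features that distinguish splice-modulating variants
(exon skipping, increased inclusion, de novo ectopic splice-site
activation) from splicing-neutral polymorphisms. This note describes
the models, the defaults and why they are set where they are, what the
synthetic data generator does and does not emulate, and the numerical
conventions.

## Variant context and inclusion filters

Variants are single-base substitutions with unordered alleles.
Ancestral/derived polarity is assigned only when two outgroup bases
are present, agree with each other, and match one of the two alleles;
everything else is a typed rejection (`MISSING_ALIGNMENT`,
`OUTGROUP_DISAGREE`, `NO_ALLELE_MATCH`), never a guess. All sequence
work is done in transcript orientation (minus-strand exons are
reverse-complemented), with 1-based inclusive coordinates at every
I/O boundary and 0-based half-open intervals internally.

Junction distance counts the exon edge base as distance 1. The cohort
filter keeps variants with distance ≥ 4 on both sides — i.e. it
excludes anything 3 bp or less from a splice junction, where the
variant would act directly on the splice-site consensus rather than on
regulatory elements. Nonsense variants (derived codon is a stop) are
excluded because nonsense-mediated mechanisms confound motif-level
interpretation, and terminal exons are excluded because exon-definition
features assume an internal (spliced-on-both-sides) exon. When a
variant falls in several annotated exons, the largest isoform wins,
with ties broken by lowest transcript identifier so batch runs are
deterministic.

## ESR change profiling

A motif collection is either a set of labelled k-mers (ESE / ESS, or
direction-free "ESR" for collections whose elements were not assigned
a direction) or a set of position weight matrices with per-matrix
site-calling thresholds. Any k-mer absent from a collection is
splicing-neutral — neutral is a biological claim. Windows containing
non-ACGT bases are *unscorable*, a data gap, and are tallied
separately rather than silently called neutral.

For a variant, every k-mer window containing the variant position and
lying fully inside the exon is classified in both alleles (at most k
windows; fewer near a junction — windows are never padded with
intronic sequence, because exonic splicing regulators are exonic by
definition; an intron-padded scan is available behind a flag for
exploration). The ordered pair of states maps to one of nine change
categories: ESE~ESE, Neutral~Neutral, ESS~ESS (same-state
"alterations"), the four single-step gains/losses, and the two direct
conversions (ESE→ESS, ESS→ESE). Direction-free collections use the
reduced 2-state scheme with four categories.

Loss/gain tallies are *inclusive* of direct conversions: an ESE→ESS
window is simultaneously an ESE loss and an ESS gain (and a direct
conversion), and the combined extent of change — the per-variant sum
of ESE losses and ESS gains — counts it twice. This matches the
interpretation in which a direct conversion is the strongest single
indicator of splice disruption: it removes an enhancer *and* installs
a silencer. Overlapping windows are counted independently; a single
substitution routinely modulates several overlapping binding sites at
once, and that multiplicity is exactly the signal the extent statistic
measures. Extent is binned {0, 1, 2, 3, ≥4}.

PWM site changes: a site is *lost* when a window scores at or above
its matrix threshold for the wild-type allele and the corresponding
window drops below threshold for the derived allele; *gained* for the
reverse; *altered* when both alleles score as sites with different
scores. For every lost site the 1-based position of the variant inside
the motif is recorded, supporting per-position loss analyses
(positions within a binding site are not functionally equivalent, and
thresholded calls hide that). Threshold-crossing "alterations" are
recorded but not used as a discriminative feature by default.

## Neutral expectation for category proportions

The null model asks: if single-base substitutions hit hexamers at
random — with realistic base-substitution bias but no selection on
splicing — what fraction of changes falls in each category? The
enumeration mutates every position of all 4^6 = 4,096 hexamers to the
three alternative bases: 4,096 × 6 × 3 = 73,728 permutations (each
mutated hexamer seen from all containing windows is the same set of
triples). Each triple is weighted by the empirical proportion of its
ordered substitution among polarized variants (a 12-entry bias table,
measurable from any polarized cohort with `substitution_bias`), and
category weights are normalized to proportions. Hexamer background
frequencies are uniform — every hexamer counted once — since the
model permutes the hexamer universe, not the genome; a genome-weighted
background would be a different (also defensible) null and can be
built by the caller.

Observed tallies are compared per category with a 2×2
continuity-corrected (Yates) chi-square of category-vs-rest against
the expected proportions scaled to the observed total, plus the
observed/expected ratio; a zero expected proportion with nonzero
observations reports an infinite ratio with an exact binomial
fallback. Observed proportions are normalized per classified window
(the alternative, per-variant normalization, differs only by the
near-constant windows-per-variant factor for mid-exon cohorts).

## Regulatory constraint (RC) scores

Constraint from splicing regulation must be decoupled from
protein-coding constraint. The 192-cell matrix assigns each (codon,
codon-position) cell the score

    score(COD, i) = (1 − Pr_CODi) × 10

where Pr_CODi is the genome-wide proportion of fully conserved
alignment columns for that cell, measured over internal coding exons
in multi-species alignments (reference plus at least two other
species, gap-free columns only). Scores are therefore inversely
proportional to background conservation: positions free to drift
(synonymous sites, and hypermutable CpG third positions most of all)
carry the highest weights, so conservation *there* is evidence of an
overlapping regulatory element. The matrix keeps per-cell observation
counts; a never-observed cell is undefined and using it is an explicit
error, not a silent zero.

The RC score of a window is

    RC = ( Σ_i S_i · δ_ci ) / N

with N the number of columns, S_i ∈ {0,1} full-column conservation,
and δ_ci the matrix weight of the human codon position at column i
(columns outside a complete codon carry weight 0 but still count in
N). Variant windows span 5 bp either side of the variant — 11
columns, covering every hexamer containing the variant — truncated at
the exon boundary. Windows with gaps, fewer than two non-reference
species, or no alignment return typed `UNSCORED` values. For batch
statistics, variants whose 11-bp windows overlap are deduplicated,
keeping the first in coordinate order, so no alignment column is
counted twice.

Exon-level conservation reports the percent of fully conserved
columns overall and restricted to non-synonymous sites, where
"non-synonymous site" means 0-fold degenerate — every possible base
change at the position alters the amino acid. Partially degenerate
positions are excluded from the non-synonymous class because part of
their conservation can be synonymous-capable; this is the
conservative reading of "non-synonymous positions" and is fixed here
as a documented convention.

## Splice-site scoring and the ΔSS metric

Donor (5') sites are scored on 9-base windows (3 exonic + 6 intronic),
acceptors (3') on 23-base windows (20 intronic + 3 exonic). The
scoring backend is pluggable behind a two-method contract
(`score(window, side)`, fixed widths). The shipped backend is a
per-position log2-odds weight model trained from true junction windows
against a background (pseudocount 0.5; uniform background when none is
given), with parameters persisted in a plain-text file; externally
derived per-position models in the same geometry drop in via that
file. The maximum-entropy family of splice-site models is deliberately
not re-derived — the contribution here is the window enumeration and
comparison logic, not the site model.

For a variant, every window placement in which the variant could play
a role is enumerated — sliding 1 bp at a time across the
concatenation of upstream intron, exon, and downstream intron, so
placements that put a putative junction inside the exon are included
(that is what an ectopic site is). At most 9 donor and 23 acceptor
placements exist; clipping at sequence ends only removes placements.
Per side, Δ = max over placements of (score_derived − score_wild), and

    ΔSS = max(Δ5'SS, Δ3'SS).

A side with no scorable placements is an explicit absent value, never
a numeric sentinel. Natural-site scores are read at the annotated
junctions with the *same* backend, and the best derived-allele window
is compared with the natural score of its own side — the site it
would compete with. The assessment records: `ectopic_like`
(ΔSS ≥ threshold, default 1.0), `ectopic_ge_natural`, and whether the
variant lies in the exon half adjacent to the natural site of the
created type (true ectopic variants cluster in that half; computational
lookalikes show the opposite pattern). Ectopic-like control selection
filters a scored cohort at the ΔSS threshold, ranks by the best
derived-allele site score, and takes the top n with coordinate
tie-breaks; a hook accepts a precomputed exclusion list for variants
with transcript evidence of real splice-site use.

**Backend limitation.** With a first-order (additive) weight model,
any substitution that creates the invariant G/T of a donor GT or A/G
of an acceptor AG in *some* placement gains a large score step, so the
fraction of variants with ΔSS ≥ 1 saturates near 100% in every
cohort; joint (maximum-entropy-style) models mute single-base effects
in otherwise poor windows and keep that fraction low. The
threshold-based flag is therefore mainly useful with a user-supplied
joint backend; with the shipped linear backend the discriminating
statistics are the best ectopic site score and the
ectopic-versus-natural comparison, which separate cohorts sharply.
Acceptance reporting uses those.

## Exon-definition features

* **ESR density**: per label, (windows scoring as that label) / (L − k + 1)
  windows across the exon; windows never cross the exon boundary.
  PWM densities are computed per matrix (widths differ) and summed
  into one overall density.
* **Intron flank density**: the same windowing on the 100 intronic
  bases flanking each junction, excluding the 2-base GT/AG
  dinucleotides (intronic positions 3–102); exons with a flanking
  intron under 102 bp are excluded rather than measured on a shorter
  flank.
* **Six-section position**: section = ⌊6·offset/length⌋ + 1, clamped
  to 6, on half-open bins; "peripheral" = sections 1 and 6. Exact
  mirror symmetry holds when 6 divides the exon length; otherwise the
  floor rule decides boundary bases (documented tie rule).
* **Junction occupancy profile**: across a qualifying exon cohort
  (length ≥ 100 bp, both flanking introns ≥ 200 bp so profiles do not
  pick up neighbouring exons), the fraction of exons whose k-mer
  starting at each position is an ESE or an ESS, positions spanning
  100 intronic and 50 exonic bases per junction. The k-mer slides
  continuously (junction-crossing k-mers included) because the
  profile's x-axis is a continuous first-base coordinate.
* **Splice-site strengths**: natural-site scores of each exon via the
  splice backend, with junction dinucleotides reported so a
  canonical-GT/AG-only filter can flag non-canonical cases rather
  than silently dropping them. Exon-level cohorts keep lengths
  between 20 and 1,000 bp.
* **Exon-length model**: fr(n) = p_SNP × obs(n) with p_SNP = 0.001
  per base and obs(n) the exon-length histogram. The printed formula
  lacks the length factor required for longer exons to be likelier to
  carry a variant; the per-base placement model
  fr(n) = p_SNP × n × obs(n) is available as `length_weighted=True`
  and is the mode validated against a placement oracle. Both are kept
  because the literal formula is the published one; the discrepancy is
  documented here rather than silently resolved.

## Cohort statistics

Cohorts are compared by stratified bootstrap: each iteration draws,
without replacement, a control subset matching the test set's stratum
counts exactly (strata are caller-chosen — consequence class,
junction-distance bins {4–10, 11–25, 26–50, >50}, or any labels), and
computes the statistic ("mean", "proportion", or "sum"). Exon-level
features deduplicate both cohorts to unique exons first, since several
variants can share an exon. The observed statistic is reported with
Z = (x − μ)/σ against the null distribution when a Shapiro–Wilk gate
passes (P > 0.05, on a subsample capped at 5,000 values — the test
degenerates at very large n), otherwise with the add-one empirical
P-value (1 + tail count)/(1 + iterations), which cannot be zero.
Two-sided by default; one-sided by flag. Identical seed and inputs
give bit-identical results. Significance uses a stringent α = 0.01
(strict inequality) in lieu of formal multiple-testing correction
across the feature battery. Auxiliary tests: Yates-corrected 2×2
chi-square (zero margins are errors) and the two-sample
Kolmogorov–Smirnov test.

Default iteration counts: 10^5 for real analyses (the CLI default);
the test suite and acceptance script use 10^3–10^4 because the
vectorized sampler makes the null mean/SD estimates stable well below
10^5 at toy problem sizes. Calibration is verified on null data
(test sets resampled from the control pool): over 2,000 simulated
comparisons at 10^3 iterations the type-I error rate at α = 0.01 must
lie within [α/2, 2α].

## The synthetic data generator

Everything the framework consumes is generated from one seed at toy
scale: a two-chromosome genome of 60 five-exon genes (exons 90–180 bp,
introns 250–400 bp, both strands) with consensus GT/AG junctions
sampled from donor/acceptor profiles; BED12 models; a labelled hexamer
collection (979 ESE / 496 ESS, the size of the largest published
neighborhood-inference collection) plus a 285-hexamer direction-free
set; four SR-protein-style PWMs with thresholds; four-species MAF
alignments; a splice model trained on the genome's own junctions; and
five variant cohorts whose sizes are the study conditions — 87
skipping, 80 verified-neutral, 20 inclusion, 54 ectopic — plus 1,000
common-variant controls (a scaled stand-in for a genome-wide SNP set,
sized to keep per-exon variant density realistic on the toy genome).

Planted structure: skipping variants sit near exon edges with
probability 0.7 and destroy 1–3 overlapping ESE hexamers while
creating 0–2 ESS hexamers (labels are assigned to the hexamers the
variant actually touches, with conflict- and guarantee-tracking so a
planted loss cannot be silently undone by later label assignments);
inclusion variants get the mirrored planting; ectopic variants have a
donor (70%) or acceptor consensus written into the exon with the
variant restoring its invariant dinucleotide, placed in the
natural-site-proximal half with probability 0.75. Alignment columns
substitute per species at codon-position-dependent rates (third
positions fastest, CpG third positions 0.45 per species) except the
11-bp windows around skipping variants, which are forced conserved —
giving the matrix its CpG-topped score structure and the skipping
cohort its elevated RC. Control outgroup bases carry small missing /
disagreeing fractions (1% each) to exercise the polarization
rejections.

What the generator does *not* emulate: real ESR motif semantics
(labels are planted or random, not biochemical), phylogeny
(substitutions are i.i.d. per species, no tree), codon usage and
composition biases of real coding sequence, linkage between variants,
length/GC correlations of real exons, and genuine splice-site
nonlinearity. Green tests therefore demonstrate that the machinery is
correct (oracle equivalence), deterministic, statistically calibrated,
and able to recover planted effect structure — not that the features
would achieve any particular accuracy on real human cohorts.

## Problem sizes and reproduction

The test suite and `scripts/acceptance.py` run the full pipeline on
the default bundle (1,241 variants across ~180 internal exons),
10^3–10^4-iteration bootstraps, and a 2,000-comparison calibration;
the whole acceptance script completes in well under a minute on one
CPU. For a full-scale reproduction with real data, supply: a genome
FASTA and exon models (BED12/GFF3), the published ESR collections
converted to the motif format in `docs/formats.md` (they are not
redistributed here), genuine multiple alignments as MAF, a
maximum-entropy-style splice model in the parameter-file format, the
polarized common-SNP cohort, and a substitution-bias table measured
from it — then run the same CLI subcommands; every analysis step is
dataset-agnostic.

## Known limitations

* First-order splice backend: see the ΔSS saturation note above.
* The neutral model is context-free (no CpG-aware substitution
  classes); the bias table captures marginal substitution skew only.
* GFF3 input uses `CDS` features and their phases; exotic gene models
  (trans-splicing, selenoproteins) are out of scope, as are indels and
  multi-nucleotide variants.
* RNA secondary-structure accessibility of motif changes is out of
  scope by design.
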