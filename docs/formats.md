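# File formats

All resource files are line-oriented UTF-8 text. `#` starts a comment
line; blank lines are ignored. Published motif collections can be
converted to these dialects with a few lines of shell.

## Motif set (k-mer) files

One motif per line, with an optional tab-separated label. Files
without per-line labels need a `default_label` at load time.

```
motif-file   ::= line*
line         ::= comment | motif-line
comment      ::= "#" <any text>
motif-line   ::= KMER ( TAB LABEL )?
KMER         ::= [ACGTacgt]{k}          ; k fixed per file (6 or 8 typically)
LABEL        ::= "ESE" | "ESS" | "UNLABELED_ESR"
```

Rules: duplicate identical lines collapse; the same k-mer with two
different labels is an error; `UNLABELED_ESR` may not be mixed with
directional labels in one set (direction-free collections such as
dicodon-derived ESR sets are a separate two-state universe).

## PWM set files

Each matrix is a header followed by exactly four weight rows in
A, C, G, T order. A window of width L scores as the sum over columns
of the weight of its base, and calls a site when score ≥ threshold.

```
pwm-file     ::= matrix+
matrix       ::= header row-A row-C row-G row-T
header       ::= ">" NAME WS "threshold=" FLOAT
row-A        ::= "A:" ( WS FLOAT ){L}
row-C        ::= "C:" ( WS FLOAT ){L}
row-G        ::= "G:" ( WS FLOAT ){L}
row-T        ::= "T:" ( WS FLOAT ){L}
```

Thresholds live in the file, not in code: site-calling cutoffs for
experimentally derived binding-site matrices are a tunable analysis
choice and must stay user-visible.

## Splice-site model files

Per-position weight parameters for the 9-base donor and 23-base
acceptor windows, written/read by `PositionWeightSpliceModel`:

```
model-file   ::= donor-section acceptor-section
donor-section    ::= ">DONOR"    row-A row-C row-G row-T      ; L = 9
acceptor-section ::= ">ACCEPTOR" row-A row-C row-G row-T      ; L = 23
```

A window's score is the column-sum of its base weights. Models
trained elsewhere (any per-position log-odds table over the same
window geometry) can be supplied in this format.

## Variant tables

Tab-separated with a header; required columns `chrom`, `pos` (1-based),
`allele_a`, `allele_b` (single ACGT bases, unordered); optional `id`,
`outgroup1`, `outgroup2` (outgroup bases for ancestral/derived
polarization; `N`, `-`, `.` or empty mean missing). Extra columns pass
through. VCF input is also accepted (SNV records only; outgroup bases
in INFO keys `OUT1`/`OUT2`).

## Other formats

* Genome: FASTA (indexed access via pyfaidx).
* Exon models: BED12 (blocks = coding exons; frame accumulated across
  blocks from phase 0) or GFF3 (`CDS` features grouped by `Parent`).
* Alignments: MAF, reference species anchored on the + strand, `src`
  fields as `species.chrom`.
* Substitution-bias tables: TSV with columns `substitution` (e.g.
  `A>T`) and `proportion`; the 12 ordered proportions must sum to 1.
* Constraint matrices: TSV with columns `codon`, `position`,
  `observed`, `conserved`, `pr_conserved`, `score` (192 rows).
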