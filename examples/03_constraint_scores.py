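"""Regulatory-constraint scoring on generated alignments.

Generates the synthetic bundle, builds the 192-cell codon-position
constraint matrix from its four-species exon alignments, and scores
the regulatory constraint (RC) of windows around variants.
"""

import tempfile

import pyfaidx

from savscan import (
    MafIndex,
    build_codon_matrix,
    build_contexts,
    read_bed12,
    read_variant_table,
    simulate_fixtures,
    variant_rc,
)
from savscan.pipeline import ScoreConfig

bundle = simulate_fixtures(tempfile.mkdtemp(), seed=7)
genome = pyfaidx.Fasta(str(bundle.genome))
exons = read_bed12(bundle.transcripts_bed)
maf = MafIndex(bundle.maf, "hum")
matrix = build_codon_matrix(maf, [e for e in exons if e.is_internal])

print("matrix corner (codon, position -> weight = (1 - Pr_conserved) x 10):")
for codon in ("ACG", "AAA"):
    for pos in (1, 2, 3):
        print(f"  {codon} pos{pos}: {matrix.score(codon, pos):5.2f}")

for cohort in ("skipping", "control"):
    table = read_variant_table(bundle.cohorts[cohort])
    ctxs, _ = build_contexts(table, genome, exons, ScoreConfig(batch_cap=None))
    scores = [r.score for r in (variant_rc(matrix, maf, c) for c in ctxs) if r.scored]
    print(f"{cohort:9s} mean RC over 11-bp variant windows: "
          f"{sum(scores) / len(scores):.3f}  (n={len(scores)})")
print()
print("Weights are highest where genome-wide coding sequence is least")
print("conserved (CpG third positions), so a high RC means conservation")
print("exactly where sequence is normally free to drift - the signature of")
print("an overlapping splicing-regulatory element. The skipping cohort sits")
print("in such windows by construction; the control cohort does not.")
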