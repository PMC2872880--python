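"""Scoring de novo (ectopic) splice-site creation with the deltaSS metric.

Trains the splice-site backend on generated junctions, then slides
every donor/acceptor window over an ectopic variant and a neutral
control, comparing the best variant-created site to the exon's
natural site.
"""

import tempfile

import pyfaidx

from savscan import (
    PositionWeightSpliceModel,
    build_contexts,
    delta_ss,
    ectopic_assessment,
    read_bed12,
    read_variant_table,
    simulate_fixtures,
)
from savscan.pipeline import ScoreConfig

bundle = simulate_fixtures(tempfile.mkdtemp(), seed=7)
genome = pyfaidx.Fasta(str(bundle.genome))
exons = read_bed12(bundle.transcripts_bed)
model = PositionWeightSpliceModel.from_file(bundle.splice_model)

for cohort in ("ectopic", "control"):
    table = read_variant_table(bundle.cohorts[cohort]).head(40)
    ctxs, _ = build_contexts(table, genome, exons, ScoreConfig(batch_cap=None))
    stronger = 0
    best_scores = []
    for ctx in ctxs:
        res = delta_ss(model, ctx)
        assess = ectopic_assessment(res, ctx)
        stronger += bool(assess.ectopic_ge_natural)
        if assess.best_ectopic_score is not None:
            best_scores.append(assess.best_ectopic_score)
    print(f"{cohort:8s}: best created-site score mean "
          f"{sum(best_scores) / len(best_scores):6.2f}; "
          f"{stronger}/{len(ctxs)} create a site >= the natural site")

ctx = build_contexts(
    read_variant_table(bundle.cohorts["ectopic"]).head(1),
    genome, exons, ScoreConfig(batch_cap=None),
)[0][0]
res = delta_ss(model, ctx)
assess = ectopic_assessment(res, ctx)
print(f"\nfirst ectopic variant: delta5'SS={res.donor.delta:.2f}  "
      f"delta3'SS={res.acceptor.delta:.2f}  deltaSS={res.delta_ss:.2f}")
print(f"best created site: side {assess.side}, score {assess.best_ectopic_score:.2f} "
      f"vs natural {assess.natural_score_same_side:.2f} on that side")
print()
print("A variant whose derived allele completes a splice-site consensus")
print("inside the exon produces a large positive deltaSS and a created site")
print("rivalling the natural one - the defining pattern of ectopic variants,")
print("essentially absent from neutral controls.")
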