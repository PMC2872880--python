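"""Classify the ESR changes a single exonic variant induces.

Builds a tiny enhancer/silencer hexamer collection, a variant context,
and prints the per-window change categories and the combined extent of
change (ESE losses + ESS gains, the headline exon-skipping indicator).
"""

from savscan import ESRMotifSet, change_profile, extent_bin, variant_windows
from savscan.motifs import Label

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _context import toy_context

# a variant destroying overlapping enhancers and creating a silencer
ctx = toy_context(
    exon_seq="TTCAGGAAGAAGATCCATGGTCA",  # GAAGAA enhancer around the middle
    offset=11,
    derived="T",  # GAAGAA -> GATGAA family of changes
)
motifs = ESRMotifSet(
    "toy",
    6,
    {
        "AAGAAG": Label.ESE,
        "AGAAGA": Label.ESE,
        "GAAGAT": Label.ESE,
        "GAATAT": Label.ESS,  # the derived form of GAAGAT: a direct conversion
    },
)

print("windows overlapping the variant (wild -> derived, variant position):")
for wild, derived, pos in variant_windows(ctx, 6):
    print(f"  {wild} -> {derived}  (position {pos} in the hexamer)")

counts = change_profile(ctx, [motifs]).per_set["toy"]
print(f"ESE losses:        {counts.ese_loss}")
print(f"ESS gains:         {counts.ess_gain}")
print(f"direct ESE->ESS:   {counts.ese_to_ess}")
print(f"combined extent:   {counts.combined_extent}  "
      f"(bin {extent_bin(change_profile(ctx, [motifs]), 'toy')})")
print()
print("Each overlapping hexamer is classified in both alleles; losses of")
print("enhancers plus gains of silencers, especially >= 4 of them or a")
print("direct conversion, mark a variant as likely to cause exon skipping.")
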