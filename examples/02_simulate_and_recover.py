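"""Recover planted co-deletions from a two-lineage synthetic panel.

Simulates 60 samples on a 5-chromosome toy genome: half carry co-occurring
losses at two loci (lineage T), half at three other loci (lineage B) —
emulating lineage-specific V(D)J deletions at T-cell receptor and
immunoglobulin loci.  Runs the full loss-loss analysis at the 2 Mb scale
and prints the ranked peak list; the top-ranked pairs should be the planted
within-lineage locus pairs (lesions centered at 10 Mb on every arm), while
cross-lineage pairs are mutually exclusive and score at or below zero.
"""

from cooccur.pipeline import two_lineage_recovery

result = two_lineage_recovery(seed=1)

print("rank  score   locus A          locus B")
for p in result["ranked"].peaks[:6]:
    print(
        f"{p.rank:>4}  {p.score:6.2f}  chr{p.chrom_a}:{p.pos_a / 1e6:5.1f} Mb"
        f"     chr{p.chrom_b}:{p.pos_b / 1e6:5.1f} Mb"
    )

print(f"\nplanted within-lineage pairs: {len(result['planted'])}")
print(f"top-2 peaks match two distinct planted pairs: {result['success']}")
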