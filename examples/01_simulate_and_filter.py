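"""Simulate a hybridogenetic cohort and apply the hard genotype filters.

The cohort mirrors a mixed water-frog population: 11 P. lessonae (L),
12 P. ridibundus (R), 13 diploid hybrids, 8 LLR and 1 LRR triploid.
"""

from hybridotype import SimConfig, filter_chain, simulate_cohort, thin_one_per_marker

table, labels, truth = simulate_cohort(SimConfig(seed=1, n_markers=400))

log = []
filtered = filter_chain(table, maf_min=0.1, dp_min=10, gq_min=20, log=log)
thinned = thin_one_per_marker(filtered)

print(f"simulated records:          {len(table)} over {table.n_samples} samples")
print(f"pass all hard filters:      {len(filtered)}")
print(f"after one-SNP-per-marker:   {len(thinned)}")
reasons = {}
for _, _, r in log:
    reasons[r] = reasons.get(r, 0) + 1
print(f"removal reasons:            {reasons}")
# Each surviving record is a biallelic SNP called in every individual with
# depth >= 10 and GQ >= 20, and minor allele frequency >= 0.1 — the input
# expected by every downstream analysis.
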