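"""Minimum regeneration sample sizes from rare-allele frequencies.

For each accession, the rarest nonzero minor-allele frequency determines
the smallest sample retaining both alleles at 95% confidence (Crossa's
retention probability).  The curve shows the sharp growth in required
sample size once allele frequencies drop below 0.1.
"""

import genebankdiv as gd

cfg = gd.sorghum_like(n_accessions=5, n_loci=800, n_chromosomes=4, seed=4)
g, _ = gd.simulate_collection(cfg)

res = gd.accession_sample_sizes(g, confidence=0.95)
print(res.table[["p_min", "n_min", "n_diploid", "n_rare_alleles"]])

curve = gd.sample_size_curve([0.5, 0.2, 0.1, 0.05, 1 / 30, 0.01])
print("\nretention curve (p -> gametes needed):")
for _, row in curve.iterrows():
    print(f"  p = {row['p']:.3f} -> n = {int(row['n_min'])}")
print("\nFAO benchmark: retaining a 0.05-frequency allele needs",
      gd.min_diploid_individuals(0.05, 0.95), "random-mating diploid plants")
# 'n_min' is on the gamete ('seed') scale; 'n_diploid' is ceil(n/2).
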