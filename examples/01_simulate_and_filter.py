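"""Simulate a small landrace collection and apply the quality filters.

Builds a sorghum-like collection (low outcrossing, 15 plants per
accession), injects missing calls, then filters markers by reproducibility
and call rate and samples by missingness — printing the bookkeeping a
curator would check before any analysis.
"""

import genebankdiv as gd

cfg = gd.sorghum_like(n_accessions=6, n_loci=1000, n_chromosomes=4,
                      missing_rate=0.08, seed=1)
g, truth = gd.simulate_collection(cfg)
print(f"simulated {g.n_individuals} plants x {g.n_loci} SNPs "
      f"in {len(g.accession_names)} accessions")

g_f, marker_report = gd.filter_markers(g)          # >=95% reproducibility, >=80% call rate
g_f, sample_report = gd.filter_samples(g_f)        # <=50% missing per plant
print(f"markers kept: {marker_report.n_loci_out}/{marker_report.n_loci_in} "
      f"(dropped by call rate: {marker_report.dropped_by['call_rate']})")
print(f"plants kept:  {sample_report.n_individuals_out}/{sample_report.n_individuals_in}")

dens = gd.snp_density(g_f, window_bp=10_000_000)
print("SNPs per chromosome:", dens["per_chromosome"])
# No MAF filter is ever applied: rare alleles are the object of study.
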