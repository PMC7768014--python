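# genebankdiv

Diversity analysis for genebank accession collections genotyped and
phenotyped at the individual-plant level, with regeneration sample-size
estimation.

Genebanks conserve landraces — farmer-maintained, genetically heterogeneous
crop populations — as *accessions* of seed. Maintaining an accession's
genetic integrity across regeneration cycles requires knowing how much
variation lives **within** each accession versus **among** accessions
(driven largely by the crop's outcrossing rate), and how many plants must
be grown to avoid losing rare alleles to genetic drift. `genebankdiv`
implements that analysis for biallelic SNP matrices (VCF or DArT-style
0/1/2 CSV) and mixed quantitative/qualitative phenotype tables:

- **Quality filtering** by marker reproducibility (≥ 0.95), call rate
  (≥ 0.80) and per-plant missingness (≤ 0.50) — deliberately with **no**
  minor-allele-frequency filter, since rare variants are the object of
  study.
- **Distances**: modified Rogers distance between plants
  `d(i,j) = sqrt((1/m) Σ_l (p_il − p_jl)²)` with `p = dosage/2`, and Gower
  dissimilarity for mixed phenotypes; within/between-accession summaries
  and a density-overlap coefficient.
- **Diversity**: observed heterozygosity, Nei gene diversity
  `1 − p² − q²`, Shannon `H′ = −Σ p_a log₂ p_a` (two aggregation modes),
  rare-allele inventories (MAF ∈ (0, 0.05]).
- **AMOVA**: three-level decomposition (among accessions / among plants
  within / within plants) on pseudo-gamete squared distances, with Phi
  statistics and seeded permutation p-values (default 99 permutations).
- **Clustering**: ward.D2 agglomeration, accession × cluster membership
  tables, bootstrap Jaccard stability, and Mantel correlation between
  phenotypic and genotypic distance matrices.
- **Sample sizes**: from Crossa's retention probability
  `P(n) = 1 − (1−p₁)ⁿ − (1−p₂)ⁿ`, the smallest n with `P(n) ≥ 0.95` at
  each accession's rarest allele frequency.
- **Simulation**: a mixed-mating generator (Balding–Nichols founder
  differentiation, selfing rate `s = 1 − t`, drift over G generations)
  that produces collections with the structure the analyses assume, for
  validation and power studies.

## Worked example

```python
import genebankdiv as gd

cfg = gd.sorghum_like(n_accessions=5, n_loci=800, n_chromosomes=4, seed=4)
g, _ = gd.simulate_collection(cfg)
res = gd.accession_sample_sizes(g, confidence=0.95)
print(res.table[["p_min", "n_min", "n_diploid", "n_rare_alleles"]])
```

prints (from `examples/04_regeneration_sample_size.py`):

```
              p_min  n_min  n_diploid  n_rare_alleles
accession
ACC001     0.033333     89         45              26
ACC002     0.033333     89         45              30
ACC003     0.033333     89         45              27
ACC004     0.033333     89         45              31
ACC005     0.033333     89         45              28
```

Each 15-plant accession's rarest variant is a single allele copy among 30
called gametes (`p_min = 1/30`), so retaining it with 95% confidence needs
`n_min = 89` seeds (gametes), i.e. 45 diploid plants; 26–31 loci per
accession carry rare alleles (MAF ≤ 0.05) that would be at risk under a
smaller regeneration sample. The classical benchmark falls out of the same
formula: an allele at frequency 0.05 needs 59 gametes, i.e. **30**
random-mating diploid individuals.

The other scripts in `examples/` walk through filtering, distance
summaries, AMOVA + Mantel, and cluster stability; each prints the numbers
it computes and a line on how to read them.

## Command line

A thin CLI wraps the pipeline for shell use:

```bash
genebankdiv all --config run.yaml --seed 1 --out results/
```

with subcommands `simulate`, `filter`, `dist`, `diversity`, `amova`,
`cluster`, `mantel`, `samplesize`, `report`, `all`. The YAML config holds
either input paths (`genotype_path`, `accession_map_path`, optional
`phenotype_path` + `trait_spec`) or a `simulate:` block, plus thresholds
and permutation counts. Every run writes its tables and a
`manifest.json` with SHA-256 checksums; identical configs and seeds give
identical checksums.

## Data formats

- **VCF** v4.x with GT calls, biallelic records (multi-allelic records are
  rejected or dropped per option).
- **dart_csv**: one row per locus with columns `locus_id`, `chromosome`,
  `position`, optional `reproducibility`/`call_rate`, then one 0/1/2
  column per plant (`-` = missing); accessions come from a two-column
  `individual_id,accession_id` CSV. The two-row presence/absence DArT
  dialect is out of scope.
- **Phenotypes**: CSV with `individual_id`, `accession`, then trait
  columns, each declared quantitative or qualitative in a trait spec.

See `docs/methods.md` for the statistical models, defaults and known
limitations.
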