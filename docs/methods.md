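# Methods

This note records the statistical models implemented in `genebankdiv`,
the defaults and why they were chosen, the numerical conventions, and the
known limits of what the synthetic-data tests demonstrate.

## Data model and filtering

Genotypes are alternate-allele dosages 0/1/2 with a dedicated missing
sentinel (−1); a missing call is never conflated with a reference
homozygote, and all downstream statistics are complete-case per locus,
pair or accession. Positions are 1-based; SNP-density windows bin
positions by `pos // window_bp` (half-open windows); strand is ignored
because dosage coding is strand-free.

Marker filters keep loci with reproducibility ≥ 0.95 and observed call
rate ≥ 0.80 (inclusive keep at the boundary — the conventional reading
when a threshold is quoted without boundary semantics). Loci lacking a
reproducibility field pass that criterion by default (a strict mode drops
them), so simulated data, which carries no assay-reproducibility notion,
is unaffected. Plants are removed when their missing fraction strictly
exceeds 0.50, so a plant at exactly 50% survives. Marker filtering runs
before sample filtering by default; the order is configurable because
either convention is defensible and the composition is idempotent at
fixed thresholds. No minor-allele-frequency filter exists anywhere: the
rare variants a MAF filter would delete are precisely what the
regeneration analysis must see.

## Distances

**Modified Rogers distance.** For plants i, j and the m_ij loci called in
both, `d = sqrt((1/m_ij) Σ_l (p_il − p_jl)²)` with `p = dosage/2`; this
equals the Euclidean allele-frequency form scaled by `1/sqrt(2m)` and is
bounded in [0, 1]. Missing data are handled by pairwise-complete loci
with per-pair renormalisation — no imputation, at the cost of slightly
different effective marker sets per pair. Pairs sharing no called locus
are undefined and flagged, never silently zero.

**Gower.** Quantitative traits contribute `|x_i − x_j| / range`, with the
range taken over the full table once (Gower's original definition, and
the reason bootstrap replicates reuse the full-table ranges); qualitative
traits contribute 0/1 mismatch; the average runs over traits observed in
both plants. Zero-range traits are skipped with a logged warning rather
than dividing by zero.

**Summaries.** Per accession, "within" averages the unordered pairs
inside the accession and "between" averages all member–outsider pairs
(the direct reading; the alternative "mean of per-accession means" is
deliberately not the default). Singleton accessions have undefined
within-means. The within/between density overlap is
`Σ_bins min(f_w, f_b) · binwidth` on a fixed 50-bin grid over [0, 1];
0 means cleanly separated distance distributions, 1 means merged.

## Diversity statistics

Observed heterozygosity is the fraction of called genotypes equal to 1,
averaged over loci; Nei gene diversity is the mean over loci of
`1 − p² − q²` from within-accession frequencies computed on called
gametes (2 × called plants), with the unbiased `2n/(2n−1)` correction
available behind a flag (default off). Shannon `H′` uses base 2 and two
modes, because aggregating a per-biallelic-locus entropy (capped at 1
bit) into a per-accession scalar is ambiguous: `allele_mean` averages the
per-locus allele entropy over loci with defined frequencies, and
`multilocus_genotype` takes the entropy of the distinct multilocus
genotype strings among the accession's plants (capped at log₂ n). The
mode is recorded in every output; no claim is made that either mode
reproduces any particular published per-accession H′ scale. Rare alleles
are loci with within-accession MAF in (0, 0.05]; monomorphic and
undefined-frequency loci are excluded (the latter counted separately).

## AMOVA

Each diploid plant expands to two pseudo-gametes per locus (heterozygote
= one reference + one alternate allele); phase is irrelevant because the
squared-difference metric is per-locus additive. The nested sums of
squares are computed as deviations of gametes from individual, population
and grand means (equivalently, from the pairwise identity
`SS_group = (1/n_g) Σ_{a<b∈g} d²_ab`, which the tests use as an
independent oracle). Degrees of freedom are `k − 1` / `N − k` / `N`.
Components solve the expected mean squares with the unbalanced-design
coefficient `n_c = (M − Σ m_p²/M)/(k − 1)` on the gamete counts `m_p`.
A missing call contributes the within-accession mean allele frequency to
both pseudo-gametes (mean substitution, logged); at the 80% call-rate
threshold the induced bias is small, and the substitution keeps the
balanced two-gametes-per-individual algebra exact.

Negative components are reported as-is with a flag (truncation would
silently bias the percentages); when the component total is ≤ 0 or the
total SS is 0 the result is flagged degenerate and percentages are NaN.
Phi indices are `Phi_ST = σ²_a/σ²_T`, `Phi_IS = σ²_b/(σ²_b + σ²_w)`,
`Phi_IT = (σ²_a + σ²_b)/σ²_T`; the table's rows carry them in the
conventional AMOVA layout (among-populations row: Phi_IT;
among-individuals row: Phi_IS; within-individuals row: Phi_ST).

Permutation p-values (default 99 permutations, per the genebank
convention for these tables) use
`p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm)` with level-specific
schemes: whole plants permuted among accessions (statistic σ²_a) for the
among-accession level; gametes permuted among plants within accessions
(statistic σ²_b) for the among-plants level; and gametes permuted among
plants across accessions with statistic Phi_IT for the within-plants row
— the Arlequin-style convention, adopted because no alternative is
specified for that level.

## Clustering, stability, Mantel

Ward clustering uses `scipy.cluster.hierarchy.linkage(method="ward")` on
the precomputed distance matrix, which is the Murtagh–Legendre ward.D2
variant: the Lance–Williams recurrence on squared dissimilarities with
heights reported on the distance scale. Exact merge ties are resolved by
scipy's deterministic nearest-neighbor-chain order. The default cut is
k = number of accessions, under the working hypothesis that each uniform
accession forms one cluster; the membership table (rows summing to 100%)
and the pure-singleton count quantify departures.

Bootstrap stability resamples plants with replacement, re-clusters the
unique retained plants on the corresponding sub-distance-matrix (for MRD
this is exactly recomputation; for Gower the full-table ranges are
retained by design), and scores each original cluster by its best-match
Jaccard coefficient on the retained plants, averaged over B replicates
(default 100). Mean Jaccard > 0.70 flags a cluster stable. Means over
replicates are reported, and multiscale-bootstrap AU p-values are out of
scope.

The Mantel statistic is the Pearson correlation over the n(n−1)/2 pairs;
the one-sided p-value permutes rows and columns of one matrix
simultaneously. Matrices whose pair values have (numerically) zero
variance yield an undefined r, returned as NaN with a warning.

## Retention probability and sample size

For the rarest biallelic locus with allele frequencies p₁ and p₂ = 1 − p₁,
the probability that n sampled gametes contain at least one copy of each
allele is `P(n) = 1 − (1−p₁)ⁿ − (1−p₂)ⁿ` (inclusion–exclusion; P(1) = 0,
and for extreme p₁ with tiny n the formula can be slightly negative,
which is reported verbatim rather than clamped). `n_min` is the smallest
integer with `P(n) ≥ confidence` (default 0.95), found from the
closed-form seed `ln(1−c)/ln(1−p)` and verified by exact integer scan.

n is reported on the gamete scale ("seeds", the convention of
per-accession sample-size tables), with a diploid view `ceil(n/2)`
alongside for comparison with individual-count standards: at p = 0.05 the
gamete scan gives 59, i.e. 30 random-mating diploid plants. p_min folds
frequencies to the minor allele (≤ 0.5) and ignores monomorphic and
undefined loci; fully monomorphic accessions are flagged with no n_min.
Only the single-rarest-locus criterion is computed; a multi-locus joint
retention probability is a different (stricter) quantity and is out of
scope.

## Synthetic collections

The generator produces the structure the analyses assume, with defaults
chosen as a realistic study scale: 36 accessions × 15 plants, 5,000
biallelic loci over 10 chromosomes of 60 Mb, ancestral allele frequencies
Uniform(0.05, 0.95), founder differentiation F_ST = 0.30 via
Balding–Nichols beta draws, outcrossing rate t = 0.18 (sorghum-like;
presets supply t = 0.30 pigeonpea-like with 15 plants and t = 0.85
pearl-millet-like with 25 plants), 30 non-overlapping generations of
mixed mating at effective size N_e = 100, and 5% missing calls. Each
offspring arises by selfing with probability s = 1 − t (two independent
gametes of one parent) or from two parents drawn with replacement, so
random selfing at rate 1/N_e is included in the outcrossing fraction
(Wright's mixed-mating convention). The equilibrium inbreeding
coefficient `F* = s/(2 − s)` — the fixed point of `F′ = s(1 + F)/2` —
serves as the simulator's oracle; realized inbreeding is estimated as
`1 − ΣH_obs/ΣH_exp` with bias-corrected H_exp from the full population.

Randomness uses one root `SeedSequence` with deterministic substreams
(loci, phenotypes, then one per accession), so enlarging the collection
never reshuffles earlier accessions, and equal seeds give bit-identical
output. Phenotypes are additive: each trait draws causal loci and normal
effects, and noise is scaled from the realized genetic variance so the
trait's narrow-sense h² (default 0.6, 25 causal loci) holds exactly in
expectation; qualitative traits threshold a liability at quantiles into
2–5 classes.

**What the generator does not emulate.** Loci are unlinked (every
downstream statistic is single-locus or a sum over loci, so linkage would
not change the quantities tested, but linkage-aware analyses cannot be
validated on this generator). Differentiation is founder-level plus
drift; there is no migration, mutation or selection, and seed exchange
between accessions is available only as an optional relabelling
`swap_fraction`. Notably, the equilibrium-drift model does **not**
reproduce the empirical pattern that selfing crops show the *smallest*
within-accession pairwise distances: under selfing, divergence among
inbred lines inflates pairwise distance (E[d²] per locus scales with
1 + F), and only much longer drift or founder bottlenecks would erode
within-accession polymorphism enough to reverse that. The mating-system
contrast the simulator does reproduce — and the tests check — is the
AMOVA one: the within-accession share of molecular variance increases
monotonically with the outcrossing rate. Passing tests therefore
demonstrate correctness of the estimators and the qualitative
variance-partition behaviour, not that simulated collections mimic any
particular crop's absolute distance scale.

## Problem sizes in the test suite

The suite validates estimators on instances of up to ~40 plants and a few
hundred loci, the oracle-equivalence checks on ≤ 12-plant instances, the
simulator calibration on 20 replicate populations of N_e = 100 with 500
loci over 30 generations, and the permutation-test calibrations on 200
null replicates with 99 permutations each — sizes chosen so every
statistical check retains power while the whole suite stays fast enough
to run routinely.

## Known limitations

- The two-row presence/absence DArT dialect is unsupported (single-row
  dosage CSV only); no imputation or phasing.
- AMOVA supports exactly three hierarchy levels; no regional grouping of
  accessions.
- Gower ranges are global, so adding plants can change all pairwise
  phenotype distances slightly.
- The within-individuals permutation scheme is a convention (see above),
  not a uniquely defined test.
- Sample-size results are per-locus retention criteria; joint retention
  over thousands of rare loci is strictly harder and not computed.
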