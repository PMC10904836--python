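# Methods

`radhaplo` implements the post-assembly computational analysis of a haploid
RAD-seq population-genomics study: locus filtering, within- and
between-population genetic statistics, ordination and model-based
clustering, and a habitat-contrast procedure that maps habitat-unique loci
to transcriptome annotations and tallies their GO terms. This note records
the models, the defaults and the design choices made where the design was
genuinely open.

## Data model

A *RAD tag* is a short consensus sequence (default 120 bp, mirroring
125 bp reads minus barcode) with per-sample haploid allele calls.
`snp_positions` are 0-based offsets into the consensus. Because the
organisms are haploid, a sample carrying more than one distinct haplotype
at a tag is evidence of paralogy or diploid contamination; such tags are
blacklisted rather than genotyped. Missing data are represented by the
absence of a call (an explicit `.` is also accepted on disk).

## Filtering

The pipeline applies filters in a fixed, logged order:

1. **Blacklist** — removal of loci flagged upstream (e.g. bacterial
   contaminants identified by taxonomic classification; classification
   itself is out of scope, only the blacklist is applied).
2. **Diploid blacklist** — any locus where at least
   `diploid_sample_threshold` (default 1) samples carry two haplotypes.
   The threshold default is conservative: haploids cannot be heterozygous,
   so a single two-allele sample already marks the tag as suspect.
3. **First SNP per tag** — one column per variant tag, at the smallest
   offset, to avoid tightly linked sites. Invariant tags are carried
   separately so diversity denominators can include them.
4. **p/r presence selection** — a population "contains" a locus only when
   at least fraction `r` of *all* its assigned individuals (not only the
   genotyped ones) are genotyped there; a locus is kept when at least `p`
   populations contain it. Defaults p=6, r=0.5 follow the study's relaxed
   setting for a multi-species data set. These are Stacks-population
   semantics, so results on real exports are comparable.

Steps 1 and 2 commute; the order is fixed only for reproducible logging.

## Within-population diversity

Per site, the unbiased haploid diversity is `n/(n−1) · (1 − Σ p_i²)` with
`n` the genotyped count and `p_i` the allele frequencies in the
population. π averages this over a configurable site basis: `all_sites`
(default; variant-site sum divided by all sites present in the population,
including invariant tags, the Stacks convention) or `variant_only`.
`gene_diversity` (the per-population Nei unbiased gene diversity, the
quantity a "per-population total heterozygosity" column reports) averages
over sites variant within the population. A population with fewer than two
genotyped samples at every site reports π as missing, never as 0.

**Private loci** are counted by presence: a locus genotyped in exactly one
population. A presence-private locus may be monomorphic within its
population, so the private count is bounded by the total site count rather
than the variant count. This matches the generator's ground truth and the
group-uniqueness semantics of the habitat contrast.

## AMOVA and Phi statistics

The distance between two haploid multilocus genotypes is the number of
mismatching loci among loci non-missing in both (pairwise deletion; no
imputation). This is the simplest defensible haploid distance; an
implementation with a different missing-data policy (e.g. GenoDive's) may
differ slightly on sparse data.

Squared distances are decomposed by hierarchical AMOVA with the standard
unbalanced-design coefficients derived from the expected mean squares.
Two-level (among/within populations) gives pairwise Phi_ST =
σ²_a/(σ²_a+σ²_w); three-level (among groups / among populations within
groups / within populations) gives Phi_CT, Phi_SC, Phi_ST. Negative
variance components are *retained* for Phi computation, so slightly
negative Phi_ST values (expected between undifferentiated populations) are
representable; the percentage report offers an optional truncate-at-zero
view. On degenerate data (all individuals identical) all components are 0
and the percentages are reported as 100% within populations by convention,
with Phi undefined (NaN). On pathological tiny instances the Phi_ST
estimate can fall below −1; such a value is not representable as a genetic
distance and the pairwise-matrix wrapper rejects it, while the underlying
AMOVA result remains available.

## Isolation by distance

The Mantel statistic is the Pearson correlation over the n(n−1)/2
unordered pairs of genetic (Phi_ST) and geographic (km) distances. The
permutation test jointly permutes the rows and columns of one matrix;
p-values use the add-one estimator `(#{r_perm ≥ r_obs}+1)/(n_perm+1)`
(default 999 permutations, seed mandatory in the API). For small n an
exhaustive mode enumerates all n! relabelings. The IBD regression is
ordinary least squares of Phi_ST on **untransformed** km: recomputing from
the packaged 8-population matrices gives R² = 0.3891, matching the
published 38.9%, which settles the raw-vs-log distance question in favour
of raw km (log km gives 0.56 and is not what the study reported).
Calibration under independent null matrices (n=8, 199 permutations) gives
an empirical type-I error within [0.03, 0.07] at α = 0.05.

Great-circle distances use the haversine formula with Earth radius
6371.0 km; the packaged distance matrix is an input, not recomputed.

## Ordination

PCoA Gower-double-centres −½·d² and eigendecomposes. Phi-based matrices
can be non-Euclidean, so negative eigenvalues are reported but excluded
from the percent-explained denominator, and no correction is applied by
default (a Lingoes correction is switchable). Axes are ordered by
descending eigenvalue.

## No-admixture Bayesian clustering and Evanno ΔK

Only the no-admixture, independent-allele-frequencies model is
implemented — the configuration behind the study's headline K=3 — because
it is fully specifiable for haploids: each individual belongs wholly to
one of K clusters; cluster allele frequencies per locus carry a symmetric
Dirichlet(1) prior. The Gibbs sampler alternates frequency draws from
Dirichlet(1+counts) and assignment draws from the full conditional under a
uniform prior; missing genotypes drop out of the likelihood.

ln P(D) uses the mean-minus-half-variance estimator of the post-burn-in
log-likelihood trace, the same approximation the original clustering tool
reports. For K=1 its infinite-MCMC limit has a closed form (posterior
Dirichlet moments of log frequencies via digamma/trigamma) which the tests
match tightly; its offset from the true Dirichlet-multinomial marginal
(≈8–10% here) is a documented property of the estimator, not of this
implementation, and largely cancels across K in the Evanno statistic.
Label switching is resolved deterministically after sampling (clusters
ordered by the first sample index of their membership); no identifiability
constraint is imposed inside the sampler.

Evanno ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate runs,
defined only at interior K; sd = 0 reports ΔK as undefined rather than
infinite. Defaults mirror the study protocol (K = 1–8, burn-in 10,000,
20,000 repetitions, 5 iterations); the test suite and the mimic experiment
run a scaled grid (K = 1–5, burn-in 1,000, 2,000 repetitions, 3
iterations), sizes chosen so a full five-batch recovery experiment remains
a desk-scale computation.

## AMOVA-based k-clustering

Populations are assigned to k groups by simulated annealing (geometric
temperature schedule, default 50,000 steps and 20 random starts, both
configurable) maximizing the among-group variance component of the
three-level AMOVA. Per-population pair sums are precomputed, making each
objective evaluation O(P²). Moves that would empty a group are rejected;
k = P degenerates to singleton groups scored by the two-level component.
Exhaustive enumeration verifies the optimum on 4-population instances.

## Habitat contrast

Loci genotyped in at least one sample of exactly one habitat group
(freshwater/saline) are aligned against the transcriptome with a seeded
ungapped local aligner: exact 11-mer seeds on both strands, one extension
per (transcript, diagonal, strand) with +1/−2 scoring and X-drop 10. An
internal aligner is used because the contrast's logic — top hit → top
annotation → tally — is the procedure of interest, the original search
tool's settings are unstated, and the synthetic transcripts embed loci
near-exactly; an adapter for external tabular (outfmt-6-style) results is
provided for real data. Ties break by transcript id then leftmost start.

The *strict* reading of "top hit's top annotation" is the default: if the
single best-scoring hit's transcript lacks annotation the locus is
ignored; a lenient fall-through mode is available. Each tallied locus
contributes +1 to every GO term of that annotation; multiple loci hitting
the same transcript each count. A term passes the screen for a group when
its count is ≥ `min_count` (default 10) and the other group's count is 0
or at least `min_fold` (default 10) times smaller — a zero other-group
count always satisfies the fold rule.

## Synthetic data generator

Population allele frequencies follow the Balding–Nichols model: ancestral
frequency uniform on [0.05, 0.95]; each population's frequency Beta with
that mean and variance scaled by its drift parameter F; haploid calls are
Bernoulli draws; calls are masked uniformly at `missing_rate`. The
expected within-population heterozygosity 2p(1−p)(1−F) is verified against
the closed form, and multi-locus pairwise Phi_ST recovers F within ±0.05
at F ∈ {0.1, 0.3, 0.6} (500 loci, 2×25 haploids, 20 replicates) — a
closed-loop justification for using F as the divergence dial.

Defaults mirror the study scale: 8 populations, 19 haploid strains each,
345 shared biallelic tags, 10% missing calls, tens of private tags per
population, 34 habitat-restricted tags per habitat split over designated
GO terms (17 loci per term, echoing the strongest habitat-linked counts),
a ~3% contaminant fraction and a handful of diploid artifacts. The
`make_study_mimic` bundle fixes the design to 8 populations in 4 regions
and two habitats forming three genetic clusters — three Antarctic saline
lakes (within-group F 0.15), two hydrologically connected Baltic sites
(F 0.02), and freshwater lakes including a strongly drifted Baikal-like
population (F 0.6) — with high between-group drift (F 0.8), mirroring the
observed near-1 between-region Phi_ST against moderate within-region
values.

What the generator does **not** emulate: read-level error, linked sites
within a tag beyond the first SNP, non-uniform missingness across
populations (real locus sharing is structured), selection, and admixture.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated generative model, not robustness to every
property of real RAD data.

All randomness flows from one explicit integer seed (numpy Generator); no
global RNG state is used anywhere.

## Numerical choices

- Presence thresholds compare counts against `r·n − 1e-9` to keep exact
  fractions (e.g. 2/4 at r = 0.5) stable under floating point.
- Distance matrices must be exactly symmetric; diagonals are forced to 0.
- PCoA treats eigenvalues below `1e-12·max` as zero.
- Mantel permutation counting uses a `1e-12` slack on `r_perm ≥ r_obs`.
- The annealing schedule is geometric from T=1 to T=10⁻³.

## Known limitations

- Pairwise Phi_ST significance is available by permutation but the
  original study's exact significance labelling is not reproduced.
- The admixture clustering model, correlated-allele-frequency model and
  selection-outlier scanning are out of scope.
- Quantities bound to the deposited sequence data (per-population
  diversity values, the specific Phi_ST entries, locus counts, AMOVA
  percentage split, ordination variance) are not reproducible at desk
  scale; the suite covers them through oracle-equivalence and
  parameter-recovery experiments instead.
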