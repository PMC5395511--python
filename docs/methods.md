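# Methods

This note documents the statistical models implemented in `wildrice`,
the conventions chosen where several were defensible, what the synthetic
data emulate, and the package's known limitations.

## Mixed-ploidy SSR diversity

**Partial heterozygotes.** Tetraploid microsatellite electrophoresis
reports the set of distinct alleles, not copy numbers. A locus showing k
distinct alleles in a tetraploid admits C(3, k−1) completions to a
4-multiset (3 for ABC: AABC/ABBC/ABCC; 3 for AB; 1 for A or ABCD). We
treat all completions as equally likely — a uniform prior over consistent
genotypes, the convention of tetraploid SSR enumeration software — and
resolve by Monte Carlo: each iteration draws one completion per ambiguous
call, giving an allele-frequency replicate; indices are replicate
averages. Default 10,000 iterations, explicit integer seed. With ≤ a few
hundred ambiguous calls the replicate ensemble is exact enumeration's
mean to well within 0.01 (tested against exact enumeration on small
tables). Unambiguous calls (homozygotes, 4-allele genotypes) contribute
fixed counts; gene-copy counts are 4 per scored tetraploid individual.

**Indices.** H_E = 1 − Σ p² per locus; diploids get Nei's unbiased
correction n_c/(n_c − 1) on gene copies (applied by default), and H_O is
the fraction of scored individuals with two distinct alleles. F_IS, F_ST
and F_IT for diploids use Weir–Cockerham (1984) variance components
(a, b, c), summed over alleles and loci before forming ratios. With a
single population F_ST is undefined (reported as NaN) and F_IS falls back
to 1 − H_O/H_E. G_ST = (H_T − H_S)/H_T with H_T computed from the
unweighted mean of group frequency vectors and H_S the unweighted mean
within-group diversity; the multi-locus value is the ratio of sums over
loci (Σ(H_T − H_S)/ΣH_T), which stays defined when individual loci are
monomorphic — the mean-of-ratios alternative does not. For tetraploids
G_ST is computed per Monte-Carlo replicate and averaged. Missing
genotypes are dropped per locus (pairwise deletion), never per
individual.

## Genetic distances and structure

**Bruvo distance.** Per allele pair, d = 1 − 2^(−|a−b|) with a, b in
repeat units (allele sizes are converted by subtracting the smallest
observed allele per locus and dividing by the repeat length; off-ladder
remainders are rounded with a warning). Between genotypes of equal
allele-set size the distance is the minimum over one-to-one assignments
of the mean allele distance (exact search; ≤ 4 alleles means ≤ 24
permutations). Between unequal sizes — ploidy unknown or mixed — we
average the genome-addition variant (smaller set padded with copies of
its own alleles, minimised over choices) and the genome-loss variant
(unmatched alleles count distance 1). This path is rare within one
species and is the original metric's convention. Pairwise matrix entries
average over loci scored in both samples; a pair sharing no locus is an
error rather than a silent hole.

**Ordination and clustering.** PCoA is classical metric scaling
(scikit-bio's eigendecomposition backend); axes with non-positive
eigenvalues are dropped from coordinates, and negative eigenvalues are
reported. UPGMA is scipy's average-linkage on the full-data matrix;
branch support is the percentage of locus-bootstrap replicates (loci
resampled with replacement — the resampling unit of the clustering tool
this mirrors; sample bootstrap is deliberately not offered) whose tree
contains the same sample clade. Because a replicate's matrix is the mean
of sampled per-locus matrices, the per-locus distance stack is computed
once and each replicate is an average — 10,000 replicates on ~50 samples
run in seconds. Supported clusters are maximal non-root clades with
support above the threshold (default 95%); everything else stays
unassigned. Ordinary bootstrap proportions (BP) are reported;
multiscale-bootstrap AU values are out of scope and can differ near the
threshold. Merge ties are resolved by scipy's deterministic ordering, so
runs are reproducible.

**Mantel test.** Pearson correlation of off-diagonal entries; one-sided
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1) over label permutations
(default 10,000). Geographic distances are haversine great circles on a
sphere of radius 6371.0088 km. The permutation scheme gives an exactly
uniform p under exchangeability, which the test suite verifies as a
type-I error in [0.03, 0.07] over 200 null data sets.

**ΔK.** L(K) is the mean replicate log-likelihood; ΔK =
|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)), defined for interior K with
positive sd; zero sd flags the value as undefined rather than producing
infinities.

## Diversity mapping

Cells (30 arc sec default) take statistics from all individuals within a
great-circle radius of half the neighborhood diameter (5 arc min
default) of the cell center; empty cells are nodata. Allelic richness is
the total distinct-allele count over loci (a per-locus mean is available
— the field reports both and the total is the primary convention here);
Shannon diversity is the across-locus mean of −Σ p ln p. At the mapping
stage tetraploid partial heterozygotes contribute their observed alleles
with equal weights (ploidy/|observed| copies each) instead of Monte-Carlo
resolution: the map stage evaluates thousands of cells and the
equal-weight frequencies equal the MC expectation for 2-allele patterns
and differ negligibly for 3-allele ones; the MC-consistent path remains
available through the diversity module on any cell's member list.

## Suitability modeling

**Calibration data.** Presences are thinned to one per grid cell.
Background cells (max 10,000, one per cell, never a presence cell) are
drawn uniformly from the presences' convex hull buffered by 10% of the
hull's largest axis — the maximum vertex-to-vertex great-circle distance,
converted to degrees at the hull centroid latitude. Nearly collinear
presences fall back to a bounding-box hull (logged). The
`hull+ecoregion` mode additionally restricts background to categorical
ecoregions containing at least one presence cell.

**Collinearity.** VIF_j = 1/(1 − R²_j) from regressing layer j on the
others; the largest-VIF layer is dropped iteratively until all are below
5. Exact collinearity drops the first offender in column order with a
warning.

**Component models and gating.** Two learners are built in — a
percentile-envelope score (per variable 1 − 2|F(x) − 0.5| on the
presence CDF, minimum over variables) and a presence/background logistic
regression with standardized linear + quadratic terms — plus a plugin
contract (factory: CalibrationSet → object with
`predict(X, lon, lat)`), because the contribution here is the
ensemble/gating machinery, not any particular learner. Evaluation runs
10 stratified split iterations (test fraction 1/k, k = 5 default): each
refits the candidates and a geographic null (suitability 1 − d/d_max to
the nearest training presence) on the training part and scores the test
part; cAUC = AUC + 0.5 − max(0.5, AUC_null) discounts the AUC attainable
from spatial sorting alone. A candidate enters the ensemble when its 10
cAUCs beat the null's own by a one-sided Mann–Whitney test at α = 0.05
(sidedness and α are choices; both are exposed). With fewer than 10 test
presences the plain AUC replaces cAUC and every candidate at or above
the null's mean AUC is kept. Ensemble weights are mean cAUCs of retained
models normalised to 1; a failed fit (e.g. non-convergent logistic) is
reported and excluded; zero retained models is an error, not a silent
empty ensemble.

**Projections.** The suitability raster is the weighted mean of
component predictions; nodata propagates. Maps are truncated at the
minimum suitability over presence cells, so every usable presence cell
is suitable by construction — a deliberately liberal threshold suited to
identifying where a species could persist. Palaeoclimate output averages
the two climate-model maps; future output requires agreement of at least
ceil(n/2) of n (default 30) thresholded projections; change maps
classify cells as never/loss/gain/stable; overlap maps classify
crop-only, CWR-only, overlap-current-both, and a merged
overlap-future-involved class for the three combinations in which at
least one of crop and CWR is suitable only in the future. Rainfed and
irrigated crop maps are merged by union of binaries before overlap.

## Synthetic data

The generators produce the structure the analyses assume, not Colombian
geography or real climate values. Genotypes come from a forward
Wright–Fisher simulation: demes of constant size, non-overlapping
generations, partial selfing, symmetric stepwise mutation (±1 repeat,
default 10⁻³/generation — a simulation convenience, not an inference
about *Oryza* markers), island or stepping-stone migration, tetrasomic
inheritance for tetraploids. Tetraploid genotypes are emitted as distinct
allele sets, so partial heterozygotes arise exactly as in scored data;
allele calls are emitted as base-pair sizes so the tables round-trip
through the I/O layer. Demes sit on a line with equal spacing; a pure
island model has no distance structure, so the isolation-by-distance
fixtures use the stepping-stone mode, where neighbor-limited migration
makes genetic distance grow with line position. Individual coordinates
are jittered ≤ 0.01° so neighborhood mapping groups individuals by deme.

Climate layers are spatial gradients plus smoothed Gaussian noise
(standardized after smoothing, so the stated noise scale is the actual
field sd); layers 1–2 are built strongly collinear to exercise VIF
pruning, and layer 4 is noise-dominated ("terrain-like"), giving species
that track it patchy, disjoint suitable areas — the regime in which a
presence hull genuinely contains unsuitable ground and null-model gating
is informative. The truth is logistic with optional quadratic terms (a
niche optimum); presences are drawn without replacement with probability
proportional to truth suitability, at most one per cell. Palaeo/future
raster sets are per-layer shifts and mild rescalings (2 and 30 replicate
sets by default).

What passing tests on these data do *not* show: robustness to null
alleles, scoring error, uneven sampling effort, non-equilibrium
demography beyond the simulated scenarios, or the sampling biases of
real occurrence records.

## Problem sizes and numerical choices

The test and reproduction runs use deme sizes of 8–30 individuals, 6–11
loci, 100–200 generations, 100×100-cell rasters, 150 presences and up to
2,000 background points; Monte-Carlo resolution and Mantel tests run at
the full 10,000 iterations/permutations in the reproduction script, and
bootstrap support at 200–1,000 replicates in tests (10,000 is the
production default). These sizes were chosen to give the statistics
comfortable signal at interactive runtimes.

Degenerate inputs are handled explicitly: empty genotypes give missing
distances; monomorphic loci contribute zero diversity but stay in
ratio-of-sums denominators; H_T = 0 across all loci, constant Mantel
matrices, single-population F_ST, and zero-sd ΔK are errors or flagged
NaNs rather than numerical surprises. All stochastic routines take
explicit integer seeds and touch no global RNG state.

## Limitations

- Published-data reproduction requires the original survey genotype
  table, which is not redistributable with the package.
- Only BP (ordinary bootstrap) branch support; AU p-values would require
  multiscale resampling.
- The ensemble ships two native learners; MAXENT/BRT/RF/GAM etc. must be
  supplied through the plugin contract.
- Rasters are ESRI ASCII grids in WGS84 only; no projection support, no
  GeoTIFF.
- No null-allele modeling, no rarefaction of allelic richness, no
  coalescent simulation.
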