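# Methods

This note documents the models, numerical choices and limitations behind
`urbanscape`, in the order the pipeline runs them.

## Synthetic data: a spatially correlated F-model

The generator emulates the study conditions the pipeline is designed for:
ten colonies (five "urban" clustered within ~15 km of a metropolitan
centroid, five "rural" within ~20 km of a second centroid ~50 km away),
19 individuals per colony, ~20,000 bi-allelic SNPs, near-panmixia with a
weak isolation-by-distance signal, and a small planted set of
environment-associated loci.

Each locus draws an ancestral frequency p₀ ~ U(0.05, 0.95).  Colony
frequencies are marginally Balding–Nichols,
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), coupled across colonies by a Gaussian
copula whose correlation declines linearly with great-circle distance,
r(d) = 1 − d/d_max (projected to the nearest PSD correlation if needed).
For a pair at distance d the expected pairwise FST is then approximately
F·d/d_max — differentiation grows linearly with distance — and F is
calibrated as F = target_fst · d_max / mean(d) so the mean over pairs hits
the target (default 0.002, the magnitude typical of highly mobile,
near-panmictic populations).  Adaptive loci add β·z(env) on the logit of
the colony frequency, where z(env) is the standardised urban-cover
covariate and β defaults to 2 (a strong but not deterministic association:
planted loci end up with |r| ≈ 0.5–0.8 against the environment at n = 190).
Genotypes are Binomial(2, p_c); depths are negative-binomial with mean 15
and shape 8 (so ~1–2% of genotypes fall under the depth-5 QC floor);
an additional 5% of genotypes is set missing so the QC stage has work to
do.  Frequencies pushed outside (0,1) by the adaptive shift are clipped
to [0.001, 0.999] and logged.

What the generator does **not** emulate: linkage disequilibrium between
loci (draws are independent given the colony frequencies), realistic site
frequency spectra, sequencing error, batch effects, or any demographic
history — the F-model parameterises differentiation directly rather than
modelling the population's past.  Passing recovery tests therefore show
that the estimators do what they claim under the stated statistical
structure, not that real data meet that structure.

## Variant QC

Filters run in a fixed order: (1) genotypes with depth < 5 are masked;
(2) loci with > 20% missing genotypes are removed; (3) loci whose mean
depth over non-missing genotypes exceeds 50 are removed (a proxy for
collapsed repeats); (4) loci with minor allele frequency < 0.03 — computed
from the post-masking genotypes — are removed, with MAF exactly 0.03
retained.  The order is a package decision: masking precedes the site
filters so that missingness and MAF reflect the data actually used
downstream.  LD pruning slides a 25-SNP window by steps of 10 per
chromosome; within a window, every pair with squared Pearson dosage
correlation (pairwise-complete) above 0.9 loses its later-positioned
member.  The tie-break is fixed and documented rather than arbitrary;
monomorphic columns are treated as uncorrelated.

## Population structure

Pairwise FST is the Weir–Cockerham (1984) estimator with multi-locus
combination as a ratio of summed variance components (the "weighted"
estimator); negative estimates are reported as computed.  Per-individual
heterozygosity follows the PLINK `--het` method of moments: expected
homozygosity from sample allele frequencies with the 2p̂q̂·n/(n−1)
small-sample correction on allele count n, and
F = (O_hom − E_hom)/(L − E_hom).

PCA imputes missing genotypes by the locus mean, centres, and scales by
unit variance by default (a Patterson √(p(1−p)) option is provided; which
scaling a given study used is rarely reported, so both are first-class).
Axis significance uses Patterson-style moment matching of the top
eigenvalue against the Tracy–Widom β = 1 law; the TW CDF itself is the
Chiani (2014) shifted-gamma approximation (k ≈ 46.446, θ ≈ 0.18605,
shift ≈ 9.84801), accurate to ~10⁻³ in probability, which is ample for
axis screening.

Admixture is a behavioural emulation of sparse-NMF ancestry inference,
not a numeric port: the dosage matrix (÷2) is factorised as QG with Q
rows on the probability simplex and G in [0,1], by alternating least
squares with Euclidean projection, filling non-training entries with the
current model prediction (an EM flavour).  A monotone safeguard reverts
any sweep that would increase the training loss and stops, so the loss
path is non-increasing by construction.  Model choice masks 5% of
observed genotypes, fits on the rest, and scores the held-out genotypes
by negative mean Binomial(2, QG) log-likelihood; the K minimising the
mean cross-entropy over restarts (10 by default, each with its own mask
and initialisation) wins.  Acceptance is behavioural — correct K and
> 0.9 ancestry assignment accuracy on structured fixtures — not equality
with any particular NMF implementation.

## Geography and isolation by distance

Distances are WGS84 ellipsoidal geodesics (Vincenty's inverse formula);
at regional scale the difference from a spherical great circle (~0.3%)
matters for reproducing rounded worked values.  Group summaries use the
n−1 SD and Welch's unequal-variance t-test between comparison classes
(the fractional degrees of freedom reported for such designs match Welch,
not a pooled test).  Two identical constant samples are reported as
t = 0, p = 1 rather than NaN.

MRM regresses the vectorised lower triangle of the response on those of
the predictors by OLS; significance permutes the response matrix's
row/column order jointly (the Mantel-family null — element-wise
permutation would break the pairwise dependence), recomputing R² and
per-coefficient |t|, with the add-one correction
p = (1 + #{perm ≥ obs})/(1 + n_perm).

## Landscape resistance and circuit theory

Five cost hypotheses map rasters to movement costs in [1, 100]:
cost = 1 + 99·light/light_max; cost = 1 + 99·min(d_orchard/d_cap, 1)
(distance by eight-neighbour multi-source Dijkstra in map units);
cost = 100 − 99·tree_pct/100; categorical land cover with orchard 1,
forest 10, grassland 80, arable 90, bare 100 and urban 50/30/10 across
three scenarios (the middle scenario's 30 interpolates the two stated
endpoints); and the cell-wise mean of the orchard and light surfaces for
the combined hypothesis.  light_max and d_cap default to the raster's own
maximum — the original cost tables live in supplementary material and can
be swapped in via `CostScheme` parameters.

The resistor network uses the "average resistance" convention: edge
resistance = mean of the two cell costs, ×√2 for diagonal neighbours
(8-neighbourhood default).  Effective resistance solves the grounded
Laplacian system with one sparse LU factorisation per connected component
serving all focal pairs; disconnected pairs are reported as infinite.
Current-density grids (per-cell mean of absolute incident edge currents
for a unit injection) are available for gene-flow density mapping.
Tests pin the solver to a dense eigendecomposition pseudo-inverse oracle
(R_ij = L⁺_ii + L⁺_jj − 2L⁺_ij) at 10⁻⁶.

## MLPE model comparison

The MLPE correlation matrix is I + ρA, where A is the adjacency of pairs
sharing exactly one population (the triangular graph); its spectrum keeps
the matrix positive definite exactly for ρ < 0.5, which motivates the
search bound.  Estimation is ML (not REML: the candidate models differ in
fixed effects, and only ML likelihoods are AICc-comparable): bounded
scalar optimisation of the profile likelihood over ρ with closed-form GLS
for β and σ² at each ρ, plus explicit endpoint checks.  Predictors are
z-scored, so βs are comparable across hypotheses.  The parameter count is
k = (#β including intercept) + 2 (ρ and σ²) and n is the number of pairs;
neither is standardised in the literature, so both are stated here.  R²
is reported as the squared correlation between fitted and observed pair
values and labelled as such.  Wald 95% CIs on β flag hypotheses whose
support excludes zero.

## Genotype–environment association

Missing genotypes are imputed by the rounded within-cluster mean dosage
(ties away from zero — "rounded mean" is otherwise ambiguous); with no
structure (K = 1) the cluster is the whole sample, which is the default.
RDA centres and unit-scales SNP columns, projects onto an orthonormal
basis of the centred constraint design (so duplicated constraints
collapse to the same subspace), and takes constrained axes from the SVD
of the projected matrix; SNP loadings are right singular vectors scaled
by axis magnitude.  Significance permutes environment rows freely (999
default).  Outliers are loci with |loading − mean| > 3 SD (n−1
denominator) on any constrained axis; under a single constraint the
loading ranking is algebraically the |r| ranking, a property the tests
assert.  Candidates are then screened by Pearson correlation of raw
dosage with the environment (pairwise-complete, two-sided t-based p,
retain p < 0.05).  The per-individual environment value is the colony's
urban-cover percentage.

## Annotation, enrichment, networks

SNPs are exonic if inside any exon of a gene, intronic if inside the gene
span only, intergenic otherwise; GTF intervals are 1-based closed, so
boundary positions belong to the feature.  Overlaps resolve to the
smallest enclosing gene span; "LOC"-prefixed (unrecognised) genes are
excluded before assignment.  The flank for "near gene" classification
defaults to 0 bp and is configurable.

Enrichment is the upper-tail hypergeometric test with fold enrichment
(k/n)/(K/N), where n counts annotated candidates and N the genes in the
supplied ontology table (both configurable).  Terms with fewer than 3
candidate genes are excluded **before** BH correction (matching the
reporting rule "minimum 3 genes per term"); applying the filter after
correction is available by argument.  The ontology table is taken as-is —
no GO-graph ancestor propagation.

Network metrics operate on a simple undirected graph over the full
candidate-gene node set (isolated genes count), with edges kept at
combined score ≥ 400.  Density is 2E/(N(N−1)); closeness uses the
harmonic variant because candidate networks are typically highly
disconnected and classic closeness is undefined there; eigenvector
centrality is the principal eigenvector of each connected component's
adjacency (dense symmetric eigendecomposition — deterministic, unlike
iterative solvers with random starts); hubs are nodes with degree
> mean + 1 SD.

## Problem sizes and determinism

Default pipeline runs simulate 2,000 loci × 190 individuals, enough for
every stage to operate at full statistical fidelity while a complete run
finishes in seconds; recovery analyses in the test suite and acceptance
script use 5,000–20,020 loci as their statements require.  Every source
of randomness flows from explicit seeds recorded in the run manifest, and
repeated runs are byte-identical (checksummed).

## Known limitations

- The admixture module is an NMF emulation; its cross-entropy values are
  not numerically comparable to other implementations, only its decisions.
- Tracy–Widom p-values are approximate (moment matching + gamma CDF);
  they rank and screen axes but are not exact tail probabilities.
- The resistance module does not reproduce published per-study cost
  tables unless they are supplied; parametric defaults stand in.
- MRM per-coefficient permutation uses |t| as the statistic; other
  implementations permute the raw coefficient.
- The GEA pipeline assumes the environment is measured per colony; raster
  extraction helpers are deliberately thin.
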