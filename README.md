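# urbanscape

Landscape genomics of urban vs. rural wildlife populations, built around
the study design of a colony network sampled along an urbanisation
gradient (e.g. fruit-bat roosts in a metropolitan area and a rural region
~50 km away, genotyped at ~20,000 reduced-representation SNPs).

The package answers three questions about such a system:

1. **Is there population structure or isolation by distance?**
   Weir–Cockerham *F*<sub>ST</sub>, PCA with Tracy–Widom axis tests,
   sparse-NMF admixture with masked cross-entropy *K* selection, and
   multiple regression on distance matrices (MRM) of linearised
   *F*<sub>ST</sub>/(1 − *F*<sub>ST</sub>) on geodesic distance.
2. **Which landscape features shape gene flow?**  Circuit-theory
   effective resistance between colonies under competing cost hypotheses
   (night-light intensity, distance to orchards, percent tree cover,
   categorical land cover, combinations), compared with maximum-likelihood
   population-effects (MLPE) mixed models via AICc/BIC evidence weights.
3. **Which loci track the urban environment?**  Redundancy analysis (RDA)
   of the genotype matrix constrained on urban cover, ±3 SD loading
   outliers, a Pearson-correlation screen, SNP annotation against a GTF,
   protein-network topology and hypergeometric GO enrichment with
   Benjamini–Hochberg FDR.

A synthetic-data generator (spatially correlated Balding–Nichols F-model
with planted environment-associated loci and a ground-truth record) makes
every stage testable by parameter recovery.

## Core statistics

- **Differentiation**: per-locus Weir–Cockerham variance components
  (a, b, c); multi-locus θ̂ = Σa / Σ(a+b+c) per colony pair (the
  "weighted" estimator); linearisation *F*<sub>ST</sub>/(1 − *F*<sub>ST</sub>)
  before any regression on distance.
- **MRM**: OLS on vectorised lower triangles; inference by jointly
  permuting the rows/columns of the response matrix,
  p = (1 + #{perm ≥ obs}) / (1 + n_perm).
- **Circuit theory**: each raster cell is a node; adjacent cells are
  joined by a resistor equal to the mean of the two cell costs (×√2 on
  diagonals); pairwise effective resistance from the grounded graph
  Laplacian; per-cell current magnitude gives a gene-flow density surface.
- **MLPE**: y<sub>pair</sub> = Xβ + ε with corr(ε<sub>ab</sub>, ε<sub>cd</sub>) = ρ
  when pairs share exactly one population; ML profile likelihood over ρ,
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), evidence weights
  w<sub>i</sub> ∝ exp(−Δ<sub>i</sub>/2).
- **RDA**: SNP columns centred/scaled; constrained axes from the SVD of
  the environment-fitted genotype matrix; pseudo-F =
  (SS<sub>fit</sub>/q)/(SS<sub>res</sub>/(n−q−1)) with free permutation of
  environment rows; outliers at |loading − mean| > 3 SD per axis.
- **Enrichment**: upper-tail hypergeometric P(X ≥ k) for k of n annotated
  candidates vs. K of N background genes; fold = (k/n)/(K/N); BH-FDR.

## Worked example

Run the whole pipeline on a simulated colony network (10 colonies, 19
individuals each, 2,000 SNPs of which 10 track urban cover with slope
β = 2 on the logit allele frequency):

```sh
urbanscape run --simulate --seed 11 --outdir demo
# completed stages: simulate, qc, structure, ibd, landscape, mlpe, gea,
#                   annotate, enrich, network
```

Selected outputs from that exact run:

- `demo/admixture_ce.tsv` — masked cross-entropy is minimised at K = 1
  (0.8425 vs 0.8451 at K = 2): the simulated landscape is effectively one
  genetic cluster, as designed.
- `demo/ibd_mrm.tsv` — isolation by distance: linearised genetic distance
  rises by 1.55 × 10⁻⁴ per km (R² = 0.94, p = 0.0001 with 9,999
  permutations).  The synthetic generator couples drift to distance, so
  the MRM detects it.
- `demo/mlpe_comparison.tsv` — with the response driven by geography, the
  isolation-by-distance model takes essentially all AICc weight
  (w ≈ 1.0) over the five landscape-resistance hypotheses.
- `demo/gea_candidates.tsv` — the RDA + 3 SD + correlation screen retains
  exactly the 10 planted loci (|r| from 0.54 to 0.80, all p < 10⁻¹⁴),
  with no neutral false positives in this run.

Every threshold applied (MAF ≥ 0.03, genotype depth ≥ 5, locus
missingness ≤ 20%, mean depth ≤ 50, LD pruning 25/10 at r² > 0.9, 9,999
MRM and 999 RDA permutations, ±3 SD, α = 0.05, interaction score ≥ 400,
≥ 3 genes per GO term) is echoed to the log and recorded in
`demo/manifest.json` together with per-file checksums.

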