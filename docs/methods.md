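# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `phylospat`, in the order the pipeline runs them.

## Synthetic data generator

The generator produces datasets carrying exactly the statistical structure
the downstream inference assumes, so every stage can be tested without any
external data.

**Trees.** A pure-birth (Yule) process conditioned on the number of extant
tips, simulated by dendropy. Branch lengths are in My; the default
`birth_rate = 0.1` with 145 tips gives crown ages around 40–60 My, the depth
typical of a mid-Cretaceous-origin plant family. Trees are ultrametric by
construction and tips are relabelled deterministically (`sp0001…`) so equal
seeds give byte-identical Newick.

**Environment.** MINT (minimum temperature of the coldest month, °C), MAP
(mean annual precipitation, mm), and soil pH are Gaussian random fields on
the cell lattice with exponential covariance exp(−d/range), `env_range = 5`
cells by default (strong, realistic spatial smoothness on a 20×20 grid of
100-km cells). Fields are affinely rescaled to realistic units (MINT
2.5 ± 7 °C, MAP 1300 ± 300 mm floored at 50 mm so logs are defined, pH
6 ± 0.75). The pH field is a linear mix of the MAP field and a second field
*empirically orthogonalized* against it, so the realized corr(pH, MAP)
equals the configured target (default −0.813) exactly rather than only in
expectation. This choice matters: with range ≈ ¼ of the grid, the effective
number of independent samples is ~16, and a mixing-weight construction
would scatter the realized correlation far around the target; the
orthogonalized mix keeps the spatial covariance (a linear combination of
GRFs is a GRF) while pinning the cross-correlation. `env_range = 0`
degenerates to iid cells.

**Occupancy.** Each species' soil-pH optimum evolves along the tree by
Brownian motion (rate `niche_sigma2 = 0.01` pH²/My, giving tip optima spread
comparable to the pH field's range over a ~50-My tree), making close
relatives occupy similar cells — the phylogenetic niche conservatism the
NRI analysis is designed to detect. Occupancy probability is a Gaussian
kernel around the optimum (`niche_breadth = 1` pH unit) times the baseline
(0.35), shifted additively by `pH_effect = −0.12` per SD of cell pH and
clipped to [0, 1]; presences are independent Bernoulli draws. The negative
pH effect plus conserved niches produce the negative richness–pH gradient
and the strongly negative pH–MAP correlation that the end-to-end tests
verify. There is no dispersal, occupancy dynamics, or geographic realism:
richness gradients arise purely from niche filtering, which is sufficient to
exercise the pipeline but means passing tests say nothing about, e.g.,
dispersal-limited range cohesion in real data.

All stochastic stages derive their generators from a single master seed via
`numpy.random.SeedSequence(master, spawn_key=path)`, so outputs are
bit-reproducible and independent across stages.

## Gridding and filtering

Occurrence points are binned half-open, [x₀+i·s, x₀+(i+1)·s), origin at the
lower-left corner of the data bounding box (the convention is arbitrary but
fixed; a record exactly on an interior boundary goes to the higher-index
cell). Duplicates collapse to one presence. Filtering applies the area
threshold (default 5,000 km², removing clipped border cells) before the
richness threshold (default 3 species, below which assemblage phylogenetic
structure carries no information); the order is fixed and only affects which
species survive through cell removal. Species left without presences are
dropped. The filter is idempotent and never increases total presences. Cell
areas are inputs (constant cell_size² for synthetic grids); no coastline
clipping is computed.

## Random-addition tree sets

Unsequenced species are grafted into each sampled tree inside their section,
defined as the MRCA subtree of ≥2 anchor tips. "Random placement" is made
precise as: a uniformly chosen edge strictly inside the subtree (the stem is
excluded — the species must be *inside* its section), then a uniform
attachment height along that edge, with the new pendant length forced by
ultrametry. A non-ultrametric alternative would break the interpretation of
MPD in time units, so it was not considered. Grafting is sequential in
randomized order, so added congeners can attach to each other's edges and
become sisters. Because grafting only subdivides edges, the pairwise
distances among original tips are preserved exactly — this is audited, not
assumed. Posterior sampling drops a configurable burn-in fraction and draws
without replacement when the pool allows, with replacement otherwise,
logging indices in the provenance.

## NRI

Patristic distances are computed once per tree in a single postorder sweep
(d(i,j) = depth_i + depth_j − 2·depth(MRCA)); the implementation is checked
against dendropy's patristic distances and, for the full ses-style score,
against picante's `ses.mpd`. MPD is the unweighted mean over unordered
pairs (the data are presence/absence; no abundance weighting). The null is
a richness-preserving label shuffle on the full species pool of the
analysis dataset — the standard null for this index; its mean and sd are
those of the uniform distribution over k-subsets, which the tests verify by
exhaustive enumeration on small pools. A zero null sd (assemblage = pool)
yields NRI = 0 with a degenerate-null flag. Per-(cell, tree) nulls use
seeds derived from (master, cell index, tree index) and are redrawn per
tree; cell NRI is the arithmetic mean over trees, with per-tree values
retrievable for audit.

## Spatial statistics

**Weights.** Queen contiguity on the lattice, row-standardized, by default;
rook and unstandardized variants are exposed. Islands are reported, and
weights are rejected only if every cell is isolated.

**Moran's I** uses the usual cross-product form with a two-sided
permutation p-value folded around the null expectation −1/(n−1). A
checkerboard on a row-standardized rook lattice gives I = −1 exactly (each
neighbor mean equals −z_i), which serves as an algebraic regression test.

**Dutilleul's modified t-test.** Autocovariances of each variable are
estimated block-constant over distance classes (12 equal-width classes by
default; the diagonal is its own class), giving Σ̂ₓ, Σ̂ᵧ; with B the
centering projector, the effective sample size is
M̂ = 1 + tr(BΣ̂ₓ)tr(BΣ̂ᵧ)/tr(BΣ̂ₓBΣ̂ᵧ), clamped to [0, n], and
t = r√((M̂−2)/(1−r²)) is referred to Student-t with M̂−2 df. Under iid data
M̂ = n and the classical test is recovered. If M̂ ≤ 2 (or a trace estimate
is non-positive, which can happen since the block estimates are not forced
positive-definite) the test is declared powerless and p = 1 is returned
with a flag. Monte-Carlo calibration on 10×10 lattices: iid fields give
mean M̂/n ≈ 0.98 and 4% rejection at α = 0.05; independent GRFs with range
= lattice/3 give ~5% rejection where the classical test rejects ~45%.
Class count is a diagnostic knob; results are insensitive between ~8 and
~15 classes at these sizes.

**SAR error model.** y = Xβ + u, u = λWu + ε. The concentrated
log-likelihood log|I−λW| − (n/2)(log 2πσ̂²(λ) + 1) is profiled over
(1/e_min + 10⁻⁶, 1/e_max − 10⁻⁶) by bounded scalar minimization (tolerance
10⁻⁸), with the eigenvalues of W taken from the similar symmetric matrix
D^(−1/2)CD^(−1/2) when W is row-standardized (same spectrum, guaranteed
real). β and σ² follow by GLS at λ̂; coefficient tests are asymptotic
normal with covariance σ̂²((AX)ᵀAX)⁻¹, A = I − λ̂W. λ̂ within 10⁻⁴ of a
search bound raises a boundary flag. At λ = 0 the likelihood, coefficients,
and (k-adjusted) AICc reduce exactly to OLS. Parameter recovery at λ = 0.6,
β = (1, −0.5) on a 15×15 rook lattice is unbiased to < 0.02 over 200
replicates. Pseudo-r² is Nagelkerke's 1 − exp((2/n)(LL₀ − LL)) against the
intercept-only OLS null — nesting guarantees values in [0, 1) — with the
squared fitted–observed correlation reported alongside. Residual Moran's I
is computed on the spatially filtered residuals ε̂ = A(y − Xβ̂), which are
white under a well-specified model.

**Model selection.** AICc = −2logL + 2k + 2k(k+1)/(n−k−1), k counting
coefficients plus σ² (plus λ for SAR). All-subsets enumeration respects
marginality (a quadratic term never enters without its linear term); Akaike
weights are normalized over the full candidate set and per-term importance
sums the weights of models containing the term. Individual fit failures are
recorded per model and skipped; only a fully failed set aborts.

## Pipeline and interpretation

Richness and MAP are natural-log transformed (both guaranteed positive: SR
≥ 3 by filtering, MAP > 0 by construction); all predictors are z-scored so
coefficients are comparable; quadratics are squares of the z-scored linear
terms. MAP and pH never co-occur in a model (their correlation far exceeds
the usual |r| > 0.7 collinearity threshold), giving two variable groups,
MINT+MAP and MINT+pH. The pipeline emits Dutilleul correlations among
{MINT, MAP, pH, NRI, SR}, SAR and OLS model selections for SR ~ env (both
groups), SR ~ NRI (+NRI²), and NRI ~ env (both groups), plus a seed
manifest making reruns byte-identical.

The interpretation stage reads only the best SR~NRI SAR model at α = 0.05:
a significant positive quadratic ⇒ U-shaped (mixed time and diversification
signals); otherwise a significant negative linear term ⇒
time-for-speciation; significant positive linear ⇒ diversification-rate;
nothing significant ⇒ cancellation-or-none. The rule is deliberately
explicit and versioned rather than narrative.

## Problem sizes

The shipped tests and the acceptance script run the chain at reduced sizes
chosen to keep the full suite interactive while leaving every Monte-Carlo
check adequately powered: 10–20-cell-side lattices, 30–60 species, 2–10
trees, 100–1,000 null randomizations, 50–1,000 calibration replicates
(grafting audits run 50 trees at the full 133→170-tip scale). All defaults
in `SimulationConfig`/`AnalysisConfig` remain at the study-scale values
(145 species, 20×20 grid, 1,000 randomizations, 1,000 trees).

## Known limitations

- The generator has no dispersal, speciation–extinction geography, or
  observation error; clustering signals arise solely from Brownian niche
  conservatism plus Gaussian filtering.
- Environment surfaces are stationary isotropic GRFs; real climate/soil
  surfaces have trends and anisotropy that Dutilleul distance classes
  summarize only roughly.
- The SAR implementation covers the error model only (no spatial-lag or CAR
  variants), with dense eigendecomposition — fine for thousands of cells,
  not for rasters.
- Dutilleul's Σ̂ estimates are method-of-moments and can be indefinite in
  small samples; the powerless flag, not a projection, handles that case.
- The interpretation mapping is a sign/significance rule on one best model;
  with weak signals it inherits the instability of model selection itself.
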