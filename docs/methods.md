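# Methods

This note documents the statistical procedures implemented in `spatsig`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Community metrics

All nine metrics are computed from the site × species biomass matrix
obtained by summing quadrat biomass within each site. Proportions are
biomass shares (the data are dry weights, not individual counts), and all
logarithms are natural, so the Hill relations `N1 = e^H` and
`N0 ≥ N1 ≥ N2` hold exactly. For single-species sites Pielou's
`J = H/ln N0` is 0/0; it is reported as missing (NaN), excluded from
correlation-based steps, and logged. `E10` and `E20` evaluate to 1 there
by their formulas. LCBD follows the Hellinger route: transform rows to
`√(y_ij/y_i·)`, center columns, and report each site's share of the total
sum of squares; the shares sum to 1 by construction.

## Spatial weighting and MEM decomposition

The spatial weighting matrix connects **all** site pairs with
`w_ij = (1/d_ij)^α`, `d` the planar Euclidean distance in meters and
`α = 1` by default (a configuration knob; coordinates supplied as lon/lat
are first projected equirectangularly at the mean latitude). Moran's
Eigenvector Maps are the eigenvectors of the doubly centered `HWH`;
eigenpairs with `|λ| ≤ 10⁻¹⁰·max|λ|` are dropped and signs are fixed by
making each eigenvector's first nonzero coordinate positive. Because the
retained eigenvectors form a complete orthonormal basis of the centered
space, `Σ_k r²(x, V_k) = 1` for every non-constant `x`; the identity
`I(V_k) = (n/S0)·λ_k` links the basis to Moran's I and both are enforced
by tests.

`S⁺`/`S⁻` are eigenvalue-weighted sums of squared correlations over the
positive and negative eigenpairs. Two modes exist:

* **raw** (default): the literal weighted sums. These depend on the scale
  of `W` — with meters in the denominator the numbers are small (~10⁻⁴ on
  a 600 km extent) — but ratios and comparisons between metrics are
  scale-free.
* **normalized**: each component divided by the summed `|λ|` of its sign
  class, bounding it in [0, 1] and making values comparable across
  weight matrices. Useful for display; the default stays raw because that
  is the canonical definition of the statistic.

Significance is a permutation test (site labels shuffled, default 9999
permutations, add-one correction, seeded). For an exchangeable null the
test is exact: under pure noise the rejection rate at α = 0.05 is 0.05 by
construction, which the calibration test verifies empirically. A constant
metric vector yields `S⁺ = S⁻ = 0` with a warning rather than an error so
degenerate configurations do not abort a pipeline run.

## Landscape connectivity

Patches within 20 km (inclusive) are linked, edge weight = distance;
shortest paths are edge-length-weighted (Dijkstra). Per focal patch:
degree `Dg`; mean (`CCe`) and maximum (`Ec`) shortest-path distance to
the other members of its connected component (missing for isolates);
betweenness `BC` over weighted shortest paths with endpoints excluded.
Tied shortest paths are counted fractionally (each pair contributes the
share of its shortest paths through the node — the standard convention);
an integer-counting variant (each distinct shortest path counts 1) is
available because the verbal definition "the sum of the shortest paths
through the focal patch" does not fix the convention. Metrics are
computed on the full patch map and then subset to the sampled sites, so a
sampled site's connectivity reflects the whole landscape, not just the
sampled network.

## Species co-occurrence

Per site, species presences across its quadrats give a binary matrix; the
C-score is the mean checkerboard-unit count `(r_a − S)(r_b − S)` over all
unordered species pairs. The raw statistic is used — no null-model
standardization — and the indicator entering the path models is its
additive opposite, so that larger values mean species co-occur more and a
positive path coefficient reads "more co-occurrence increases the
metric". Sites with fewer than two species yield a missing score with a
warning.

## PLS path modeling

The measurement model has four exogenous latents — environmental
variability (formative: altitude, slope, MAWS, SnowNDays, NDVI, δNDVI),
wetland connectivity (formative: Dg, CCe, Ec, BC), wetland size
(formative, single indicator), species co-occurrence (reflective, single
indicator) — and a single-indicator reflective endogenous block holding
one community metric. Nine models are fitted, one per metric.

Estimation is the classical Lohmöller alternating algorithm on indicators
standardized with the n−1 sample SD: outer approximation (weighted block
sums, scores scaled to unit variance), inner approximation (centroid
scheme by default — proxies weighted by the *sign* of the inter-latent
correlation; factorial and path schemes selectable), outer weight update
(mode A: indicator–proxy correlations; mode B: multiple regression of the
proxy on the block), iterated until the largest weight change is below
10⁻⁷ (at most 300 iterations; non-convergence raises). Path coefficients
are then the OLS coefficients of the endogenous latent on the four
exogenous latents; with standardized scores these are standardized
betas, and with single-indicator blocks they coincide with standardized
multiple-regression coefficients to machine precision (a tested
identity). Each latent is sign-aligned so its loading on the first-listed
anchor indicator (Dg, wetland_size, the co-occurrence score, altitude) is
positive, making "more connectivity", "larger wetlands" etc. the positive
direction.

Inference resamples whole sites with replacement (default 10,000
replicates; a fast mode around 1,000 is adequate for smoke runs), refits,
and reports the bootstrap SD as SE and percentile 95% intervals; a path
is significant when its interval excludes zero. Replicates that fail
(zero-variance indicator after resampling, non-convergence) are dropped
and counted, with a warning above 5%.

**Known property, not a defect:** under a pure-noise null, a
multi-indicator *formative* latent is unidentified — its weights chase
chance correlation with the outcome in every resample — so bootstrap
significance for such a block's own path runs slightly hot (~7–8% at
n = 21 with six indicators) while the other paths run conservative. The
procedure's calibration is therefore assessed where the null is
well-defined (single-indicator blocks, where rejection rates sit inside
the binomial band around 5%); results for small samples with wide
formative blocks should be read with this in mind.

Environmental-variable screening (PLS1 with NIPALS via scikit-learn's
`PLSRegression`): component count at the first local minimum of the
leave-one-out RMSEP curve (global minimum with a warning when the curve
is monotone), variables kept at VIP ≥ 1, union across metrics. Screening
is off by default — the default indicator set is already the screened
one — and can be enabled in the pipeline config.

## Attribution of autocorrelation to factors

The per-factor summary of a 9 × 4 path table reports the mean absolute
coefficient and a coefficient of variation computed on the *signed*
coefficients (100·sd/|mean|, n−1 SD) — the convention that reproduces the
published summary rows from the published coefficients.

Best-subset regression fits OLS for every nonempty predictor subset and
ranks by `AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1)` with `p = k + 2`
(intercept and residual variance counted). Subsets with no residual
degrees of freedom are skipped and logged. The best model is reported
with adjusted R², F test, per-coefficient t tests and a Shapiro–Wilk
check of its residuals. With nine observations and four predictors the
search is exhaustive by construction and is verified against an
independent enumeration.

The confound screen regresses `S⁺` and `S⁻` on principal coordinates of
the metric correlation structure. Correlations map to distances via
`d = √(2(1 − r))` by default — Euclidean-embeddable for any correlation
matrix, so the PCoA has no meaningful negative eigenvalues (checked at
10⁻⁸); `1 − r` and `1 − |r|` are selectable since the transform is a
genuine modelling choice.

The `S⁺` ~ `S⁻` link is tested two ways: the Pearson correlation of the
two nine-vectors, and a likelihood-ratio test of the slope in a GLS model
with error covariance proportional to the metric correlation matrix `C`
(fitted by ML; the shared `ln|C|` cancels, so `LR = n·ln(RSS₀/RSS₁)` on
whitened data, referred to χ²₁). This is the fixed-slope formulation of
"a mixed model with the metric correlation matrix as a random effect"; a
singular `C` receives a 10⁻⁸ ridge, logged. At n = 9 the χ²₁ reference is
slightly liberal (no small-sample correction is applied), which the
calibration test documents by accepting a moderately inflated band.

## Synthetic metacommunity generator

The generator emulates a chain of insular wetlands along a 600 × 60 km
strip: 120 patches with lognormal sizes, 21 sampled so their latitudinal
ranks are evenly spaced, 52 species, 5 quadrats per site. Environmental
variables are a latitudinal trend (per-variable loading) plus a
unit-variance Gaussian random field with exponential covariance (100 km
range by default, Cholesky-factored) plus a nugget (30% unstructured
variance), standardized.

Expected per-patch abundance is built in stages, each a switchable
mechanism recorded in the ground-truth object:

* **filtering** — Gaussian niches on the normalized latitude
  (σ = 0.18) over a species pool whose optima density is tilted along
  the gradient (the emulated region is richer at its temperate end), and
  a structured productivity multiplier `exp(0.8·quality)` where quality
  aggregates the gradient-loaded variables. Both make richness and
  dominance metrics vary smoothly in space.
* **dispersal** — a distance-decayed (20 km scale) immigration term
  summed over all other patches, so well-connected patches are enriched
  and nearby communities are more alike.
* **drift** — lognormal abundance noise with SD scaled by
  1/√(relative patch size): small wetlands drift more.
* **interactions** — a site-specific power distortion of the biomass
  allocation with a spatially unstructured lognormal exponent
  (SD 0.6). The distortion reshapes dominance and evenness but leaves
  occupancy — and hence richness — to the undistorted expectations:
  interactions decide who dominates locally, not which species manage to
  persist at all. Distorting occupancy as well would (with detection in
  its λ-sensitive regime) inject unstructured noise into richness and
  blur the broad-versus-local contrast the mechanism is meant to
  produce.

Quadrat realization: per-quadrat occupancy is Bernoulli
`1 − exp(−λ/κ)` with κ = 30 g/m², biomass conditional on presence is
`(λ/n_quadrats)` × lognormal noise (σ = 0.5, mean-corrected). The
defaults (amplitude lognormal with median 12 g/m², σ = 0.6) give mean
site richness around 17–20 of 52 species and total biomass in the
hundreds of g/m², realistic for the emulated system. An entirely empty
site is redrawn once, then raises.

**What the generator does and does not show.** It reproduces the spatial
*logic* of the study system — structured gradients, distance-limited
similarity, unstructured local distortion — with known switches, so
passing tests demonstrate that the pipeline recovers the direction and
spatial signature of each mechanism when it is present and stays quiet
when all are off. It is not a mechanistic metacommunity model: there is
no temporal dynamics, no explicit competition kernel, no calibration to
real floras, and detection noise is lognormal rather than estimated from
field data. Quantitative effect sizes on real data are outside what these
tests can certify.

## Numerical choices and problem sizes

Tolerances: MEM eigenpair truncation at 10⁻¹⁰ relative; PLS weight
convergence at 10⁻⁷; completeness and orthogonality asserted at 10⁻⁸ or
tighter; OLS-equivalence identities at 10⁻¹⁰. Randomness always flows
through `numpy.random.default_rng` with explicit seeds; pipeline stages
derive per-metric seeds from the stage seed so runs are bit-reproducible.
The test suite scales simulation sizes to keep the default run fast
(e.g., 199-permutation and 399-bootstrap calibrations, 50-replicate
recovery experiments at n = 21, 100–500-case oracle sweeps); these sizes
are stated in the tests themselves and were chosen as the smallest that
keep Monte-Carlo error well inside the asserted bands.

## Known limitations

* Raw `S±` values are scale-dependent on the weight matrix; compare them
  only within a basis (or use normalized mode).
* Percentile-bootstrap significance with wide formative blocks at n ≈ 21
  is mildly anti-conservative for the block's own path (see above).
* The χ²₁ reference of the correlated-errors LR test is liberal at
  n = 9.
* The published per-factor CV for wetland size cannot be recovered from
  the published rounded coefficients (the printed summary was evidently
  computed before rounding); the other three CVs reproduce to 0.01
  percentage points and are the ones asserted.
* `J` is undefined at single-species sites; such sites are excluded from
  the affected metric's spatial test (with a log message) rather than
  imputed.
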