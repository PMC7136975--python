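# Methods

## The model and its assumptions

gradscape regresses a pairwise genetic distance on landscape predictors
with maximum-likelihood-population-effects (MLPE) mixed models.  For sites
i < j,

    y_ij = X_ij β + u_i + u_j + ε_ij,
    u_k ~ N(0, σ_u²) i.i.d. per site,   ε_ij ~ N(0, σ_e²) i.i.d. per pair.

In matrix form y = Xβ + Zu + ε with Z the n_pairs × n_sites incidence
matrix carrying two unit entries per row.  The marginal covariance is
σ_e²(I + θ ZZᵀ) with θ = σ_u²/σ_e².  The model assumes Gaussian errors
after transformation, a complete pair universe over the sites, and
exchangeable site effects; it does not model spatial autocorrelation
beyond the shared-site structure, which is why a residual Moran's I check
is run on every full model.

**Estimation.**  ZZᵀ is eigendecomposed once per pair universe
(n_pairs × n_pairs, 136×136 at 17 sites).  For any θ, rotating y and X by
the eigenvectors makes the covariance diagonal, so GLS β̂ and the
closed-form σ̂_e² are direct; the profiled ML or REML criterion is then
maximized over log θ with bounded scalar optimization (log θ ∈ [−12, 8]),
and the boundary θ = 0 (no site effects, plain regression) is always
evaluated and kept if it dominates.  AIC uses the ML log-likelihood with
k = #β + 2 (two variance parameters) — a convention that has to be fixed
somewhere; this matches common mixed-model practice.  Standard errors come
from σ̂_e²(XᵀW⁻¹X)⁻¹.

**Reported summaries.**  Marginal/conditional R² follow the Nakagawa
variance-partition: the per-observation random-effect variance is 2σ_u²
because each pair loads two site effects, so R²_m = σ_f²/(σ_f² + 2σ_u² +
σ_e²) and R²_c adds 2σ_u² to the numerator, with σ_f² the variance of the
fixed-effect predictor from a REML refit.  The dependency ρ = σ_u²/(2σ_u²
+ σ_e²) is the model-implied correlation between two pairs sharing exactly
one site; it lies in [0, 0.5) by construction.  An empirical rank-based
variant of ρ is not claimed equivalent and is not implemented beyond this
model-implied quantity.

**Selection.**  The response is Box–Cox transformed (shift
max(0, 10⁻⁶ − min y); λ on a [−2, 2] grid in steps of 0.01 — a grid, not
the analytic optimum, for reproducibility and boundary safety).
Predictors are left untransformed but standardized.  Multivariate
approaches are first pruned by iterative VIF (threshold 10, recomputing
all VIFs after each drop, ties dropping the later column, infinite VIF for
exact collinearity).  Dredging enumerates all predictor subsets including
the intercept-only model (giving the plain-distance null a seat in every
candidate set), discards subsets containing any pair with |r| ≥ 0.6, fits
each by ML and ranks by AIC.  Cross-approach Akaike weights are normalized
over the full dredged candidate set by default (a printed weight of 0.03
for a best model only arises with a large candidate set; a six-best-only
mode exists as a flag).  Single-predictor approaches (LCP, CD, IBD) are
fitted directly.

## Landscape predictors

**Pairwise ellipses.**  Each pair's metrics are computed inside an ellipse
centered on the pair midpoint and oriented along the inter-site bearing.
The default is deterministic: semi-major a = d/2 · 1.1, semi-minor
b = a · axis_ratio (default 0.5).  A correlated-random-walk envelope is
the stochastic alternative: wrapped-normal turning angles (concentration
κ), lognormal step lengths, success = entering the arrival tolerance of
the far site; the fitted semi-axes are coverage quantiles (default 0.95)
of pooled positions of successful walks.  All CRW distribution parameters
are exposed rather than fixed, since no canonical values exist for them.
Cell membership is by cell-center test; the two endpoint cells are always
retained so a narrow ellipse cannot drop its own sites.

**Gradient surface metrics.**  Heights are mean-referenced over valid
cells.  Sa = mean |z|, Ssk = mean z³ / Sq³, S10 averages the five highest
strict-8-neighbor peaks and five deepest pits (divisor fixed at 5).
Sdr triangulates each complete 2×2 block into two 3-D triangles (x, y in
meters, z in native units) and reports the percent excess over plan area.
The Fourier metrics mean-fill masked cells (adding no power), mean-center,
apply a Hann taper (toggleable) and use the 2-D amplitude spectrum:
Std is the first-maximum 1° bin of mean amplitude by wavevector angle,
Stdi = mean/max of that angular spectrum, Srwi = mean/max of the mean
amplitude per unit radial annulus.  Per-bin *means* (not sums) are used so
the uneven bin population of a square grid cannot masquerade as texture —
an isotropic surface then gives a flat spectrum, as it should.  Sfd fits
log radially-averaged power against log radius over r ∈ [2, Nyquist/2]
and reports Sfd = 4 + s/2, the convention under which a
fractional-Brownian surface of roughness exponent H has Sfd = 3 − H; that
identity anchors the validation.  Sbi = Sq divided by the mean-referenced
height at 5 % bearing area (95th percentile, linear interpolation), ≈
1/1.645 for a Gaussian surface.  Degenerate inputs (constant surface,
zero-variance, too-small clip) yield NaN components with a warning rather
than aborting the pair.

**Patch-mosaic metrics.**  Patches are per-class connected components,
8-connectivity by default (4 by flag).  Core cells survive an 8-neighbor
erosion of depth 1 (configurable).  Edges count 4-adjacent faces between
valid cells of differing class × cell size; faces against the landscape
boundary or masked cells are excluded by default (clipped landscapes),
includable by flag.  The ten metrics follow the standard landscape-level
definitions; split = A²/Σa_i² and mesh = Σa_i²/A satisfy mesh·split = A
exactly, which the tests assert on random mosaics.  iji requires at least
three classes and is omitted under the two-class scheme.  Under PMM2,
masked ex-non-habitat cells count toward neither area nor edge.

**Resistance models.**  Conductance C = 1 + H³ compresses contrast among
good habitat and stretches it among poor habitat.  Edge conductance is
the mean of the two cell conductances divided by the move length in cell
units (1 rook, √2 diagonal).  "Least-cost" is operationalized as minimal
cumulative resistance Σ 1/g along a path — the most conductive corridor —
because a literal maximal cumulative conductance is unbounded by detours.
Commute distance is Vol(G) · R_eff(i, j); R_eff comes from the Laplacian
pseudoinverse (dense, `hermitian=True`, up to 3000 nodes) or from one
sparse LU factorization with per-pair solves above that; the two routes
agree to 10⁻⁶ and the result matches a first-step-analysis Markov oracle
to 10⁻⁸.  Whether distances are computed statewide or per-ellipse is a
pipeline choice; the default is the full raster.  The neighborhood
(4 vs 8) is a flag, default 8.

## Genetic distances

R_ST uses, per population pair and locus, a one-way ANOVA on allele sizes
(alleles as observations): σ²_a = (MSA − MSW)/n₀ with the unequal-sample-
size correction n₀, σ²_w = MSW; loci are combined by summing components
before the ratio.  Negative per-locus among components are floored at zero
(toggleable) so distances stay in [0, 1] and remain Box–Cox-safe; the
per-pair ANOVA reading (rather than a global weighting) is an explicit
design choice.  D_PS = 1 − mean over co-typed loci of Σ_a min(p_a, q_a).
Missing alleles are dropped per locus (available-case); a pair with no
co-typed locus yields NaN with a warning.

## The synthetic-data generator

The generator emulates the study conditions end to end; all draws flow
from one seeded generator per call, so every artifact is a pure function
of (spec, seed).

* **Suitability surface** — spectral synthesis: amplitudes set exactly to
  f^(−(2H+2)/2) with Hermitian-symmetric random phases, inverse FFT,
  min-max rescale to [0, 1].  Exact amplitude control (not white-noise
  filtering) makes the planted spectral slope recoverable to ~±0.02,
  which the Sfd validation exploits.  Default H = 0.6, 224×224 cells of
  100 m.  The pipeline smooths it with a 2.1 km moving-window mean,
  mirroring the moving-window construction of habitat-suitability models.
* **Cover mosaic** — thresholds of a rank-uniformized blend of the
  suitability basis (weight 0.25) with a rougher field (H = 0.2), breaks
  (0.25, 0.6), giving 40 % forest, 35 % complementary, 25 % non-habitat.
  The blend keeps the mosaic correlated with suitability while the
  roughness guarantees the reported property of the real ellipsoids that
  every clip contains all three classes — a two-class clip would make
  PMM2 degenerate.
* **Sites** — rejection-sampled with min separation 3.5 km and a 1.6 km
  border margin (so no clip is truncated below the 16-cell minimum the
  Fourier metrics need); 17 sites by default, hence 136 pairs.
* **Genotypes** — forward-in-time island model, one deme per site, ~27
  diploids per deme (≈460 individuals), 10 loci, founder alleles
  {10, 12, 14, 16, 18}; per-gamete immigration from deme j with
  probability 0.05·exp(−d_ij/6 km) (clipped at 0.95 total), stepwise ±1
  mutation at 5·10⁻⁴, 150 generations.  This yields mean pairwise R_ST
  around 0.1–0.3 with clear isolation by distance.  It is *not* a
  coalescent simulation: no linkage, no null alleles or genotyping error,
  equilibrium is approached but not guaranteed — so passing tests show
  the estimators and the selection machinery behave correctly, not that
  any particular field system behaves like the generator.
* **Planted responses** — y = Xβ + u_i + u_j + ε with chosen β, σ_u, σ_e;
  the selection-recovery study plants β = (0, 1.0, −0.8) on the two
  texture-direction metrics (Std, Stdi) with σ_u = σ_e = 0.5, echoing the
  structure of the headline surface-metrics model.

## Numerical choices and degenerate inputs

Box–Cox λ grid step 0.01; symmetry tolerance 10⁻⁹ for loaded distance
matrices; Std ties resolve to the smallest angle; zero-variance surfaces
are detected on the raw values (ptp = 0) to avoid float-epsilon ghosts;
constant surfaces keep Sa = S10 = 0 and Sdr = 0 while the undefined
metrics go NaN; VIF ties drop the later column; the profile optimizer's
boundary θ = 0 is compared explicitly against the interior optimum.
Moran's I uses row-standardized inverse-distance weights on site-averaged
residuals with a one-sided 999-permutation p-value.

## Problem sizes of the validation harness

The validation harness (driven by `scripts/acceptance.py` and the
acceptance tests) uses desk-scale sizes chosen to give stable statistics
in about a minute: 100 random graphs of ≤25 nodes for the commute oracle,
20 small rasters for exhaustive path enumeration, 200 random mosaics for
the mesh·split identity, 10 surfaces of 256² per roughness exponent for
Sfd, 200 replicates at 136 pairs for MLPE recovery and for the Moran
type-I calibration, and 5 scenes × 10 planted responses for selection
recovery.

## Known limitations

The ellipse delineation defaults to the deterministic axis-ratio form;
the CRW envelope is faithful to the correlated-random-walk idea but its
distribution parameters are unconstrained by any published values.  Only
the ten named landscape-level metrics and nine surface metrics are
implemented (both registries are extensible); class- and patch-level
catalogs, Mantel tests, Bayesian fits and resistance-surface optimization
are out of scope.  Commute distances assume an undirected graph
(symmetric resistance).  The identity of the tenth, collinearity-removed
surface metric in the original metric set is not recorded anywhere and is
deliberately not guessed.
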