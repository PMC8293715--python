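# Methods

This note documents the models implemented in `elevrange`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic tests
do and do not establish about real survey data.

## Range sizes and Stevens profiles

A species' elevational range size is the span between the highest and
lowest *plot* where it was recorded — an estimate from the sampling design,
not the true physiological range. Consequences embraced by the
implementation:

- a species recorded in a single plot has range size 0 m and *stays* in the
  per-plot averages (excluding it would bias the Stevens statistic upward);
- a plot holding no species of the requested group has an *undefined* mean,
  flagged missing and dropped from regressions — substituting 0 would
  fabricate a small-range signal at the gradient ends;
- elevations are exact plot attributes; there is no binning into elevation
  bands.

Group filters: `overall`, `woody`/`herbaceous` (life form),
`temperate`/`tropical` (biogeographical affinity). Cosmopolitan species are
excluded from the affinity contrasts, as is conventional, but — by default —
included in `overall`, along with species whose areal-type label could not
be classified (they are recorded species; a flag restores the stricter
reading). The areal-type → affinity lookup ships as a data file
(`data/areal_types.csv`) so the classification is auditable; matching is
case/whitespace-insensitive and unknown labels map to `unclassified` with a
warning, never a silent drop.

## Rapoport regression

OLS of the per-plot mean range size on plot elevation; "supported" means
slope > 0 with p < 0.05 (the significance gate is configurable, since the
classical criterion speaks only of a positive relationship). Note an
important calibration caveat, measured in this package's own test suite:
because neighbouring plots share most of their species, Stevens profiles
carry strong spatial autocorrelation (lag-1 residual correlation ≈ 0.7 in
the synthetic null), and the i.i.d.-error t-test over-rejects — under a
planted zero slope the nominal-0.05 positive-and-significant rate is ≈15%,
not 5%. This anti-conservativeness is intrinsic to per-plot averaging of
shared ranges and is precisely why the SAR model accompanies OLS in the
inference layer.

## Mid-domain-effect null model

Each simulation places **every** empirical range size exactly once (sizes
sampled without replacement, so the whole multiset is reshuffled); only the
midpoint is random, uniform on the feasible interval
`[low + r/2, high − r/2]`. A plot is covered on the closed interval;
boundary-touching counts. Per plot and simulation the statistic is the mean
size of covering ranges; simulations covering the plot with nothing
contribute no term, and `n_effective_sims` records the divisor. Default
1,000 simulations; the seed is mandatory.

Zero-size ranges are legal and placeable anywhere but cover a plot only at
exact elevation equality — with continuous midpoints, effectively never.
For the same reason a plot sitting *exactly* on a domain boundary is
covered with probability zero by any range narrower than the domain: its
simulated prediction is correctly "missing". Where a complete environmental
table is required, the pipeline fills such boundary plots with the
closed-form continuity limit (the exact expectation evaluated a vanishing
distance inside the domain) and logs the substitution.

`mde_expected_profile` computes the exact expectation of the simulated
statistic. Coverage events are independent Bernoulli(p_k); with
`S = Σ r_k B_k`, `N = Σ B_k`, the identity `1/N = ∫₀¹ t^(N−1) dt` turns
`E[S/N | N ≥ 1]` into a polynomial integral evaluated *exactly* by
Gauss–Legendre quadrature (log-space products keep k ≈ 500 stable). A 2^k
enumeration over coverage outcomes is kept as an independent oracle for
small k, and a breakpoint-aligned grid integration over the product
midpoint space as a third; the three agree to ~1e−12.

A geometry worth knowing: the mid-peak of the predicted *mean range size*
is guaranteed only when the size multiset lives well below the domain
width. Ranges close to the domain width saturate at coverage probability 1
and dominate plots near the boundaries, where small ranges almost never
reach — multisets containing near-domain-wide ranges can be *edge*-peaked
(e.g. sizes {1800, 3600} on a 3,600 m domain: 2,700 m at the centre,
≈3,550 m near an edge). In surveys where >90% of species occupy less than
half the gradient — the regime this package targets — the prediction is
mid-peaked, and the tests assert it there.

## Environmental layers

- **Station summaries.** Per station-year: MAT = mean of 12 monthly means;
  MAP = sum of monthly precipitation; TS = population (n = 12) SD of
  monthly means, in °C (not the ×100 WorldClim convention); MATR =
  warmest-month minus coldest-month mean. Years are then averaged. Both
  variability definitions are deliberate, documented choices; alternates
  can be computed from the same series.
- **Kriging.** Ordinary kriging along the *elevation axis only* — with six
  stations strung along one valley the elevation coordinate carries the
  climatic signal, so the 2-D geostatistical problem is reduced to 1-D by
  design. Default variogram is linear, γ(h) = c·h: with six support points
  no variogram model can be fitted, and the linear model's weights are
  independent of the scale c (a spherical option exists). The interpolator
  is exact at stations; plots outside the station span (here 1,800–2,457
  and 5,230–5,400 m) are extrapolations, logged, and — as ordinary kriging
  does — level off toward the nearest station value.
- **IDW population.** Weights d^(−power), power 2 by default, distance
  measured along elevation (an x/y option exists). Exact at villages; a
  target coincident with several villages takes their mean — the true
  limit of the weights as d → 0.
- **LGM deltas.** TC = present MAT − LGM MAT and PC = present MAP − LGM
  MAP, so positive values mean post-glacial warming/wetting; multiple
  palaeoclimate model layers are averaged before differencing.
- **Assembly.** One complete row per plot in fixed order (MAT, MAP, MATR,
  TS, TC, PC, MDE, POP); any missing plot in any component is an error
  naming plot and variable — no silent gaps.

## Inference layer

- **Standardization.** z-scores with the sample (n−1) SD; constant input is
  an error. With both variables standardized the single-predictor OLS
  coefficient equals the Pearson correlation (tested to 1e−10).
- **SAR.** The *error* variant, `y = Xβ + u`, `u = λWu + ε` — the standard
  choice when the goal is absorbing spatial autocorrelation in residuals.
  Weights: symmetric k-nearest-neighbour graph (union rule, k = 5 default,
  along-gradient distance, deterministic tie-breaks), row-standardized.
  `λ` is profiled out by bounded scalar maximum likelihood on
  `(1/min eig(W), 1)`; `log|I − λW|` uses the (real) eigenvalues of the
  row-standardized matrix via the symmetric similarity
  `D^(−1/2) A D^(−1/2)`. SE(β) = σ̂²((AX)ᵀAX)⁻¹ with the ML σ̂²;
  AIC = 2k − 2logL with k = #β + 2 (λ and σ²). A zero weights matrix
  collapses the fit to OLS exactly. Recovery, measured in the tests:
  λ = 0.6 planted at n = 400 is recovered within ±0.1 in 95/100
  replicates; under λ = 0 the estimator is unbiased with sampling SD ≈
  0.14 at n = 200 (so single-fit λ̂ values of ±0.2 are unremarkable there).
- **Random forest %IncMSE.** Per run a fresh forest (100 trees by default)
  is fitted; each predictor's column is permuted and
  `%IncMSE = 100·(MSE_perm − MSE_base)/MSE_base` with out-of-bag MSE
  (a holdout variant is available). Out-of-bag membership per tree is
  regenerated from the tree's stored integer seed by replaying the
  bootstrap draw; a test pins this replication to scikit-learn's own
  `oob_score_` to 1e−12. Results average over `n_runs` independently
  seeded runs (1,000 by default, matching common practice; tests use
  1–50), together with the mean explained variance
  `100·(1 − MSE_base/Var(y))`. Because %IncMSE is a ratio of MSEs, affine
  rescaling of the response leaves the ranking unchanged. No
  multiple-testing correction is applied anywhere; significance stars
  follow the *, **, *** convention with raw p-values kept in the outputs.

## Synthetic generator

The generator's defaults describe the emulated study system: domain
1,800–5,400 m, 96 evenly spaced plots (spacing ≈ 37.9 m; optional jitter),
545 species whose life-form and affinity labels are drawn at the observed
survey proportions (29%/71%, 62%/21%/18%), six weather stations at the
installed elevations (2,457–5,230 m), three years of monthly records, and
two population centres at 2,700 and 4,200 m over a backdrop of minor
villages.

Range geometry is midpoint-parameterised: midpoint uniform on the domain,
latent size `max(0, a + b·(midpoint − low) + ε)` with defaults a = 400 m,
b = 0.35, σ_ε = 300 m — chosen so that most species occupy well under half
the gradient, as montane floras do. Truncation to the domain preserves the
drawn size and clamps the midpoint into its feasible interval (the same
geometry as the MDE null); `truncate_to_domain=False` lets ranges overhang,
in which case only in-domain plots are observable. Detection is i.i.d.
Bernoulli per (species, plot), default 0.9 — an exhaustive but imperfect
inventory. Group labels are independent of range geometry by default (no
group-specific slopes are planted; a `group_slopes` map can plant them).
Climate: lapse rate 5.5 K/km from a 22 °C sea-level mean, seasonal
amplitude 10 K (constant across stations, so TS and MATR are *flat* along
elevation unless configured otherwise), annual precipitation 1,500 mm at
sea level declining 0.15 mm/m. LGM offsets decline smoothly from 5 °C /
300 mm at the bottom of the domain to 3 °C / 120 mm at the top. Every
stage draws from its own seed substream, so one root seed fixes the whole
run and changing, say, the number of forest runs never perturbs the
community draw.

**What passing tests show — and don't.** The generator plants a linear
range-size gradient with independent noise and homogeneous detection; real
surveys have patchy detection, phylogenetic and spatial clustering of
ranges, elevation-dependent richness, and genuinely 2-D terrain. Synthetic
recovery therefore demonstrates that the estimators are correct *under the
model*, not that a real survey of this size has comparable power; and the
flat TS/MATR default means the generator does not reproduce the increasing
climate-variability gradients that real Himalayan transects show unless
they are configured in.

## Problem sizes in tests and the acceptance script

The acceptance script runs the survey-scale configuration (96 plots, 545
species, 1,000 MDE simulations) with 200-replicate random forests per
group; unit and acceptance tests use 10,000-simulation MDE checks, 100–200
replicate recovery studies (SAR at n = 400, Rapoport at survey scale) and
1–50-run forests. These sizes were chosen so the whole suite completes in a
few minutes while keeping Monte-Carlo error well below the tolerances being
asserted.

## Known limitations

- 1-D reduction throughout (kriging, IDW, SAR weights use along-gradient
  distance); no raster/GIS handling.
- The kriging extrapolation below the lowest and above the highest station
  flattens rather than continuing the lapse trend.
- The OLS Rapoport gate is anti-conservative under spatial autocorrelation
  (see above); interpret its p-values alongside the SAR fits.
- The MDE null fixes the empirical size multiset and randomises midpoints
  only; no range-cohesion or with-replacement variants, and no confidence
  envelopes — only the mean prediction, which is what enters the
  regressions as a predictor.
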