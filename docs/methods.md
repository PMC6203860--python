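# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Vertical hydrodynamics

### Forward model

Sinusoidal diurnal forcing of period P at the sediment–water interface,
propagated by 1-D conduction–advection through saturated sediment with
effective thermal diffusivity κe (m²/day) and thermal front velocity v
(m/day, positive downward; interface at z = 0, z positive downward):

    T(z, t) = T̄ + A0 f(z) cos(ωt − φ(z)) + ε,   ω = 2π/P
    f(z) = exp( z (v − p) / (2κe) ),  p = √((α + v²)/2)
    φ(z) = z q / (2κe),               q = √((α − v²)/2)
    α = √(v⁴ + (8π κe / P)²)

p and q are the real and imaginary parts of the complex wavenumber of the
decaying solution, so amplitude and phase laws are mutually consistent.
Since p ≥ |v|, f never grows with depth. Sensors above the interface
(z < 0) record the undamped surface signal. Noise ε is i.i.d. Gaussian
per record.

### Inverse method

Per calendar day and sensor, ordinary least squares of
T = m + a·cos(ωt) + b·sin(ωt) gives amplitude √(a² + b²) and phase
atan2(b, a) (so T = m + A cos(ωt − phase); the phase is reported but not
used by the solver). Calendar-day windows make the fits deterministic.
For each adjacent sub-surface sensor pair the amplitude ratio
Ar = A_lower/A_upper is inverted for v by Brent root finding of
ln Ar = (Δz/2κe)(v − p) on v ∈ [−10, 10] m/day (residual < 1e−10; the
exponent is strictly increasing in v — d/dv = 1 − v·p/α > 0 — so the
root is unique and monotone in Ar). At v = 0 the exponent reduces
analytically to −Δz √(π/(κe P)), which anchors the conduction-limit
tests. Darcy flux is q = γ·v with γ the heat-capacity ratio
(default 1.0: the thermal front velocity is the recoverable quantity;
γ for a real site comes from its sediment properties).

Pairs are excluded (flagged, never silently dropped) when either
amplitude is below the 0.04 °C sensor resolution or Ar ∉ (0, 1): ratios
at or below the resolution are noise-dominated. A site's condition is
the sign of the mean over converged pair–window velocities with a
±0.01 m/day dead band (UW / DW / indeterminate). The thermal extinction
interval is the first adjacent sensor pair whose window-averaged
amplitude crosses below 0.04 °C, scanning downward; deeper than the
lance ⇒ none.

Defaults κe = 0.05 m²/day and P = 1 day are physically plausible for
sandy streambeds and configurable; the recovery studies state their own
values explicitly.

This windowed-harmonic approach deliberately replaces dynamic harmonic
regression with low-pass resampling (as in MATLAB flux toolboxes): the
estimator of interest is the amplitude-ratio inversion itself, and
per-day least squares is fully specified, deterministic and sufficient
for regularly sampled series. Consequence: irregular gaps simply drop
windows below the sample-count threshold rather than being interpolated.

## 2. Biomass, turnover and secondary production

Conversion chain per counted organism (length L, width W in µm):

* biovolume: sphere (π/6)L³ (requires L = W), prolate spheroid
  (π/6)L·W², cylinder (π/4)W²·L, or a user factor × L·W². Default
  group→shape mapping: flagellate/ciliate → prolate spheroid,
  invertebrate → cylinder, overridable per record.
* carbon: protozoa 0.14 pg C/µm³; invertebrates
  V × specific gravity (default 1.05 pg/µm³) × 0.25 (dry/wet) × 0.4
  (C/dry).
* biomass concentration: Σ carbon × count / sample volume, reported in
  mg C/L (1 mg = 10⁹ pg), grouped by (site, condition, date, layer,
  group, taxon), with the mean individual body mass carried along for
  the turnover step.
* turnover: r = a·exp((E/k)(1/T₀ − 1/T))·M^b per day, with M in mg C.
  Modes: "allometric" (intrinsic rate of population increase; protozoa
  and permanent meiofauna) and "growth_equation" (instantaneous growth;
  insect meiofauna/macroinvertebrates), the latter taking per-taxon
  (a, b) overrides. Defaults E = 0.63 eV, k = 8.617×10⁻⁵ eV/K,
  T₀ = 288.15 K. Temperatures outside 263–323 K warn but compute.
  Negative rates raise — they are configuration errors, never silently
  zeroed.
* production: P_i = B̂·r·Δt per interval with B̂ the arithmetic mean of
  the two endpoint biomasses (the only defensible "mean biomass within
  the interval" with two observations); P_t = Σ P_i. With four weekly
  dates P_t covers three intervals and is reported per month without
  rescaling to 30 days.

**Placeholder coefficients.** The allometric intercepts/exponents shipped
as defaults (2×10⁻³ … 2.5×10⁻² per day at T₀, b = −0.25) are order-of-
magnitude placeholders spanning the flagellate→invertebrate range; real
analyses must supply taxon-specific literature values through
`TurnoverParams`. The exponent −0.25 is the canonical metabolic scaling
choice.

In the pipeline, the temperature for each (site, layer, interval) is the
harmonic-fit mean temperature of the nearest sub-surface sensor averaged
over the interval's windows, converted to K; a configured fallback water
temperature covers sites without thermal coverage.

## 3. Community structure and boundary delineation

* Shannon–Wiener H′ = −Σ p_i ln p_i over taxa with p_i > 0; an all-zero
  layer is undefined (NaN) and drops out of the models.
* Bray–Curtis d = 1 − 2Σmin(x,y)/Σ(x+y) ∈ [0, 1]; a both-zero pair is
  undefined rather than 0 or 1 — two empty samples carry no
  compositional information. (A zero vs non-zero sample is well defined:
  d = 1.)
* ANOSIM: R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) over the off-diagonal dissimilarities, average ranks on
  ties. One-sided permutation p with the (1 + exceedances)/(1 + n_perm)
  estimator (never exactly 0); group labels permuted, default 1000
  times. Ranks are computed once per matrix; permutations only relabel,
  which is what makes the 500-dataset null calibration cheap.
* Boundary delineation: within one hydrodynamic condition, replicate
  samples (site × date) per 5-cm layer form the groups; adjacent layer
  pairs (k, k+1) are tested top-down (optionally layers 0..k pooled vs
  k+1, the "cumulative" mode). The boundary is the shallowest pair with
  p < α (default 0.05); the averaged between-layer Bray–Curtis
  similarity at that pair is reported. All-zero replicates are dropped
  before the test; a layer left with < 2 informative replicates
  truncates the scan with a warning. `holm=True` applies a Holm
  correction across the scanned pairs before thresholding.
* Layer clustering: UPGMA (average linkage) on the layer-averaged
  dissimilarities via scipy, deterministic, refusing undefined entries;
  dendrograms serialize to Newick.

**Multiplicity.** The default scan is uncorrected, matching common field
practice; but a shallowest-significant-pair rule stops early on a null
pair with family-wise probability ≈ 1 − (1−α)^k over k null pairs
(~26% for six pairs at α = 0.05). The boundary-recovery study and the
null-scenario test therefore use the Holm mode, which makes "no boundary
under homogeneity" a ≥ 95% event and lets the study measure boundary
recovery rather than the multiplicity artefact. Uncorrected scans of the
same data are still available and are what the demo pipeline reports.

**Density gradients.** Bray–Curtis on raw abundances responds to any
consistent density shift, not only to compositional turnover. With a
realistic exponential depth decay, adjacent layers differ systematically
in total abundance, and with enough replicates the scan will flag that
gradient at the shallowest pair regardless of where the compositional
boundary lies. This is a property of the method, not a bug; analysts
who want a purely compositional boundary should standardise samples
before the scan. The boundary-recovery study isolates the compositional
signal by simulating a near-flat density profile (decay 0.005/cm).

## 4. Mixed models

All models have a random intercept per site, fitted by maximum
likelihood. Gaussian responses use statsmodels `MixedLM` (ML, default
optimizer; fits with non-finite likelihood are retried with conjugate
gradients). The Poisson-log family is fitted by a self-contained
adaptive Gauss–Hermite routine: per site, the random-intercept integral
is re-centred on its posterior mode (Newton) and rescaled by the local
curvature before 15-node quadrature — necessary because with tens of
observations per site the integrand is far narrower than the prior
scale. The log-normaliser uses lgamma(y+1), i.e. a quasi-likelihood that
accepts the continuous diversity index, replicating the historical
practice of Poisson-GLMM on H′; this is reproduced, flagged and not
endorsed — the Gaussian family is the recommended default for new data.
A fit whose random-effect variance collapses to the boundary is retained
and flagged singular.

Inference is flat-prior direct simulation: n draws (default 5000) from
MVN(β̂, Σ̂) of the fixed effects; summaries are the draw means, 2.5%/97.5%
quantiles and P(β < 0). Non-positive-definite covariances are repaired
by eigenvalue clipping with a warning.

WAIC = −2(lppd − p_waic) with lppd = Σ_i log mean_d exp ℓ_id and
p_waic = Σ_i var_d(ℓ_id) (sample variance), over those draws. Pointwise
likelihoods integrate the random intercept observation-wise: Gaussian
marginals have variance σ²_resid + σ²_site; Poisson points use 20-node
quadrature at the fitted random-effect scale. More than 10% of pointwise
variance terms above 0.4 triggers an instability warning. Model
enumeration covers every subset of the main terms with every first-order
interaction whose main effects are present (18 candidates for three
mains); non-converged candidates are excluded with a warning and the
minimum-WAIC model is reported with the full ranking.

Conditional R² = (σ²_f + σ²_α)/(σ²_f + σ²_α + σ²_ε) with σ²_f the
population variance of the fitted linear predictor; for the Poisson-log
family σ²_ε is the lognormal approximation ln(1 + 1/λ̄) with λ̄ the mean
response. The dispersion check is Pearson χ²/(n − p) with conditional
means at the empirical-Bayes modes of the site intercepts; ≈ 1 for
equidispersed counts, ≪ 1 for a bounded continuous index (the demo
campaign's diversity model sits around 0.03–0.04).

Log₁₀ responses with zeros are offset by half the smallest positive
value; no offset otherwise. Depth enters in cm at stratum midpoints
(2.5, 7.5, …, 32.5).

## 5. Synthetic data: what it emulates, what it does not

`ThermalScenario` reproduces the lance design: 8 sensors (−2.5 to
57.5 cm in the package's positive-down convention), 0.04 °C-class noise,
10-min cadence, multi-week records, sinusoidal diurnal forcing. It does
not simulate weather (non-sinusoidal forcing), stage-driven daily
fluctuation, scour, or heterogeneous sediment; passing recovery tests
show the estimator chain is correct under its own physics, not that a
field record satisfies those assumptions.

`CommunityScenario` reproduces the sampling design (six sites alternating
UW/DW, four weekly dates, seven 5-cm strata, pooled cores as one sample
per stratum) and the qualitative structure: group-specific exponential
depth decay (steepest for invertebrates: 0.12/cm vs 0.08 ciliates, 0.05
flagellates), higher density under DW (×1.6), and benthic→hyporheic
pool replacement with logistic weight w(z) = 1/(1 + exp(s(z − z_b))),
z_b = 10 cm (UW) / 15 cm (DW). Surface densities (60/35/8 ind/L) were
chosen once so a campaign counts roughly the reported thousands of
invertebrates and ciliates and hundreds of flagellates. Counts are
Poisson (optionally negative-binomial via a dispersion parameter —
Poisson is the recoverable default given the underdispersion the
diversity models show); body sizes are lognormal per taxon with
flagellates ≪ ciliates ≪ invertebrates so the size–frequency
distribution separates the groups. A lognormal site multiplier
(sd 0.15 on the log scale) induces the intra-class correlation that
motivates the random intercept. Not emulated: taxon-level temporal
dynamics, spatial autocorrelation within a site, measurement error in
body dimensions, or the chemistry (Fe²⁺/redox) side of the field design.

Study problem sizes: flux recovery uses 5 velocities × 50 replicates of
14-day, 7-sensor records; the ANOSIM null uses 500 datasets × 1000
permutations; boundary recovery 20 campaigns of 6 replicates/stratum;
model recovery 100 replicates of the 504-observation design and WAIC
selection 50 × 18 candidates. All sizes are stated in
`hyporheic/experiments.py` and run end to end in about a minute.

## 6. Numerical and design details

* Determinism: every stochastic routine takes a seed or Generator;
  scenario seeds derive from a root seed via `SeedSequence` spawn keys;
  pipeline outputs are byte-identical across reruns of the same config
  (CSV floats at %.10g).
* Brent bracket [−10, 10] m/day covers any plausible streambed velocity;
  a ratio outside the attainable range raises with diagnostics rather
  than returning a boundary value.
* Tie-break in UPGMA and in the WAIC ranking is deterministic (label
  order / terms string).
* The exp() calls in the GLMM likelihood are clipped at large linear
  predictors to keep the optimizer finite far from the optimum; the
  clip is inactive at any reasonable solution.
* Degenerate inputs: single sampling date (production), all-zero layers
  (diversity, boundary scan), < 2 sites (mixed models), empty taxon
  pools and invalid scenario parameters all raise explicit errors.

## 7. Known limitations

* The amplitude method assumes purely vertical, steady flow and
  sinusoidal forcing; non-stationary forcing biases windowed amplitudes.
* Production ignores losses (migration, predation, disease) by
  construction of the non-cohort method, and the shipped turnover
  coefficients are placeholders.
* The boundary scan on raw abundances conflates density gradients with
  compositional turnover (see §3); the similarity matrices it reports
  average over replicates and hide within-layer heterogeneity.
* With six sites the random-intercept variance is weakly identified;
  credible intervals from the MVN approximation can undercover
  site-level contrasts (the coverage study tracks this: pooled coverage
  ~0.90–0.93).
* WAIC here is computed from the normal-approximation posterior, not
  from MCMC; it inherits the approximation error of that posterior.
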