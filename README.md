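# hyporheic

Coupled ecohydrology and community analysis of streambeds: estimate
vertical hyporheic exchange from temperature depth profiles, quantify the
biomass, secondary production and diversity of the size-structured
assemblages living in the sediment, and delineate — from the biology
alone — the boundary between the benthic community and the hyporheos.

The package is aimed at freshwater ecologists and ecohydrologists working
with temperature-lance records and layered sediment core counts
(eumetazoan invertebrates, ciliates, flagellates in 5-cm strata), and at
methodologists who want a tested, fully synthetic test bed for these
methods: every estimator here can be exercised against a forward
simulator with known ground truth.

## Methods at a glance

**Heat as a tracer (Hatch amplitude method).** The diurnal surface
temperature signal propagates into saturated sediment following the 1-D
conduction–advection equation; its amplitude decays with depth *z* as

    A(z) = A0 · exp( z (v − √((α + v²)/2)) / (2 κe) ),
    α = √(v⁴ + (8 π κe / P)²),

where κe is the effective thermal diffusivity (m²/day), P the forcing
period and v the thermal front velocity (m/day, positive downward).
Windowed harmonic least squares extract daily amplitudes per sensor; the
amplitude ratio of each adjacent sensor pair is inverted for v by
bracketed root finding (the exponent is strictly increasing in v, so the
root is unique). Sites are classified upwelling (UW, v < 0) or
downwelling (DW, v > 0) from the mean over converged pair–window
estimates; the thermal extinction depth is where the daily amplitude
drops below the 0.04 °C sensor resolution.

**Biomass and non-cohort secondary production.** Measured body dimensions
become biovolume through a geometric shape catalogue; protozoan carbon is
0.14 pg C/µm³, invertebrate carbon goes through fresh mass (specific
gravity), a dry/wet ratio of 0.25 and a carbon/dry ratio of 0.4. Daily
biomass turnover r follows an allometric power law r = a·M^b (or
per-taxon growth equations), with the intercept Arrhenius-corrected,
exp((E/k)(1/T₀ − 1/T)), using temperatures from the co-located lances.
Interval production is P_i = B̂·r·Δt with B̂ the mean of the endpoint
biomasses; total production P_t sums the intervals.

**Community structure.** Shannon–Wiener H′ per layer; Bray–Curtis
dissimilarities between replicate samples; permutation ANOSIM (R
statistic, group labels permuted 1000×); the benthos/hyporheos boundary
is the shallowest adjacent layer pair whose assemblages differ
significantly (adjacent-pair or cumulative mode, optional Holm
correction); UPGMA clustering of layers with Newick export.

**Mixed models.** Random-intercept-per-site models for log₁₀ biomass,
log₁₀ production (Gaussian) and diversity (Gaussian, or the historical
Poisson-log quasi-likelihood evaluation that tolerates the continuous
index). Model selection enumerates all main-term subsets plus
first-order interactions (marginality respected) and ranks by WAIC from
flat-prior posterior draws; coefficients are summarised by 5000-draw
posterior simulation (means, 95% credible intervals, P(β < 0)), plus
conditional R² and a Pearson dispersion check. The Poisson GLMM is fitted
by adaptive Gauss–Hermite maximum likelihood and agrees with
`lme4::glmer` to five decimals on test fixtures.

## Worked example

`examples/01_flux_estimation.py` simulates a downwelling site
(v = +0.3 m/day) with the 8-sensor lance layout and noisy 10-min records,
then inverts the amplitude profile:

```
Mean diurnal amplitude per sensor depth (deg C):
site_id  depth_cm  amplitude  mean_t
demo-DW      -2.5     3.0000 14.9997
demo-DW       2.5     2.6333 15.0000
demo-DW      12.5     1.5642 14.9998
...
demo-DW      57.5     0.1485 15.0001

converged pair-window estimates: 84
site-mean thermal front velocity: +0.2990 m/day (truth +0.30)
classification: DW
```

The amplitude decays with depth but remains detectable at 57.5 cm —
downward flow carries the signal deep, so no extinction depth is reached
and the recovered velocity matches the planted truth within 0.4%.

`examples/03_boundary_delineation.py` plants a compositional turnover at
10 cm (UW) and 15 cm (DW) and scans adjacent layer pairs:

```
UW (true boundary 10 cm):
  layers 0-1 (edge    5 cm): R = -0.111, p = 0.8601, between-layer similarity = 0.77
  layers 1-2 (edge   10 cm): R = +1.000, p = 0.0020, between-layer similarity = 0.00
  ...
  -> detected boundary interval: layers (1, 2), edge at 10.0 cm
```

R ≈ 0 where adjacent assemblages are exchangeable and R = 1 at the full
turnover; both planted boundaries are recovered and the DW boundary sits
deeper, as expected when surface water pushes the benthic community down
into the bed. The other examples walk the production chain
(`02_secondary_production.py`), WAIC selection and posterior summaries
(`04_mixed_models.py`), and the full pipeline on the six-site demo
campaign (`05_full_pipeline.py`).

A thin CLI wraps the same stages:

```sh
hyporheic simulate --out campaign --seed 1
hyporheic run-all --sensor-log campaign/sensor_log.csv \
    --count-table campaign/counts.csv --output-dir results --seed 1
```

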