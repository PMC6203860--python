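"""Estimate vertical hyporheic flux from a simulated temperature lance.

A downwelling site (thermal front velocity +0.3 m/day) is simulated with
realistic sensor noise; the diurnal amplitude profile is extracted by
windowed harmonic fits and inverted pairwise with the Hatch amplitude
relation.  Positive velocities mean downward flow (stream water entering
the sediment)."""

from hyporheic.hydrodynamics import (
    ThermalParams,
    classify_site,
    fit_diurnal_harmonic,
    flux_profile,
    mean_amplitude_profile,
    thermal_extinction_depth,
)
from hyporheic.simulate import ThermalScenario, simulate_temperature

scenario = ThermalScenario(
    site_id="demo-DW",
    velocity_v=0.3,  # m/day, true value to recover
    kappa_e=0.05,  # m^2/day effective thermal diffusivity
    sensor_depths_cm=(-2.5, 2.5, 12.5, 17.5, 22.5, 27.5, 37.5, 57.5),
    noise_sd=0.02,  # deg C, comparable to sensor resolution
    duration_days=14,
    seed=1,
)
series = simulate_temperature(scenario)
fits = [f for s in series for f in fit_diurnal_harmonic(s)]

print("Mean diurnal amplitude per sensor depth (deg C):")
print(mean_amplitude_profile(fits).round(4).to_string(index=False))

params = ThermalParams(kappa_e=scenario.kappa_e)
profile = flux_profile(fits, params)
site = classify_site(profile, extinction_interval=thermal_extinction_depth(fits))
print(f"\nconverged pair-window estimates: {site.n_estimates}")
print(f"site-mean thermal front velocity: {site.mean_velocity:+.4f} m/day "
      f"(truth {scenario.velocity_v:+.2f})")
print(f"classification: {site.condition}")
print(f"thermal extinction interval: {site.extinction_interval} cm "
      "(None = signal detectable at every sensor)")
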