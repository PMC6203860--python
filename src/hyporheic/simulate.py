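"""Forward simulators with known ground truth.

Two generators mirror the field campaign this package analyses:

* :func:`simulate_temperature` — a sinusoidal diurnal surface temperature
  signal propagated into the streambed by conduction and advection with a
  known thermal front velocity, sampled by a vertical lance of sensors.
  The forward model is exactly the amplitude/phase law that the Hatch
  inverse solver assumes, so recovery tests have an unambiguous truth.

* :func:`simulate_community` — size-structured assemblages (eumetazoan
  invertebrates, ciliates, flagellates) in 5-cm sediment layers down to
  35 cm.  Expected density of each group decays exponentially with depth,
  downwelling (DW) sites carry a density multiplier relative to upwelling
  (UW) sites, and composition switches from a benthic to a hyporheic taxon
  pool with a logistic weight centred on a planted boundary depth.  Counts
  are Poisson; each counted individual gets lognormal body dimensions.

Both are fully determined by (scenario, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hydrodynamics import (
    TemperatureSeries,
    hatch_amplitude_factor,
    stallman_phase_lag,
)

__all__ = [
    "ThermalScenario",
    "CommunityScenario",
    "TaxonInfo",
    "GroupProfile",
    "simulate_temperature",
    "simulate_community",
    "abundance_table",
    "write_fixture",
    "demo_thermal_scenarios",
    "demo_community_scenario",
]

#: Sensor depths (cm, positive downward) of the 8-sensor lance; the first
#: sensor sits 2.5 cm above the sediment-water interface.
LANCE_DEPTHS_CM = (-2.5, 2.5, 12.5, 17.5, 22.5, 27.5, 37.5, 57.5)

#: 5-cm strata midpoints for layers 0..6 covering 0-35 cm.
LAYER_MIDPOINTS_CM = tuple(2.5 + 5.0 * k for k in range(7))


@dataclass(frozen=True)
class ThermalScenario:
    """Parameters of one site's thermal forward simulation."""

    site_id: str = "S1"
    velocity_v: float = 0.0  # thermal front velocity, m/day, + downward
    kappa_e: float = 0.05  # m^2/day
    period_days: float = 1.0
    surface_mean: float = 15.0  # deg C
    surface_amplitude: float = 3.0  # deg C
    sensor_depths_cm: tuple[float, ...] = LANCE_DEPTHS_CM
    noise_sd: float = 0.02  # deg C
    cadence_min: float = 10.0
    duration_days: float = 28.0
    start: str = "2016-05-16"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_e <= 0 or self.period_days <= 0:
            raise ValueError("kappa_e and period_days must be > 0")
        if self.surface_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("surface_amplitude and noise_sd must be >= 0")
        if self.duration_days < 2:
            raise ValueError("duration_days must be >= 2")


def simulate_temperature(scenario: ThermalScenario) -> list[TemperatureSeries]:
    """Simulate the lance's temperature records for one site.

    At depth ``z`` (m, below the interface) the signal is
    ``T = mean + A0 * f(z) * cos(w t - phi(z)) + eps`` where ``f`` and
    ``phi`` are the conduction-advection amplitude decay and phase lag for
    the scenario's velocity.  Sensors above the interface (z < 0) record the
    undamped surface signal.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_days * 1440.0 / scenario.cadence_min))
    time = pd.date_range(
        scenario.start, periods=n, freq=pd.Timedelta(minutes=scenario.cadence_min)
    )
    t_days = np.arange(n) * scenario.cadence_min / 1440.0
    omega = 2.0 * np.pi / scenario.period_days
    out: list[TemperatureSeries] = []
    for depth_cm in scenario.sensor_depths_cm:
        z_m = max(depth_cm, 0.0) / 100.0
        amp = scenario.surface_amplitude * hatch_amplitude_factor(
            z_m, scenario.velocity_v, scenario.kappa_e, scenario.period_days
        )
        phase = stallman_phase_lag(
            z_m, scenario.velocity_v, scenario.kappa_e, scenario.period_days
        )
        temp = scenario.surface_mean + amp * np.cos(omega * t_days - phase)
        if scenario.noise_sd > 0:
            temp = temp + rng.normal(0.0, scenario.noise_sd, size=n)
        out.append(
            TemperatureSeries(
                site_id=scenario.site_id,
                depth_cm=float(depth_cm),
                time=time,
                temp_c=temp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonInfo:
    """A taxon of the benthic or hyporheic pool, with lognormal body size.

    ``length_meanlog``/``length_sdlog`` parameterise ln(length in um);
    width is ``width_ratio * length`` (ratio <= 1 keeps W <= L).
    """

    name: str
    group: str  # invertebrate | ciliate | flagellate
    shape_class: str  # sphere | prolate_spheroid | cylinder
    length_meanlog: float
    length_sdlog: float
    width_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.width_ratio <= 1:
            raise ValueError("width_ratio must be in (0, 1]")


@dataclass(frozen=True)
class GroupProfile:
    """Depth profile of one taxonomic group's expected density."""

    surface_density: float  # ind/L at z = 0
    decay_rate: float  # per cm, > 0

    def __post_init__(self) -> None:
        if self.surface_density < 0:
            raise ValueError("surface_density must be >= 0")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0")


def _default_taxon_pools() -> tuple[tuple[TaxonInfo, ...], tuple[TaxonInfo, ...]]:
    """Benthic and hyporheic pools spanning the three size-groups.

    Sizes are set so that flagellates << ciliates << invertebrates, giving
    a body-size frequency distribution that cleanly separates the groups.
    """
    benthic = (
        TaxonInfo("Chironomidae", "invertebrate", "cylinder", np.log(900.0), 0.35, 0.10),
        TaxonInfo("Naididae", "invertebrate", "cylinder", np.log(1200.0), 0.40, 0.08),
        TaxonInfo("Cyclopoida", "invertebrate", "prolate_spheroid", np.log(500.0), 0.30, 0.35),
        TaxonInfo("Chydoridae", "invertebrate", "prolate_spheroid", np.log(350.0), 0.25, 0.55),
        TaxonInfo("Peritrichia", "ciliate", "prolate_spheroid", np.log(60.0), 0.30, 0.55),
        TaxonInfo("Stichotrichia", "ciliate", "prolate_spheroid", np.log(90.0), 0.30, 0.35),
        TaxonInfo("Prostomatea", "ciliate", "prolate_spheroid", np.log(45.0), 0.25, 0.60),
        TaxonInfo("Euglenida", "flagellate", "prolate_spheroid", np.log(12.0), 0.30, 0.45),
        TaxonInfo("Cryptomonadida", "flagellate", "prolate_spheroid", np.log(9.0), 0.25, 0.60),
    )
    hyporheic = (
        TaxonInfo("Harpacticoida", "invertebrate", "cylinder", np.log(450.0), 0.30, 0.20),
        TaxonInfo("Nematoda", "invertebrate", "cylinder", np.log(800.0), 0.40, 0.05),
        TaxonInfo("Bdelloidea", "invertebrate", "cylinder", np.log(250.0), 0.30, 0.25),
        TaxonInfo("Tardigrada", "invertebrate", "cylinder", np.log(300.0), 0.25, 0.30),
        TaxonInfo("Karyorelictea", "ciliate", "cylinder", np.log(150.0), 0.30, 0.15),
        TaxonInfo("Haptoria", "ciliate", "prolate_spheroid", np.log(70.0), 0.30, 0.30),
        TaxonInfo("Colpodea", "ciliate", "sphere", np.log(35.0), 0.25, 1.00),
        TaxonInfo("Kinetoplastida", "flagellate", "sphere", np.log(7.0), 0.25, 1.00),
        TaxonInfo("Choanoflagellata", "flagellate", "prolate_spheroid", np.log(8.0), 0.25, 0.55),
    )
    return benthic, hyporheic


@dataclass(frozen=True)
class CommunityScenario:
    """Study design and effect sizes of the community forward simulation.

    Defaults emulate the field design: six sites, alternating UW/DW, four
    weekly sampling dates, seven 5-cm layers to 35 cm.  Depth decay is
    steepest for invertebrates and mildest for flagellates; the benthic
    assemblage extends deeper under DW (boundary 15 cm) than UW (10 cm).
    """

    site_conditions: Mapping[str, str] = field(
        default_factory=lambda: {
            "S1": "UW", "S2": "DW", "S3": "UW", "S4": "DW", "S5": "UW", "S6": "DW",
        }
    )
    n_dates: int = 4
    date_start: str = "2016-05-16"
    interval_days: float = 7.0
    n_layers: int = 7
    layer_thickness_cm: float = 5.0
    groups: Mapping[str, GroupProfile] = field(
        default_factory=lambda: {
            "invertebrate": GroupProfile(60.0, 0.12),
            "ciliate": GroupProfile(35.0, 0.08),
            "flagellate": GroupProfile(8.0, 0.05),
        }
    )
    dw_multiplier: float = 1.6
    boundary_depth: Mapping[str, float] = field(
        default_factory=lambda: {"UW": 10.0, "DW": 15.0}
    )
    turnover_sharpness: float = 1.0  # per cm
    benthic_pool: tuple[TaxonInfo, ...] = field(default_factory=lambda: _default_taxon_pools()[0])
    hyporheic_pool: tuple[TaxonInfo, ...] = field(default_factory=lambda: _default_taxon_pools()[1])
    sample_volume_l: float = 1.0
    site_effect_sd: float = 0.15  # sd of lognormal site density multiplier
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dw_multiplier < 1:
            raise ValueError("dw_multiplier must be >= 1")
        for cond, b in self.boundary_depth.items():
            if not 0 < b < self.n_layers * self.layer_thickness_cm:
                raise ValueError(f"boundary depth for {cond} outside sampled range")
        if not self.benthic_pool or not self.hyporheic_pool:
            raise ValueError("taxon pools must be non-empty")
        if self.sample_volume_l <= 0:
            raise ValueError("sample_volume_l must be > 0")
        for cond in self.site_conditions.values():
            if cond not in ("UW", "DW"):
                raise ValueError(f"unknown condition {cond!r}")

    @property
    def layer_midpoints_cm(self) -> np.ndarray:
        return self.layer_thickness_cm * (np.arange(self.n_layers) + 0.5)


def benthic_weight(z_cm, boundary_cm: float, sharpness: float):
    """Logistic share of the benthic pool at depth z; 0.5 at the boundary."""
    return 1.0 / (1.0 + np.exp(sharpness * (np.asarray(z_cm, float) - boundary_cm)))


def expected_group_density(
    scenario: CommunityScenario, group: str, z_cm, condition: str
) -> np.ndarray:
    """Expected density (ind/L) of a group at depth z under UW/DW."""
    prof = scenario.groups[group]
    mult = scenario.dw_multiplier if condition == "DW" else 1.0
    return prof.surface_density * np.exp(-prof.decay_rate * np.asarray(z_cm, float)) * mult


def simulate_community(scenario: CommunityScenario) -> pd.DataFrame:
    """Draw one campaign's organism table.

    Returns a tidy frame with one row per counted individual:
    (site, date, condition, layer, taxon, group, shape_class, length_um,
    width_um, count=1, sample_volume_l).
    """
    rng = np.random.default_rng(scenario.seed)
    pools = {"benthic": scenario.benthic_pool, "hyporheic": scenario.hyporheic_pool}
    dates = pd.date_range(
        scenario.date_start,
        periods=scenario.n_dates,
        freq=pd.Timedelta(days=scenario.interval_days),
    )
    site_mult = {
        site: float(np.exp(rng.normal(0.0, scenario.site_effect_sd)))
        for site in scenario.site_conditions
    }
    rows: list[tuple] = []
    for site, condition in scenario.site_conditions.items():
        boundary = scenario.boundary_depth[condition]
        for date in dates:
            for layer in range(scenario.n_layers):
                z = scenario.layer_midpoints_cm[layer]
                w_benthic = float(
                    benthic_weight(z, boundary, scenario.turnover_sharpness)
                )
                for pool_name, pool in pools.items():
                    w_pool = w_benthic if pool_name == "benthic" else 1.0 - w_benthic
                    by_group: dict[str, list[TaxonInfo]] = {}
                    for taxon in pool:
                        by_group.setdefault(taxon.group, []).append(taxon)
                    for group, taxa in by_group.items():
                        if group not in scenario.groups:
                            continue
                        dens = expected_group_density(scenario, group, z, condition)
                        mean_count = (
                            dens * w_pool * scenario.sample_volume_l
                            * site_mult[site] / len(taxa)
                        )
                        for taxon in taxa:
                            if scenario.overdispersion is None:
                                n_ind = int(rng.poisson(mean_count))
                            else:
                                k = scenario.overdispersion
                                lam = rng.gamma(k, mean_count / k) if mean_count > 0 else 0.0
                                n_ind = int(rng.poisson(lam))
                            if n_ind == 0:
                                continue
                            lengths = np.exp(
                                rng.normal(
                                    taxon.length_meanlog, taxon.length_sdlog, n_ind
                                )
                            )
                            widths = lengths * taxon.width_ratio
                            for length, width in zip(lengths, widths):
                                rows.append(
                                    (
                                        site,
                                        date,
                                        condition,
                                        layer,
                                        taxon.name,
                                        group,
                                        taxon.shape_class,
                                        float(length),
                                        float(width),
                                        1,
                                        scenario.sample_volume_l,
                                    )
                                )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "date",
            "condition",
            "layer",
            "taxon",
            "group",
            "shape_class",
            "length_um",
            "width_um",
            "count",
            "sample_volume_l",
        ],
    )


def abundance_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pivot an organism table to abundances (ind/L).

    Rows are samples indexed by (site, date, condition, layer); columns are
    taxa; entries are summed counts divided by sample volume.
    """
    df = measurements.copy()
    df["abundance"] = df["count"] / df["sample_volume_l"]
    table = df.pivot_table(
        index=["site", "date", "condition", "layer"],
        columns="taxon",
        values="abundance",
        aggfunc="sum",
        fill_value=0.0,
    )
    table.columns.name = None
    return table


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def demo_thermal_scenarios(seed: int = 0) -> list[ThermalScenario]:
    """Six sites: odd-numbered upwelling, even-numbered downwelling."""
    velocities = {
        "S1": -0.30, "S2": +0.35, "S3": -0.20, "S4": +0.25, "S5": -0.15, "S6": +0.40,
    }
    seeds = np.random.SeedSequence(seed).generate_state(len(velocities)) % (2**31)
    return [
        replace(ThermalScenario(), site_id=site, velocity_v=v, seed=int(s))
        for (site, v), s in zip(velocities.items(), seeds)
    ]


def demo_community_scenario(seed: int = 0) -> CommunityScenario:
    return replace(CommunityScenario(), seed=int(seed % (2**31)))


def write_fixture(
    directory: str | Path,
    thermal_scenarios: Sequence[ThermalScenario] | None = None,
    community_scenario: CommunityScenario | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate and write a complete campaign to delimited text files.

    Writes ``sensor_log.csv``, ``counts.csv``, a ``ground_truth.csv``
    sidecar (site, condition, true velocity, boundary depth, decay rates)
    and a ``manifest.json``.  With no scenarios given, the default demo
    campaign (6 sites, 3 UW + 3 DW, 4 dates, 7 layers) is generated.
    Returns the paths keyed by role.
    """
    from . import io as hio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if thermal_scenarios is None and community_scenario is None:
        thermal_scenarios = demo_thermal_scenarios(seed)
        community_scenario = demo_community_scenario(seed + 1)
    thermal_scenarios = thermal_scenarios or []

    paths: dict[str, Path] = {}
    manifest: dict = {"seed": int(seed), "files": {}}

    if thermal_scenarios:
        series = [s for sc in thermal_scenarios for s in simulate_temperature(sc)]
        paths["sensor_log"] = directory / "sensor_log.csv"
        hio.write_sensor_log(series, paths["sensor_log"])
        manifest["files"]["sensor_log"] = paths["sensor_log"].name
    if community_scenario is not None:
        counts = simulate_community(community_scenario)
        paths["counts"] = directory / "counts.csv"
        hio.write_count_table(counts, paths["counts"])
        manifest["files"]["counts"] = paths["counts"].name

    truth_rows = []
    cond_by_site = dict(community_scenario.site_conditions) if community_scenario else {}
    for sc in thermal_scenarios:
        cond = cond_by_site.get(
            sc.site_id, "DW" if sc.velocity_v > 0 else "UW" if sc.velocity_v < 0 else "indeterminate"
        )
        truth_rows.append(
            {
                "site": sc.site_id,
                "condition": cond,
                "true_velocity_m_day": sc.velocity_v,
                "boundary_depth_cm": (
                    community_scenario.boundary_depth.get(cond, np.nan)
                    if community_scenario
                    else np.nan
                ),
            }
        )
    if not thermal_scenarios and community_scenario is not None:
        for site, cond in community_scenario.site_conditions.items():
            truth_rows.append(
                {
                    "site": site,
                    "condition": cond,
                    "true_velocity_m_day": np.nan,
                    "boundary_depth_cm": community_scenario.boundary_depth[cond],
                }
            )
    paths["ground_truth"] = directory / "ground_truth.csv"
    pd.DataFrame(
        truth_rows,
        columns=["site", "condition", "true_velocity_m_day", "boundary_depth_cm"],
    ).to_csv(paths["ground_truth"], index=False)
    manifest["files"]["ground_truth"] = paths["ground_truth"].name

    paths["manifest"] = directory / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
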