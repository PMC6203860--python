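"""End-to-end orchestration: flux -> communities -> models.

``run_pipeline`` sequences the full analysis on one campaign's data:

1. vertical hydrodynamics — diurnal harmonic fits, Hatch flux profiles,
   thermal extinction depth, UW/DW site classification;
2. biomass, secondary production and Shannon diversity per 5-cm layer,
   with turnover rates temperature-corrected from the lance records;
3. benthos/hyporheos boundary delineation per hydrodynamic condition;
4. random-intercept mixed models with WAIC selection and posterior
   summaries for biomass, production and diversity.

Every output is a delimited text table in the output directory, plus a
JSON run log carrying the configuration, its hash and the seed, which
together reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, community, hydrodynamics as hydro, io as hio, models
from .simulate import abundance_table

__all__ = ["run_pipeline", "flux_stage", "production_stage", "model_stage"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def flux_stage(cfg: hio.PipelineConfig, out: Path) -> pd.DataFrame:
    """Flux estimation and UW/DW classification; returns the site table."""
    if not Path(cfg.sensor_log).exists():
        raise StageError("flux", f"sensor log not found: {cfg.sensor_log}")
    series = hio.read_sensor_log(cfg.sensor_log)
    params = hydro.ThermalParams(
        kappa_e=cfg.kappa_e, period_days=cfg.period_days, gamma=cfg.gamma
    )
    fits_by_site: dict[str, list] = {}
    for s in series:
        fits_by_site.setdefault(s.site_id, []).extend(hydro.fit_diurnal_harmonic(s))
    estimates = []
    classifications = []
    amplitude_rows = []
    for site in sorted(fits_by_site):
        fits = fits_by_site[site]
        extinction = hydro.thermal_extinction_depth(
            fits, threshold=cfg.amplitude_threshold
        )
        profile = hydro.flux_profile(
            fits, params, amplitude_threshold=cfg.amplitude_threshold
        )
        estimates.extend(profile)
        classifications.append(
            hydro.classify_site(profile, tol=cfg.classify_tol,
                                extinction_interval=extinction)
        )
        amplitude_rows.append(hydro.mean_amplitude_profile(fits))
    hio.flux_table(estimates).to_csv(
        out / "flux.csv", index=False, float_format=hio.FLOAT_FORMAT
    )
    class_df = hio.classification_table(classifications)
    class_df.to_csv(out / "classification.csv", index=False,
                    float_format=hio.FLOAT_FORMAT)
    pd.concat(amplitude_rows, ignore_index=True).to_csv(
        out / "amplitude_profile.csv", index=False, float_format=hio.FLOAT_FORMAT
    )
    return class_df


def _layer_temperatures(cfg: hio.PipelineConfig, dates: pd.DatetimeIndex,
                        layers: np.ndarray) -> pd.DataFrame:
    """Mean temperature (K) per (site, layer, interval) from the lance fits.

    Each 5-cm layer midpoint maps to the nearest sub-surface sensor; the
    sensor's harmonic mean temperature is averaged over the windows of
    each sampling interval.  Sites or intervals without thermal coverage
    fall back to the configured water temperature.
    """
    midpoints = 5.0 * layers + 2.5
    fallback = cfg.water_temp_fallback_c + 273.15
    rows = []
    if Path(cfg.sensor_log).exists():
        series = hio.read_sensor_log(cfg.sensor_log)
        fits = [
            f for s in series if s.depth_cm > 0
            for f in hydro.fit_diurnal_harmonic(s)
        ]
        frame = pd.DataFrame(
            {
                "site": [f.site_id for f in fits],
                "depth_cm": [f.depth_cm for f in fits],
                "window_start": [f.window_start for f in fits],
                "mean_t": [f.mean_t for f in fits],
            }
        )
    else:
        frame = pd.DataFrame(columns=["site", "depth_cm", "window_start", "mean_t"])
    for site in sorted(frame["site"].unique()) if len(frame) else []:
        sub = frame[frame["site"] == site]
        depths = np.sort(sub["depth_cm"].unique())
        for interval in range(len(dates) - 1):
            lo, hi = dates[interval], dates[interval + 1]
            window = sub[(sub["window_start"] >= lo) & (sub["window_start"] < hi)]
            for layer, mid in zip(layers, midpoints):
                nearest = depths[np.argmin(np.abs(depths - mid))]
                vals = window.loc[window["depth_cm"] == nearest, "mean_t"]
                temp = vals.mean() + 273.15 if len(vals) else fallback
                rows.append((site, int(layer), interval, float(temp)))
    return pd.DataFrame(rows, columns=["site", "layer", "interval", "temp_k"])


def production_stage(
    cfg: hio.PipelineConfig,
    out: Path,
    conditions: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Biomass, production and diversity tables from the count data."""
    if not Path(cfg.count_table).exists():
        raise StageError("production", f"count table not found: {cfg.count_table}")
    counts = hio.read_count_table(cfg.count_table)
    counts["condition"] = counts["site"].map(conditions).fillna(counts["condition"])
    carbon = allometry.CarbonParams()
    turnover = allometry.TurnoverParams()

    biomass = allometry.biomass_concentration(
        counts, carbon, by=("site", "condition", "date", "layer", "group", "taxon")
    )
    biomass.to_csv(out / "biomass.csv", index=False, float_format=hio.FLOAT_FORMAT)

    dates = pd.DatetimeIndex(np.sort(counts["date"].unique()))
    if len(dates) < 2:
        raise StageError("production", "need >= 2 sampling dates")
    layers = np.sort(counts["layer"].unique())
    temps = _layer_temperatures(cfg, dates, layers)

    prod_rows = []
    keys = ["site", "condition", "layer", "group", "taxon"]
    for key, grp in biomass.groupby(keys, sort=True):
        by_date = (
            grp.set_index("date")["biomass_mg_l"].reindex(dates).fillna(0.0).to_numpy()
        )
        mass = grp["mean_mass_mg"].mean()  # campaign-mean individual mass
        site, condition, layer, group, taxon = key
        r = np.zeros(len(dates) - 1)
        for interval in range(len(dates) - 1):
            t_row = temps[
                (temps["site"] == site)
                & (temps["layer"] == layer)
                & (temps["interval"] == interval)
            ]
            temp_k = (
                float(t_row["temp_k"].iloc[0])
                if len(t_row)
                else cfg.water_temp_fallback_c + 273.15
            )
            if np.isfinite(mass) and mass > 0:
                r[interval] = float(
                    allometry.turnover_rate(mass, group, temp_k, turnover, taxon=taxon)
                )
        dts = np.diff(dates.view("int64")) / 86400e9
        rec = allometry.interval_and_total_production(
            by_date, r, dt_days=float(dts.mean()), key=key
        )
        prod_rows.append(
            dict(zip(keys, key))
            | {"p_t_mg_l_month": rec.p_t, "mean_r_per_day": float(r.mean())}
        )
    production = pd.DataFrame(prod_rows)
    production.to_csv(out / "production.csv", index=False,
                      float_format=hio.FLOAT_FORMAT)

    table = abundance_table(counts)
    h = table.apply(community.shannon, axis=1)
    diversity = h.rename("shannon_h").reset_index()
    diversity.to_csv(out / "diversity.csv", index=False,
                     float_format=hio.FLOAT_FORMAT)
    return biomass, production, diversity


def boundary_stage(cfg: hio.PipelineConfig, out: Path,
                   conditions: dict[str, str], seed: int) -> pd.DataFrame:
    counts = hio.read_count_table(cfg.count_table)
    counts["condition"] = counts["site"].map(conditions).fillna(counts["condition"])
    table = abundance_table(counts)
    rows = []
    pair_rows = []
    for i, condition in enumerate(sorted({c for c in conditions.values()})):
        sub = table[table.index.get_level_values("condition") == condition]
        if not len(sub):
            continue
        result = community.delineate_boundary(
            sub,
            condition=condition,
            alpha=cfg.alpha,
            n_permutations=cfg.n_permutations,
            seed=seed + i,
            mode=cfg.boundary_mode,
        )
        rows.append(
            {
                "condition": condition,
                "boundary_upper_layer": result.boundary_interval[0]
                if result.boundary_interval else np.nan,
                "boundary_lower_layer": result.boundary_interval[1]
                if result.boundary_interval else np.nan,
                "boundary_depth_cm": result.boundary_depth_cm,
                "boundary_similarity": result.boundary_similarity,
            }
        )
        for t in result.pair_tests:
            pair_rows.append(
                {
                    "condition": condition,
                    "upper_layer": t.upper_layer,
                    "lower_layer": t.lower_layer,
                    "anosim_r": t.result.r_statistic,
                    "p_value": t.result.p_value,
                    "mean_between_similarity": t.mean_between_similarity,
                }
            )
        # layer-by-layer averaged similarity matrix and UPGMA dendrogram
        sim = _layer_similarity(sub)
        sim.to_csv(out / f"similarity_{condition}.csv",
                   float_format=hio.FLOAT_FORMAT)
        dissim = 1.0 - sim
        np.fill_diagonal(dissim.values, 0.0)
        if dissim.notna().all().all() and len(dissim) >= 3:
            Z, labels = community.cluster_layers(dissim)
            (out / f"dendrogram_{condition}.nwk").write_text(
                community.linkage_to_newick(Z, labels) + "\n"
            )
    boundary = pd.DataFrame(rows)
    boundary.to_csv(out / "boundary.csv", index=False, float_format=hio.FLOAT_FORMAT)
    pd.DataFrame(pair_rows).to_csv(out / "anosim_pairs.csv", index=False,
                                   float_format=hio.FLOAT_FORMAT)
    return boundary


def _layer_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Bray-Curtis similarity (1 - dissimilarity) between layers."""
    d = community.dissimilarity_matrix(table)
    layers = table.index.get_level_values("layer").to_numpy()
    uniq = np.unique(layers)
    sim = pd.DataFrame(index=uniq, columns=uniq, dtype=float)
    arr = d.to_numpy()
    for a in uniq:
        for b in uniq:
            block = arr[np.ix_(layers == a, layers == b)]
            if a == b:
                block = block[~np.eye(block.shape[0], dtype=bool)]
            with np.errstate(invalid="ignore"):
                sim.loc[a, b] = 1.0 - np.nanmean(block) if np.isfinite(
                    block
                ).any() else np.nan
    sim.index.name = "layer"
    return sim


def model_stage(cfg: hio.PipelineConfig, out: Path, biomass: pd.DataFrame,
                production: pd.DataFrame, diversity: pd.DataFrame,
                seed: int) -> pd.DataFrame:
    """WAIC selection and posterior summaries for the three responses."""
    coef_rows = []
    ranking_frames = []
    summary_rows = []

    def run(name: str, data: pd.DataFrame, response: str, mains: tuple[str, ...],
            family: str, offset_seed: int) -> None:
        best, ranking = models.select_by_waic(
            data, response, mains, family=family,
            n_draws=cfg.waic_draws, seed=seed + offset_seed,
        )
        fit = models.fit_model(data, best)
        post = models.simulate_posterior(fit, n_draws=cfg.n_draws,
                                         seed=seed + offset_seed + 500)
        ranking.insert(0, "response", name)
        ranking_frames.append(ranking)
        for coef_name, row in post.table.iterrows():
            coef_rows.append({"response": name, "coefficient": coef_name, **row})
        summary = {
            "response": name,
            "family": family,
            "best_terms": " + ".join(best.terms) or "1",
            "conditional_r2": models.conditional_r2(fit),
            "random_var": fit.random_var,
            "loglik": fit.loglik,
        }
        if family == "poisson":
            summary["dispersion"] = models.dispersion_check(fit)
        summary_rows.append(summary)

    bio = (
        biomass.groupby(["site", "condition", "date", "layer", "group"],
                        as_index=False)["biomass_mg_l"].sum()
    )
    bio["depth"] = 5.0 * bio["layer"] + 2.5
    bio = bio.rename(columns={"condition": "hydro"})
    bio["log10_biomass"], _ = models.log10_with_offset(bio["biomass_mg_l"])
    run("biomass", bio, "log10_biomass", ("depth", "hydro", "group"),
        "gaussian", 0)

    prod = (
        production.groupby(["site", "condition", "layer", "group"],
                           as_index=False)["p_t_mg_l_month"].sum()
    )
    prod["depth"] = 5.0 * prod["layer"] + 2.5
    prod = prod.rename(columns={"condition": "hydro"})
    prod["log10_production"], _ = models.log10_with_offset(prod["p_t_mg_l_month"])
    run("production", prod, "log10_production", ("depth", "hydro", "group"),
        "gaussian", 1000)

    div = diversity.dropna(subset=["shannon_h"]).copy()
    div["depth"] = 5.0 * div["layer"] + 2.5
    div = div.rename(columns={"condition": "hydro"})
    run("diversity", div, "shannon_h", ("depth", "hydro"),
        cfg.diversity_family, 2000)

    pd.concat(ranking_frames, ignore_index=True).to_csv(
        out / "model_ranking.csv", index=False, float_format=hio.FLOAT_FORMAT
    )
    coefs = pd.DataFrame(coef_rows)
    coefs.to_csv(out / "coefficients.csv", index=False,
                 float_format=hio.FLOAT_FORMAT)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "model_summary.csv", index=False,
                   float_format=hio.FLOAT_FORMAT)
    return summary


def run_pipeline(cfg: hio.PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns a manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)

    try:
        class_df = flux_stage(cfg, out)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("flux", str(exc)) from exc
    conditions = dict(zip(class_df["site"], class_df["condition"]))

    try:
        biomass, production, diversity = production_stage(cfg, out, conditions)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("production", str(exc)) from exc

    try:
        boundary_stage(cfg, out, conditions, seed)
    except Exception as exc:
        raise StageError("delineation", str(exc)) from exc

    try:
        model_stage(cfg, out, biomass, production, diversity, seed)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("models", str(exc)) from exc

    from . import __version__

    cfg_dict = asdict(cfg)
    run_log = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"run_log.json"}
        ),
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return run_log
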