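"""End-to-end pipeline commands behind the CLI.

Each command is a pure function of (inputs, configuration, seed): repeated
runs write byte-identical primary outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, config as config_mod, montecarlo, proxies, tpc
from .config import RunConfig

log = logging.getLogger("otofmr")

#: Table-style summary columns, one block per age group
TPC_COLUMNS = [
    "age_group",
    "n",
    "t_pref",
    "t_pref_sd",
    "t_iqr_max",
    "t_iqr_max_sd",
    "vertex_T",
    "vertex_T_sd",
    "breakpoint_T",
    "breakpoint_T_sd",
    "slope_low",
    "slope_high",
    "davies_p",
]


def cmd_estimate(cfg: RunConfig) -> dict[str, Path]:
    """Run the isotope → physiology chain with Monte-Carlo propagation.

    Writes ``estimates.csv`` (long format: sample_id, replicate,
    temperature, c_resp) and ``ci_widths.csv`` (per-sample 95% widths with
    dataset means in the final row).
    """
    if cfg.records_path is None:
        raise ValueError("config must set records_path")
    config_mod.log_provenance(cfg)
    records = proxies.read_records(cfg.records_path, cfg.column_map or None)
    if cfg.age_groups:
        records = records[records["age_group"].isin(cfg.age_groups)]
        if records.empty:
            raise ValueError(f"no records left after age-group filter {cfg.age_groups}")
    ens = montecarlo.run_monte_carlo(
        records,
        cfg.parameter_set(),
        cfg.mc,
        unknown_origin_water=cfg.unknown_origin_water,
    )
    widths = montecarlo.individual_ci_widths(ens, cfg.mc.ci_level)
    out = config_mod.ensure_outdir(cfg)
    est_path = out / "estimates.csv"
    ens.to_csv(est_path)
    widths_path = out / "ci_widths.csv"
    summary = pd.DataFrame(
        [
            {
                "sample_id": "__mean__",
                "temperature_width": widths.attrs["mean_temperature_width"],
                "c_resp_width": widths.attrs["mean_c_resp_width"],
            }
        ]
    )
    pd.concat([widths, summary], ignore_index=True).to_csv(widths_path, index=False)
    log.info(
        "mean 95%% CI widths: temperature %.3f degC, C_resp %.4f",
        widths.attrs["mean_temperature_width"],
        widths.attrs["mean_c_resp_width"],
    )
    return {"estimates": est_path, "ci_widths": widths_path}


def replicate_metrics(
    group: pd.DataFrame,
    grid_step: float = 0.05,
    k_points: int = 10,
    min_n: int = 15,
) -> pd.DataFrame:
    """Per-replicate thermal-performance metrics for one estimate table.

    ``group`` is long-format (sample_id, replicate, temperature, c_resp).
    Returns one row per replicate with T_pref, T(IQR max), quadratic
    vertex, breakpoint, slopes and Davies' p.
    """
    rows = []
    for rep, g in group.groupby("replicate"):
        t = g["temperature"].to_numpy()
        y = g["c_resp"].to_numpy()
        fit = tpc.fit_thermal_performance(t, y, grid_step=grid_step, k_points=k_points)
        curve = tpc.iqr_curve(t, y, min_n=min_n)
        rows.append(
            {
                "replicate": rep,
                "t_pref": tpc.modal_temperature(t),
                "t_iqr_max": curve.attrs["t_iqr_max"],
                "vertex_T": fit.vertex_T,
                "breakpoint_T": fit.breakpoint_T,
                "slope_low": fit.slope_low,
                "slope_high": fit.slope_high,
                "davies_p": fit.davies_p,
            }
        )
    return pd.DataFrame(rows)


def group_summary(metrics: pd.DataFrame, age_group: str, n_fish: int) -> dict:
    """One summary row: central (replicate 0) values with MC mean/sd in brackets."""
    central = metrics[metrics["replicate"] == 0].iloc[0]
    noisy = metrics[metrics["replicate"] > 0]
    if len(noisy) >= 2:
        sd = noisy[["t_pref", "t_iqr_max", "vertex_T", "breakpoint_T"]].std(ddof=1)
    else:
        sd = pd.Series(np.nan, index=["t_pref", "t_iqr_max", "vertex_T", "breakpoint_T"])
    return {
        "age_group": age_group,
        "n": n_fish,
        "t_pref": central["t_pref"],
        "t_pref_sd": sd["t_pref"],
        "t_iqr_max": central["t_iqr_max"],
        "t_iqr_max_sd": sd["t_iqr_max"],
        "vertex_T": central["vertex_T"],
        "vertex_T_sd": sd["vertex_T"],
        "breakpoint_T": central["breakpoint_T"],
        "breakpoint_T_sd": sd["breakpoint_T"],
        "slope_low": central["slope_low"],
        "slope_high": central["slope_high"],
        "davies_p": central["davies_p"],
    }


def cmd_tpc(
    cfg: RunConfig,
    estimates_path=None,
    min_group_n: int = 50,
    grid_step: float = 0.05,
    k_points: int = 10,
) -> dict[str, Path]:
    """Thermal-performance metrics per age group and pooled.

    Needs both the long-format estimates (from :func:`cmd_estimate`) and
    the original records (for age-group membership).  Groups with fewer
    than ``min_group_n`` fish are skipped with a warning.  Writes
    ``tpc_replicates.csv`` (per group × replicate) and ``tpc_summary.csv``.
    """
    if cfg.records_path is None:
        raise ValueError("config must set records_path")
    out = config_mod.ensure_outdir(cfg)
    estimates_path = Path(estimates_path or out / "estimates.csv")
    if not estimates_path.exists():
        raise ValueError(f"estimates file {estimates_path} not found; run estimate first")
    est = pd.read_csv(estimates_path)
    records = proxies.read_records(cfg.records_path, cfg.column_map or None)
    est = est.merge(records[["sample_id", "age_group"]], on="sample_id", how="left")

    groups: list[tuple[str, pd.DataFrame]] = [("all", est)]
    groups += [(str(g), df) for g, df in est.groupby("age_group")]

    summary_rows = []
    rep_frames = []
    for name, df in groups:
        n_fish = df["sample_id"].nunique()
        if n_fish < min_group_n:
            log.warning("age group %s has %d fish (< %d); skipped", name, n_fish, min_group_n)
            continue
        metrics = replicate_metrics(df, grid_step=grid_step, k_points=k_points)
        metrics.insert(0, "age_group", name)
        rep_frames.append(metrics)
        summary_rows.append(group_summary(metrics, name, n_fish))

    rep_path = out / "tpc_replicates.csv"
    sum_path = out / "tpc_summary.csv"
    pd.concat(rep_frames, ignore_index=True).to_csv(rep_path, index=False)
    pd.DataFrame(summary_rows, columns=TPC_COLUMNS).to_csv(sum_path, index=False)
    return {"replicates": rep_path, "summary": sum_path}


def cmd_climate(
    model_paths: list,
    obs_path,
    output_dir,
    threshold: float = 28.0,
    months=climate.JAS,
    ref_year: int = 2016,
    region: dict | None = None,
) -> dict[str, Path]:
    """Seasonal means, bias correction, ensemble stats and crossing-year map.

    ``region`` optionally holds lat/lon bounds (lat_min, lat_max, lon_min,
    lon_max) for the trajectory.  Writes the crossing map as netCDF plus a
    CSV summary and the regional trajectory CSV.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs_monthly = climate.read_sst(obs_path)
    obs_seasonal = climate.seasonal_mean(obs_monthly, months)
    corrected = []
    for p in model_paths:
        cube = climate.read_sst(p)
        seasonal = climate.seasonal_mean(cube, months)
        try:
            corrected.append(climate.bias_correct(seasonal, obs_seasonal, ref_year))
        except ValueError as err:
            raise ValueError(f"model file {p}: {err}") from err
    mean, sd, zscores = climate.ensemble_mean(corrected)
    outliers = zscores[zscores.abs() > 2]
    for model, z in outliers.items():
        log.warning("model %s is a candidate outlier (z = %.2f)", model, z)
    cross = climate.crossing_year(mean, threshold=threshold)

    mask = None
    if region:
        lat, lon = mean["lat"], mean["lon"]
        mask = (
            (lat >= region["lat_min"]) & (lat <= region["lat_max"])
        ) * ((lon >= region["lon_min"]) & (lon <= region["lon_max"]))
        mask = mask.broadcast_like(mean.isel(year=0)).astype(bool)
    traj = climate.regional_trajectory(corrected, region_mask=mask)

    cross_nc = out / "crossing_map.nc"
    climate.write_sst(cross.rename("first_year"), cross_nc)
    cross_csv = out / "crossing_map.csv"
    cross.to_dataframe().reset_index().to_csv(cross_csv, index=False)
    traj_csv = out / "trajectory.csv"
    traj.to_csv(traj_csv)
    zscores.to_csv(out / "model_zscores.csv")
    return {"crossing_nc": cross_nc, "crossing_csv": cross_csv, "trajectory": traj_csv}
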