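"""Monte-Carlo propagation of parameter and measurement uncertainty.

Every uncertain quantity in the isotope-to-physiology chain — the two
thermometry coefficients, the diet and DIC carbon end-members, ambient
water d18O, and the measured otolith values themselves — is redrawn from
independent normal distributions centred on its measured or central value
with sd = (full 95% width) / 3.92.  Thermometry coefficients are drawn once
per replicate and shared across all fish; measurement-level values are
redrawn per fish per replicate.  Replicate 0 is the central, noise-free
pass, so the ensemble always contains the deterministic pipeline output.

The per-individual 95% confidence-interval widths summarised by
:func:`individual_ci_widths` are empirical quantile ranges across the noisy
replicates; :func:`delta_method_sd` provides the independent first-order
analytic propagation used for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CarbonParams, McConfig, ParameterSet, ThermometryParams
from . import proxies

ENSEMBLE_COLUMNS = ["sample_id", "replicate", "temperature", "c_resp"]


@dataclass(frozen=True)
class ReplicateEnsemble:
    """Long-format replicate ensemble plus the per-replicate drawn coefficients.

    ``estimates`` has one row per (sample_id, replicate) with columns
    ``temperature`` and ``c_resp``; replicate 0 holds central values.
    ``drawn_params`` records the shared thermometry (a, b) pair per replicate.
    """

    estimates: pd.DataFrame
    drawn_params: pd.DataFrame

    @property
    def n_replicates(self) -> int:
        """Number of noisy replicates (excluding the central replicate 0)."""
        return int(self.estimates["replicate"].max())

    def noisy(self) -> pd.DataFrame:
        return self.estimates[self.estimates["replicate"] > 0]

    def central(self) -> pd.DataFrame:
        return self.estimates[self.estimates["replicate"] == 0]

    def to_csv(self, path) -> None:
        """Write the long-format (sample_id, replicate, temperature, c_resp) table."""
        self.estimates[ENSEMBLE_COLUMNS].to_csv(path, index=False)


def run_monte_carlo(
    records: pd.DataFrame,
    params: ParameterSet | None = None,
    cfg: McConfig | None = None,
    *,
    unknown_origin_water: float | None = None,
) -> ReplicateEnsemble:
    """Propagate all parameter and measurement uncertainty for a record table.

    Parameters
    ----------
    records : DataFrame
        Canonical per-fish table (see :mod:`otofmr.proxies`).
    params : ParameterSet
        Central values and 95% widths for every uncertain quantity.
    cfg : McConfig
        Replicate count, seed, width-to-sd divisor and draw granularity.
    unknown_origin_water : float, optional
        Central d18O_water to assume for ``unknown``-origin fish; without it
        such records are an error.

    Notes
    -----
    One root seed spawns independent per-replicate substreams, so replicate
    k is reproducible in isolation and the ensemble is identical for a
    fixed seed regardless of execution order.
    """
    params = params or ParameterSet()
    cfg = cfg or McConfig()
    records = proxies.validate_records(records)
    carbon = params.carbon
    therm = params.thermometry
    n = len(records)
    if n == 0:
        raise ValueError("no records supplied")

    water_central = proxies.origin_water_values(
        records["origin"], carbon, default=unknown_origin_water
    )
    d13c_meas = records["d13C_oto"].to_numpy(dtype=float)
    d18o_meas = records["d18O_oto"].to_numpy(dtype=float)
    birth = records["birth_year"].to_numpy(dtype=float)
    ids = records["sample_id"].to_numpy()

    k = cfg.width_to_sd
    sd = {
        "a": therm.ci_a / k,
        "b": therm.ci_b / k,
        "diet": carbon.ci_d13C_diet / k,
        "dic": carbon.ci_d13C_DIC / k,
        "water": carbon.ci_d18O_water / k,
        "d13c": carbon.ci_d13C_oto / k,
        "d18o": carbon.ci_d18O_oto / k,
    }

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)

    frames = []
    drawn = []
    # replicate 0: central, no noise
    central = proxies.central_estimates(records, params) if unknown_origin_water is None else None
    if central is None:
        d13c_adj = proxies.suess_adjust(d13c_meas, birth, carbon.suess_rate, carbon.suess_ref_year)
        c0 = proxies.c_resp_from_d13C(d13c_adj, carbon.d13C_diet, carbon.d13C_DIC, carbon.epsilon_frac)
        t0 = proxies.temperature_from_d18O(d18o_meas, water_central, therm)
    else:
        t0 = central["temperature"].to_numpy()
        c0 = central["c_resp"].to_numpy()
    frames.append(
        pd.DataFrame({"sample_id": ids, "replicate": 0, "temperature": t0, "c_resp": c0})
    )
    drawn.append({"replicate": 0, "intercept_a": therm.intercept_a, "slope_b": therm.slope_b})

    for r, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        if cfg.shared_coefficients:
            a = rng.normal(therm.intercept_a, sd["a"])
            b = rng.normal(therm.slope_b, sd["b"])
        else:
            a = rng.normal(therm.intercept_a, sd["a"], size=n)
            b = rng.normal(therm.slope_b, sd["b"], size=n)
        src_size = n if cfg.per_fish_sources else None
        diet = rng.normal(carbon.d13C_diet, sd["diet"], size=src_size)
        dic = rng.normal(carbon.d13C_DIC, sd["dic"], size=src_size)
        water = rng.normal(water_central, sd["water"])
        d13c = rng.normal(d13c_meas, sd["d13c"])
        d18o = rng.normal(d18o_meas, sd["d18o"])

        d13c_adj = proxies.suess_adjust(d13c, birth, carbon.suess_rate, carbon.suess_ref_year)
        c_resp = proxies.c_resp_from_d13C(d13c_adj, diet, dic, carbon.epsilon_frac)
        temp = proxies.temperature_from_d18O(d18o, water, intercept_a=a, slope_b=b)
        frames.append(
            pd.DataFrame(
                {"sample_id": ids, "replicate": r, "temperature": temp, "c_resp": c_resp}
            )
        )
        drawn.append(
            {
                "replicate": r,
                "intercept_a": float(np.mean(a)),
                "slope_b": float(np.mean(b)),
            }
        )

    estimates = pd.concat(frames, ignore_index=True)
    return ReplicateEnsemble(estimates=estimates, drawn_params=pd.DataFrame(drawn))


def individual_ci_widths(ens: ReplicateEnsemble, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-fish empirical CI widths across noisy replicates, plus dataset means.

    Width = upper minus lower empirical quantile at (1 ± ci_level)/2 with
    linear interpolation.  The dataset means are attached as DataFrame
    ``attrs`` (``mean_temperature_width``, ``mean_c_resp_width``).
    """
    noisy = ens.noisy()
    n_rep = noisy["replicate"].nunique()
    if n_rep < 2:
        raise ValueError("at least 2 noisy replicates are required for CI widths")
    lo, hi = (1 - ci_level) / 2, (1 + ci_level) / 2

    def width(g: pd.Series) -> float:
        q = np.quantile(g.to_numpy(), [lo, hi])
        return float(q[1] - q[0])

    grouped = noisy.groupby("sample_id", sort=False)
    out = pd.DataFrame(
        {
            "temperature_width": grouped["temperature"].apply(width),
            "c_resp_width": grouped["c_resp"].apply(width),
        }
    ).reset_index()
    out.attrs["mean_temperature_width"] = float(out["temperature_width"].mean())
    out.attrs["mean_c_resp_width"] = float(out["c_resp_width"].mean())
    return out


def delta_method_sd(
    d13C_oto: float,
    temperature: float,
    params: ParameterSet | None = None,
    origin: str = "med",
    width_to_sd: float = 3.92,
) -> dict[str, float]:
    """First-order analytic propagation of all input uncertainties.

    Independent oracle for the Monte-Carlo widths: returns the analytic
    standard deviations of C_resp and temperature for one fish, from the
    partial derivatives of the mass balance and thermometry equations.
    """
    params = params or ParameterSet()
    carbon, therm = params.carbon, params.thermometry
    k = width_to_sd
    # carbon mass balance f = 1 - (D - C)/(D - I): D diet, I DIC, C (Suess-adjusted) oto
    D, I = carbon.d13C_diet, carbon.d13C_DIC
    u = D - d13C_oto
    v = D - I
    dC = 1.0 / v
    dD = -(v - u) / v**2
    dI = -u / v**2
    var_c = (
        (dC * carbon.ci_d13C_oto / k) ** 2
        + (dD * carbon.ci_d13C_diet / k) ** 2
        + (dI * carbon.ci_d13C_DIC / k) ** 2
    )
    # thermometry T = (delta - a)/b
    b = therm.slope_b
    dO = 1.0 / b
    dW = -1.0 / b
    da = -1.0 / b
    db = -temperature / b
    var_t = (
        (dO * carbon.ci_d18O_oto / k) ** 2
        + (dW * carbon.ci_d18O_water / k) ** 2
        + (da * therm.ci_a / k) ** 2
        + (db * therm.ci_b / k) ** 2
    )
    return {"c_resp_sd": float(np.sqrt(var_c)), "temperature_sd": float(np.sqrt(var_t))}
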