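"""Deterministic conversions between otolith isotope values and physiology.

Two proxies anchor the chain:

* **Temperature** from the oxygen isotope composition of otolith aragonite,
  via the linear thermometry relationship
  ``d18O_oto - d18O_water = a + b * T`` (a = 5.193 ‰, b = -0.27 ‰/°C), so
  ``T = ((d18O_oto - d18O_water) - a) / b``.

* **C_resp**, the proportion of respiratory (diet-derived) carbon in the
  otolith, from a two-end-member carbon mass balance between diet and
  dissolved inorganic carbon (DIC):
  ``C_resp = 1 - (d13C_diet - d13C_oto) / (d13C_diet - d13C_DIC)``.
  C_resp is a dimensionless fraction used as a field-metabolic-rate proxy.

Measured d13C_oto values are first standardised to a reference year with a
linear Suess-effect correction.  All functions are vectorised over numpy
arrays and validate their inputs; out-of-range C_resp values (outside
[0, 1]) are reported by :func:`flag_out_of_range`, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import CarbonParams, ThermometryParams

AGE_GROUPS = ("age0", "yearling", "post2yr_3month", "post2yr")
ORIGINS = ("west", "med", "unknown")

#: canonical column names of the per-fish input table
RECORD_COLUMNS = [
    "sample_id",
    "age_group",
    "origin",
    "capture_region",
    "birth_year",
    "d13C_oto",
    "d18O_oto",
]


@dataclass(frozen=True)
class OtolithRecord:
    """One fish's measured otolith isotope values plus metadata."""

    sample_id: str
    age_group: str
    origin: str
    capture_region: str
    birth_year: int
    d13C_oto: float
    d18O_oto: float

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}")
        if not -20.0 <= self.d13C_oto <= 5.0:
            raise ValueError(f"d13C_oto {self.d13C_oto} outside [-20, 5] ‰")
        if not -10.0 <= self.d18O_oto <= 5.0:
            raise ValueError(f"d18O_oto {self.d18O_oto} outside [-10, 5] ‰")
        if not 1950 <= self.birth_year <= 2100:
            raise ValueError(f"birth_year {self.birth_year} outside [1950, 2100]")


def _check_finite(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def temperature_from_d18O(
    d18O_oto,
    d18O_water,
    therm: ThermometryParams | None = None,
    *,
    intercept_a: float | None = None,
    slope_b: float | None = None,
):
    """Infer otolith growth temperature (°C) from oxygen isotope values.

    Inverts ``d18O_oto - d18O_water = a + b*T``.  With the default
    coefficients this is ``T = (5.193 - (d18O_oto - d18O_water)) / 0.27``.

    Parameters
    ----------
    d18O_oto, d18O_water : array-like
        Otolith and ambient-water d18O in ‰ VPDB.
    therm : ThermometryParams, optional
        Thermometry coefficients; defaults to the Pacific-bluefin-derived
        relationship.  ``intercept_a``/``slope_b`` override individually
        (used by the Monte-Carlo driver with drawn coefficients).
    """
    if therm is None:
        therm = ThermometryParams()
    a = therm.intercept_a if intercept_a is None else intercept_a
    b = therm.slope_b if slope_b is None else slope_b
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr == 0):
        raise ValueError("thermometry slope must be non-zero")
    oto = _check_finite("d18O_oto", d18O_oto)
    water = _check_finite("d18O_water", d18O_water)
    delta = oto - water
    t = (delta - a) / b_arr
    return float(t) if np.ndim(t) == 0 else t


def d18O_from_temperature(temperature, d18O_water, therm: ThermometryParams | None = None):
    """Forward thermometry: noise-free d18O_oto for a known temperature."""
    if therm is None:
        therm = ThermometryParams()
    t = _check_finite("temperature", temperature)
    water = _check_finite("d18O_water", d18O_water)
    out = water + therm.intercept_a + therm.slope_b * t
    return float(out) if np.ndim(out) == 0 else out


def c_resp_from_d13C(
    d13C_oto,
    d13C_diet: float = CarbonParams.d13C_diet,
    d13C_DIC: float = CarbonParams.d13C_DIC,
    epsilon_frac: float = 0.0,
):
    """Proportion of respiratory carbon in otolith aragonite (two-source mixing).

    ``C_resp = 1 - (d13C_diet - (d13C_oto - epsilon_frac)) / (d13C_diet - d13C_DIC)``.

    With ``epsilon_frac = 0`` this is the plain mass balance: 0 when the
    otolith carries pure DIC carbon, 1 when pure diet carbon.  Values may
    fall outside [0, 1] for extreme inputs; they are returned as-is.
    """
    diet = np.asarray(d13C_diet, dtype=float)
    dic = np.asarray(d13C_DIC, dtype=float)
    if np.any(diet == dic):
        raise ValueError(
            "d13C_diet equals d13C_DIC: mixing proportions are unidentifiable"
        )
    oto = _check_finite("d13C_oto", d13C_oto)
    out = 1.0 - (diet - (oto - epsilon_frac)) / (diet - dic)
    return float(out) if np.ndim(out) == 0 else out


def d13C_from_c_resp(
    c_resp,
    d13C_diet: float = CarbonParams.d13C_diet,
    d13C_DIC: float = CarbonParams.d13C_DIC,
    epsilon_frac: float = 0.0,
):
    """Inverse mass balance: otolith d13C implied by a C_resp fraction."""
    if d13C_diet == d13C_DIC:
        raise ValueError("d13C_diet equals d13C_DIC")
    c = _check_finite("c_resp", c_resp)
    oto = d13C_diet - (1.0 - c) * (d13C_diet - d13C_DIC) + epsilon_frac
    return float(oto) if np.ndim(oto) == 0 else oto


def suess_adjust(
    d13C_oto,
    birth_year,
    suess_rate: float = CarbonParams.suess_rate,
    ref_year: int = CarbonParams.suess_ref_year,
):
    """Standardise measured d13C_oto to ``ref_year`` for the oceanic Suess effect.

    Adds ``suess_rate * (ref_year - birth_year)``: with the default negative
    rate, earlier-born fish are corrected downward toward the reference-year
    DIC baseline.  Composes additively over year splits.
    """
    year = np.asarray(birth_year, dtype=float)
    if np.any(year > ref_year):
        raise ValueError("birth_year must not exceed the Suess reference year")
    oto = _check_finite("d13C_oto", d13C_oto)
    out = oto + suess_rate * (ref_year - year)
    return float(out) if np.ndim(out) == 0 else out


def c_resp_to_mo2(c_resp, calib_slope: Optional[float] = None, calib_intercept: Optional[float] = None):
    """Convert C_resp to oxygen consumption rate (mg O2 kg^-1 h^-1).

    The conversion is a species-specific linear calibration that must be
    supplied explicitly — there is no defensible default, so missing
    coefficients raise rather than silently assuming identity.
    """
    if calib_slope is None or calib_intercept is None:
        raise ValueError(
            "c_resp_to_mo2 requires explicit calib_slope and calib_intercept; "
            "no default calibration is assumed"
        )
    c = _check_finite("c_resp", c_resp)
    out = calib_intercept + calib_slope * c
    return float(out) if np.ndim(out) == 0 else out


def flag_out_of_range(c_resp, low: float = 0.0, high: float = 1.0) -> np.ndarray:
    """Boolean mask of C_resp values outside the physically meaningful band."""
    c = np.asarray(c_resp, dtype=float)
    return (c < low) | (c > high)


def central_estimates(records: pd.DataFrame, params=None) -> pd.DataFrame:
    """Deterministic per-fish temperature and C_resp from measured values.

    This is the replicate-0 (no-noise) pass of the Monte-Carlo scheme:
    Suess-adjust d13C_oto by birth year, then apply the carbon mass balance
    and the thermometry equation with central parameter values.

    Parameters
    ----------
    records : DataFrame
        Canonical record table (see :data:`RECORD_COLUMNS`).
    params : ParameterSet, optional

    Returns
    -------
    DataFrame with columns sample_id, temperature, c_resp, c_resp_flagged.
    """
    from .params import ParameterSet

    if params is None:
        params = ParameterSet()
    records = validate_records(records)
    carbon = params.carbon
    water = origin_water_values(records["origin"], carbon)
    d13c = suess_adjust(
        records["d13C_oto"].to_numpy(),
        records["birth_year"].to_numpy(),
        carbon.suess_rate,
        carbon.suess_ref_year,
    )
    c_resp = c_resp_from_d13C(d13c, carbon.d13C_diet, carbon.d13C_DIC, carbon.epsilon_frac)
    temp = temperature_from_d18O(records["d18O_oto"].to_numpy(), water, params.thermometry)
    return pd.DataFrame(
        {
            "sample_id": records["sample_id"].to_numpy(),
            "temperature": temp,
            "c_resp": c_resp,
            "c_resp_flagged": flag_out_of_range(c_resp),
        }
    )


def origin_water_values(origin: pd.Series, carbon: CarbonParams, default: float | None = None) -> np.ndarray:
    """Per-fish central d18O_water chosen by origin.

    ``unknown`` origins take ``default`` when given; otherwise they raise,
    identifying the offending samples.
    """
    origin = origin.astype(str)
    water = np.where(origin == "west", carbon.d18O_water_west, carbon.d18O_water_med)
    unknown = ~origin.isin(["west", "med"])
    if unknown.any():
        if default is None:
            bad = origin.index[unknown].tolist()[:10]
            raise ValueError(
                f"records at index {bad} have unknown origin and no default "
                "d18O_water was supplied"
            )
        water = np.where(unknown, default, water)
    return water.astype(float)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical schema and physical ranges of a record table."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table is missing columns: {missing}")
    df = df.copy()
    df["birth_year"] = df["birth_year"].astype(int)
    for col in ("d13C_oto", "d18O_oto"):
        df[col] = pd.to_numeric(df[col])
        if df[col].isna().any():
            raise ValueError(f"column {col} contains missing values")
    if not df["age_group"].isin(AGE_GROUPS).all():
        bad = sorted(set(df["age_group"]) - set(AGE_GROUPS))
        raise ValueError(f"unrecognised age_group values: {bad}")
    if not df["origin"].isin(ORIGINS).all():
        bad = sorted(set(df["origin"]) - set(ORIGINS))
        raise ValueError(f"unrecognised origin values: {bad}")
    checks = {
        "d13C_oto": (-20.0, 5.0),
        "d18O_oto": (-10.0, 5.0),
        "birth_year": (1950, 2100),
    }
    for col, (lo, hi) in checks.items():
        out = ~df[col].between(lo, hi)
        if out.any():
            raise ValueError(
                f"{int(out.sum())} records have {col} outside [{lo}, {hi}]"
            )
    return df


def read_records(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-fish isotope CSV into the canonical schema.

    ``column_map`` maps canonical names to the file's headers so externally
    deposited tables can be ingested without code changes, e.g.
    ``{"d13C_oto": "d13C", "sample_id": "fish_id"}``.  ‰ values are plain
    decimals; empty fields are missing values (rejected by validation).
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canonical for canonical, src in column_map.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise ValueError(f"mapped source columns absent from file: {missing_src}")
        df = df.rename(columns=rename)
    return validate_records(df[[c for c in RECORD_COLUMNS if c in df.columns]])
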