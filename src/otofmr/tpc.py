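"""Thermal performance curves for otolith-inferred field metabolic rate.

Population-level statistics relating C_resp (the FMR proxy) to experienced
temperature:

* :class:`QuadraticThermalModel` — ordinary least squares with a quadratic
  term; its vertex estimates the limiting temperature T_lim when the
  curvature is concave and the vertex lies inside the data range.
* :class:`SegmentedThermalModel` — continuous two-segment regression
  ``y = b0 + b1*T + b2*(T - psi)_+`` with the breakpoint psi profiled over
  an RSS grid and locally refined; the breakpoint is the alternative T_lim
  estimate and the two slopes give the thermal sensitivity of FMR either
  side of it.
* :func:`davies_test` — upper bound on the p-value for a non-zero
  difference-in-slope parameter when the breakpoint is unidentified under
  the null (tests whether the segmented model beats a simple line).
* :func:`modal_temperature` — kernel-density mode of experienced
  temperatures, the population preferred temperature T_pref.
* :func:`iqr_curve` — inter-quartile range of C_resp per integer-degree
  temperature bin, a field analogue of aerobic scope; its maximising bin
  lies between T_pref and T_lim in the study system.
* :func:`summarize_replicates` — across-Monte-Carlo-replicate means, sds
  and z-scored curves.

Both model classes follow the scikit-learn estimator contract (``fit`` /
``predict``, ``get_params``/``set_params``, fitted attributes with trailing
underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from sklearn.base import BaseEstimator, RegressorMixin


def _as_xy(temps, cresp=None):
    t = np.asarray(temps, dtype=float).ravel()
    if cresp is None:
        return t
    y = np.asarray(cresp, dtype=float).ravel()
    if t.shape != y.shape:
        raise ValueError("temperature and c_resp vectors differ in length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    return t, y


def _column_of(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("estimators expect a single temperature feature")
        return X[:, 0]
    return X.ravel()


class QuadraticThermalModel(BaseEstimator, RegressorMixin):
    """OLS fit of ``c_resp = c0 + c1*T + c2*T**2``.

    Fitted attributes
    -----------------
    coef_ : ndarray (c0, c1, c2)
    vertex_ : float
        ``-c1 / (2*c2)``; nan when c2 == 0.
    vertex_interior_ : bool
        True only when the parabola opens downward (c2 < 0) and the vertex
        lies within the fitted temperature range.
    rss_ : float
    """

    def fit(self, X, y):
        t = _column_of(X)
        t, y = _as_xy(t, y)
        if t.size < 4:
            raise ValueError("quadratic fit needs at least 4 observations")
        if np.var(t) == 0:
            raise ValueError("temperature has zero variance: design is degenerate")
        design = np.column_stack([np.ones_like(t), t, t**2])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("degenerate (collinear) design for quadratic fit")
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef
        resid = y - design @ coef
        self.rss_ = float(resid @ resid)
        self.n_ = t.size
        self.t_range_ = (float(t.min()), float(t.max()))
        c0, c1, c2 = coef
        self.vertex_ = float(-c1 / (2 * c2)) if c2 != 0 else float("nan")
        self.vertex_interior_ = bool(
            c2 < 0 and np.isfinite(self.vertex_) and self.t_range_[0] <= self.vertex_ <= self.t_range_[1]
        )
        return self

    def predict(self, X):
        t = _column_of(X)
        c0, c1, c2 = self.coef_
        return c0 + c1 * t + c2 * t**2


def _segmented_design(t: np.ndarray, psi: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - psi, 0.0)])


def _segmented_rss(t: np.ndarray, y: np.ndarray, psi: float):
    X = _segmented_design(t, psi)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


class SegmentedThermalModel(BaseEstimator, RegressorMixin):
    """Continuous two-segment linear regression with unknown breakpoint.

    ``c_resp = b0 + b1*T + b2*(T - psi)_+`` fitted by profiling the residual
    sum of squares over candidate breakpoints on a grid spanning the
    [5th, 95th] temperature percentiles (default step 0.05 °C), followed by
    bounded local refinement.  Deterministic: no random restarts.

    Parameters
    ----------
    grid_step : float
        Breakpoint grid spacing in °C.
    min_side : int
        Minimum number of distinct temperatures required on each side of an
        admissible breakpoint.

    Fitted attributes
    -----------------
    breakpoint_ : float or nan
        Estimated psi; nan when no interior RSS minimum exists (the model
        collapses to a simple line and ``has_breakpoint_`` is False).
    slope_low_, slope_high_ : float
        b1 and b1 + b2.
    rss_, rss_linear_ : float
        Segmented and simple-linear residual sums of squares.
    """

    def __init__(self, grid_step: float = 0.05, min_side: int = 3):
        self.grid_step = grid_step
        self.min_side = min_side

    def fit(self, X, y):
        t = _column_of(X)
        t, y = _as_xy(t, y)
        if t.size < 10:
            raise ValueError("segmented fit needs at least 10 observations")
        uniq = np.unique(t)
        lo, hi = np.percentile(t, [5, 95])

        # linear baseline
        Xlin = np.column_stack([np.ones_like(t), t])
        coef_lin, _, _, _ = np.linalg.lstsq(Xlin, y, rcond=None)
        resid = y - Xlin @ coef_lin
        self.rss_linear_ = float(resid @ resid)
        self.coef_linear_ = coef_lin
        self.n_ = t.size
        self.t_range_ = (float(t.min()), float(t.max()))

        grid = np.arange(lo, hi + self.grid_step / 2, self.grid_step)
        # admissibility: enough distinct temperatures strictly on each side
        admissible = np.array(
            [
                (np.sum(uniq < p) >= self.min_side) and (np.sum(uniq > p) >= self.min_side)
                for p in grid
            ]
        )
        grid = grid[admissible]
        if grid.size == 0:
            self._collapse_to_linear()
            return self

        rss = np.array([_segmented_rss(t, y, p)[0] for p in grid])
        i = int(np.argmin(rss))
        # require an interior minimum of the RSS profile
        if i == 0 or i == rss.size - 1:
            interior = rss[i] < self.rss_linear_ - 1e-12
            if not interior:
                self._collapse_to_linear()
                return self
        left = grid[max(i - 1, 0)]
        right = grid[min(i + 1, grid.size - 1)]
        if right > left:
            res = optimize.minimize_scalar(
                lambda p: _segmented_rss(t, y, p)[0],
                bounds=(left, right),
                method="bounded",
                options={"xatol": 1e-6},
            )
            psi = float(res.x)
            if _segmented_rss(t, y, psi)[0] > rss[i]:
                psi = float(grid[i])
        else:
            psi = float(grid[i])

        rss_best, coef = _segmented_rss(t, y, psi)
        # no genuine improvement over the straight line -> no breakpoint
        if self.rss_linear_ - rss_best <= 1e-10 * max(self.rss_linear_, 1e-300):
            self._collapse_to_linear()
            return self
        self.breakpoint_ = psi
        self.coef_ = coef
        self.slope_low_ = float(coef[1])
        self.slope_high_ = float(coef[1] + coef[2])
        self.rss_ = rss_best
        self.has_breakpoint_ = True
        return self

    def _collapse_to_linear(self) -> None:
        self.breakpoint_ = float("nan")
        self.coef_ = np.array([self.coef_linear_[0], self.coef_linear_[1], 0.0])
        self.slope_low_ = float(self.coef_linear_[1])
        self.slope_high_ = float(self.coef_linear_[1])
        self.rss_ = self.rss_linear_
        self.has_breakpoint_ = False

    def predict(self, X):
        t = _column_of(X)
        b0, b1, b2 = self.coef_
        psi = self.breakpoint_ if np.isfinite(self.breakpoint_) else np.inf
        return b0 + b1 * t + b2 * np.maximum(t - psi, 0.0)


@dataclass(frozen=True)
class ThermalPerformanceFit:
    """Combined quadratic + segmented fit of one (temperature, C_resp) sample."""

    quad_coeffs: tuple
    vertex_T: float
    vertex_interior: bool
    breakpoint_T: float
    slope_low: float
    slope_high: float
    davies_p: float
    rss_segmented: float
    rss_linear: float
    n: int


def fit_quadratic(temps, cresp) -> QuadraticThermalModel:
    """Fit the quadratic thermal performance model (thin estimator wrapper)."""
    t, y = _as_xy(temps, cresp)
    return QuadraticThermalModel().fit(t[:, None], y)


def fit_segmented(temps, cresp, grid_step: float = 0.05) -> SegmentedThermalModel:
    """Fit the two-segment breakpoint model (thin estimator wrapper)."""
    t, y = _as_xy(temps, cresp)
    return SegmentedThermalModel(grid_step=grid_step).fit(t[:, None], y)


def fit_thermal_performance(temps, cresp, grid_step: float = 0.05, k_points: int = 10) -> ThermalPerformanceFit:
    """Quadratic and segmented fits plus the Davies' test, in one record."""
    t, y = _as_xy(temps, cresp)
    quad = fit_quadratic(t, y)
    seg = fit_segmented(t, y, grid_step=grid_step)
    p = davies_test(t, y, k_points=k_points)
    return ThermalPerformanceFit(
        quad_coeffs=tuple(float(c) for c in quad.coef_),
        vertex_T=quad.vertex_,
        vertex_interior=quad.vertex_interior_,
        breakpoint_T=seg.breakpoint_,
        slope_low=seg.slope_low_,
        slope_high=seg.slope_high_,
        davies_p=p,
        rss_segmented=seg.rss_,
        rss_linear=seg.rss_linear_,
        n=t.size,
    )


def davies_test(temps, cresp, k_points: int = 10) -> float:
    """Davies' upper bound on the p-value for a non-zero difference in slope.

    At ``k_points`` equally spaced candidate breakpoints between the 10th
    and 90th temperature percentiles, fits ``y = b0 + b1*T + b2*(T-psi)_+``
    and forms the Wald statistic ``S = b2 / se(b2)``.  The bound for the
    supremum of |S| follows Davies (1987):

        p <= 2 * [ Phi(-M) + V * exp(-M**2 / 2) / sqrt(8*pi) ]

    with M = max |S_i| and V the total variation sum |S_{i+1} - S_i|.  The
    bound is conservative: under a true straight-line model the rejection
    rate at level alpha stays at or below alpha.
    """
    t, y = _as_xy(temps, cresp)
    if t.size < 10:
        raise ValueError("Davies' test needs at least 10 observations")
    if np.var(t) == 0 or np.var(y) == 0:
        raise ValueError("degenerate variance: Davies' test undefined")
    lo, hi = np.percentile(t, [10, 90])
    if hi <= lo:
        raise ValueError("interior temperature range is empty")
    psis = np.linspace(lo, hi, k_points)
    stats_i = np.empty(k_points)
    for j, psi in enumerate(psis):
        X = _segmented_design(t, psi)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            stats_i[j] = 0.0
            continue
        resid = y - X @ coef
        dof = t.size - 3
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[2, 2])
        stats_i[j] = coef[2] / se if se > 0 else 0.0
    m = float(np.max(np.abs(stats_i)))
    v = float(np.sum(np.abs(np.diff(stats_i))))
    p_one = stats.norm.sf(m) + v * np.exp(-(m**2) / 2.0) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, 2.0 * p_one))


def modal_temperature(temps, grid_step: float = 0.1) -> float:
    """Population preferred temperature: mode of a Gaussian KDE of temperatures.

    Silverman-bandwidth KDE evaluated on a regular ``grid_step`` grid over
    the data range.  Needs n >= 30 for a stable density; for smaller
    samples use a histogram mode instead.
    """
    t = _as_xy(temps)
    if t.size < 30:
        raise ValueError(
            "modal_temperature needs >= 30 observations; "
            "use a histogram mode for smaller samples"
        )
    if np.ptp(t) == 0:
        return float(t[0])
    kde = stats.gaussian_kde(t, bw_method="silverman")
    grid = np.arange(t.min(), t.max() + grid_step / 2, grid_step)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def iqr_curve(temps, cresp, min_n: int = 15) -> pd.DataFrame:
    """IQR of C_resp per integer-degree temperature bin.

    Temperatures are rounded half-away-from-zero to the nearest integer °C;
    only bins with strictly more than ``min_n`` observations are retained.
    The returned frame (columns ``t_bin``, ``iqr``, ``n``) carries
    ``attrs["t_iqr_max"]`` — the bin of maximal IQR, ties broken toward the
    lower temperature — or nan when no bin qualifies.
    """
    t, y = _as_xy(temps, cresp)
    bins = np.sign(t) * np.floor(np.abs(t) + 0.5)
    df = pd.DataFrame({"t_bin": bins.astype(int), "c": y})
    rows = []
    for b, g in df.groupby("t_bin"):
        if len(g) > min_n:
            q1, q3 = np.percentile(g["c"], [25, 75])
            rows.append({"t_bin": int(b), "iqr": float(q3 - q1), "n": int(len(g))})
    curve = pd.DataFrame(rows, columns=["t_bin", "iqr", "n"])
    if len(curve):
        best = curve.loc[curve["iqr"] == curve["iqr"].max(), "t_bin"].min()
        curve.attrs["t_iqr_max"] = float(best)
    else:
        curve.attrs["t_iqr_max"] = float("nan")
    return curve


SUMMARY_METRICS = ["t_pref", "t_iqr_max", "vertex_T", "breakpoint_T", "slope_low", "slope_high"]


def summarize_replicates(per_replicate: pd.DataFrame, curves: dict[str, pd.DataFrame] | None = None):
    """Across-replicate mean and sd of the thermal-performance metrics.

    Parameters
    ----------
    per_replicate : DataFrame
        One row per Monte-Carlo replicate with any subset of
        :data:`SUMMARY_METRICS` as columns.
    curves : mapping name -> DataFrame(grid, value), optional
        Curves (temperature density, mean C_resp, IQR) on a common grid;
        each is z-scored (mean 0, sd 1 over its grid) in the output.

    Returns
    -------
    summary : DataFrame with rows mean / sd, and optionally a dict of
    z-scored curves.
    """
    if len(per_replicate) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    cols = [c for c in SUMMARY_METRICS if c in per_replicate.columns]
    summary = pd.DataFrame(
        {c: [per_replicate[c].mean(), per_replicate[c].std(ddof=1)] for c in cols},
        index=["mean", "sd"],
    )
    if curves is None:
        return summary
    zcurves = {}
    for name, cur in curves.items():
        vals = np.asarray(cur.iloc[:, 1], dtype=float)
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        zcurves[name] = pd.DataFrame({cur.columns[0]: cur.iloc[:, 0], "z": z})
    return summary, zcurves
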