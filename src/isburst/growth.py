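"""Two-phase growth analysis of OD time series.

Dense batch cultures of cyanobacteria typically grow exponentially until
light/carbon limitation, then linearly. The analysis here segments a curve at
the breakpoint minimizing the summed squared error of a two-parameter
exponential fit (log-linear OLS of log OD on time) before the break and a
two-parameter linear OLS fit after it, then compares evolved populations to
the ancestor with a one-tailed t test and regresses linear growth rate on
fixed-insertion counts (Pearson R, F = R^2 (n-2) / (1 - R^2) on df (1, n-2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthFit:
    phase: str                  # 'exponential' or 'linear'
    params: dict[str, float]    # exponential: a, r; linear: b, m
    stderr: dict[str, float]
    r_squared: float
    window: tuple[float, float]
    n_points: int
    degenerate: bool = False


@dataclass
class RegressionResult:
    R: float
    F: float
    df: tuple[int, int]
    p: float
    slope: float
    slope_se: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """slope, intercept, se_slope, se_intercept, R^2 (two-parameter OLS)."""
    n = len(x)
    if n < 2 or np.var(x) == 0:
        raise ValueError("degenerate predictor: need >= 2 distinct x values")
    res = stats.linregress(x, y)
    ss_res = np.sum((y - (res.intercept + res.slope * x)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return res.slope, res.intercept, res.stderr, res.intercept_stderr, r2


def fit_exponential(od_series: pd.DataFrame, window: tuple[float, float] | None = None) -> GrowthFit:
    """Two-parameter exponential fit OD = a e^{rt} by OLS on log OD."""
    t, od = _window(od_series, window)
    if (od <= 0).any():
        bad = t[od <= 0]
        raise ValueError(f"non-positive OD at t={bad.tolist()}; cannot take log")
    slope, intercept, se_s, se_i, r2 = _ols(t, np.log(od))
    return GrowthFit(
        phase="exponential",
        params={"a": float(np.exp(intercept)), "r": float(slope)},
        stderr={"r": float(se_s), "log_a": float(se_i)},
        r_squared=float(r2),
        window=(float(t.min()), float(t.max())),
        n_points=len(t),
    )


def fit_linear(od_series: pd.DataFrame, window: tuple[float, float] | None = None) -> GrowthFit:
    """Two-parameter linear fit OD = b + m t by OLS."""
    t, od = _window(od_series, window)
    if len(t) < 4:
        raise ValueError("linear fit needs >= 4 points")
    slope, intercept, se_s, se_i, r2 = _ols(t, od)
    return GrowthFit(
        phase="linear",
        params={"b": float(intercept), "m": float(slope)},
        stderr={"m": float(se_s), "b": float(se_i)},
        r_squared=float(r2),
        window=(float(t.min()), float(t.max())),
        n_points=len(t),
    )


def _window(od_series: pd.DataFrame, window) -> tuple[np.ndarray, np.ndarray]:
    t = od_series["time_h"].to_numpy(dtype=float)
    od = od_series["od"].to_numpy(dtype=float)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, od = t[mask], od[mask]
    if len(t) == 0:
        raise ValueError("no points in window")
    return t, od


def segment_phases(od_series: pd.DataFrame, min_points: int = 4) -> tuple[float, bool]:
    """Breakpoint t* minimizing SSE(exponential on t <= t*) + SSE(linear on
    t >= t*) over observed timepoints with >= ``min_points`` per side (ties ->
    earliest). Returns (t*, degenerate) where degenerate marks an exponential
    segment with no positive curvature support (e.g. purely linear data fit
    at the earliest admissible break)."""
    t = od_series["time_h"].to_numpy(dtype=float)
    od = od_series["od"].to_numpy(dtype=float)
    if len(t) < 2 * min_points:
        raise ValueError(f"need >= {2 * min_points} timepoints to segment")
    order = np.argsort(t)
    t, od = t[order], od[order]

    best = (np.inf, None)
    for i in range(min_points - 1, len(t) - min_points):
        t_star = t[i]
        left = t <= t_star
        right = t >= t_star
        tl, odl = t[left], od[left]
        tr, odr = t[right], od[right]
        if len(tl) < min_points or len(tr) < min_points:
            continue
        if (odl <= 0).any():
            continue
        sl, il, *_ = _ols(tl, np.log(odl))
        sse_e = float(np.sum((odl - np.exp(il + sl * tl)) ** 2))
        sr, ir, *_ = _ols(tr, odr)
        sse_l = float(np.sum((odr - (ir + sr * tr)) ** 2))
        sse = sse_e + sse_l
        if sse < best[0] - 1e-15:
            best = (sse, t_star)
    if best[1] is None:
        raise ValueError("no admissible breakpoint (non-positive OD in every left segment)")
    t_star = float(best[1])
    exp_fit = fit_exponential(od_series, (t.min(), t_star))
    degenerate = exp_fit.params["r"] <= 0 or t_star <= t[min_points - 1]
    return t_star, degenerate


def fit_two_phase(od_series: pd.DataFrame) -> tuple[GrowthFit, GrowthFit, float]:
    """Segment and fit both phases; returns (exponential fit, linear fit, t*)."""
    t_star, degenerate = segment_phases(od_series)
    e = fit_exponential(od_series, (-np.inf, t_star))
    l = fit_linear(od_series, (t_star, np.inf))
    e.degenerate = degenerate
    return e, l, t_star


def compare_to_ancestor(
    evolved_rates: list[float] | np.ndarray,
    ancestor_rate: float | list[float],
    mode: str = "one-sample",
) -> dict:
    """One-tailed t test of evolved-population rates against the ancestor
    (alternative: evolved > ancestor).

    one-sample (default): t test of the evolved per-population means against
    the ancestor point estimate. welch: two-sample Welch t against ancestor
    replicate values.
    """
    evolved = np.asarray(evolved_rates, dtype=float)
    if len(evolved) < 2:
        raise ValueError("need >= 2 evolved values")
    if np.std(evolved, ddof=1) == 0:
        raise ValueError("zero variance among evolved values")
    if mode == "one-sample":
        anc = float(np.mean(np.atleast_1d(ancestor_rate)))
        res = stats.ttest_1samp(evolved, anc, alternative="greater")
        df = len(evolved) - 1
    elif mode == "welch":
        anc_vals = np.atleast_1d(np.asarray(ancestor_rate, dtype=float))
        if len(anc_vals) < 2:
            raise ValueError("welch mode needs ancestor replicate values")
        res = stats.ttest_ind(evolved, anc_vals, equal_var=False, alternative="greater")
        df = res.df
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": float(df), "mode": mode}


def regress_rate_on_fixed(
    linear_rates: list[float] | np.ndarray,
    fixed_counts: list[int] | np.ndarray,
) -> RegressionResult:
    """Pearson correlation of linear growth rate with fixed-insertion count;
    F = R^2 (n-2)/(1-R^2) on df (1, n-2) with its upper-tail p."""
    y = np.asarray(linear_rates, dtype=float)
    x = np.asarray(fixed_counts, dtype=float)
    n = len(y)
    if n < 3 or len(x) != n:
        raise ValueError("need matched samples with n >= 3")
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("fixed counts must be non-negative integers")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable")
    R = float(np.corrcoef(x, y)[0, 1])
    F = R**2 * (n - 2) / (1 - R**2) if abs(R) < 1 else np.inf
    p = float(stats.f.sf(F, 1, n - 2))
    lr = stats.linregress(x, y)
    return RegressionResult(
        R=R, F=float(F), df=(1, n - 2), p=p,
        slope=float(lr.slope), slope_se=float(lr.stderr), n=n,
    )


class TwoPhaseGrowthModel:
    """Model-object wrapper: build from an OD series, ``fit()`` returns a
    results object with both phase fits, the breakpoint and a summary."""

    def __init__(self, od_series: pd.DataFrame):
        if not {"time_h", "od"} <= set(od_series.columns):
            raise ValueError("od_series needs columns time_h, od")
        self.data = od_series.sort_values("time_h").reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_h", od_col: str = "od"):
        return cls(df.rename(columns={time_col: "time_h", od_col: "od"}))

    def fit(self) -> "TwoPhaseGrowthResults":
        e, l, t_star = fit_two_phase(self.data)
        return TwoPhaseGrowthResults(self, e, l, t_star)


class TwoPhaseGrowthResults:
    def __init__(self, model, exponential: GrowthFit, linear: GrowthFit, t_break: float):
        self.model = model
        self.exponential = exponential
        self.linear = linear
        self.t_break = t_break

    def summary(self) -> pd.DataFrame:
        rows = [
            {"phase": "exponential", "parameter": "r", "estimate": self.exponential.params["r"],
             "stderr": self.exponential.stderr["r"], "r_squared": self.exponential.r_squared,
             "n_points": self.exponential.n_points},
            {"phase": "exponential", "parameter": "a", "estimate": self.exponential.params["a"],
             "stderr": np.nan, "r_squared": self.exponential.r_squared,
             "n_points": self.exponential.n_points},
            {"phase": "linear", "parameter": "m", "estimate": self.linear.params["m"],
             "stderr": self.linear.stderr["m"], "r_squared": self.linear.r_squared,
             "n_points": self.linear.n_points},
            {"phase": "linear", "parameter": "b", "estimate": self.linear.params["b"],
             "stderr": self.linear.stderr["b"], "r_squared": self.linear.r_squared,
             "n_points": self.linear.n_points},
        ]
        df = pd.DataFrame(rows)
        df.attrs["t_break"] = self.t_break
        return df
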