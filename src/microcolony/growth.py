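"""Growth-model fitting, model selection, density-dependence inference and
hypothesis tests.

Supported regression models (least squares throughout, R^2 = 1 - SSres/SStot):

==================  ===========================================  =============
model               equation                                     parameters
==================  ===========================================  =============
linear              y = a + b x                                  a, b
exponential         y = N0 exp(r x)                              N0, r
saturating-exp      y = Ymax (1 - exp(-k x))                     Ymax, k
monod               y = Ymax x / (K + x)                         Ymax, K
logistic            y = K / (1 + ((K-N0)/N0) exp(-r x))          K, r, N0
semilog-linear      y = a + b log10(x)                           a, b
==================  ===========================================  =============

The doubling time of an exponential-family fit is ln 2 / r.  Nonlinear fits
use deterministic initializations: exponential r from the endpoint log-ratio,
logistic K from max(y) and r from the early log-linear phase, Monod/saturating
plateaus from max(y).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import assign_birth_bins
from .lineage import CellRecord

MODELS = ("linear", "exponential", "saturating-exponential", "monod", "logistic", "semilog-linear")

_N_PARAMS = {
    "linear": 2,
    "exponential": 2,
    "saturating-exponential": 2,
    "monod": 2,
    "logistic": 3,
    "semilog-linear": 2,
}


class FitError(RuntimeError):
    """A fit could not be computed at all (wrong input, unknown model)."""


@dataclass
class GrowthFit:
    """A fitted growth/regression model."""

    model: str
    params: dict[str, float]
    r2: float
    df_resid: int
    success: bool = True
    message: str = ""
    predict: callable = field(default=None, repr=False)

    @property
    def doubling_time_h(self) -> float:
        r = self.params.get("r", self.params.get("k", float("nan")))
        return math.log(2) / r if (r is not None and r > 0) else float("nan")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_growth_model(x, y, model: str) -> GrowthFit:
    """Least-squares fit of one named model.

    Closed form for linear and semilog-linear; nonlinear least squares for
    the rest.  Non-convergence is reported as ``success=False`` with a
    message, not raised.  SStot = 0 yields an undefined (NaN) R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if model not in MODELS:
        raise FitError(f"unknown model {model!r}")
    if len(x) < _N_PARAMS[model] + 1:
        raise FitError(f"{model} needs at least {_N_PARAMS[model] + 1} points")
    df_resid = len(x) - _N_PARAMS[model]

    try:
        if model == "linear":
            b, a = np.polyfit(x, y, 1)
            params = {"a": float(a), "b": float(b)}
            fn = lambda t, a=a, b=b: a + b * np.asarray(t, dtype=float)
        elif model == "semilog-linear":
            if np.any(x <= 0):
                raise FitError("semilog-linear requires positive x")
            lx = np.log10(x)
            b, a = np.polyfit(lx, y, 1)
            params = {"a": float(a), "b": float(b)}
            fn = lambda t, a=a, b=b: a + b * np.log10(np.asarray(t, dtype=float))
        elif model == "exponential":
            if np.any(y <= 0):
                # fall back on direct NLS with crude initialization
                r0, n0 = 0.1, max(y[0], 1e-6)
            else:
                span = x[-1] - x[0]
                r0 = (math.log(y[-1]) - math.log(y[0])) / span if span > 0 else 0.1
                n0 = y[0]
            f = lambda t, N0, r: N0 * np.exp(r * t)
            popt, _ = optimize.curve_fit(f, x, y, p0=[n0, r0], maxfev=10000)
            params = {"N0": float(popt[0]), "r": float(popt[1])}
            fn = lambda t, p=popt: f(np.asarray(t, dtype=float), *p)
        elif model == "saturating-exponential":
            f = lambda t, ymax, k: ymax * (1.0 - np.exp(-k * t))
            ymax0 = max(float(np.max(y)), 1e-9)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.clip(1.0 - y / (ymax0 * 1.05), 1e-6, 1.0)
            pos = x > 0
            k0 = float(np.median(-np.log(frac[pos]) / x[pos])) if pos.any() else 1.0
            popt, _ = optimize.curve_fit(f, x, y, p0=[ymax0, max(k0, 1e-6)], maxfev=10000)
            params = {"Ymax": float(popt[0]), "k": float(popt[1])}
            fn = lambda t, p=popt: f(np.asarray(t, dtype=float), *p)
        elif model == "monod":
            f = lambda t, ymax, K: ymax * t / (K + t)
            ymax0 = max(float(np.max(y)), 1e-9)
            half = 0.5 * ymax0
            above = np.flatnonzero(y >= half)
            K0 = float(x[above[0]]) if len(above) else float(np.median(x))
            popt, _ = optimize.curve_fit(
                f, x, y, p0=[ymax0, max(K0, 1e-6)],
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
            )
            params = {"Ymax": float(popt[0]), "K": float(popt[1])}
            fn = lambda t, p=popt: f(np.asarray(t, dtype=float), *p)
        else:  # logistic
            f = lambda t, K, r, N0: K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))
            K0 = float(np.max(y)) * 1.05
            ypos = np.clip(y, 1e-9, None)
            early = ypos <= 0.5 * K0
            if early.sum() >= 2:
                r0 = max(float(np.polyfit(x[early], np.log(ypos[early]), 1)[0]), 1e-3)
            else:
                r0 = 0.1
            N00 = max(float(ypos[0]), 1e-9)
            popt, _ = optimize.curve_fit(
                f, x, y, p0=[K0, r0, N00],
                bounds=([1e-9, 1e-9, 1e-12], [np.inf, np.inf, np.inf]), maxfev=20000,
            )
            params = {"K": float(popt[0]), "r": float(popt[1]), "N0": float(popt[2])}
            fn = lambda t, p=popt: f(np.asarray(t, dtype=float), *p)
    except FitError:
        raise
    except Exception as exc:  # curve_fit non-convergence and friends
        return GrowthFit(model, {}, float("nan"), df_resid, success=False, message=str(exc))

    return GrowthFit(model, params, _r2(y, fn(x)), df_resid, predict=fn)


def select_best_model(fits: list[GrowthFit]) -> GrowthFit:
    """The successful fit with the highest R^2; ties favor fewer parameters."""
    ok = [f for f in fits if f.success and np.isfinite(f.r2)]
    if not ok:
        raise FitError("all candidate fits failed")
    return max(ok, key=lambda f: (f.r2, -f.n_params))


# ---------------------------------------------------------------------------
# birth-time binning and density dependence
# ---------------------------------------------------------------------------

@dataclass
class BinSummary:
    """Median growth rate and mean chamber occupancy of one birth-time bin."""

    bin_lo_h: float
    bin_hi_h: float
    median_rate: float
    mean_count: float
    n_cells: int


def bin_growth_by_birth_time(
    records: list[CellRecord],
    counts: pd.DataFrame,
    edges,
) -> list[BinSummary]:
    """Per-bin median growth rate and mean sessile count.

    Cells are assigned to half-open birth-time bins ``[lo, hi)`` (last bin
    closed); the occupancy of a bin is the mean of the sessile-count series
    over the bin's time interval.  Empty bins are omitted.
    """
    edges = np.asarray(edges, dtype=float)
    births = np.array([r.birth_time for r in records])
    rates = np.array([r.growth_rate for r in records])
    idx = assign_birth_bins(births, edges)
    t = counts["time_h"].to_numpy()
    n = counts["n_sessile"].to_numpy()
    out: list[BinSummary] = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        lo, hi = edges[b], edges[b + 1]
        in_bin = (t >= lo) & (t < hi) if b < len(edges) - 2 else (t >= lo) & (t <= hi)
        mean_count = float(n[in_bin].mean()) if in_bin.any() else float("nan")
        out.append(
            BinSummary(
                float(lo),
                float(hi),
                float(np.median(rates[mask])),
                mean_count,
                int(mask.sum()),
            )
        )
    return out


def rate_density_slope(
    bins: list[BinSummary],
    method: str = "linear",
) -> float:
    """Change of growth rate with the number of cells present (1/h per cell).

    ``method='linear'`` (default) is the linear-regression slope of median
    rate on mean count; ``method='initial-derivative'`` fits the saturating
    Monod model and returns its derivative at n=0, Ymax/K, which tracks the
    reciprocal of the half-saturation cell number.
    """
    if len(bins) < 3:
        raise FitError("need at least 3 bins for a slope")
    x = np.array([b.mean_count for b in bins])
    y = np.array([b.median_rate for b in bins])
    if method == "linear":
        return float(np.polyfit(x, y, 1)[0])
    if method == "initial-derivative":
        fit = fit_growth_model(x, y, "monod")
        if not fit.success:
            raise FitError(f"monod fit failed: {fit.message}")
        return fit.params["Ymax"] / fit.params["K"]
    raise ValueError(f"unknown slope method {method!r}")


def instantaneous_rate_vs_count(table: pd.DataFrame) -> pd.DataFrame:
    """Per-frame chamber growth rate paired with the cell count at that frame.

    For each consecutive frame pair the rate is the median log-area increment
    per hour over cells present in both frames that did not divide in
    between (divisions halve the segmented area; increments outside
    ln(0.7)..ln(1.9) per step are treated as division or segmentation
    artifacts and dropped).  Unlike per-cell lifetime rates, this pairing
    does not smear the density dependence across the ~doubling of the colony
    that happens within one cell cycle, so it is the estimator of choice for
    recovering r(n) parameters.
    """
    frames = np.sort(table["frame"].unique())
    by_frame = {f: g.set_index("cell_id") for f, g in table.groupby("frame")}
    rows = []
    for f0, f1 in zip(frames, frames[1:]):
        g0, g1 = by_frame[f0], by_frame[f1]
        common = g0.index.intersection(g1.index)
        if len(common) == 0:
            continue
        dt = float(g1["time_h"].iloc[0] - g0["time_h"].iloc[0])
        ratio = g1.loc[common, "area_um2"].to_numpy() / g0.loc[common, "area_um2"].to_numpy()
        ok = (ratio > 0.7) & (ratio < 1.9)
        if not ok.any():
            continue
        rate = float(np.median(np.log(ratio[ok]) / dt))
        rows.append((int(f0), len(g0), rate))
    return pd.DataFrame(rows, columns=["frame", "n_cells", "rate_per_h"])


@dataclass
class StatResult:
    """One hypothesis-test outcome."""

    test: str
    statistic: float
    p_value: float
    effect_size: float
    q_value: float | None = None
    group_ns: tuple[int, ...] = ()
    note: str = ""


def ancova_rate_density(rates, counts, birth_times) -> StatResult:
    """F-test of the cell-count effect on growth rate, birth time as covariate.

    Compares the nested linear models ``rate ~ birth`` and
    ``rate ~ birth + count``; the effect size is the partial eta^2 of the
    count term.  Collinear predictors are reported, not silently dropped.
    """
    rates = np.asarray(rates, dtype=float)
    counts = np.asarray(counts, dtype=float)
    births = np.asarray(birth_times, dtype=float)
    if len(rates) < 8:
        raise FitError("ANCOVA needs at least 8 observations")
    note = ""
    corr = np.corrcoef(births, counts)[0, 1]
    if abs(corr) > 0.999:
        note = f"predictors nearly collinear (r={corr:.4f}); F-test unstable"
    X_red = sm.add_constant(births)
    X_full = sm.add_constant(np.column_stack([births, counts]))
    fit_red = sm.OLS(rates, X_red).fit()
    fit_full = sm.OLS(rates, X_full).fit()
    df_num = 1
    df_den = int(fit_full.df_resid)
    ss_diff = fit_red.ssr - fit_full.ssr
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    if fit_red.ssr <= 1e-12 * max(ss_tot, 1e-300):
        # birth time alone already explains the rates exactly: the count
        # term has nothing left to absorb
        f_stat, p = 0.0, 1.0
        ss_diff = 0.0
    elif fit_full.ssr <= 0:
        f_stat = float("inf") if ss_diff > 0 else 0.0
        p = 0.0 if ss_diff > 0 else 1.0
    else:
        f_stat = (ss_diff / df_num) / (fit_full.ssr / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    eta_p = ss_diff / (ss_diff + fit_full.ssr) if (ss_diff + fit_full.ssr) > 0 else 0.0
    return StatResult(
        "ancova-count|birth", float(f_stat), p, float(eta_p),
        group_ns=(len(rates),), note=note,
    )


# ---------------------------------------------------------------------------
# batch-culture analysis
# ---------------------------------------------------------------------------

@dataclass
class BatchMetrics:
    max_growth_rate: float  # logistic r, 1/h
    max_od: float
    t_half_h: float
    fit: GrowthFit


def batch_metrics(curve: pd.DataFrame, smooth_window: int = 3) -> BatchMetrics:
    """Maximum growth rate, maximum OD and time to half-maximum OD.

    The maximum growth rate is the r of a logistic fit (the convention of
    standard growth-curve tooling); the maximum OD is the peak of a centered
    rolling-mean smoothed series; t_half is the earliest time the smoothed OD
    crosses half that maximum, linearly interpolated between samples.
    """
    t = curve["time_h"].to_numpy(dtype=float)
    od = curve["od600"].to_numpy(dtype=float)
    if len(t) < 6:
        raise FitError("need at least 6 OD samples")
    sm_od = pd.Series(od).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    fit = fit_growth_model(t, od, "logistic")
    max_od = float(np.max(sm_od))
    half = max_od / 2.0
    t_half = float("nan")
    above = sm_od >= half
    idx = np.flatnonzero(above)
    if len(idx):
        i = idx[0]
        if i == 0:
            t_half = float(t[0])
        else:
            t0, t1 = t[i - 1], t[i]
            y0, y1 = sm_od[i - 1], sm_od[i]
            t_half = float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))
    rate = fit.params.get("r", float("nan")) if fit.success else float("nan")
    if fit.success and fit.params["K"] - fit.params["N0"] < 1e-3 * fit.params["K"]:
        rate = 0.0  # flat curve: K ~ N0 makes r unidentifiable, no growth
    return BatchMetrics(rate, max_od, t_half, fit)


def semilog_inoculum_regression(
    t_half: dict[str, np.ndarray],
    densities: dict[str, np.ndarray],
) -> tuple[dict[str, GrowthFit], StatResult]:
    """Per-group semilog regression of t_half on log10(inoculum density),
    plus a slope-difference test between two groups.

    The slope difference is the interaction term of the pooled model
    ``t_half ~ log10(d) * group`` (t-test on the interaction coefficient).
    """
    groups = sorted(t_half)
    if len(groups) != 2:
        raise ValueError("slope-difference test needs exactly two groups")
    fits: dict[str, GrowthFit] = {}
    for g in groups:
        d = np.asarray(densities[g], dtype=float)
        if np.any(d <= 0):
            raise ValueError("inoculum densities must be positive")
        fits[g] = fit_growth_model(d, np.asarray(t_half[g], dtype=float), "semilog-linear")

    y = np.concatenate([np.asarray(t_half[g], dtype=float) for g in groups])
    ld = np.concatenate([np.log10(np.asarray(densities[g], dtype=float)) for g in groups])
    grp = np.concatenate(
        [np.full(len(t_half[g]), i, dtype=float) for i, g in enumerate(groups)]
    )
    X = sm.add_constant(np.column_stack([ld, grp, ld * grp]))
    ols = sm.OLS(y, X).fit()
    tval = float(ols.tvalues[3])
    pval = float(ols.pvalues[3])
    df = float(ols.df_resid)
    eta = tval**2 / (tval**2 + df) if np.isfinite(tval) else float("nan")
    res = StatResult(
        "slope-difference", tval, pval, eta,
        group_ns=tuple(len(t_half[g]) for g in groups),
    )
    return fits, res


# ---------------------------------------------------------------------------
# two-sample tests with FDR
# ---------------------------------------------------------------------------

def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Exact enumeration of all C(n+m, n) labelings; intended for small groups
    and as an oracle for the normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_stat(idx_a: tuple[int, ...]) -> float:
        xa = pooled[list(idx_a)]
        xb = np.delete(pooled, list(idx_a))
        u = 0.0
        for va in xa:
            u += np.sum(va > xb) + 0.5 * np.sum(va == xb)
        return u

    u_obs = u_stat(tuple(range(n)))
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_stat(comb) - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def stat_tests(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    test: str = "t",
    fdr: bool = False,
    exact_threshold: int = 8,
) -> list[StatResult]:
    """Two-sided two-sample tests over named comparisons, with optional BH-FDR.

    ``groups`` maps a comparison name to its two samples.  For t-tests the
    effect size is eta^2 = t^2/(t^2+df); for Mann-Whitney the rank-biserial
    correlation magnitude.  Exact Mann-Whitney p-values are used when both
    groups have at most ``exact_threshold`` observations, the normal
    approximation above.  BH is the step-up procedure across the listed
    comparisons.
    """
    results: list[StatResult] = []
    for name, (a, b) in groups.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{name}: need at least 2 values per group")
        note = ""
        if test == "t":
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                stat_v, p = 0.0, 1.0
                note = "zero variance in both groups with equal means; p=1 by convention"
                df = len(a) + len(b) - 2
            else:
                tt = stats.ttest_ind(a, b)
                stat_v, p = float(tt.statistic), float(tt.pvalue)
                df = len(a) + len(b) - 2
            eff = stat_v**2 / (stat_v**2 + df) if np.isfinite(stat_v) else float("nan")
            tname = "t"
        elif test == "mann-whitney":
            if len(a) <= exact_threshold and len(b) <= exact_threshold:
                u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic)
                p = mann_whitney_exact_p(a, b)
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
                u, p = float(res.statistic), float(res.pvalue)
            stat_v = u
            eff = abs(2.0 * u / (len(a) * len(b)) - 1.0)  # rank-biserial magnitude
            tname = "mann-whitney"
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(
            StatResult(f"{tname}:{name}", stat_v, p, eff, group_ns=(len(a), len(b)), note=note)
        )
    if fdr and results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up q-values (wrapper kept for a stable module surface)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]
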