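"""Growth-curve kinetics: mu_max, carrying capacity, strain comparison.

Two estimators are provided for OD600 time series, mirroring common
practice for bacterial batch cultures:

* ``fit_easylinear`` — the sliding-window log-linear method: fit
  ln(OD) ~ t by least squares in every contiguous window and take the
  steepest well-fitting window's slope as the maximum specific growth
  rate mu_max (h^-1).
* ``fit_logistic`` — a parametric least-squares fit of the logistic
  N(t) = K / (1 + ((K - N0)/N0) e^(-mu t)), yielding mu, the carrying
  capacity K (OD600 units) and the inoculum N0, with multi-start
  initialization for robustness.

Strains (e.g. a siderophore-producing wild type vs a biosynthesis
knockout) are compared per condition with an independent two-tailed
Student's t test on the fitted parameters, pooled variance by default
and Welch's correction behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import logistic

DEFAULT_WINDOW_SIZE = 5
DEFAULT_MIN_WINDOW_R2 = 0.95


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series."""

    times: tuple[float, ...]  # hours, strictly increasing
    od: tuple[float, ...]
    condition: str = ""
    strain: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if len(self.times) < 5:
            raise ValueError("need at least 5 points to fit a growth curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(v < 0 for v in self.od):
            raise ValueError("od values must be >= 0")


@dataclass(frozen=True)
class GrowthFit:
    mu_max: float  # h^-1; >= 0 (non-growth reported as 0, flagged)
    K: float | None
    N0: float | None
    method: str  # "easylinear" | "logistic"
    fit_r2: float
    window: tuple[int, int] | None = None  # index span, easylinear only
    n_excluded: int = 0  # non-positive OD points excluded from log space
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return "failed" not in self.flags


def fit_easylinear(
    curve: GrowthCurve,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_r2: float = DEFAULT_MIN_WINDOW_R2,
) -> GrowthFit:
    """Sliding-window log-linear estimate of mu_max.

    ln(OD) is regressed on time in every contiguous window of
    ``window_size`` points (after excluding non-positive OD values,
    which blank subtraction can produce); mu_max is the largest slope
    among windows with r^2 >= ``min_r2``.  If no window fits that well,
    the best-r^2 window is used and the fit flagged.  Negative best
    slopes are reported as mu_max = 0 with a "non-growth" flag.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    positive = od > 0
    n_excluded = int((~positive).sum())
    t, od = t[positive], od[positive]
    if len(t) < window_size:
        raise ValueError(
            f"only {len(t)} positive OD points; need >= window_size ({window_size})"
        )
    log_od = np.log(od)
    best: tuple[float, float, tuple[int, int]] | None = None  # slope, r2, span
    qualifying: tuple[float, float, tuple[int, int]] | None = None
    for i in range(len(t) - window_size + 1):
        sl = slice(i, i + window_size)
        res = stats.linregress(t[sl], log_od[sl])
        r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0
        entry = (float(res.slope), r2, (i, i + window_size - 1))
        if best is None or r2 > best[1]:
            best = entry
        if r2 >= min_r2 and (qualifying is None or entry[0] > qualifying[0]):
            qualifying = entry
    flags: list[str] = []
    if qualifying is not None:
        slope, r2, span = qualifying
    else:
        slope, r2, span = best
        flags.append("no-window-met-r2")
    if slope <= 0 or np.isclose(slope, 0.0, atol=1e-12):
        return GrowthFit(
            0.0, None, None, "easylinear", r2, span, n_excluded,
            tuple(flags) + ("non-growth",),
        )
    return GrowthFit(slope, None, None, "easylinear", r2, span, n_excluded, tuple(flags))


def fit_logistic(curve: GrowthCurve) -> GrowthFit:
    """Least-squares logistic fit returning (mu, K, N0) and r^2.

    Several starting points are tried (K from the OD plateau, mu from
    coarse log-slopes, N0 from the first positive reading); the best
    converged fit by residual sum of squares wins.  A series with no
    upward trend, or failure of every start, yields a flagged failure
    with no parameter values.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    if od.max() <= 0 or np.all(np.diff(od) <= 0):
        return GrowthFit(0.0, None, None, "logistic", 0.0, flags=("failed", "non-growth"))
    k0 = float(od.max())
    n0_guess = float(max(od[od > 0][0] if np.any(od > 0) else k0 / 100, 1e-6))
    span = t[-1] - t[0]
    starts = [
        (mu0, k0 * s, n0_guess)
        for mu0 in (0.1, 0.5, 1.0, 4.0 / max(span, 1e-9))
        for s in (1.0, 1.2)
    ]
    best_fit = None
    best_rss = np.inf
    for mu0, K0, N00 in starts:
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, mu, K, N0: logistic(tt, mu, K, N0),
                t, od, p0=(mu0, K0, N00),
                bounds=([1e-9, 1e-9, 1e-12], [50.0, 100.0 * k0, k0 * 2 + 1e-9]),
                maxfev=20_000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((logistic(t, *popt) - od) ** 2))
        if rss < best_rss:
            best_rss, best_fit = rss, popt
    if best_fit is None:
        return GrowthFit(0.0, None, None, "logistic", 0.0, flags=("failed",))
    mu, K, N0 = (float(v) for v in best_fit)
    ss_tot = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 - best_rss / ss_tot if ss_tot > 0 else 0.0
    return GrowthFit(mu, K, N0, "logistic", r2)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float
    welch: bool


def _extract(values: Sequence) -> np.ndarray:
    out = [v.mu_max if isinstance(v, GrowthFit) else float(v) for v in values]
    return np.asarray(out, dtype=float)


def compare_strains(
    fits_a: Sequence,
    fits_b: Sequence,
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Independent two-tailed t test between two groups of fits/values.

    Accepts GrowthFit objects (their mu_max is compared) or plain
    numbers.  Pooled-variance Student's t by default; Welch's unequal
    variance form with ``welch=True``.  Two identical zero-variance
    groups return t=0, p=1 rather than an undefined statistic.
    """
    a, b = _extract(fits_a), _extract(fits_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 fits per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, len(a) + len(b) - 2, 1.0, False, alpha, welch)
        return TTestResult(
            np.inf if a.mean() > b.mean() else -np.inf,
            len(a) + len(b) - 2, 0.0, True, alpha, welch,
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), df, p, p < alpha, alpha, welch)


def load_growth_table(path: str) -> list[GrowthCurve]:
    """Read a long-format TSV (condition, strain, replicate, time_h, od600)."""
    df = pd.read_csv(path, sep="\t")
    return curves_from_frame(df)


def curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for (cond, strain, rep), grp in df.groupby(
        ["condition", "strain", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=tuple(grp["time_h"].astype(float)),
                od=tuple(grp["od600"].astype(float)),
                condition=str(cond),
                strain=str(strain),
                replicate=int(rep),
            )
        )
    return curves


def fit_table(
    curves: Sequence[GrowthCurve], method: str = "both",
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> pd.DataFrame:
    """Fit every curve and tabulate the results."""
    rows = []
    for c in curves:
        fits = []
        if method in ("easylinear", "both"):
            fits.append(fit_easylinear(c, window_size))
        if method in ("logistic", "both"):
            fits.append(fit_logistic(c))
        for f in fits:
            rows.append(
                {
                    "condition": c.condition,
                    "strain": c.strain,
                    "replicate": c.replicate,
                    "method": f.method,
                    "mu_max": f.mu_max,
                    "K": f.K,
                    "N0": f.N0,
                    "r2": f.fit_r2,
                    "flags": ",".join(f.flags),
                }
            )
    return pd.DataFrame(rows)


def compare_table(
    fits: pd.DataFrame, parameter: str = "mu_max",
    strain_a: str = "WT", strain_b: str = "mutant",
    alpha: float = 0.05, welch: bool = False,
) -> pd.DataFrame:
    """Per-condition, per-method strain comparison table."""
    rows = []
    for (cond, method), grp in fits.groupby(["condition", "method"], sort=True):
        a = grp.loc[grp["strain"] == strain_a, parameter].dropna()
        b = grp.loc[grp["strain"] == strain_b, parameter].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"condition {cond!r} ({method}): fewer than 2 fits per strain; skipped",
                stacklevel=2,
            )
            continue
        res = compare_strains(list(a), list(b), alpha, welch)
        rows.append(
            {
                "condition": cond,
                "method": method,
                "parameter": parameter,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
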