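"""Melting-curve fitting, Tm-shift testing and Tm-distribution summaries.

A protein's ratio profile r(T) (intensities normalized to the
reference-temperature channel) is fit with the descending logistic

    s(T) = (1 - p) / (1 + exp(k * (T - Tm))) + p

by bounded nonlinear least squares.  The reported melting point is the
0.5 crossing of the plateau-free normalized curve (s - p) / (1 - p),
which is exactly the fitted ``Tm`` parameter — independent of the
plateau, as "50% soluble" should be.

Because the sigmoid objective is multimodal under noise, fitting uses a
data-driven start (the interpolated half-decay temperature of the
min-max-normalized profile) and falls back to a fixed multi-start grid
over Tm in {45, 50, 55, 60} degC whenever the current best solution
still fails quality control; among the starts tried, the best
least-squares solution wins.  Fits are quality-controlled on goodness
of fit and plateau height, and failed fits are flagged invalid rather
than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import QuantMatrix
from .pisa_stats import storey_qvalues, ttest_equal_variance

#: Fixed multi-start grid over Tm (deg C).
TM_STARTS = (45.0, 50.0, 55.0, 60.0)


@dataclass(frozen=True)
class FitQC:
    """Quality-control thresholds for accepting a curve fit.

    ``r2_min`` — minimum coefficient of determination; ``plateau_max`` —
    maximum fitted non-denaturing plateau (a near-flat "non-melter" has
    no meaningful Tm); valid fits must also place Tm inside the fitted
    temperature range.
    """

    r2_min: float = 0.8
    plateau_max: float = 0.3


@dataclass(frozen=True)
class CurveFit:
    """Result of fitting one melting curve."""

    tm_celsius: float
    slope: float
    plateau: float
    r_squared: float
    valid: bool
    message: str = ""


@dataclass(frozen=True)
class TmTestResult:
    """Equal-variance two-sample comparison of fitted melting points."""

    protein_id: str
    delta_tm: float
    t_statistic: float
    p_value: float
    q_value: float = float("nan")
    testable: bool = True


def _sigmoid(t: np.ndarray, tm: float, k: float, p: float) -> np.ndarray:
    return (1.0 - p) / (1.0 + np.exp(np.clip(k * (t - tm), -500, 500))) + p


def _sigmoid_jac(t: np.ndarray, tm: float, k: float, p: float) -> np.ndarray:
    e = np.exp(np.clip(k * (t - tm), -500, 500))
    denom = (1.0 + e) ** 2
    d_tm = (1.0 - p) * k * e / denom
    d_k = -(1.0 - p) * (t - tm) * e / denom
    d_p = e / (1.0 + e)
    return np.column_stack([d_tm, d_k, d_p])


def _data_driven_tm_start(t: np.ndarray, r: np.ndarray) -> float | None:
    """Interpolated temperature where the min-max-normalized profile
    crosses 0.5, scanning from low to high temperature."""
    lo, hi = float(np.min(r)), float(np.max(r))
    if hi - lo < 1e-12:
        return None
    z = (r - lo) / (hi - lo)
    below = np.nonzero(z <= 0.5)[0]
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return float(t[0])
    t0, t1, z0, z1 = t[j - 1], t[j], z[j - 1], z[j]
    if z0 == z1:
        return float(t1)
    return float(t0 + (z0 - 0.5) / (z0 - z1) * (t1 - t0))


def fit_melting_curve(temperatures, ratios, qc: FitQC = FitQC()) -> CurveFit:
    """Fit the melting logistic to a (temperature, ratio) profile.

    Requires at least 5 observed pairs (missing ratios are dropped
    first).  Optimizer failure or QC failure yields ``valid=False``; only
    malformed input raises.
    """
    t = np.asarray(temperatures, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape:
        raise ValueError("temperatures and ratios must have equal length")
    keep = np.isfinite(t) & np.isfinite(r)
    t, r = t[keep], r[keep]
    if t.size < 5:
        raise ValueError(f"need >= 5 observed (temperature, ratio) pairs, got {t.size}")
    if np.any(r < 0):
        raise ValueError("ratios must be non-negative")

    order = np.argsort(t)
    t, r = t[order], r[order]
    tmin, tmax = float(t[0]), float(t[-1])
    lb = np.array([tmin - 5.0, 1e-3, 0.0])
    ub = np.array([tmax + 5.0, 10.0, 1.0 - 1e-9])

    starts: list[float] = []
    guess = _data_driven_tm_start(t, r)
    if guess is not None:
        starts.append(float(np.clip(guess, lb[0], ub[0])))
    starts.extend(TM_STARTS)

    p0_guess = float(np.clip(np.min(r), 0.0, 0.9))
    best = None
    sst = float(np.sum((r - r.mean()) ** 2))

    def _passes_qc(sse: float, x: np.ndarray) -> bool:
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        return (r2 >= qc.r2_min) and (x[2] < qc.plateau_max) and (tmin <= x[0] <= tmax)

    for tm0 in starts:
        x0 = np.array([tm0, 1.0, p0_guess])
        try:
            sol = least_squares(lambda x: _sigmoid(t, *x) - r, x0,
                                jac=lambda x: _sigmoid_jac(t, *x),
                                bounds=(lb, ub), method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:  # optimizer failure -> try next start
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
        if _passes_qc(*best):
            break  # the remaining grid starts are a fallback for poor fits
    if best is None:
        return CurveFit(math.nan, math.nan, math.nan, 0.0, False, "optimizer failed")

    sse, (tm, k, p) = best
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    valid = bool((r2 >= qc.r2_min) and (p < qc.plateau_max) and (tmin <= tm <= tmax))
    msg = "" if valid else "failed QC"
    return CurveFit(float(tm), float(k), float(p), float(max(r2, 0.0)), valid, msg)


def fit_all(matrix: QuantMatrix, qc: FitQC = FitQC()) -> pd.DataFrame:
    """Fit one melting curve per (protein, condition, replicate) of a
    ratio matrix; returns a tidy table of :class:`CurveFit` fields."""
    meta = matrix.run_meta.loc[matrix.values.columns]
    temps = pd.to_numeric(meta["temperature"], errors="coerce")
    rows = []
    for (extract, condition, rep), group in meta.groupby(
            ["extract", "condition", "replicate"], sort=False):
        runs = list(group.index)
        t = temps[runs].to_numpy(dtype=float)
        block = matrix.values[runs].to_numpy(dtype=float)
        drug = group["drug"].iloc[0]
        conc = group["concentration"].iloc[0]
        for i, pid in enumerate(matrix.protein_ids):
            r = block[i]
            n_obs = int(np.isfinite(r).sum())
            if n_obs < 5:
                fit = CurveFit(math.nan, math.nan, math.nan, 0.0, False, "too few points")
            else:
                fit = fit_melting_curve(t, r, qc)
            rows.append({"protein_id": pid, "drug": drug, "concentration": conc,
                         "extract": extract, "replicate": rep,
                         "tm_celsius": fit.tm_celsius, "slope": fit.slope,
                         "plateau": fit.plateau, "r_squared": fit.r_squared,
                         "valid": fit.valid})
    return pd.DataFrame(rows)


def tm_shift_test(treated_fits, control_fits, protein_id: str = "") -> TmTestResult:
    """Two-sided equal-variance t-test on fitted Tm values.

    Each argument is a list of :class:`CurveFit` (invalid fits are
    dropped) or a plain sequence of Tm values.  Fewer than two valid
    fits in either group makes the result untestable.
    """
    def _tms(fits):
        vals = []
        for f in fits:
            if isinstance(f, CurveFit):
                if f.valid:
                    vals.append(f.tm_celsius)
            else:
                vals.append(float(f))
        return np.asarray(vals, dtype=float)

    x, y = _tms(treated_fits), _tms(control_fits)
    if x.size < 2 or y.size < 2:
        return TmTestResult(protein_id, math.nan, math.nan, math.nan, testable=False)
    tt = ttest_equal_variance(x, y)
    delta = float(x.mean() - y.mean())
    if not tt.ok:
        return TmTestResult(protein_id, delta, math.nan, math.nan, testable=False)
    return TmTestResult(protein_id, delta, tt.t, tt.p, testable=True)


def tm_shift_screen(fits: pd.DataFrame, treated_condition: str, control_condition: str,
                    extract: str | None = None) -> pd.DataFrame:
    """Per-protein Tm-shift tests between two conditions of a
    :func:`fit_all` table, with Storey q-values over the testable family."""
    df = fits if extract is None else fits[fits["extract"] == extract]
    cond = df["drug"].astype(str) + "|" + df["concentration"].astype(str)
    rows = []
    for pid, sub in df.assign(_cond=cond).groupby("protein_id", sort=True):
        x = sub.loc[(sub["_cond"] == treated_condition) & sub["valid"], "tm_celsius"]
        y = sub.loc[(sub["_cond"] == control_condition) & sub["valid"], "tm_celsius"]
        res = tm_shift_test(list(x), list(y), protein_id=pid)
        rows.append({"protein_id": pid, "delta_tm": res.delta_tm,
                     "t_statistic": res.t_statistic, "p_value": res.p_value,
                     "testable": res.testable})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    testable = out["testable"] & out["p_value"].notna()
    if testable.any():
        q, _ = storey_qvalues(out.loc[testable, "p_value"].to_numpy())
        out.loc[testable, "q_value"] = q
    return out


@dataclass(frozen=True)
class TmSummary:
    """Summary of a proteome-wide Tm distribution."""

    median: float
    fraction_in_window: float
    window: tuple[float, float]
    suggested_pooling: tuple[float, float, float]


def summarize_tm_distribution(tm_values, window: tuple[float, float] = (50.0, 55.0),
                              spacing: float = 3.0) -> TmSummary:
    """Median Tm, fraction inside the closed ``window``, and a suggested
    pooling-temperature triple.

    The suggestion starts at the smallest integer strictly above the
    median and spaces three temperatures ``spacing`` degC apart — biased
    above the median to favor detection of thermally stabilized targets,
    where the treated/control solubility contrast is largest.
    """
    tm = np.asarray([v for v in np.ravel(tm_values) if math.isfinite(v)], dtype=float)
    if tm.size == 0:
        raise ValueError("no finite Tm values")
    med = float(np.median(tm))
    lo, hi = window
    frac = float(np.mean((tm >= lo) & (tm <= hi)))
    start = math.floor(med) + 1  # smallest integer strictly above the median
    pooling = (float(start), float(start + spacing), float(start + 2 * spacing))
    return TmSummary(median=med, fraction_in_window=frac, window=window,
                     suggested_pooling=pooling)


__all__ = [
    "FitQC", "CurveFit", "TmTestResult", "TmSummary",
    "fit_melting_curve", "fit_all", "tm_shift_test", "tm_shift_screen",
    "summarize_tm_distribution", "TM_STARTS",
]
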