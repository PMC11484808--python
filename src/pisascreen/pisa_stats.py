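"""The PISA differential-abundance screen.

Each (drug, concentration) condition is compared, protein by protein,
against the pooled replicates of *all other conditions of the same
experiment* ("all-other-drugs" control design), after removing from the
control pool

  i)   the same drug at other concentrations,
  ii)  drugs that are structurally similar (Tanimoto index >= 0.6), and
  iii) drugs sharing at least one known target

(exclusion sets are built in :mod:`pisascreen.chem_similarity`).  The
per-protein statistic is a plain two-sided equal-variance (pooled
variance) t-test on log2 intensities; p-values are adjusted per
(drug, concentration, extract) test family with Storey q-values, and a
protein is called significant at q <= 0.05 and |log2FC| >= 0.5 (both
inclusive).  Positive log2FC means thermally stabilized (more protein
remained soluble at the pooled temperatures under treatment).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix

STABILIZED = "stabilized"
DESTABILIZED = "destabilized"


@dataclass(frozen=True)
class TTestOutcome:
    """Pooled-variance two-sample t-test outcome."""

    t: float
    p: float
    df: float
    ok: bool = True


@dataclass(frozen=True)
class ScreenThresholds:
    """Significance thresholds of the screen (both comparisons inclusive)."""

    q_max: float = 0.05
    min_abs_log2fc: float = 0.5
    min_replicates: int = 2  # smallest group size with df > 0


def ttest_equal_variance(x, y) -> TTestOutcome:
    """Two-sided unpaired t-test with pooled (equal) variance.

    df = n_x + n_y - 2.  Degenerate cases: zero pooled variance with
    equal means gives t = 0, p = 1; zero pooled variance with different
    means is untestable (``ok=False``).  Fewer than two values in either
    group is untestable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        return TTestOutcome(math.nan, math.nan, math.nan, ok=False)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestOutcome(0.0, 1.0, float(df))
        return TTestOutcome(math.nan, math.nan, float(df), ok=False)
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestOutcome(float(t), float(min(p, 1.0)), float(df))


#: Lambda grid for pi0 estimation (Storey's method).
PI0_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)

#: Below this family size the pi0 smoother is unstable; fall back to 1.
PI0_MIN_TESTS = 100


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray = PI0_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 from a p-value family.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a
    cubic polynomial over the lambda grid and evaluated at the largest
    lambda, then clamped to (0, 1].  Small families (m < 100) or a
    non-positive estimate fall back to pi0 = 1 (making the q-values
    coincide with Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < PI0_MIN_TESTS:
        return 1.0
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    if not np.isfinite(pi0) or pi0 <= 0.0:
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(p_values, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values for a family of p-values.

    q_(i) = min over j >= i of pi0 * m * p_(j) / j over the ascending
    order statistics, clamped to [0, 1]; monotone non-decreasing in p.
    Returns (q-values in the input order, pi0 used).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, float(pi0)


def _group_stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and ddof-1 variance of a proteins x runs block
    with NaN as missing."""
    n = np.sum(np.isfinite(block), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(block, axis=1)
        var = np.nanvar(block, axis=1, ddof=1)
    return n, mean, var


def _vectorized_ttest(x_block: np.ndarray, y_block: np.ndarray, min_n: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t-tests; returns (fc, t, p, nx, ny)."""
    nx, mx, vx = _group_stats(x_block)
    ny, my, vy = _group_stats(y_block)
    testable = (nx >= min_n) & (ny >= min_n)
    fc = np.where(testable, mx - my, np.nan)
    df = nx + ny - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / np.where(df > 0, df, 1)
        se = np.sqrt(sp2 * (1.0 / np.where(nx > 0, nx, 1) + 1.0 / np.where(ny > 0, ny, 1)))
        t = fc / se
    p = np.full(t.shape, np.nan)
    ok = testable & np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # zero pooled variance, equal means -> t = 0, p = 1
    degenerate = testable & ~np.isfinite(t) & (sp2 == 0) & (fc == 0)
    t[degenerate], p[degenerate] = 0.0, 1.0
    t[~testable] = np.nan
    return fc, t, np.minimum(p, 1.0), nx, ny


def run_screen(matrix: QuantMatrix, exclusions=None,
               thresholds: ScreenThresholds = ScreenThresholds(),
               test_conditions: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Run the PISA screen on a preprocessed log2 matrix.

    Parameters
    ----------
    matrix
        Log2-scale pooled-temperature matrix with run metadata.
    exclusions
        :class:`pisascreen.chem_similarity.ExclusionSet` (or None for no
        chemistry-based exclusions); a drug's own runs are never in its
        control pool regardless.
    thresholds
        Significance thresholds.
    test_conditions
        Optional subset of (drug, concentration) pairs to test; default
        is every condition present.

    Returns a tidy table with one row per (drug, concentration, extract,
    protein); untestable rows (too few observed replicates, or a control
    pool of fewer than two runs) carry NaN statistics and are excluded
    from their Storey family.
    """
    if not matrix.log_scale:
        raise ValueError("run_screen expects a log2-transformed matrix")
    meta = matrix.run_meta.loc[matrix.values.columns]
    values = matrix.values
    results = []
    for extract in meta["extract"].unique():
        emeta = meta[meta["extract"] == extract]
        conds = list(dict.fromkeys(zip(emeta["drug"], emeta["concentration"])))
        targets = conds if test_conditions is None else [c for c in conds if c in test_conditions]
        for drug, conc in targets:
            treated_runs = list(emeta.index[(emeta["drug"] == drug)
                                            & (emeta["concentration"] == conc)])
            excluded: set[tuple[str, str]] = set()
            if exclusions is not None:
                excluded = set(exclusions.excluded_conditions(drug))
            control_runs = [r for r in emeta.index
                            if (emeta.at[r, "drug"], emeta.at[r, "concentration"]) != (drug, conc)
                            and emeta.at[r, "drug"] != drug
                            and (emeta.at[r, "drug"], emeta.at[r, "concentration"]) not in excluded]
            frame = pd.DataFrame({
                "drug": drug, "concentration": conc, "extract": extract,
                "protein_id": matrix.protein_ids,
            })
            if len(control_runs) < 2 or len(treated_runs) < 2:
                warnings.warn(f"condition ({drug!r}, {conc!r}) in {extract!r} has an "
                              "insufficient control or treated pool; untestable", stacklevel=2)
                frame["log2_fc"] = np.nan
                frame["t_statistic"] = np.nan
                frame["p_value"] = np.nan
                nx = np.sum(np.isfinite(values[treated_runs].to_numpy()), axis=1) \
                    if treated_runs else np.zeros(matrix.n_proteins, dtype=int)
                frame["n_treated"] = nx
                frame["n_control"] = 0
            else:
                fc, t, p, nx, ny = _vectorized_ttest(
                    values[treated_runs].to_numpy(dtype=float),
                    values[control_runs].to_numpy(dtype=float),
                    thresholds.min_replicates)
                frame["log2_fc"] = fc
                frame["t_statistic"] = t
                frame["p_value"] = p
                frame["n_treated"] = nx
                frame["n_control"] = ny
            results.append(frame)
    if not results:
        raise ValueError("no conditions to test")
    out = pd.concat(results, ignore_index=True)

    # Storey correction per (drug, concentration, extract) family
    out["q_value"] = np.nan
    for _, idx in out.groupby(["drug", "concentration", "extract"], sort=False).groups.items():
        sub = out.loc[idx]
        testable = sub["p_value"].notna()
        if testable.any():
            q, _ = storey_qvalues(sub.loc[testable, "p_value"].to_numpy())
            out.loc[sub.index[testable], "q_value"] = q

    out["significant"] = (
        (out["q_value"] <= thresholds.q_max)
        & (out["log2_fc"].abs() >= thresholds.min_abs_log2fc)
    ).fillna(False)
    out["direction"] = np.where(out["log2_fc"] > 0, STABILIZED,
                                np.where(out["log2_fc"] < 0, DESTABILIZED, ""))
    out.loc[out["log2_fc"].isna(), "direction"] = ""
    return out


__all__ = [
    "TTestOutcome", "ScreenThresholds", "ttest_equal_variance",
    "estimate_pi0", "storey_qvalues", "run_screen",
    "STABILIZED", "DESTABILIZED", "PI0_LAMBDA_GRID", "PI0_MIN_TESTS",
]
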