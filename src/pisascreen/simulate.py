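"""Synthetic thermal-denaturation proteomics data with known ground truth.

Each protein denatures along a descending logistic in temperature,

    s(T) = (1 - p) / (1 + exp(k * (T - Tm))) + p,

where ``Tm`` is the melting point (the 0.5 crossing of the plateau-free
normalized curve, i.e. the temperature at which half of the meltable
protein is still soluble), ``k > 0`` the steepness (1/degC) and
``p in [0, 1)`` a non-denaturing plateau.  A drug that engages a protein
shifts its Tm by ``delta_tm`` (positive = thermally stabilized).

Two layouts are produced:

* TPP — the soluble fraction is measured at every rung of a temperature
  ladder (default 37-67 degC, ten temperatures), one column per
  (condition, replicate, temperature);
* PISA — the soluble fractions of a few temperatures (default 53, 56,
  59 degC) are pooled before measurement, so the expected intensity is the
  baseline times the *mean* of s(T) over the pooling temperatures, one
  column per (condition, replicate).

Noise is multiplicative log-normal with unit mean, parameterized by a
coefficient of variation; missing values are injected completely at
random (an optional intensity-dependent mode is available).  Every
simulation is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import POOLED, Condition, QuantMatrix, StudyDesign, run_meta_frame

#: Physically plausible melting-point window (deg C).
DEFAULT_TM_WINDOW: tuple[float, float] = (35.0, 75.0)


@dataclass(frozen=True)
class MeltModel:
    """Logistic melting parameters of one protein.

    Parameters
    ----------
    tm_celsius
        Melting temperature (deg C); must lie inside ``tm_window``.
    slope
        Logistic steepness k (1/degC), > 0.
    plateau
        Non-denaturing fraction p in [0, 1).
    baseline_abundance
        Expected unheated MS intensity (arbitrary units, > 0).
    tm_window
        Physical window enforced on ``tm_celsius``.
    """

    tm_celsius: float
    slope: float = 1.0
    plateau: float = 0.0
    baseline_abundance: float = 1.0e7
    tm_window: tuple[float, float] = DEFAULT_TM_WINDOW

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tm_celsius) and math.isfinite(self.slope)
                and math.isfinite(self.plateau) and math.isfinite(self.baseline_abundance)):
            raise ValueError("MeltModel parameters must be finite")
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.plateau < 1.0):
            raise ValueError(f"plateau must be in [0, 1), got {self.plateau}")
        if not self.baseline_abundance > 0:
            raise ValueError("baseline_abundance must be > 0")
        lo, hi = self.tm_window
        if not (lo <= self.tm_celsius <= hi):
            raise ValueError(
                f"tm_celsius {self.tm_celsius} outside physical window [{lo}, {hi}]")

    def shifted(self, delta_tm: float) -> "MeltModel":
        """Copy with the melting point shifted by ``delta_tm`` (clamped to the window)."""
        lo, hi = self.tm_window
        return MeltModel(
            tm_celsius=float(np.clip(self.tm_celsius + delta_tm, lo, hi)),
            slope=self.slope, plateau=self.plateau,
            baseline_abundance=self.baseline_abundance, tm_window=self.tm_window,
        )


@dataclass(frozen=True)
class EffectSpec:
    """A ground-truth drug effect: a signed Tm shift for one protein.

    An empty ``applies_in_extracts`` set means the effect holds in every
    extract.
    """

    protein_id: str
    drug_id: str
    delta_tm: float
    applies_in_extracts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_tm):
            raise ValueError("delta_tm must be finite")

    def applies_to(self, extract: str) -> bool:
        return not self.applies_in_extracts or extract in self.applies_in_extracts


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal noise and missingness settings.

    ``cv`` is the coefficient of variation of the unit-mean intensity
    noise; ``missing_rate`` the per-cell probability of being
    unobserved.  ``intensity_dependent_missing`` switches the mask from
    completely-at-random to a logistic in log-intensity (low-abundance
    values go missing more often) with the same marginal rate.
    """

    cv: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0
    intensity_dependent_missing: bool = False

    def __post_init__(self) -> None:
        if not (self.cv >= 0):
            raise ValueError("cv must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def log_sigma(self) -> float:
        """Sigma of the unit-mean log-normal factor implied by cv."""
        return math.sqrt(math.log1p(self.cv ** 2))


def melt_fraction(temperature, model: MeltModel):
    """Soluble fraction s(T) of a protein at ``temperature`` (deg C).

    Accepts a scalar or array of temperatures; strictly decreasing in T;
    ``s(Tm) = (1 + p) / 2``.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    p = model.plateau
    z = np.clip(model.slope * (t - model.tm_celsius), -500.0, 500.0)
    s = (1.0 - p) / (1.0 + np.exp(z)) + p
    return float(s) if np.isscalar(temperature) else s


def _as_model_dict(models) -> dict[str, MeltModel]:
    if isinstance(models, Mapping):
        out = dict(models)
    else:
        out = {}
        for pid, m in models:
            if pid in out:
                raise ValueError(f"duplicate protein id: {pid!r}")
            out[pid] = m
    if not out:
        raise ValueError("model set is empty")
    return out


def _effect_lookup(effects: Iterable[EffectSpec]) -> dict[tuple[str, str], EffectSpec]:
    out: dict[tuple[str, str], EffectSpec] = {}
    for e in effects:
        key = (e.protein_id, e.drug_id)
        if key in out:
            raise ValueError(f"duplicate effect for {key}")
        out[key] = e
    return out


def ground_truth_table(effects: Iterable[EffectSpec]) -> pd.DataFrame:
    """Effects as a tidy table (protein_id, drug_id, delta_tm, extract)."""
    rows = []
    for e in effects:
        extracts = sorted(e.applies_in_extracts) or [""]
        for x in extracts:
            rows.append({"protein_id": e.protein_id, "drug_id": e.drug_id,
                         "delta_tm": e.delta_tm, "extract": x})
    cols = ["protein_id", "drug_id", "delta_tm", "extract"]
    return pd.DataFrame(rows, columns=cols)


def _expected_fraction_matrix(conditions: list[Condition],
                              models: dict[str, MeltModel],
                              effects: dict[tuple[str, str], EffectSpec],
                              temperatures: np.ndarray, pooled: bool) -> dict[Condition, np.ndarray]:
    """Per condition: proteins x temperatures soluble-fraction array (or
    proteins-vector of pooled means when ``pooled``)."""
    out = {}
    pids = list(models)
    for cond in conditions:
        frac = np.empty((len(pids), len(temperatures)))
        for i, pid in enumerate(pids):
            m = models[pid]
            eff = effects.get((pid, cond.drug))
            if eff is not None and eff.applies_to(cond.extract):
                m = m.shifted(eff.delta_tm)
            frac[i] = melt_fraction(temperatures, m)
        out[cond] = frac.mean(axis=1) if pooled else frac
    return out


def _apply_noise(expected: np.ndarray, rng: np.random.Generator, noise: NoiseSpec) -> np.ndarray:
    if noise.cv == 0:
        return expected.copy()
    sigma = noise.log_sigma
    factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=expected.shape)
    return expected * factors


def _missing_mask(values: np.ndarray, rng: np.random.Generator, noise: NoiseSpec) -> np.ndarray:
    if noise.missing_rate == 0:
        return np.zeros(values.shape, dtype=bool)
    if not noise.intensity_dependent_missing:
        return rng.random(values.shape) < noise.missing_rate
    # Logistic in log-intensity, centered so the marginal rate matches.
    logv = np.log(np.maximum(values, 1e-300))
    z = (np.median(logv) - logv) / max(np.std(logv), 1e-12)
    prob = 1.0 / (1.0 + np.exp(-z))
    prob *= noise.missing_rate / max(prob.mean(), 1e-12)
    return rng.random(values.shape) < np.clip(prob, 0.0, 1.0)


def simulate_tpp(design: StudyDesign, models, effects: Iterable[EffectSpec] = (),
                 noise: NoiseSpec = NoiseSpec()) -> tuple[QuantMatrix, pd.DataFrame]:
    """Simulate a full-gradient (TPP) matrix: one run per
    (condition, replicate, temperature).

    Returns the matrix and the ground-truth effect table.
    """
    models = _as_model_dict(models)
    effects = list(effects)
    eff = _effect_lookup(effects)
    temps = np.asarray(design.temperatures, dtype=float)
    if temps.size == 0:
        raise ValueError("design declares no temperatures")
    rng = np.random.default_rng(noise.seed)
    pids = list(models)
    baselines = np.array([models[p].baseline_abundance for p in pids])

    frac = _expected_fraction_matrix(list(design.conditions), models, eff, temps, pooled=False)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in design.conditions:
        expected = baselines[:, None] * frac[cond]  # proteins x temps
        for rep in range(1, design.n_replicates + 1):
            noisy = _apply_noise(expected, rng, noise)
            for j, t in enumerate(temps):
                run_id = f"{cond.label}|r{rep}|T{t:g}"
                cols[run_id] = noisy[:, j]
                meta_rows.append({"run_id": run_id, "condition": cond.condition,
                                  "drug": cond.drug, "concentration": cond.concentration,
                                  "extract": cond.extract, "replicate": rep,
                                  "temperature": float(t)})
    values = pd.DataFrame(cols, index=pd.Index(pids, name="protein_id"))
    mask = _missing_mask(values.to_numpy(), rng, noise)
    values = values.mask(mask)
    matrix = QuantMatrix(values=values, run_meta=run_meta_frame(meta_rows))
    return matrix, ground_truth_table(effects)


def simulate_pisa(design: StudyDesign, models, effects: Iterable[EffectSpec] = (),
                  noise: NoiseSpec = NoiseSpec()) -> tuple[QuantMatrix, pd.DataFrame]:
    """Simulate a pooled-temperature (PISA) matrix: one run per
    (condition, replicate); expected intensity = baseline x mean of
    s(T) over the pooling temperatures.
    """
    models = _as_model_dict(models)
    effects = list(effects)
    eff = _effect_lookup(effects)
    temps = np.asarray(design.pooling_temperatures, dtype=float)
    if temps.size == 0:
        raise ValueError("design declares no pooling temperatures")
    rng = np.random.default_rng(noise.seed)
    pids = list(models)
    baselines = np.array([models[p].baseline_abundance for p in pids])

    pooled = _expected_fraction_matrix(list(design.conditions), models, eff, temps, pooled=True)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in design.conditions:
        expected = baselines * pooled[cond]  # proteins-vector
        for rep in range(1, design.n_replicates + 1):
            run_id = f"{cond.label}|r{rep}"
            cols[run_id] = _apply_noise(expected, rng, noise)
            meta_rows.append({"run_id": run_id, "condition": cond.condition,
                              "drug": cond.drug, "concentration": cond.concentration,
                              "extract": cond.extract, "replicate": rep,
                              "temperature": POOLED})
    values = pd.DataFrame(cols, index=pd.Index(pids, name="protein_id"))
    mask = _missing_mask(values.to_numpy(), rng, noise)
    values = values.mask(mask)
    matrix = QuantMatrix(values=values, run_meta=run_meta_frame(meta_rows))
    return matrix, ground_truth_table(effects)


def inject_missing(matrix: QuantMatrix, noise: NoiseSpec) -> QuantMatrix:
    """Mask observed cells independently with probability ``missing_rate``.

    Seeded and deterministic; the resulting NaN pattern is the recorded
    mask.  ``missing_rate`` must be < 1 (an all-missing matrix is useless).
    """
    arr = matrix.values.to_numpy(dtype=float)
    rng = np.random.default_rng(noise.seed)
    mask = _missing_mask(np.nan_to_num(arr, nan=0.0), rng, noise)
    out = matrix.copy()
    out.values = out.values.mask(mask)
    return out


def draw_proteome(n_proteins: int, seed: int = 0, *, tm_mean: float = 52.5,
                  tm_sd: float = 3.0, tm_range: tuple[float, float] = (40.0, 70.0),
                  slope_range: tuple[float, float] = (0.6, 1.5),
                  plateau_max: float = 0.2) -> dict[str, MeltModel]:
    """Draw a ground-truth proteome of melting models.

    Melting points are normal(52.5, 3 degC) truncated to [40, 70],
    matching the empirical observation that proteome median melting
    points fall between 50 and 55 degC; slopes and plateaus are drawn
    uniformly over ranges typical of sigmoidal melting curves, and
    baseline abundances are log-normal over ~2 orders of magnitude.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = tm_range
    models = {}
    for i in range(n_proteins):
        tm = rng.normal(tm_mean, tm_sd)
        while not (lo <= tm <= hi):
            tm = rng.normal(tm_mean, tm_sd)
        models[f"P{i:05d}"] = MeltModel(
            tm_celsius=float(tm),
            slope=float(rng.uniform(*slope_range)),
            plateau=float(rng.uniform(0.0, plateau_max)),
            baseline_abundance=float(np.exp(rng.normal(np.log(1e7), 1.0))),
        )
    return models


__all__ = [
    "MeltModel", "EffectSpec", "NoiseSpec",
    "melt_fraction", "simulate_tpp", "simulate_pisa", "inject_missing",
    "draw_proteome", "ground_truth_table", "DEFAULT_TM_WINDOW",
]
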