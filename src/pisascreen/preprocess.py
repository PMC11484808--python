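"""Normalization and filtering of quantification matrices.

The canonical order, which :func:`preprocess_pisa` enforces and records, is

    filter protein groups -> log2 -> (quantile normalize | median align)
    -> exclude high-missing runs

with quantile normalization used for isobaric (TMT) data and median
re-alignment for label-free (DIA) data.  Missing values are never
imputed anywhere in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import QuantMatrix

#: Runs whose missing-value fraction strictly exceeds this are dropped.
DEFAULT_MISSING_RUN_MAX = 0.40

#: Reference temperature for ratio conversion of full-gradient data (deg C).
REFERENCE_TEMPERATURE = 37.0


@dataclass
class PreprocessReport:
    """Audit trail of the preprocessing applied to one matrix."""

    n_proteins_in: int = 0
    n_proteins_out: int = 0
    runs_excluded: dict[str, float] = field(default_factory=dict)
    transforms_applied: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def record(self, transform: str) -> None:
        self.transforms_applied.append(transform)


def filter_protein_groups(matrix: QuantMatrix,
                          report: PreprocessReport | None = None) -> QuantMatrix:
    """Drop reverse-sequence hits, potential contaminants and protein
    groups without any quantified proteotypic peptide.

    Idempotent; an all-flagged input yields an empty matrix with a
    warning, not an error.
    """
    f = matrix.flags
    keep = ~(f["is_reverse"] | f["is_contaminant"] | ~f["has_proteotypic"])
    if not keep.any():
        warnings.warn("all protein groups removed by flag filtering", stacklevel=2)
    out = matrix.subset_proteins(matrix.values.index[keep])
    if report is not None:
        report.n_proteins_in = matrix.n_proteins
        report.n_proteins_out = out.n_proteins
        report.record("filter_protein_groups")
    return out


def log2_transform(matrix: QuantMatrix,
                   report: PreprocessReport | None = None) -> QuantMatrix:
    """Elementwise log2; missing stays missing.

    An observed zero or negative value is an error: zeros should already
    have been converted to missing by the reader.
    """
    if matrix.log_scale:
        raise ValueError("matrix is already log2-transformed")
    arr = matrix.values.to_numpy(dtype=float)
    bad = np.isfinite(arr) & (arr <= 0)
    if bad.any():
        raise ValueError("observed values <= 0; zeros must be converted to missing on read")
    out = matrix.with_values(np.log2(matrix.values), log_scale=True)
    if report is not None:
        report.record("log2_transform")
    return out


def quantile_normalize(matrix: QuantMatrix,
                       report: PreprocessReport | None = None) -> QuantMatrix:
    """Quantile normalization across runs on the log scale.

    Every run's observed values are replaced by the reference
    distribution (the across-run mean of sorted values, interpolated for
    runs with differing numbers of observations); tied values receive
    the mean of their candidate quantile targets.  Runs with fewer than
    two observed values are left untouched with a warning.
    """
    values = matrix.values
    n = len(values.index)
    if n == 0:
        raise ValueError("empty matrix")
    grid = np.linspace(0.0, 1.0, num=max(n, 2))
    curves = []
    usable = []
    for run in values.columns:
        obs = values[run].dropna().to_numpy()
        if obs.size < 2:
            warnings.warn(f"run {run!r} has < 2 observed values; excluded from "
                          "quantile normalization", stacklevel=2)
            continue
        usable.append(run)
        sv = np.sort(obs)
        curves.append(np.interp(grid, np.linspace(0.0, 1.0, sv.size), sv))
    if not usable:
        raise ValueError("no run has enough observed values to normalize")
    reference = np.mean(curves, axis=0)

    out = values.copy()
    for run in usable:
        col = values[run]
        obs_mask = col.notna()
        obs = col[obs_mask]
        # average ranks handle ties -> mean of the tied quantile targets
        ranks = obs.rank(method="average").to_numpy()
        n_j = obs.size
        pos = np.zeros(n_j) if n_j == 1 else (ranks - 1.0) / (n_j - 1.0)
        out.loc[obs_mask, run] = np.interp(pos, grid, reference)
    result = matrix.with_values(out)
    if report is not None:
        report.record("quantile_normalize")
    return result


def median_align(matrix: QuantMatrix,
                 report: PreprocessReport | None = None) -> QuantMatrix:
    """Additively shift each run so its observed median equals the grand
    median of run medians (log-scale median re-alignment across runs)."""
    values = matrix.values
    medians = values.median(axis=0, skipna=True)
    grand = float(np.median(medians.dropna()))
    out = values.add(grand - medians, axis=1)
    result = matrix.with_values(out)
    if report is not None:
        report.record("median_align")
    return result


def exclude_high_missing_runs(matrix: QuantMatrix, threshold: float = DEFAULT_MISSING_RUN_MAX,
                              report: PreprocessReport | None = None) -> QuantMatrix:
    """Drop runs whose missing fraction is strictly greater than
    ``threshold`` (a run at exactly the threshold is kept)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    frac = matrix.missing_fraction_per_run()
    keep = frac.index[frac <= threshold]
    if len(keep) == 0:
        raise ValueError("all runs exceed the missing-value threshold")
    out = matrix.subset_runs(keep)
    if report is not None:
        for run in frac.index[frac > threshold]:
            report.runs_excluded[str(run)] = float(frac[run])
        report.thresholds["missing_run_max"] = threshold
        report.record("exclude_high_missing_runs")
    return out


def normalize_to_reference_temperature(matrix: QuantMatrix,
                                       reference: float = REFERENCE_TEMPERATURE,
                                       report: PreprocessReport | None = None) -> QuantMatrix:
    """Convert a full-gradient (TPP) intensity matrix to ratios relative
    to the reference-temperature channel within each (condition, replicate).

    Operates on the intensity (linear) scale; the reference column
    becomes identically 1.  A protein missing its reference value gets
    missing ratios for that replicate.
    """
    if matrix.log_scale:
        raise ValueError("ratio conversion expects linear-scale intensities")
    meta = matrix.run_meta.loc[matrix.values.columns]
    temps = pd.to_numeric(meta["temperature"], errors="coerce")
    out = matrix.values.copy()
    for (_, _), group in meta.groupby(["condition", "replicate"], sort=False):
        runs = list(group.index)
        ref_runs = [r for r in runs if temps[r] == reference]
        if len(ref_runs) != 1:
            raise ValueError(
                f"expected exactly one {reference:g} degC run per (condition, replicate), "
                f"got {len(ref_runs)} for {runs[0]!r}...")
        ref = matrix.values[ref_runs[0]]
        out[runs] = matrix.values[runs].div(ref, axis=0)
    result = matrix.with_values(out)
    if report is not None:
        report.record(f"normalize_to_reference_temperature({reference:g})")
    return result


def average_replicates(matrix: QuantMatrix,
                       report: PreprocessReport | None = None) -> pd.DataFrame:
    """Mean over observed replicate values per (extract, condition).

    Returns a proteins x condition table for reporting and network
    annotation only — statistical tests always consume replicate-level
    data (a t-test needs within-group variance).
    """
    meta = matrix.run_meta.loc[matrix.values.columns]
    keys = meta["extract"].astype(str) + "|" + meta["condition"].astype(str)
    out = matrix.values.T.groupby(keys.to_numpy()).mean().T
    if report is not None:
        report.record("average_replicates")
    return out


def compute_completeness(matrix: QuantMatrix) -> float:
    """Fraction of proteins quantified in every run (data completeness)."""
    if matrix.n_proteins == 0 or matrix.n_runs == 0:
        raise ValueError("empty matrix")
    return float((~matrix.values.isna()).all(axis=1).mean())


def preprocess_pisa(matrix: QuantMatrix, *, normalization: str = "quantile",
                    missing_run_max: float = DEFAULT_MISSING_RUN_MAX
                    ) -> tuple[QuantMatrix, PreprocessReport]:
    """Run the canonical PISA preprocessing chain and return the report.

    ``normalization`` is ``"quantile"`` (isobaric/TMT data),
    ``"median"`` (label-free/DIA data) or ``"none"``.
    """
    if normalization not in ("quantile", "median", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    report = PreprocessReport()
    m = filter_protein_groups(matrix, report)
    m = log2_transform(m, report)
    if normalization == "quantile":
        m = quantile_normalize(m, report)
    elif normalization == "median":
        m = median_align(m, report)
    m = exclude_high_missing_runs(m, missing_run_max, report)
    return m, report


__all__ = [
    "PreprocessReport", "filter_protein_groups", "log2_transform",
    "quantile_normalize", "median_align", "exclude_high_missing_runs",
    "normalize_to_reference_temperature", "average_replicates",
    "compute_completeness", "preprocess_pisa",
    "DEFAULT_MISSING_RUN_MAX", "REFERENCE_TEMPERATURE",
]
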