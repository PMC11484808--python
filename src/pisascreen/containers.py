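"""Shared in-memory containers for quantification matrices and study designs.

A :class:`QuantMatrix` is the pipeline's central object: a proteins x runs
intensity table (``pandas.DataFrame`` with ``NaN`` marking missing values)
plus per-run metadata and per-protein quality flags.  Two experimental
layouts share the container: TPP matrices carry one run per
(condition, replicate, temperature) with a numeric ``temperature``, while
PISA matrices carry one run per (condition, replicate) with
``temperature == "pooled"`` because the soluble fractions of several
temperatures were pooled before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Temperature ladder of a full thermal-profiling gradient (deg C).
TPP_TEMPERATURES: tuple[float, ...] = (37.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0, 67.0)

#: Default pooling temperatures for the integral (PISA) layout (deg C).
DEFAULT_POOLING_TEMPERATURES: tuple[float, ...] = (53.0, 56.0, 59.0)

#: Marker used in run metadata for pooled-temperature (PISA) runs.
POOLED = "pooled"

RUN_META_COLUMNS = ("condition", "drug", "concentration", "extract", "replicate", "temperature")
FLAG_COLUMNS = ("is_reverse", "is_contaminant", "has_proteotypic")


@dataclass(frozen=True)
class Condition:
    """One treatment condition: a drug at a concentration in one extract.

    ``extract`` names the biological source (an organ extract or cell
    line); statistics are computed within one extract only.
    """

    drug: str
    concentration: str = ""
    extract: str = "E1"

    @property
    def condition(self) -> str:
        """Condition label, unique within an extract."""
        return f"{self.drug}|{self.concentration}"

    @property
    def label(self) -> str:
        return f"{self.extract}|{self.drug}|{self.concentration}"


@dataclass(frozen=True)
class StudyDesign:
    """Replicate and temperature structure of a thermal-profiling study."""

    conditions: tuple[Condition, ...]
    n_replicates: int = 4
    temperatures: tuple[float, ...] = TPP_TEMPERATURES
    pooling_temperatures: tuple[float, ...] = DEFAULT_POOLING_TEMPERATURES

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate conditions in design")
        pool = self.pooling_temperatures
        if len(pool) and any(b <= a for a, b in zip(pool, pool[1:])):
            raise ValueError("pooling temperatures must be strictly increasing")

    @property
    def extracts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c.extract, None)
        return tuple(seen)


def _make_flags(protein_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"is_reverse": False, "is_contaminant": False, "has_proteotypic": True},
        index=pd.Index(protein_ids, name="protein_id"),
    )


@dataclass
class QuantMatrix:
    """Proteins x runs intensity matrix with metadata and missing mask.

    Parameters
    ----------
    values
        Intensities, index = protein-group identifiers (";"-joined
        accession strings are kept verbatim as keys), columns = run ids.
        ``NaN`` marks a missing (unquantified) value.  Observed values
        must be non-negative; after :func:`pisascreen.preprocess.log2_transform`
        they live on the log2 scale and may be negative (``log_scale`` is
        then set).
    run_meta
        One row per run: condition, drug, concentration, extract,
        replicate and temperature (a float, or :data:`POOLED`).
    flags
        Per-protein booleans ``is_reverse``, ``is_contaminant``,
        ``has_proteotypic``; defaults to unflagged.
    log_scale
        Whether ``values`` are log2-transformed.
    """

    values: pd.DataFrame
    run_meta: pd.DataFrame
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = _make_flags(self.values.index)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate run id: {dup!r}")
        missing_meta = v.columns.difference(self.run_meta.index)
        if len(missing_meta):
            raise ValueError(f"runs without metadata: {list(missing_meta)!r}")
        for col in RUN_META_COLUMNS:
            if col not in self.run_meta.columns:
                raise ValueError(f"run_meta lacks column {col!r}")
        if not self.log_scale:
            arr = v.to_numpy(dtype=float)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError("observed intensities must be non-negative")
        if not self.flags.index.equals(v.index):
            raise ValueError("flags index must match protein ids")

    # -- convenience accessors -------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    def missing_fraction_per_run(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def runs_for(self, *, drug: str | None = None, concentration: str | None = None,
                 extract: str | None = None, condition: str | None = None) -> list[str]:
        """Run ids matching the given metadata filters (AND-combined)."""
        meta = self.run_meta.loc[self.values.columns]
        mask = pd.Series(True, index=meta.index)
        if drug is not None:
            mask &= meta["drug"] == drug
        if concentration is not None:
            mask &= meta["concentration"] == concentration
        if extract is not None:
            mask &= meta["extract"] == extract
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])

    def subset_runs(self, run_ids: Iterable[str]) -> "QuantMatrix":
        run_ids = list(run_ids)
        return QuantMatrix(
            values=self.values[run_ids].copy(),
            run_meta=self.run_meta.loc[run_ids].copy(),
            flags=self.flags.copy(),
            log_scale=self.log_scale,
        )

    def subset_proteins(self, protein_ids: Iterable[str]) -> "QuantMatrix":
        protein_ids = list(protein_ids)
        return QuantMatrix(
            values=self.values.loc[protein_ids].copy(),
            run_meta=self.run_meta.copy(),
            flags=self.flags.loc[protein_ids].copy(),
            log_scale=self.log_scale,
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values.copy(),
            run_meta=self.run_meta.copy(),
            flags=self.flags.copy(),
            log_scale=self.log_scale,
        )

    def with_values(self, values: pd.DataFrame, *, log_scale: bool | None = None) -> "QuantMatrix":
        """New matrix sharing metadata but with replaced values."""
        return QuantMatrix(
            values=values,
            run_meta=self.run_meta.loc[values.columns].copy(),
            flags=self.flags.loc[values.index].copy(),
            log_scale=self.log_scale if log_scale is None else log_scale,
        )


def run_meta_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a run-metadata frame indexed by ``run_id`` from row dicts."""
    meta = pd.DataFrame(rows).set_index("run_id")
    for col in RUN_META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"run metadata lacks column {col!r}")
    return meta


__all__ = [
    "Condition",
    "StudyDesign",
    "QuantMatrix",
    "run_meta_frame",
    "TPP_TEMPERATURES",
    "DEFAULT_POOLING_TEMPERATURES",
    "POOLED",
    "RUN_META_COLUMNS",
    "FLAG_COLUMNS",
]
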