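"""Readers and writers for the two quantification-matrix dialects and the
metadata tables the pipeline consumes.

Supported dialects:

* MaxQuant ``proteinGroups.txt``-like TSV — isobaric (TMT) reporter
  intensities, one column per channel, with ``Reverse`` /
  ``Potential contaminant`` flag columns and per-group proteotypic
  (unique) peptide counts.  Zero intensities encode "not quantified" and
  are converted to missing on read.
* DIA-NN ``pg_matrix``-like TSV — label-free quantification, one
  intensity column per MS run; empty cells (and zeros) are missing.

Readers never filter rows: reverse/contaminant/proteotypic exclusions
happen downstream in :mod:`pisascreen.preprocess` where they are logged.
Protein groups are keyed by their full ";"-joined identifier string,
exactly as emitted by the upstream search engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import POOLED, QuantMatrix, run_meta_frame

FLOAT_FORMAT = "%.9g"  # text round-trip at 9 significant digits

TMT_ID_COLUMN = "Protein IDs"
TMT_REVERSE_COLUMN = "Reverse"
TMT_CONTAMINANT_COLUMN = "Potential contaminant"
TMT_UNIQUE_PEPTIDES_COLUMN = "Peptide counts (unique)"
PG_ID_COLUMN = "Protein.Group"


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DesignError(ValueError):
    """Run columns and the study-design table disagree."""


@dataclass(frozen=True)
class DrugRecord:
    """One drug: fingerprint bits, known targets, tested concentrations."""

    drug_id: str
    fingerprint: frozenset[int] = frozenset()
    known_targets: frozenset[str] = frozenset()
    concentration_labels: frozenset[str] = frozenset()
    smiles: str = ""

    def __post_init__(self) -> None:
        if any((not isinstance(b, (int, np.integer))) or b < 0 for b in self.fingerprint):
            raise ValueError(f"fingerprint bits must be non-negative ints ({self.drug_id})")


@dataclass(frozen=True)
class OrthologMap:
    """Mapping from one species' protein/gene identifiers to human gene symbols."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        if any(not v for v in self.pairs.values()):
            raise ValueError("ortholog map values must be non-empty")

    def get(self, key: str) -> str | None:
        return self.pairs.get(key)


def _channel_frame(channel_map) -> pd.DataFrame:
    """Normalize a channel map (dict column->temperature, or DataFrame) to
    a frame with column/drug/concentration/extract/replicate/temperature."""
    if isinstance(channel_map, Mapping):
        cm = pd.DataFrame({"column": list(channel_map), "temperature": list(channel_map.values())})
    else:
        cm = channel_map.copy()
    if "column" not in cm.columns or "temperature" not in cm.columns:
        raise DesignError("channel map needs 'column' and 'temperature' columns")
    defaults = {"drug": "", "concentration": "", "extract": "E1", "replicate": 1}
    for col, default in defaults.items():
        if col not in cm.columns:
            cm[col] = default
    if "run_id" not in cm.columns:
        cm["run_id"] = cm["column"]
    return cm


def _parse_unique_counts(cell: str) -> bool:
    """True if any group member has >= 1 unique (proteotypic) peptide."""
    if cell is None or str(cell).strip() == "":
        return False
    try:
        return any(int(x) > 0 for x in str(cell).split(";"))
    except ValueError:
        return False


def read_tmt_protein_groups(path, channel_map) -> QuantMatrix:
    """Read a MaxQuant proteinGroups-like TSV of corrected reporter intensities.

    ``channel_map`` maps reporter columns to run metadata: either a dict
    ``{column_name: temperature}`` or a DataFrame with columns
    ``column, temperature`` and optional ``drug, concentration, extract,
    replicate, run_id``.  Zero intensities become missing; flag columns
    populate the per-protein flags (no rows are dropped here).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (TMT_ID_COLUMN, TMT_REVERSE_COLUMN, TMT_CONTAMINANT_COLUMN):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    cm = _channel_frame(channel_map)
    absent = [c for c in cm["column"] if c not in df.columns]
    if absent:
        raise FormatError(f"missing reporter column {absent[0]!r} in {path}")
    ids = pd.Index(df[TMT_ID_COLUMN], name="protein_id")
    if ids.has_duplicates:
        raise FormatError(f"duplicate protein group id {ids[ids.duplicated()][0]!r} in {path}")

    values = df[list(cm["column"])].apply(pd.to_numeric, errors="coerce")
    values = values.mask(values == 0)  # zero encodes "not quantified"
    values.index = ids
    values.columns = list(cm["run_id"])

    if TMT_UNIQUE_PEPTIDES_COLUMN in df.columns:
        proteotypic = df[TMT_UNIQUE_PEPTIDES_COLUMN].map(_parse_unique_counts).to_numpy()
    else:
        proteotypic = np.ones(len(df), dtype=bool)
    flags = pd.DataFrame({
        "is_reverse": (df[TMT_REVERSE_COLUMN].fillna("") == "+").to_numpy(),
        "is_contaminant": (df[TMT_CONTAMINANT_COLUMN].fillna("") == "+").to_numpy(),
        "has_proteotypic": proteotypic,
    }, index=ids)

    meta_rows = [{"run_id": r["run_id"], "condition": f"{r['drug']}|{r['concentration']}",
                  "drug": r["drug"], "concentration": str(r["concentration"]),
                  "extract": r["extract"], "replicate": int(r["replicate"]),
                  "temperature": float(r["temperature"])}
                 for _, r in cm.iterrows()]
    return QuantMatrix(values=values, run_meta=run_meta_frame(meta_rows), flags=flags)


def write_tmt_protein_groups(matrix: QuantMatrix, path) -> None:
    """Write the TMT dialect; missing values are encoded as 0 per the dialect."""
    out = pd.DataFrame({TMT_ID_COLUMN: matrix.protein_ids})
    out[TMT_REVERSE_COLUMN] = np.where(matrix.flags["is_reverse"], "+", "")
    out[TMT_CONTAMINANT_COLUMN] = np.where(matrix.flags["is_contaminant"], "+", "")
    out[TMT_UNIQUE_PEPTIDES_COLUMN] = np.where(matrix.flags["has_proteotypic"], "1", "0")
    for run in matrix.run_ids:
        out[run] = matrix.values[run].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_pg_matrix(path, design_table: pd.DataFrame) -> QuantMatrix:
    """Read a DIA-NN pg_matrix-like TSV (one intensity column per run).

    ``design_table`` must carry one row per run column: ``column, drug,
    concentration, extract, replicate`` (optional ``run_id``, default the
    column name).  Temperature metadata is set to ``"pooled"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if PG_ID_COLUMN not in df.columns:
        raise FormatError(f"missing required column {PG_ID_COLUMN!r} in {path}")
    dt = design_table.copy()
    if "column" not in dt.columns:
        raise DesignError("design table needs a 'column' column naming run columns")
    if "run_id" not in dt.columns:
        dt["run_id"] = dt["column"]
    for col in ("drug", "concentration", "extract", "replicate"):
        if col not in dt.columns:
            raise DesignError(f"design table lacks column {col!r}")
    absent = [c for c in dt["column"] if c not in df.columns]
    if absent:
        raise DesignError(f"run column {absent[0]!r} absent from {path}")
    ids = pd.Index(df[PG_ID_COLUMN], name="protein_id")
    if ids.has_duplicates:
        raise FormatError(f"duplicate protein group id {ids[ids.duplicated()][0]!r} in {path}")

    values = df[list(dt["column"])].apply(pd.to_numeric, errors="coerce")
    values = values.mask(values == 0)
    values.index = ids
    values.columns = list(dt["run_id"])
    meta_rows = [{"run_id": r["run_id"], "condition": f"{r['drug']}|{r['concentration']}",
                  "drug": r["drug"], "concentration": str(r["concentration"]),
                  "extract": r["extract"], "replicate": int(r["replicate"]),
                  "temperature": POOLED}
                 for _, r in dt.iterrows()]
    return QuantMatrix(values=values, run_meta=run_meta_frame(meta_rows))


def write_pg_matrix(matrix: QuantMatrix, path) -> None:
    """Write the pg_matrix dialect; missing values become empty cells."""
    out = pd.DataFrame({PG_ID_COLUMN: matrix.protein_ids})
    for run in matrix.run_ids:
        out[run] = matrix.values[run].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _split_set(cell: str, sep: str = ";") -> frozenset[str]:
    if cell is None or str(cell).strip() == "" or str(cell) == "nan":
        return frozenset()
    return frozenset(x.strip() for x in str(cell).split(sep) if x.strip())


def read_drug_table(path) -> dict[str, DrugRecord]:
    """Read the drug metadata TSV.

    Headers: ``drug_id`` (required), ``fingerprint`` (";"-separated on-bit
    indices), ``known_targets`` (";"-separated gene symbols),
    ``concentrations`` (";"-separated labels), ``smiles``.  Empty fields
    yield empty sets.  Malformed rows raise with their line number.
    """
    drugs: dict[str, DrugRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "drug_id" not in reader.fieldnames:
            raise FormatError(f"missing required column 'drug_id' in {path}")
        for lineno, row in enumerate(reader, start=2):
            drug_id = (row.get("drug_id") or "").strip()
            if not drug_id:
                raise FormatError(f"{path}: line {lineno}: empty drug_id")
            if drug_id in drugs:
                raise FormatError(f"{path}: line {lineno}: duplicate drug_id {drug_id!r}")
            try:
                bits = frozenset(int(b) for b in _split_set(row.get("fingerprint", "")))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad fingerprint bit ({exc})") from exc
            try:
                drugs[drug_id] = DrugRecord(
                    drug_id=drug_id,
                    fingerprint=bits,
                    known_targets=_split_set(row.get("known_targets", "")),
                    concentration_labels=_split_set(row.get("concentrations", "")),
                    smiles=(row.get("smiles") or "").strip(),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return drugs


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV ``source_id<TAB>human_gene``; duplicate keys are an error."""
    pairs: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        for lineno, row in enumerate(reader, start=2):
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
            key, value = row[0].strip(), row[1].strip()
            if key in pairs:
                raise FormatError(f"{path}: line {lineno}: duplicate key {key!r}")
            if not value:
                raise FormatError(f"{path}: line {lineno}: empty ortholog for {key!r}")
            pairs[key] = value
    return OrthologMap(pairs=pairs)


def read_homology_table(path) -> pd.DataFrame:
    """Read STRING-style scored protein pairs: ``protein_a, protein_b, score``.

    Scores are kept as numeric weights; no cutoff is applied.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    for col in ("protein_a", "protein_b", "score"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    try:
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric homology score ({exc})") from exc
    return df[["protein_a", "protein_b", "score"]]


RESULT_COLUMNS = [
    "drug", "concentration", "extract", "protein_id", "log2_fc",
    "t_statistic", "p_value", "q_value", "n_treated", "n_control",
    "significant", "direction",
]


def write_results(results: pd.DataFrame, path) -> None:
    """Write a screen-result table with deterministic column order (UTF-8 TSV)."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "concentration": str,
                                            "extract": str, "protein_id": str})
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


__all__ = [
    "DrugRecord", "OrthologMap", "FormatError", "DesignError",
    "read_tmt_protein_groups", "write_tmt_protein_groups",
    "read_pg_matrix", "write_pg_matrix",
    "read_drug_table", "read_ortholog_map", "read_homology_table",
    "write_results", "read_results", "RESULT_COLUMNS",
]
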