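"""Shared fixtures: tiny synthetic matrices, drug tables and designs.

All fixture data is generated programmatically; no binary files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pisascreen import (
    Condition,
    DrugRecord,
    EffectSpec,
    MeltModel,
    NoiseSpec,
    QuantMatrix,
    StudyDesign,
    simulate_pisa,
)
from pisascreen.containers import run_meta_frame

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def simple_model() -> MeltModel:
    return MeltModel(tm_celsius=53.0, slope=1.0, plateau=0.0)


@pytest.fixture
def small_design() -> StudyDesign:
    conditions = (
        Condition("DMSO", "", "E1"),
        Condition("drugA", "10uM", "E1"),
        Condition("drugB", "10uM", "E1"),
    )
    return StudyDesign(conditions=conditions, n_replicates=4)


@pytest.fixture
def small_models() -> dict[str, MeltModel]:
    return {
        "P1": MeltModel(tm_celsius=50.0, slope=1.0, plateau=0.05),
        "P2": MeltModel(tm_celsius=53.0, slope=1.2, plateau=0.0),
        "P3": MeltModel(tm_celsius=56.0, slope=0.8, plateau=0.1),
    }


@pytest.fixture
def noiseless() -> NoiseSpec:
    return NoiseSpec(cv=0.0, missing_rate=0.0, seed=7)


@pytest.fixture
def pisa_matrix(small_design, small_models, noiseless) -> QuantMatrix:
    effects = [EffectSpec("P2", "drugA", delta_tm=3.0)]
    matrix, _ = simulate_pisa(small_design, small_models, effects, noiseless)
    return matrix


def make_matrix(values: np.ndarray, protein_ids=None, run_ids=None,
                temperatures=None, drugs=None, log_scale=False) -> QuantMatrix:
    """Hand-rolled QuantMatrix for arithmetic-oracle tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    protein_ids = protein_ids or [f"P{i}" for i in range(n)]
    run_ids = run_ids or [f"run{j}" for j in range(m)]
    temperatures = temperatures if temperatures is not None else ["pooled"] * m
    drugs = drugs or ["drugX"] * m
    meta = run_meta_frame([
        {"run_id": r, "condition": f"{d}|c", "drug": d, "concentration": "c",
         "extract": "E1", "replicate": 1, "temperature": t}
        for j, (r, d, t) in enumerate(zip(run_ids, drugs, temperatures))
    ])
    df = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                      columns=run_ids)
    return QuantMatrix(values=df, run_meta=meta, log_scale=log_scale)


@pytest.fixture
def toy_drugs() -> dict[str, DrugRecord]:
    """Toy drug table: a shared-target pair (A, B), a tau = 0.6 pair
    (A, C via fingerprints {1,2,3} vs {1,2,3,4,5}), and drug D at two
    concentrations, unrelated to the rest."""
    return {
        "A": DrugRecord("A", fingerprint=frozenset({1, 2, 3}),
                        known_targets=frozenset({"PTGS1"}),
                        concentration_labels=frozenset({"10uM"})),
        "B": DrugRecord("B", fingerprint=frozenset({10, 11}),
                        known_targets=frozenset({"PTGS1", "EGFR"}),
                        concentration_labels=frozenset({"10uM"})),
        "C": DrugRecord("C", fingerprint=frozenset({1, 2, 3, 4, 5}),
                        known_targets=frozenset(),
                        concentration_labels=frozenset({"10uM"})),
        "D": DrugRecord("D", fingerprint=frozenset({20, 21}),
                        known_targets=frozenset({"HEXB"}),
                        concentration_labels=frozenset({"1uM", "10uM"})),
    }
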