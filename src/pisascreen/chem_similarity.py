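"""Pairwise drug similarity and control-exclusion sets.

Structural similarity is the Tanimoto index over binary fingerprint bit
sets, tau = |A & B| / |A | B| (0 by convention when both sets are
empty, so an unfingerprintable drug never excludes controls by
similarity).  A drug's control pool excludes

  i)   its own conditions at other concentrations,
  ii)  drugs with tau >= 0.6 (threshold inclusive), and
  iii) drugs sharing at least one known target,

so that a true target of the tested drug is never hidden inside its own
control distribution.  Fingerprint generation is pluggable: precomputed
bit sets in the drug table are preferred, with an rdkit path-based
fingerprint available for SMILES input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quant_io import DrugRecord

#: Exclusion threshold on the Tanimoto index (inclusive).
DEFAULT_TAU_EXCLUDE = 0.6

REASON_SAME_DRUG = "same-drug-other-concentration"
REASON_SIMILAR = "similar-structure"
REASON_SHARED_TARGET = "shared-target"


def tanimoto(fp_a: Iterable[int], fp_b: Iterable[int]) -> float:
    """Tanimoto index |A & B| / |A | B| of two fingerprint bit sets.

    Both empty -> 0 by convention.
    """
    a, b = set(fp_a), set(fp_b)
    if any((not isinstance(x, (int, np.integer))) or x < 0 for x in a | b):
        raise ValueError("fingerprint bits must be non-negative integers")
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric drug-drug Tanimoto matrix with unit diagonal for
    non-empty fingerprints."""

    tanimoto: pd.DataFrame

    @property
    def drug_ids(self) -> list[str]:
        return list(self.tanimoto.index)

    def tau(self, a: str, b: str) -> float:
        try:
            return float(self.tanimoto.at[a, b])
        except KeyError as exc:
            raise KeyError(f"drug {exc.args[0]!r} missing from similarity matrix") from exc

    def to_tsv(self, path) -> None:
        self.tanimoto.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return cls(tanimoto=df)


def compute_similarity_matrix(drugs: Mapping[str, DrugRecord]) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix over the drug table's fingerprints."""
    ids = sorted(drugs)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            tau = tanimoto(drugs[a].fingerprint, drugs[b].fingerprint)
            mat.at[a, b] = tau
            mat.at[b, a] = tau
    return SimilarityMatrix(tanimoto=mat)


@dataclass
class ExclusionSet:
    """Per tested drug: conditions removed from its control pool.

    ``excluded[test_drug]`` maps each excluded (drug, concentration)
    condition label to the set of reasons for the exclusion.
    """

    excluded: dict[str, dict[tuple[str, str], frozenset[str]]] = field(default_factory=dict)

    def excluded_conditions(self, test_drug: str) -> set[tuple[str, str]]:
        return set(self.excluded.get(test_drug, {}))

    def excluded_drugs(self, test_drug: str) -> set[str]:
        return {drug for drug, _ in self.excluded_conditions(test_drug)}

    def reasons(self, test_drug: str, condition: tuple[str, str]) -> frozenset[str]:
        return self.excluded.get(test_drug, {}).get(condition, frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"test_drug": d, "excluded_drug": c[0], "excluded_concentration": c[1],
                 "reasons": ";".join(sorted(r))}
                for d in sorted(self.excluded)
                for c, r in sorted(self.excluded[d].items())]
        return pd.DataFrame(rows, columns=["test_drug", "excluded_drug",
                                           "excluded_concentration", "reasons"])


def build_exclusions(drugs: Mapping[str, DrugRecord], sim: SimilarityMatrix,
                     tau_threshold: float = DEFAULT_TAU_EXCLUDE) -> ExclusionSet:
    """Build the control-exclusion sets from similarity and shared targets.

    Similarity (tau >= ``tau_threshold``, inclusive) and shared-target
    exclusions are symmetric between drug pairs; every drug additionally
    excludes its own conditions at all concentrations (rule i — a drug is
    never its own control).  The result is independent of drug-table
    row order.
    """
    missing = [d for d in drugs if d not in sim.tanimoto.index]
    if missing:
        raise KeyError(f"drug {missing[0]!r} missing from similarity matrix")

    out: dict[str, dict[tuple[str, str], set[str]]] = {d: {} for d in drugs}

    def add(test_drug: str, other: DrugRecord, reason: str) -> None:
        concs = sorted(other.concentration_labels) or [""]
        for conc in concs:
            out[test_drug].setdefault((other.drug_id, conc), set()).add(reason)

    for a in drugs.values():
        add(a.drug_id, a, REASON_SAME_DRUG)
        for b in drugs.values():
            if b.drug_id == a.drug_id:
                continue
            if sim.tau(a.drug_id, b.drug_id) >= tau_threshold:
                add(a.drug_id, b, REASON_SIMILAR)
                add(b.drug_id, a, REASON_SIMILAR)
            if a.known_targets & b.known_targets:
                add(a.drug_id, b, REASON_SHARED_TARGET)
                add(b.drug_id, a, REASON_SHARED_TARGET)

    return ExclusionSet(excluded={
        d: {c: frozenset(r) for c, r in conds.items()} for d, conds in out.items()
    })


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048) -> frozenset[int]:
    """Path-based binary fingerprint of a SMILES string (rdkit backend).

    Optional: when no fingerprinting backend is available the pipeline
    requires precomputed fingerprints in the drug table instead.  An
    empty or unparseable SMILES raises.
    """
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    try:
        from rdkit import Chem  # noqa: PLC0415 (optional backend)
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - backend present in CI
        raise RuntimeError(
            "no fingerprinting backend available; supply precomputed "
            "fingerprints in the drug table") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


__all__ = [
    "tanimoto", "SimilarityMatrix", "compute_similarity_matrix",
    "ExclusionSet", "build_exclusions", "fingerprint_from_smiles",
    "DEFAULT_TAU_EXCLUDE", "REASON_SAME_DRUG", "REASON_SIMILAR",
    "REASON_SHARED_TARGET",
]
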