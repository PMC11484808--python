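"""Protein-drug target-network assembly and export.

The network summarizes a screen: drug and protein nodes, with

* ``association`` edges — one per significant (drug, concentration,
  protein, extract) result, attributed with extract, direction
  (stabilized/destabilized), log2 fold change and q-value.  A target
  found in several extracts yields parallel edges;
* ``known_target`` edges — curated drug-target pairs for the tested
  drugs (their target proteins are added as nodes and flagged);
* ``drug_similarity`` edges — Tanimoto index strictly > 0.6 (note the
  exclusion rule in the screen is inclusive at 0.6; the edge rule is
  strict, as the two thresholds serve different purposes);
* ``homology`` edges — scored protein-protein pairs, restricted to
  proteins already present as nodes, so homologs can reveal an expected
  target that the screen itself missed.

Results from different species are first harmonized to human gene
symbols via :func:`map_orthologs`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .chem_similarity import SimilarityMatrix
from .pisa_stats import DESTABILIZED, STABILIZED
from .quant_io import DrugRecord, OrthologMap

#: Drug-drug similarity edges require tau strictly above this.
DEFAULT_TAU_EDGE = 0.6

ASSOCIATION = "association"
KNOWN_TARGET = "known_target"
DRUG_SIMILARITY = "drug_similarity"
HOMOLOGY = "homology"

EXPORT_FORMATS = ("graphml", "sif", "tsv")


def map_orthologs(results: pd.DataFrame, ortholog_map: OrthologMap) -> pd.DataFrame:
    """Replace protein-group identifiers with human gene symbols.

    The representative of a ";"-joined protein group is its first
    identifier; identifiers without an ortholog are retained verbatim
    and flagged in the added ``unmapped`` column.  Adds a ``gene``
    column and keeps ``protein_id`` untouched.
    """
    out = results.copy()
    representatives = out["protein_id"].astype(str).str.split(";").str[0]
    mapped = representatives.map(lambda r: ortholog_map.get(r))
    out["gene"] = mapped.fillna(representatives)
    out["unmapped"] = mapped.isna()
    return out


def build_network(results: pd.DataFrame, drugs: Mapping[str, DrugRecord],
                  sim: SimilarityMatrix | None = None,
                  homology: pd.DataFrame | None = None,
                  tau_edge: float = DEFAULT_TAU_EDGE) -> nx.MultiGraph:
    """Assemble the typed target network from significance-filtered results.

    ``results`` must contain only significant rows (columns: drug,
    concentration, extract, log2_fc, q_value, direction and a protein
    label in ``gene`` or ``protein_id``).  Node attribute ``kind`` is
    ``"drug"`` or ``"protein"``; protein nodes carry ``known_target``.
    The graph is invariant to row order of the inputs.
    """
    label_col = "gene" if "gene" in results.columns else "protein_id"
    G = nx.MultiGraph()

    tested_drugs = sorted(set(results["drug"].astype(str)))
    for d in tested_drugs:
        G.add_node(d, kind="drug")

    rows = results.sort_values(
        ["drug", "concentration", "extract", label_col], kind="stable")
    for _, row in rows.iterrows():
        protein = str(row[label_col])
        fc = float(row["log2_fc"])
        if fc == 0.0:
            # cannot happen for significant rows (|log2FC| >= 0.5 > 0);
            # direction would be undefined
            raise ValueError(f"significant association with log2_fc == 0: {row.to_dict()}")
        direction = STABILIZED if fc > 0 else DESTABILIZED
        if "direction" in row and isinstance(row["direction"], str) and row["direction"]:
            direction = row["direction"]
        if protein not in G:
            G.add_node(protein, kind="protein", known_target=False)
        G.add_edge(str(row["drug"]), protein, edge_type=ASSOCIATION,
                   extract=str(row.get("extract", "")),
                   concentration=str(row.get("concentration", "")),
                   direction=direction, log2_fc=fc,
                   q_value=float(row.get("q_value", float("nan"))))

    # curated known-target edges for the tested drugs; targets are added
    # as nodes so missed-but-expected targets appear in the map
    for d in tested_drugs:
        rec = drugs.get(d)
        if rec is None:
            continue
        for target in sorted(rec.known_targets):
            if target not in G:
                G.add_node(target, kind="protein", known_target=True)
            else:
                G.nodes[target]["known_target"] = True
            G.add_edge(d, target, edge_type=KNOWN_TARGET)

    if sim is not None:
        for i, a in enumerate(tested_drugs):
            for b in tested_drugs[i + 1:]:
                if a in sim.tanimoto.index and b in sim.tanimoto.index:
                    tau = sim.tau(a, b)
                    if tau > tau_edge:  # strictly above
                        G.add_edge(a, b, edge_type=DRUG_SIMILARITY, tanimoto=float(tau))

    if homology is not None:
        pairs = homology.sort_values(["protein_a", "protein_b"], kind="stable")
        for _, row in pairs.iterrows():
            a, b = str(row["protein_a"]), str(row["protein_b"])
            if a in G and b in G and a != b:
                if G.nodes[a]["kind"] == "protein" and G.nodes[b]["kind"] == "protein":
                    G.add_edge(a, b, edge_type=HOMOLOGY, score=float(row["score"]))
    return G


def _sorted_copy(G: nx.MultiGraph) -> nx.MultiGraph:
    """Copy with deterministically ordered nodes and edges."""
    H = nx.MultiGraph()
    for n in sorted(G.nodes):
        H.add_node(n, **G.nodes[n])
    edges = sorted(G.edges(keys=True, data=True),
                   key=lambda e: (str(e[0]), str(e[1]), e[3].get("edge_type", ""),
                                  e[3].get("extract", ""), e[3].get("concentration", "")))
    for u, v, _, data in edges:
        H.add_edge(u, v, **data)
    return H


def export_network(G: nx.MultiGraph, path, fmt: str = "graphml") -> list[Path]:
    """Export the network; returns the written paths.

    Formats: ``graphml`` (lossless; re-import reproduces the graph),
    ``sif`` (one ``source<TAB>edge_type<TAB>target`` line per edge), or
    ``tsv`` (paired ``<path>.nodes.tsv`` / ``<path>.edges.tsv`` tables).
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    path = Path(path)
    H = _sorted_copy(G)
    if fmt == "graphml":
        nx.write_graphml(H, path)
        return [path]
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in H.edges(data=True):
                fh.write(f"{u}\t{data.get('edge_type', 'edge')}\t{v}\n")
        return [path]
    nodes_path = path.with_suffix(".nodes.tsv")
    edges_path = path.with_suffix(".edges.tsv")
    nodes = pd.DataFrame(
        [{"node": n, **H.nodes[n]} for n in H.nodes],
        columns=["node", "kind", "known_target"])
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edge_cols = ["source", "target", "edge_type", "extract", "concentration",
                 "direction", "log2_fc", "q_value", "tanimoto", "score"]
    edges = pd.DataFrame(
        [{"source": u, "target": v, **data} for u, v, data in H.edges(data=True)],
        columns=edge_cols)
    edges.to_csv(edges_path, sep="\t", index=False)
    return [nodes_path, edges_path]


def import_graphml(path) -> nx.MultiGraph:
    """Read a GraphML export back into a MultiGraph."""
    G = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiGraph(G)


__all__ = [
    "map_orthologs", "build_network", "export_network", "import_graphml",
    "ASSOCIATION", "KNOWN_TARGET", "DRUG_SIMILARITY", "HOMOLOGY",
    "DEFAULT_TAU_EDGE", "EXPORT_FORMATS",
]
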