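"""Config-driven orchestration of the screen: one structured YAML config,
seeded end-to-end, with every applied threshold recorded in the report.

Stages: read + preprocess the pooled-temperature matrix -> build
chemistry-based control exclusions -> differential screen -> ortholog
harmonization -> network assembly and export.  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem_similarity, network, preprocess, quant_io
from .containers import DEFAULT_POOLING_TEMPERATURES, Condition, StudyDesign
from .pisa_stats import ScreenThresholds, run_screen
from .simulate import EffectSpec, NoiseSpec, draw_proteome, simulate_pisa


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the seed of one screen run."""

    # input paths (pg_matrix dialect + metadata tables)
    pisa_matrix: str = ""
    design_table: str = ""
    drug_table: str = ""
    ortholog_map: str = ""      # optional
    homology_table: str = ""    # optional

    normalization: str = "median"   # quantile | median | none
    pooling_temperatures: tuple[float, ...] = DEFAULT_POOLING_TEMPERATURES

    q_max: float = 0.05
    min_abs_log2fc: float = 0.5
    tau_exclude: float = 0.6
    tau_edge: float = 0.6
    missing_run_max: float = 0.40

    seed: int = 0

    # simulation block (used by run_simulation only)
    sim_n_proteins: int = 500
    sim_drugs: tuple[str, ...] = tuple(f"drug{i:02d}" for i in range(1, 24))
    sim_concentration: str = "10uM"
    sim_extracts: tuple[str, ...] = ("E1",)
    sim_n_replicates: int = 4
    sim_cv: float = 0.1
    sim_missing_rate: float = 0.02
    sim_targets_per_drug: int = 1
    sim_delta_tm: float = 3.0

    def validate(self, *, for_simulation: bool = False) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise PipelineError(f"config: q_max must be in (0, 1], got {self.q_max}")
        if self.min_abs_log2fc < 0:
            raise PipelineError("config: min_abs_log2fc must be >= 0")
        for name in ("tau_exclude", "tau_edge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PipelineError(f"config: {name} must be in [0, 1], got {v}")
        if not (0.0 < self.missing_run_max < 1.0):
            raise PipelineError("config: missing_run_max must be in (0, 1)")
        pool = tuple(self.pooling_temperatures)
        if len(pool) == 0 or any(b <= a for a, b in zip(pool, pool[1:])):
            raise PipelineError("config: pooling_temperatures must be non-empty, strictly increasing")
        if self.normalization not in ("quantile", "median", "none"):
            raise PipelineError(f"config: unknown normalization {self.normalization!r}")
        if for_simulation:
            if not self.sim_drugs:
                raise PipelineError("config: simulation needs at least one drug")
            if self.sim_n_proteins < 1:
                raise PipelineError("config: sim_n_proteins must be >= 1")
        else:
            for name in ("pisa_matrix", "design_table", "drug_table"):
                p = getattr(self, name)
                if not p:
                    raise PipelineError(f"config: required path {name!r} not set")
                if not Path(p).exists():
                    raise PipelineError(f"config: {name} path does not exist: {p}")
            for name in ("ortholog_map", "homology_table"):
                p = getattr(self, name)
                if p and not Path(p).exists():
                    raise PipelineError(f"config: {name} path does not exist: {p}")


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are an error (typo protection)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    for key in ("pooling_temperatures", "sim_drugs", "sim_extracts"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def run_simulation(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Generate a synthetic PISA screen: matrix + design + drug table +
    ground truth, written in the pipeline's own input dialects."""
    config.validate(for_simulation=True)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    conditions = tuple(Condition(drug=d, concentration=config.sim_concentration, extract=x)
                       for x in config.sim_extracts for d in config.sim_drugs)
    design = StudyDesign(conditions=conditions, n_replicates=config.sim_n_replicates,
                         pooling_temperatures=tuple(config.pooling_temperatures))
    models = draw_proteome(config.sim_n_proteins, seed=config.seed)
    pids = list(models)
    effects = []
    for i, drug in enumerate(config.sim_drugs):
        for j in range(config.sim_targets_per_drug):
            pid = pids[(i * config.sim_targets_per_drug + j) % len(pids)]
            effects.append(EffectSpec(protein_id=pid, drug_id=drug,
                                      delta_tm=config.sim_delta_tm))
    noise = NoiseSpec(cv=config.sim_cv, missing_rate=config.sim_missing_rate,
                      seed=config.seed)
    matrix, truth = simulate_pisa(design, models, effects, noise)

    paths = {
        "pisa_matrix": outdir / "pisa_pg_matrix.tsv",
        "design_table": outdir / "design.tsv",
        "drug_table": outdir / "drugs.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    quant_io.write_pg_matrix(matrix, paths["pisa_matrix"])
    meta = matrix.run_meta.reset_index().rename(columns={"run_id": "column"})
    meta[["column", "drug", "concentration", "extract", "replicate"]].to_csv(
        paths["design_table"], sep="\t", index=False)
    pd.DataFrame({
        "drug_id": list(config.sim_drugs),
        "fingerprint": "",
        "known_targets": "",
        "concentrations": config.sim_concentration,
        "smiles": "",
    }).to_csv(paths["drug_table"], sep="\t", index=False)
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, object]:
    """Execute preprocess -> screen -> ortholog mapping -> network.

    Writes the results TSV, network exports and a JSON report of every
    threshold applied; returns {name: path or object} for the outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    design_table = stage("read-design", lambda: pd.read_csv(config.design_table, sep="\t"))
    matrix = stage("read-matrix",
                   lambda: quant_io.read_pg_matrix(config.pisa_matrix, design_table))
    prepped, report = stage("preprocess", lambda: preprocess.preprocess_pisa(
        matrix, normalization=config.normalization,
        missing_run_max=config.missing_run_max))

    drugs = stage("read-drugs", lambda: quant_io.read_drug_table(config.drug_table))
    sim = stage("similarity", lambda: chem_similarity.compute_similarity_matrix(drugs))
    exclusions = stage("exclusions", lambda: chem_similarity.build_exclusions(
        drugs, sim, tau_threshold=config.tau_exclude))

    thresholds = ScreenThresholds(q_max=config.q_max, min_abs_log2fc=config.min_abs_log2fc)
    results = stage("screen", lambda: run_screen(prepped, exclusions, thresholds))

    if config.ortholog_map:
        omap = stage("read-orthologs", lambda: quant_io.read_ortholog_map(config.ortholog_map))
        results = stage("map-orthologs", lambda: network.map_orthologs(results, omap))

    homology = None
    if config.homology_table:
        homology = stage("read-homology",
                         lambda: quant_io.read_homology_table(config.homology_table))

    significant = results[results["significant"]]
    G = stage("network", lambda: network.build_network(
        significant, drugs, sim, homology, tau_edge=config.tau_edge))

    results_path = outdir / "screen_results.tsv"
    quant_io.write_results(results, results_path)
    graphml_path = outdir / "target_network.graphml"
    network.export_network(G, graphml_path, fmt="graphml")
    tsv_paths = network.export_network(G, outdir / "target_network.tsv", fmt="tsv")
    sim.to_tsv(outdir / "drug_similarity.tsv")
    exclusions.to_frame().to_csv(outdir / "control_exclusions.tsv", sep="\t", index=False)

    report_payload = {
        "preprocess": asdict(report),
        "thresholds": {
            "q_max": config.q_max, "min_abs_log2fc": config.min_abs_log2fc,
            "tau_exclude": config.tau_exclude, "tau_edge": config.tau_edge,
            "missing_run_max": config.missing_run_max,
        },
        "normalization": config.normalization,
        "seed": config.seed,
        "n_tests": int(results["p_value"].notna().sum()),
        "n_significant": int(results["significant"].sum()),
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report_payload, indent=2, sort_keys=True),
                           encoding="utf-8")
    return {
        "results": results_path, "graphml": graphml_path, "tsv": tsv_paths,
        "similarity": outdir / "drug_similarity.tsv", "report": report_path,
        "screen_table": results, "network": G,
    }


__all__ = ["PipelineConfig", "PipelineError", "load_config",
           "run_simulation", "run_pipeline"]
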