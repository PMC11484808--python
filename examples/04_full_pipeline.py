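"""The whole pipeline in two calls: simulate a screen, then analyze it.

`run_simulation` writes a label-free (pg_matrix-dialect) intensity
matrix, a run-design table, a drug table and the ground truth;
`run_pipeline` reads them back, preprocesses (filter -> log2 -> median
alignment -> run exclusion), screens every drug against the others,
and assembles the target network.  Equivalent shell usage:

    pisascreen all --seed 11 --out out/
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from pisascreen import PipelineConfig, run_pipeline, run_simulation

workdir = Path(tempfile.mkdtemp(prefix="pisascreen_"))
cfg = PipelineConfig(seed=11, sim_n_proteins=200,
                     sim_drugs=tuple(f"d{i:02d}" for i in range(10)),
                     sim_cv=0.08, sim_missing_rate=0.02, sim_targets_per_drug=2)

paths = run_simulation(cfg, workdir / "sim")
cfg.pisa_matrix = str(paths["pisa_matrix"])
cfg.design_table = str(paths["design_table"])
cfg.drug_table = str(paths["drug_table"])

out = run_pipeline(cfg, workdir / "out")
report = json.loads(Path(out["report"]).read_text())
print(f"tests run: {report['n_tests']}, significant: {report['n_significant']}, "
      f"network: {report['n_nodes']} nodes / {report['n_edges']} edges")

truth = pd.read_csv(paths["ground_truth"], sep="\t")
hits = out["screen_table"]
hits = hits[hits["significant"]]
true_pairs = set(zip(truth["drug_id"], truth["protein_id"]))
called = set(zip(hits["drug"], hits["protein_id"]))
tp = len(true_pairs & called)
print(f"planted targets: {len(true_pairs)}, recovered: {tp}, "
      f"false positives: {len(called) - tp}")
print(f"outputs in {workdir}/out (screen_results.tsv, target_network.graphml, "
      "report.json)")
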