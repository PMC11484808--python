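# pisascreen

Drug-target deconvolution from protein thermal stability, for
proteomics and chemical-biology groups running thermal proteome
profiling (TPP/CETSA) or its integral variant, PISA (proteome integral
solubility alteration).

When a drug binds a protein, the protein's melting behavior changes.
TPP measures the soluble fraction after heating at a ladder of
temperatures and fits a melting curve per protein,

s(T) = (1 − p) / (1 + exp(k (T − Tm))) + p,

where Tm is the melting point (50 % of the meltable protein still
soluble), k the steepness and p a non-denaturing plateau. PISA skips
the curve: the soluble fractions at a few temperatures just above the
proteome's median Tm (53/56/59 °C) are pooled, and drug-induced
stabilization (ΔTm > 0) appears as a pooled-abundance increase —
turning target identification into a differential-abundance test that
scales to drug panels.

The package provides, as a library plus a thin `pisascreen` CLI:

* **simulation** of TPP and PISA quantification matrices with known
  ground truth (logistic melting, signed ΔTm effects, log-normal noise,
  missing values; seeded and bit-reproducible);
* **I/O** for MaxQuant `proteinGroups`-style (TMT reporter) and DIA-NN
  `pg_matrix`-style (label-free) TSVs plus drug / ortholog / homology
  metadata tables;
* **preprocessing**: flag filtering, log2, quantile normalization or
  median re-alignment, >40 %-missing run exclusion, 37 °C ratio
  conversion;
* **melting-curve fitting** with QC, Tm-shift t-tests, and Tm
  distribution summaries;
* **the PISA screen**: per-drug equal-variance t-tests against the
  pooled runs of all other drugs — excluding the same drug at other
  concentrations, structurally similar drugs (Tanimoto ≥ 0.6) and
  drugs sharing a known target — with Storey q-values per comparison
  and significance at q ≤ 0.05, |log2FC| ≥ 0.5;
* **network assembly**: typed drug–protein graphs (association /
  known-target / drug-similarity / homology edges) after rat→human
  ortholog harmonization, exported as GraphML/SIF/TSV for Cytoscape.

See `docs/methods.md` for the models and defaults, and `examples/` for
one narrative script per capability.

## Worked example

Simulate a 12-drug screen with one planted target per drug and run the
full analysis (`python examples/02_pisa_screen.py`):

```python
import numpy as np
import pisascreen as ps
from pisascreen.preprocess import log2_transform

rng = np.random.default_rng(7)
drugs = [f"drug{i:02d}" for i in range(12)]
design = ps.StudyDesign(
    conditions=tuple(ps.Condition(d, "10uM", "liver") for d in drugs),
    n_replicates=4)
models = ps.draw_proteome(300, seed=7)
targets = dict(zip(drugs, rng.choice(list(models), 12, replace=False)))
effects = [ps.EffectSpec(p, d, delta_tm=3.0) for d, p in targets.items()]
matrix, truth = ps.simulate_pisa(design, models, effects,
                                 ps.NoiseSpec(cv=0.1, missing_rate=0.02, seed=7))
results = ps.run_screen(log2_transform(matrix))
```

This prints:

```
3600 (drug, protein) tests, 7 significant (q <= 0.05 and |log2FC| >= 0.5)
planted targets recovered: 7/12

Top hits (log2FC > 0 means the drug thermally stabilized the protein):
  drug protein_id  log2_fc  q_value  direction
drug00     P00016   2.2042      0.0 stabilized
drug03     P00261   1.8181      0.0 stabilized
...
```

Each row is one (drug, protein) comparison of the drug's 4 replicates
against the pooled runs of the other drugs: `log2_fc` is the pooled
solubility change (positive = stabilized, i.e. a likely target or
downstream effector), `q_value` the Storey-adjusted FDR. All seven
calls here are planted targets; the five missed ones melt too far
below the 53/56/59 °C pooling window to shift the integral — the
intrinsic blind spot of the pooled readout.

The same from the shell:

```bash
pisascreen all --seed 7 --out out/
# -> out/screen_results.tsv, out/target_network.graphml, out/report.json
```

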