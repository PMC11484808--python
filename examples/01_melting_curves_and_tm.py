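"""Simulate a full thermal gradient, fit melting curves, recover Tm.

A protein's soluble fraction falls sigmoidally with temperature; the
melting point Tm is where half of the meltable protein is still
soluble.  Here we simulate a small staurosporine-style experiment
(treated vs vehicle, 4 replicates, ten temperatures from 37 to 67 degC),
convert intensities to ratios against the 37 degC channel, fit the
logistic per replicate, and test the drug-induced Tm shift.
"""

import numpy as np

import pisascreen as ps
from pisascreen.preprocess import normalize_to_reference_temperature

design = ps.StudyDesign(
    conditions=(ps.Condition("DMSO", "", "lysate"),
                ps.Condition("STS", "10uM", "lysate")),
    n_replicates=4,
)
models = {
    "KinaseA": ps.MeltModel(tm_celsius=51.0, slope=1.1, plateau=0.05),
    "Bystander": ps.MeltModel(tm_celsius=54.0, slope=0.9, plateau=0.10),
}
effects = [ps.EffectSpec("KinaseA", "STS", delta_tm=3.0)]  # stabilized by +3 degC

matrix, truth = ps.simulate_tpp(design, models, effects,
                                ps.NoiseSpec(cv=0.05, seed=42))
ratios = normalize_to_reference_temperature(matrix)
fits = ps.fit_all(ratios)

print("Per-replicate fitted melting points (degC):")
print(fits.pivot_table(index="protein_id", columns="drug", values="tm_celsius",
                       aggfunc="mean").round(2))

shift = ps.tm_shift_screen(fits, "STS|10uM", "DMSO|")
print("\nTm-shift test (treated minus control):")
print(shift[["protein_id", "delta_tm", "t_statistic", "p_value"]].round(4))

print("""
KinaseA's mean fitted Tm rises by ~3 degC under staurosporine (its
planted shift) with a small p-value, while the bystander protein shows
no shift: the melting-curve route recovers the ground truth.""")

tm_values = fits.loc[(fits["drug"] == "DMSO") & fits["valid"], "tm_celsius"]
summary = ps.summarize_tm_distribution(tm_values)
print(f"Vehicle Tm median {summary.median:.1f} degC -> suggested pooling "
      f"temperatures {summary.suggested_pooling} (just above the median, "
      "where stabilization is most visible).")
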