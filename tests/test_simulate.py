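"""Melting-model arithmetic and simulator contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pisascreen import (
    Condition,
    EffectSpec,
    MeltModel,
    NoiseSpec,
    StudyDesign,
    inject_missing,
    melt_fraction,
    simulate_pisa,
    simulate_tpp,
)
from pisascreen.containers import TPP_TEMPERATURES


class TestMeltFraction:
    @pytest.mark.parametrize("tm,k,p,t,expected", [
        (53.0, 1.0, 0.0, 53.0, 0.5),        # midpoint of a plateau-free logistic
        (53.0, 1.0, 0.2, 53.0, 0.6),        # (1 - p)/2 + p at Tm
    ])
    def test_midpoint(self, tm, k, p, t, expected):
        m = MeltModel(tm_celsius=tm, slope=k, plateau=p)
        assert melt_fraction(t, m) == pytest.approx(expected, abs=1e-12)

    def test_high_temperature_limit_is_plateau(self):
        m = MeltModel(tm_celsius=53.0, slope=1.0, plateau=0.15)
        assert melt_fraction(53.0 + 1000.0, m) == pytest.approx(0.15, abs=1e-9)

    def test_non_finite_temperature_rejected(self):
        m = MeltModel(tm_celsius=53.0)
        with pytest.raises(ValueError):
            melt_fraction(float("nan"), m)

    @given(tm=st.floats(40, 70), k=st.floats(0.1, 5), p=st.floats(0, 0.9))
    def test_strictly_decreasing_on_grid(self, tm, k, p):
        m = MeltModel(tm_celsius=tm, slope=k, plateau=p)
        grid = np.linspace(tm - 15, tm + 15, 61)
        s = melt_fraction(grid, m)
        assert np.all(np.diff(s) <= 0)
        assert np.all((s > 0) & (s <= 1))
        # strict away from floating-point saturation of the tails
        interior = (s > m.plateau + 1e-9) & (s < 1 - 1e-9)
        idx = np.nonzero(interior[:-1] & interior[1:])[0]
        assert np.all(np.diff(s)[idx] < 0)

    @pytest.mark.parametrize("bad", [
        {"tm_celsius": 53, "slope": 0.0},
        {"tm_celsius": 53, "plateau": 1.0},
        {"tm_celsius": 53, "plateau": -0.1},
        {"tm_celsius": 80.0},                 # outside physical window
        {"tm_celsius": float("inf")},
    ])
    def test_invalid_model_rejected(self, bad):
        with pytest.raises(ValueError):
            MeltModel(**bad)


class TestSimulateTpp:
    def test_no_effect_no_noise_treated_equals_control(self, small_design, noiseless):
        models = {"P1": MeltModel(tm_celsius=52.0)}
        matrix, _ = simulate_tpp(small_design, models, [], noiseless)
        for t in TPP_TEMPERATURES:
            treated = matrix.values[f"E1|drugA|10uM|r1|T{t:g}"]
            control = matrix.values[f"E1|DMSO||r1|T{t:g}"]
            pd.testing.assert_series_equal(treated, control, check_names=False)

    def test_positive_shift_raises_treated_intensities(self, small_design, noiseless):
        models = {"P1": MeltModel(tm_celsius=52.0, slope=1.0)}
        matrix, truth = simulate_tpp(
            small_design, models, [EffectSpec("P1", "drugA", 3.0)], noiseless)
        assert truth.loc[0, "delta_tm"] == 3.0
        for t in TPP_TEMPERATURES:
            treated = matrix.values.at["P1", f"E1|drugA|10uM|r1|T{t:g}"]
            control = matrix.values.at["P1", f"E1|DMSO||r1|T{t:g}"]
            assert treated >= control
            s = melt_fraction(t, models["P1"])
            if 1e-6 < s < 1 - 1e-6:
                assert treated > control

    def test_fixed_seed_is_bit_identical(self, small_design, small_models):
        noise = NoiseSpec(cv=0.2, missing_rate=0.1, seed=11)
        m1, _ = simulate_tpp(small_design, small_models, [], noise)
        m2, _ = simulate_tpp(small_design, small_models, [], noise)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        m3, _ = simulate_tpp(small_design, small_models, [],
                             NoiseSpec(cv=0.2, missing_rate=0.1, seed=12))
        assert not m1.values.equals(m3.values)

    def test_reference_temperature_near_full_solubility(self, small_design, noiseless):
        # at 37 degC a protein with Tm >= 50 is essentially fully soluble
        for tm in (50.0, 55.0, 60.0):
            models = {"P1": MeltModel(tm_celsius=tm, slope=0.6, plateau=0.0)}
            matrix, _ = simulate_tpp(small_design, models, [], noiseless)
            frac = matrix.values.at["P1", "E1|DMSO||r1|T37"] / models["P1"].baseline_abundance
            assert frac >= 0.95

    def test_empty_model_set_rejected(self, small_design, noiseless):
        with pytest.raises(ValueError):
            simulate_tpp(small_design, {}, [], noiseless)

    def test_duplicate_protein_ids_rejected(self, small_design, noiseless):
        pairs = [("P1", MeltModel(tm_celsius=50)), ("P1", MeltModel(tm_celsius=55))]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_tpp(small_design, pairs, [], noiseless)


class TestSimulatePisa:
    def test_pooled_value_matches_direct_arithmetic(self, small_design, noiseless):
        # oracle: evaluate the logistic at 53, 56, 59 and average
        model = MeltModel(tm_celsius=53.0, slope=1.0, plateau=0.0)
        oracle = (0.5 + 1 / (1 + math.e ** 3) + 1 / (1 + math.e ** 6)) / 3
        matrix, _ = simulate_pisa(small_design, {"P1": model}, [], noiseless)
        got = matrix.values.at["P1", "E1|DMSO||r1"] / model.baseline_abundance
        assert got == pytest.approx(oracle, rel=1e-12)
        assert got == pytest.approx(0.18330, abs=5e-6)

    def test_non_melter_keeps_baseline(self, small_design, noiseless):
        # Tm far above the pooling window approximates a flat non-melter
        model = MeltModel(tm_celsius=75.0, slope=1.5, plateau=0.0)
        matrix, _ = simulate_pisa(small_design, {"P1": model}, [], noiseless)
        frac = matrix.values.at["P1", "E1|DMSO||r1"] / model.baseline_abundance
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_stabilization_raises_pooled_intensity(self, small_design, noiseless):
        model = MeltModel(tm_celsius=53.0, slope=1.0)
        matrix, _ = simulate_pisa(small_design, {"P1": model},
                                  [EffectSpec("P1", "drugA", 3.0)], noiseless)
        assert (matrix.values.at["P1", "E1|drugA|10uM|r1"]
                > matrix.values.at["P1", "E1|DMSO||r1"])

    def test_extract_restricted_effect(self, noiseless):
        design = StudyDesign(conditions=(
            Condition("drugA", "10uM", "E1"), Condition("drugA", "10uM", "E2")),
            n_replicates=1)
        model = MeltModel(tm_celsius=53.0)
        eff = [EffectSpec("P1", "drugA", 3.0, applies_in_extracts=frozenset({"E1"}))]
        matrix, _ = simulate_pisa(design, {"P1": model}, eff, noiseless)
        assert (matrix.values.at["P1", "E1|drugA|10uM|r1"]
                > matrix.values.at["P1", "E2|drugA|10uM|r1"])

    def test_empty_pooling_set_rejected(self, small_models, noiseless):
        design = StudyDesign(conditions=(Condition("DMSO"),), pooling_temperatures=())
        with pytest.raises(ValueError, match="pooling"):
            simulate_pisa(design, small_models, [], noiseless)


class TestInjectMissing:
    def test_zero_rate_is_identity(self, pisa_matrix):
        out = inject_missing(pisa_matrix, NoiseSpec(missing_rate=0.0, seed=3))
        pd.testing.assert_frame_equal(out.values, pisa_matrix.values)

    def test_rate_one_rejected(self, pisa_matrix):
        with pytest.raises(ValueError):
            NoiseSpec(missing_rate=1.0)

    def test_seeded_mask_is_reproducible(self, pisa_matrix):
        a = inject_missing(pisa_matrix, NoiseSpec(missing_rate=0.3, seed=5))
        b = inject_missing(pisa_matrix, NoiseSpec(missing_rate=0.3, seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.values.isna().to_numpy().sum() > 0

    def test_intensity_dependent_mode_prefers_low_intensity(self, small_design):
        models = {f"P{i}": MeltModel(tm_celsius=50 + (i % 10),
                                     baseline_abundance=10.0 ** (4 + 4 * (i % 2)))
                  for i in range(200)}
        matrix, _ = simulate_pisa(small_design, models, [], NoiseSpec(cv=0, seed=1))
        out = inject_missing(matrix, NoiseSpec(missing_rate=0.3, seed=2,
                                               intensity_dependent_missing=True))
        miss = out.values.isna()
        low = [p for p, m in models.items() if m.baseline_abundance < 1e6]
        high = [p for p, m in models.items() if m.baseline_abundance >= 1e6]
        assert miss.loc[low].to_numpy().mean() > miss.loc[high].to_numpy().mean()
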