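"""Tuning metrics: preference index, sparseness, triangle selectivity, state tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aobpop.tuning import (TRIANGLE_ANGLES, cross_state_preference_correlation,
                           default_state_comparisons, lifetime_sparseness,
                           mean_pairwise_preferences, pair_preference_table,
                           pairwise_selectivity_compare, preference_index,
                           preference_state_test, selectivity_comparison_table,
                           selectivity_index, stimulus_pairs,
                           triangle_coordinates, unit_metrics)
from aobpop.stimuli import PANEL_TOKENS

from conftest import make_matrix

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=50, allow_nan=False)


class TestPreferenceIndex:
    def test_examples(self):
        assert preference_index(2.0, 0.0) == pytest.approx(1.0)
        assert preference_index(0.0, 2.0) == pytest.approx(-1.0)
        assert preference_index(1.0, 1.0) == pytest.approx(0.0)
        assert preference_index(3.0, 1.0) == pytest.approx(0.5)

    def test_negative_rectified(self):
        # a suppressed response counts as 0 after rectification
        assert preference_index(-1.0, 2.0) == pytest.approx(-1.0)
        assert preference_index(-1.0, -2.0) is None

    def test_both_zero_excluded(self):
        assert preference_index(0.0, 0.0) is None

    @settings(deadline=None, derandomize=True)
    @given(a=positive, b=positive)
    def test_bounded_and_antisymmetric(self, a, b):
        pi = preference_index(a, b)
        assert -1.0 <= pi <= 1.0
        assert preference_index(b, a) == pytest.approx(-pi, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=positive, b=positive, s=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, a, b, s):
        assert preference_index(s * a, s * b) == pytest.approx(
            preference_index(a, b), abs=1e-9)


def test_pair_count():
    assert len(stimulus_pairs()) == 55
    assert len(set(stimulus_pairs())) == 55


class TestPairTable:
    def test_inclusion_rules(self):
        # unit 0: significant to stim A only; unit 1: significant nowhere;
        # unit 2: significant to A but both rectified responses are 0
        vals = np.zeros((3, 11))
        vals[0, 0], vals[0, 1] = 2.0, 1.0
        vals[2, 0] = -1.0
        sig = np.zeros((3, 11), dtype=bool)
        sig[0, 0] = sig[2, 0] = True
        m = make_matrix(vals, significant=sig)
        a, b = PANEL_TOKENS[0], PANEL_TOKENS[1]
        table = pair_preference_table(m, pairs=[(a, b)])
        assert table.loc[0, "included"] and table.loc[0, "pi"] == pytest.approx(1 / 3)
        assert not table.loc[1, "included"]
        assert not table.loc[2, "included"]

    def test_mean_grid_complete(self, rng):
        m = make_matrix(rng.normal(size=(20, 11)) + 1.0)
        means = mean_pairwise_preferences(m)
        assert len(means) == 110  # 55 pairs x 2 states
        assert (means["n"] >= 0).all()

    def test_cross_state_correlation_identical_states(self, rng):
        # duplicate the same units into both states: means match, cc = 1
        vals = np.abs(rng.normal(size=(15, 11))) + 0.5
        both = np.vstack([vals, vals])
        states = ["non_estrus"] * 15 + ["estrus"] * 15
        m = make_matrix(both, states=states)
        out = cross_state_preference_correlation(m)
        assert out["cc"] == pytest.approx(1.0)
        assert out["n_pairs"] == 55 and out["all_pairs_defined"]


class TestPreferenceStateTest:
    def test_identical_groups_p_one_sided_high(self, rng):
        vals = np.abs(rng.normal(size=(40, 11))) + 0.5
        m = make_matrix(vals)
        pair = (PANEL_TOKENS[0], PANEL_TOKENS[10])
        out = preference_state_test(m, pair, n_shuffles=2000, seed=4)
        assert 0.0 <= out["p_value"] <= 1.0
        assert out["n_estrus"] + out["n_non_estrus"] == 40

    def test_uniform_under_null(self, rng):
        # p-values across independent null datasets are near-uniform
        pair = (PANEL_TOKENS[0], PANEL_TOKENS[10])
        ps = []
        for i in range(120):
            vals = np.abs(rng.normal(size=(30, 11))) + 0.5
            m = make_matrix(vals)
            ps.append(preference_state_test(m, pair, n_shuffles=400,
                                            seed=1000 + i)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_large_shift(self):
        # estrus units all prefer A, non-estrus all prefer B
        vals = np.full((40, 11), 0.5)
        states = ["estrus"] * 20 + ["non_estrus"] * 20
        vals[:20, 0], vals[:20, 1] = 3.0, 0.1
        vals[20:, 0], vals[20:, 1] = 0.1, 3.0
        m = make_matrix(vals, states=states)
        out = preference_state_test(m, (PANEL_TOKENS[0], PANEL_TOKENS[1]),
                                    n_shuffles=2000, seed=8)
        assert out["p_value"] < 0.01

    def test_deterministic(self, rng):
        vals = np.abs(rng.normal(size=(24, 11))) + 0.5
        m = make_matrix(vals)
        pair = (PANEL_TOKENS[2], PANEL_TOKENS[7])
        a = preference_state_test(m, pair, n_shuffles=1000, seed=21)
        b = preference_state_test(m, pair, n_shuffles=1000, seed=21)
        assert a == b


class TestSparseness:
    def test_one_hot_is_one(self):
        r = np.zeros(11)
        r[3] = 5.0
        assert lifetime_sparseness(r) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert lifetime_sparseness(np.full(11, 2.5)) == pytest.approx(0.0)
        assert lifetime_sparseness(np.full(11, -2.5)) == pytest.approx(0.0)

    def test_all_zero_is_zero(self):
        assert lifetime_sparseness(np.zeros(11)) == 0.0

    def test_two_equal_nonzero_is_09(self):
        # N=11, two equal entries: S = (1 - (2/11)^2/(2/11)) / (10/11) = 0.9
        r = np.zeros(11)
        r[0] = r[5] = 3.0
        assert lifetime_sparseness(r) == pytest.approx(0.9)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(finite, min_size=11, max_size=11))
    def test_bounded(self, vals):
        s = lifetime_sparseness(vals)
        assert -1e-9 <= s <= 1.0 + 1e-9

    def test_sign_insensitive(self, rng):
        r = rng.normal(size=11)
        assert lifetime_sparseness(r) == pytest.approx(lifetime_sparseness(np.abs(r)))


class TestTriangle:
    def test_vertices(self):
        for i, ang in enumerate(TRIANGLE_ANGLES):
            w = [0.0, 0.0, 0.0]
            w[i] = 1.0
            x, y = triangle_coordinates(*w)
            assert x == pytest.approx(np.cos(np.deg2rad(ang)), abs=1e-12)
            assert y == pytest.approx(np.sin(np.deg2rad(ang)), abs=1e-12)

    def test_centre(self):
        x, y = triangle_coordinates(1.0, 1.0, 1.0)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_excluded(self):
        assert triangle_coordinates(0.0, 0.0, 0.0) is None
        assert selectivity_index(0.0, -1.0, 0.0) is None

    def test_si_examples(self):
        assert selectivity_index(1.0, 1.0, 1.0) == pytest.approx(0.0)
        assert selectivity_index(4.0, 0.0, 0.0) == pytest.approx(1.0)
        assert selectivity_index(0.5, 0.5, 0.0) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(a=positive, b=positive, c=positive)
    def test_si_equals_distance_from_centre(self, a, b, c):
        # |point|^2 = (3*sum(w^2) - 1)/2 = Si^2: the triangle-plot distance
        # from the centre equals the selectivity index exactly
        x, y = triangle_coordinates(a, b, c)
        si = selectivity_index(a, b, c)
        assert np.hypot(x, y) == pytest.approx(si, abs=1e-9)


class TestUnitMetrics:
    def test_schema(self, rng):
        m = make_matrix(np.abs(rng.normal(size=(10, 11))))
        um = unit_metrics(m)
        assert set(um.columns) == {"state", "sparseness", "selectivity_ICR",
                                   "selectivity_BC", "selectivity_C57"}
        assert len(um) == 10
        assert um["sparseness"].between(0, 1).all()

    def test_selectivity_matches_direct(self, rng):
        m = make_matrix(np.abs(rng.normal(size=(5, 11))))
        um = unit_metrics(m)
        row = m.magnitudes.iloc[0]
        direct = selectivity_index(row["M_BC_NAIVE"], row["M_BC_DOM"], row["M_BC_CAST"])
        assert um["selectivity_BC"].iloc[0] == pytest.approx(direct)


class TestSelectivityComparisons:
    def test_default_families(self):
        comps = default_state_comparisons()
        assert len(comps) == 23
        types = [c["type"] for c in comps]
        assert types.count("female_vs_female") == 1
        assert types.count("male_vs_female") == 4
        assert types.count("status_within_strain") == 9
        assert types.count("strain_within_status") == 9
        pairs = [tuple(sorted(c["pair"])) for c in comps]
        assert len(set(pairs)) == 23

    def test_table(self, rng):
        m = make_matrix(np.abs(rng.normal(size=(30, 11))) + 0.2)
        table = selectivity_comparison_table(m)
        assert len(table) == 23
        assert np.allclose(table["bonferroni_threshold"], 0.05 / 23)
        assert table["p_value"].dropna().between(0, 1).all()

    def test_identical_groups_not_significant(self, rng):
        vals = np.abs(rng.normal(size=(12, 11))) + 0.2
        both = np.vstack([vals, vals])
        m = make_matrix(both, states=["estrus"] * 12 + ["non_estrus"] * 12)
        out = pairwise_selectivity_compare(m, ("F_ICR_EST", "F_ICR_NON_EST"))
        assert out["selectivity_estrus"] == pytest.approx(out["selectivity_non_estrus"])
        assert out["p_value"] == 1.0  # fully tied pooled values
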