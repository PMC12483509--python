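"""State comparisons: binomial exact test, magnitude tests, ANOVA, rank Tukey-Kramer."""

import numpy as np
import pytest
from scipy import stats

from aobpop.compare import (BINOMIAL_CAVEAT, binomial_exact_state_test,
                            bonferroni_threshold, magnitude_state_table,
                            magnitude_state_test, pattern_frequency_state_test,
                            rank_tukey_kramer, responder_fraction_table,
                            summarize_population, two_way_anova)
from aobpop.patterns import count_patterns, default_registry, shuffle_null
from aobpop.stimuli import PANEL_TOKENS

from conftest import make_matrix

REG = default_registry()


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 16) == pytest.approx(0.05 / 16)
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.05 / 12)
        assert bonferroni_threshold(0.05, 11) == pytest.approx(0.05 / 11)
        assert bonferroni_threshold(0.05, 23) == pytest.approx(0.05 / 23)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestBinomialExact:
    def test_closed_form_extreme(self):
        # k1=5/5 vs k2=0/5: pooled p=0.5, min tail = P(X1>=5) = 0.5^5
        assert binomial_exact_state_test(5, 5, 0, 5) == pytest.approx(0.5 ** 5)

    def test_closed_form_balanced(self):
        # identical counts: every tail >= 0.5 is impossible, but the min of
        # the four tails must be large; compute one case exactly
        p = binomial_exact_state_test(2, 4, 2, 4)   # pooled 0.5
        expected = min(stats.binom.sf(1, 4, 0.5), stats.binom.cdf(2, 4, 0.5))
        assert p == pytest.approx(expected)
        assert p > 0.3

    def test_symmetry_under_group_swap(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            assert binomial_exact_state_test(k1, n1, k2, n2) == pytest.approx(
                binomial_exact_state_test(k2, n2, k1, n1))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_exact_state_test(3, 0, 1, 5)
        with pytest.raises(ValueError):
            binomial_exact_state_test(6, 5, 1, 5)


class TestPopulationSummary:
    def test_fractions_match_flags(self, rng):
        vals = rng.normal(size=(40, 11))
        sig = rng.random((40, 11)) < 0.4
        m = make_matrix(vals, significant=sig)
        pop = summarize_population(m)
        ps = pop["per_stimulus"]
        for j, stim in enumerate(PANEL_TOKENS):
            inc = (sig[:, j] & (vals[:, j] > 0)).mean() * 100
            dec = (sig[:, j] & (vals[:, j] <= 0)).mean() * 100
            assert ps.loc[stim, "percent_increase"] == pytest.approx(inc)
            assert ps.loc[stim, "percent_decrease"] == pytest.approx(dec)
            assert ps.loc[stim, "mean_magnitude"] == pytest.approx(vals[:, j].mean())
        hist = pop["effective_counts"]
        assert hist.sum() == 40
        assert (hist.index == range(12)).all()

    def test_responder_table_matches_binomial(self, rng):
        vals = rng.normal(size=(30, 11))
        sig = rng.random((30, 11)) < 0.3
        m = make_matrix(vals, significant=sig)
        table = responder_fraction_table(m)
        est = (m.states == "estrus").to_numpy()
        row = table.set_index("stimulus").loc[PANEL_TOKENS[4]]
        k1 = int(sig[est, 4].sum())
        k2 = int(sig[~est, 4].sum())
        assert row["p_value"] == pytest.approx(
            binomial_exact_state_test(k1, int(est.sum()), k2, int((~est).sum())))
        assert row["bonferroni_threshold"] == pytest.approx(0.05 / 11)
        assert table.attrs["caveat"] == BINOMIAL_CAVEAT


class TestMagnitudeTests:
    def test_identical_states_tied(self, rng):
        vals = rng.normal(size=(10, 11))
        both = np.vstack([vals, vals])
        m = make_matrix(both, states=["estrus"] * 10 + ["non_estrus"] * 10)
        # identical value sets in both groups: p must be far from significant
        for stim in PANEL_TOKENS[:3]:
            assert magnitude_state_test(m, stim) > 0.9

    def test_strong_shift_detected(self, rng):
        vals = rng.normal(size=(40, 11))
        states = ["estrus"] * 20 + ["non_estrus"] * 20
        vals[:20, 0] += 5.0
        m = make_matrix(vals, states=states)
        table = magnitude_state_table(m)
        row = table.set_index("stimulus").loc[PANEL_TOKENS[0]]
        assert row["p_value"] < 0.05 / 11 and row["significant"]
        assert row["mean_estrus"] > row["mean_non_estrus"]

    def test_all_tied_gives_one(self):
        m = make_matrix(np.ones((10, 11)))
        assert magnitude_state_test(m, PANEL_TOKENS[0]) == 1.0


class TestTwoWayAnova:
    def test_null_uniformish(self, rng):
        m = make_matrix(rng.normal(size=(60, 11)))
        out = two_way_anova(m)
        for key in ("p_stimulus", "p_state", "p_interaction"):
            assert 0.0 <= out[key] <= 1.0

    def test_stimulus_effect_detected(self, rng):
        vals = rng.normal(size=(60, 11))
        vals[:, 0] += 3.0
        out = two_way_anova(make_matrix(vals))
        assert out["p_stimulus"] < 0.001
        assert out["p_state"] > 0.001  # no state structure was injected

    def test_state_effect_detected(self, rng):
        vals = rng.normal(size=(60, 11))
        states = ["estrus"] * 30 + ["non_estrus"] * 30
        vals[:30] += 1.0
        out = two_way_anova(make_matrix(vals, states=states))
        assert out["p_state"] < 0.001

    def test_matches_statsmodels_directly(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        m = make_matrix(rng.normal(size=(30, 11)))
        out = two_way_anova(m)
        tidy = m.to_tidy()
        table = sm.stats.anova_lm(
            smf.ols("magnitude ~ C(stimulus) * C(state)", data=tidy).fit(), typ=2)
        assert out["p_stimulus"] == pytest.approx(table.loc["C(stimulus)", "PR(>F)"])


class TestPatternFrequency:
    def test_table_schema_and_thresholds(self, rng):
        est = make_matrix(rng.normal(size=(30, 11)), states=["estrus"] * 30)
        non = make_matrix(rng.normal(size=(25, 11)), states=["non_estrus"] * 25)
        ce = count_patterns(est.magnitudes, REG)
        cn = count_patterns(non.magnitudes, REG)
        sh_e = shuffle_null(est.magnitudes, REG, n_shuffles=100, seed=1)
        sh_n = shuffle_null(non.magnitudes, REG, n_shuffles=100, seed=2)
        table = pattern_frequency_state_test(ce, 30, cn, 25, REG,
                                             shuffle_results_est=sh_e,
                                             shuffle_results_non=sh_n)
        assert len(table) == 28
        thr = table.set_index("pattern")["bonferroni_threshold"]
        assert thr["FEMALE"] == pytest.approx(0.05 / 16)
        assert thr["DOM_STRAIN"] == pytest.approx(0.05 / 12)
        assert {"overrep_estrus", "overrep_non_estrus"} <= set(table.columns)
        assert table["freq_estrus"].between(0, 1).all()

    def test_frequency_shift_detected(self):
        # 40% vs 2% FEMALE prevalence with n=100 per state
        ce = {p.id: 0 for p in REG}
        cn = dict(ce)
        ce["FEMALE"], cn["FEMALE"] = 40, 2
        import pandas as pd
        table = pattern_frequency_state_test(pd.Series(ce), 100, pd.Series(cn), 100, REG)
        row = table.set_index("pattern").loc["FEMALE"]
        assert row["p_value"] < 0.05 / 16 and row["significant"]


class TestRankTukeyKramer:
    def test_schema_and_bounds(self, rng):
        m = make_matrix(rng.normal(size=(25, 11)))
        table = rank_tukey_kramer(m)
        assert len(table) == 55
        assert table["p_tukey_kramer"].between(0, 1).all()
        # the Tukey-Kramer correction can only make pairs harder to reject
        assert (table["p_tukey_kramer"] >= table["p_uncorrected"] - 1e-12).all()

    def test_outlier_stimulus_flagged(self, rng):
        vals = rng.normal(size=(40, 11))
        vals[:, 5] += 10.0
        table = rank_tukey_kramer(make_matrix(vals))
        outlier = PANEL_TOKENS[5]
        involved = table[(table["stim_a"] == outlier) | (table["stim_b"] == outlier)]
        rest = table[(table["stim_a"] != outlier) & (table["stim_b"] != outlier)]
        assert involved["significant_corrected"].all()
        assert not rest["significant_corrected"].any()
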