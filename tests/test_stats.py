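"""Component windows, sign/t tests, RM-ANOVA, TTI profile, error map."""

import numpy as np
import pandas as pd
import pytest

from erpspell.paradigm import make_letter_matrix
from erpspell.preprocessing import EpochSet, extract_epochs
from erpspell.simulate import SimulationConfig, erp_kernel, \
    simulate_recording
from erpspell.stats import (ComponentWindow, adjacency_error_map,
                            bonferroni_adjust, component_window_mean,
                            paired_sign_test, repeated_measures_anova_2way,
                            tti_accuracy_profile, two_sample_t)


def constant_epochs(value, n=3, channels=("Cz", "PO7")):
    times = np.arange(-20, 80) * 10.0
    data = np.full((n, len(channels), times.size), float(value))
    return EpochSet(data=data, times_ms=times,
                    labels=np.zeros(n, dtype=int), channels=channels,
                    metadata=pd.DataFrame({"trial": np.arange(n)}))


class TestComponentWindowMean:
    def test_constant_epoch(self):
        ep = constant_epochs(3.0)
        win = ComponentWindow.standard("P300")
        assert np.allclose(component_window_mean(ep, win), 3.0)

    def test_standard_windows(self):
        assert ComponentWindow.standard("N170") == ComponentWindow(
            "N170", "PO7", (130.0, 200.0))
        assert ComponentWindow.standard("P300").channel == "Cz"
        assert ComponentWindow.standard("N400f").window_ms == (400.0, 550.0)

    def test_missing_channel_rejected(self):
        ep = constant_epochs(1.0, channels=("Fz", "Oz"))
        with pytest.raises(KeyError, match="Cz"):
            component_window_mean(ep, ComponentWindow.standard("P300"))

    def test_noiseless_self_face_n400f_closed_form(
            self, single_flash_schedule):
        """The N400f window mean of a noiseless self-face target epoch
        equals amplitude x mean kernel value at Cz (no other component
        overlaps 400-550 ms)."""
        sched = single_flash_schedule("self_face", is_target=True)
        cfg = SimulationConfig(noise_sigma=0.0)
        rec = simulate_recording(sched, cfg, rng=0)
        ep = extract_epochs(rec, sched)
        win = ComponentWindow.standard("N400f")
        got = component_window_mean(ep, win)[0]
        mask = (ep.times_ms >= 400) & (ep.times_ms <= 550)
        expected = -4.0 * erp_kernel((400.0, 550.0),
                                     ep.times_ms[mask]).mean()
        assert got == pytest.approx(expected, abs=1e-10)


class TestPairedSignTest:
    def test_fifteen_of_fifteen(self):
        a, b = np.arange(15) + 1.0, np.arange(15)
        assert paired_sign_test(a, b) == pytest.approx(2 * 0.5**15,
                                                       rel=1e-9)

    def test_eight_of_fifteen_not_significant(self):
        a = np.array([1.0] * 8 + [-1.0] * 7)
        b = np.zeros(15)
        assert paired_sign_test(a, b) > 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        assert paired_sign_test(a, b) == pytest.approx(
            paired_sign_test(b, a))

    def test_ties_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 3.0])
        b = np.array([0.0, 1.0, 3.0, 3.0])   # two ties -> n = 2
        assert paired_sign_test(a, b) == pytest.approx(0.5)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            paired_sign_test([1.0, 2.0], [1.0, 2.0])


class TestBonferroni:
    def test_scaling_and_cap(self):
        adj = bonferroni_adjust([0.01, 0.5], m=3)
        assert adj[0] == pytest.approx(0.03)
        assert adj[1] == 1.0

    def test_order_preserved(self):
        p = np.array([0.001, 0.02, 0.04])
        adj = bonferroni_adjust(p)
        assert np.all(np.diff(adj) >= 0)

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # pooled var 1, se = sqrt(2/3), t = -3 / se
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_negation_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(-a, -b)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_constant_equal_groups(self):
        t, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


def anova_oracle(data):
    """Independent oracle: statsmodels AnovaRM on the long format."""
    from statsmodels.stats.anova import AnovaRM
    s, a, b = data.shape
    subj, fa, fb = np.meshgrid(np.arange(s), np.arange(a), np.arange(b),
                               indexing="ij")
    long = pd.DataFrame({"subject": subj.ravel(), "A": fa.ravel(),
                         "B": fb.ravel(), "y": data.ravel()})
    return AnovaRM(long, depvar="y", subject="subject",
                   within=["A", "B"]).fit().anova_table


class TestRepeatedMeasuresAnova:
    def test_df_structure_15x3x10(self):
        rng = np.random.default_rng(0)
        res = repeated_measures_anova_2way(rng.standard_normal((15, 3, 10)))
        t = res.table
        assert (t.loc["speller", "df1"], t.loc["speller", "df2"]) == (2, 28)
        assert (t.loc["sequences", "df1"],
                t.loc["sequences", "df2"]) == (9, 126)
        assert (t.loc["spellerxsequences", "df1"],
                t.loc["spellerxsequences", "df2"]) == (18, 252)

    def test_constant_data_gives_zero_f(self):
        data = np.tile(np.arange(6.0)[:, None, None], (1, 3, 4))
        res = repeated_measures_anova_2way(data)
        assert np.allclose(res.table["F"], 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((8, 3, 5))
        res = repeated_measures_anova_2way(data).table
        oracle = anova_oracle(data)
        assert np.allclose(res["F"].to_numpy(),
                           oracle["F Value"].to_numpy(), atol=1e-8)
        assert np.allclose(res["p"].to_numpy(),
                           oracle["Pr > F"].to_numpy(), atol=1e-8)

    def test_invariant_to_per_subject_offsets(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((6, 3, 4))
        shifted = data + rng.standard_normal((6, 1, 1)) * 10.0
        f1 = repeated_measures_anova_2way(data).table["F"].to_numpy()
        f2 = repeated_measures_anova_2way(shifted).table["F"].to_numpy()
        assert np.allclose(f1, f2, atol=1e-8)

    def test_incomplete_design_rejected(self):
        data = np.ones((4, 3, 3))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            repeated_measures_anova_2way(data)


class TestTtiProfile:
    def test_all_correct(self):
        tti = np.array([0.0, 1.0, 5.0, 9.0, np.nan])
        prof = tti_accuracy_profile(np.ones(5, dtype=bool), tti)
        assert prof["0"] == 1.0 and prof["1"] == 1.0
        assert prof[">=5"] == 1.0
        assert prof["2"] is None            # empty bin -> undefined

    def test_binning(self):
        tti = np.array([0, 0, 3, 7], dtype=float)
        correct = np.array([True, False, True, True])
        prof = tti_accuracy_profile(correct, tti)
        assert prof["0"] == 0.5
        assert prof["3"] == 1.0
        assert prof[">=5"] == 1.0
        assert prof["4"] is None


class TestAdjacencyErrorMap:
    def test_all_correct_counts_center(self):
        m = make_letter_matrix()
        grid = adjacency_error_map(("A", "B", "C"), ("A", "B", "C"), m)
        assert grid[5, 5] == 3
        assert grid.sum() == 3

    def test_one_column_off(self):
        m = make_letter_matrix()
        grid = adjacency_error_map(("B",), ("A",), m)   # one col right
        assert grid[5, 6] == 1
        assert grid.sum() == 1

    def test_conservation(self):
        m = make_letter_matrix()
        rng = np.random.default_rng(2)
        symbols = list(m.symbols)
        decoded = rng.choice(symbols, size=50)
        truth = rng.choice(symbols, size=50)
        grid = adjacency_error_map(tuple(decoded), tuple(truth), m)
        assert grid.sum() == 50
        correct = sum(d == t for d, t in zip(decoded, truth))
        assert grid[5, 5] == correct


class TestBonferroniProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_adjusted_values_valid_and_order_preserving(self, ps):
        adj = bonferroni_adjust(ps)
        assert np.all((0.0 <= adj) & (adj <= 1.0))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)
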