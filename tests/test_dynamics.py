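import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hsekit as hk
from hsekit.dynamics import StateSequence
from hsekit.errors import DomainError, StateClassificationError, WeightsError

from oracles import gaussian_mixture_density


def te_panel_from_wide(values, start_year=2000):
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    units = [f"U{i:02d}" for i in range(1, n + 1)]
    years = list(range(start_year, start_year + T))
    return hk.EfficiencyPanel(pd.DataFrame({
        "unit_id": np.repeat(units, T),
        "year": np.tile(years, n),
        "te": values.ravel(),
    }))


class TestSilvermanBandwidth:
    def test_two_point_hand_computation(self):
        # s = 1/sqrt(2), IQR = 0.5 -> delta = 0.5/1.34, h = 1.06 delta 2^{-1/5}
        expected = 1.06 * (0.5 / 1.34) * 2 ** (-0.2)
        assert hk.silverman_bandwidth([0.0, 1.0]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3443, abs=5e-5)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, a):
        v = np.array([0.1, 0.4, 0.7, 1.3, 2.1])
        assert hk.silverman_bandwidth(a * v) == pytest.approx(
            a * hk.silverman_bandwidth(v), rel=1e-12)

    def test_normal_sample_uses_smaller_of_sd_and_iqr(self):
        v = np.random.default_rng(0).normal(0, 1, 10_000)
        s = v.std(ddof=1)
        q = np.subtract(*np.percentile(v, [75, 25]))
        expected = 1.06 * min(s, q / 1.34) * 10_000 ** (-0.2)
        assert hk.silverman_bandwidth(v) == pytest.approx(expected, rel=1e-12)

    def test_constant_values_raise(self):
        with pytest.raises(DomainError):
            hk.silverman_bandwidth([1.0, 1.0, 1.0])


class TestKDE:
    def test_single_point_is_gaussian(self):
        res = hk.kde_curve([0.3], grid=np.linspace(-0.5, 1.1, 1601), bandwidth=0.2)
        peak = res.grid[np.argmax(res.density)]
        assert peak == pytest.approx(0.3, abs=1e-9)
        assert res.density.max() == pytest.approx(1 / (0.2 * np.sqrt(2 * np.pi)),
                                                  rel=1e-9)

    def test_two_point_mixture_closed_form(self):
        pts, h = [0.0, 1.0], 0.25
        res = hk.kde_curve(pts, grid=np.array([-0.2, 0.5, 1.1]), bandwidth=h)
        for x, d in zip(res.grid, res.density):
            assert d == pytest.approx(gaussian_mixture_density(x, pts, h), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_density_integrates_to_one(self, seed):
        v = np.random.default_rng(seed).uniform(0.6, 0.95, 31)
        res = hk.kde_curve(v)
        assert 0.99 <= res.integral() <= 1.01
        assert (res.density >= 0).all()

    def test_empty_sample_raises(self):
        with pytest.raises(DomainError):
            hk.kde_curve([])


class TestClassifyStates:
    def test_four_distinct_values_span_all_states(self):
        te = te_panel_from_wide([[0.1], [0.2], [0.3], [0.4]])
        states = hk.classify_states(te)
        assert sorted(states.data["state"]) == [1, 2, 3, 4]

    def test_tied_values_share_a_state(self):
        te = te_panel_from_wide([[0.1], [0.25], [0.25], [0.3], [0.4], [0.9]])
        states = hk.classify_states(te)
        tied = states.data.merge(te.data)[lambda d: d["te"] == 0.25]
        assert tied["state"].nunique() == 1

    def test_massive_ties_raise_with_advice(self):
        # >50% of the mass at one value collapses q25 and q50 onto each other
        te = te_panel_from_wide([[0.5]] * 6 + [[0.6], [0.7], [0.8]])
        with pytest.raises(StateClassificationError, match="per_year"):
            hk.classify_states(te)

    def test_per_year_scheme_classifies_within_year(self):
        rng = np.random.default_rng(6)
        te = te_panel_from_wide(rng.uniform(0.5, 0.9, (8, 3)))
        states = hk.classify_states(te, scheme="per_year_quartiles")
        for _, g in states.data.groupby("year"):
            assert set(g["state"]) == {1, 2, 3, 4}


class TestTransitionMatrix:
    def test_constant_states_give_identity(self):
        te = te_panel_from_wide([[0.1] * 3, [0.3] * 3, [0.5] * 3, [0.9] * 3])
        tm = hk.transition_matrix(hk.classify_states(te))
        assert np.allclose(tm.probabilities, np.eye(4))

    def test_hand_tallied_toy_sequence(self):
        df = pd.DataFrame({
            "unit_id": ["A"] * 3 + ["B"] * 3,
            "year": [0, 1, 2] * 2,
            "state": [1, 2, 2, 3, 4, 4],
        })
        tm = hk.transition_matrix(StateSequence(df, np.array([0.2, 0.5, 0.8]),
                                                "pooled_quartiles"))
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 1] = 1  # A: 1 -> 2
        expected[1, 1] = 1  # A: 2 -> 2
        expected[2, 3] = 1  # B: 3 -> 4
        expected[3, 3] = 1  # B: 4 -> 4
        assert np.array_equal(tm.counts, expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_row_stochastic_and_conserving(self, seed):
        rng = np.random.default_rng(seed)
        te = te_panel_from_wide(rng.uniform(0.4, 1.0, (10, 6)))
        tm = hk.transition_matrix(hk.classify_states(te))
        p = tm.probabilities
        defined = tm.origin_totals > 0
        assert np.allclose(p[defined].sum(axis=1), 1.0, atol=1e-12)
        assert np.isnan(p[~defined]).all()
        assert tm.origin_totals.sum() == 10 * 5

    def test_empty_origin_row_reports_nan(self):
        df = pd.DataFrame({"unit_id": ["A"] * 2, "year": [0, 1], "state": [1, 1]})
        tm = hk.transition_matrix(StateSequence(df, np.array([0.2, 0.5, 0.8]),
                                                "pooled_quartiles"))
        assert np.isnan(tm.probabilities[3]).all()


class TestSpatialTransitionMatrix:
    def test_four_ring_hand_example(self):
        # A-B-C-D ring; staircase panel keeps every unit in its own quartile.
        te = te_panel_from_wide([[0.1, 0.2, 0.3],
                                 [0.4, 0.5, 0.6],
                                 [0.7, 0.8, 0.9],
                                 [1.0, 1.0, 1.0]])
        w = hk.generate_weights(4, "ring")
        states = hk.classify_states(te)
        stm = hk.spatial_transition_matrix(states, te, w)
        # lag(A) = mean(B, D) lands in state III both origin years; lag(B) in II
        blocks = {k: m.counts for k, m in stm.blocks.items()}
        assert blocks["II"][1, 1] == 2 and blocks["II"][3, 3] == 2
        assert blocks["III"][0, 0] == 2 and blocks["III"][2, 2] == 2
        assert blocks["I"].sum() == 0 and blocks["IV"].sum() == 0

    def test_blocks_partition_unconditional_transitions(self, fixture_panel,
                                                        china_weights):
        states = hk.classify_states(fixture_panel)
        tm = hk.transition_matrix(states)
        stm = hk.spatial_transition_matrix(states, fixture_panel, china_weights)
        total = sum(m.counts for m in stm.blocks.values())
        assert np.array_equal(total, tm.counts)

    def test_zero_weight_row_raises(self):
        te = te_panel_from_wide(np.linspace(0.1, 0.9, 8).reshape(4, 2))
        w = hk.SpatialWeights(tuple(te.units), np.zeros((4, 4)))
        with pytest.raises(WeightsError):
            hk.spatial_transition_matrix(hk.classify_states(te), te, w)
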