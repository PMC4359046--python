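import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from ccm import (
    EmbeddingParams,
    Library,
    TimeSeries,
    assess_convergence,
    crossmap_point,
    embed,
    exp_weights,
    neighbor_rank,
    pairwise_distances,
    skill,
    window_sweep,
)
from ccm.crossmap import CrossMapResult

from ._reference import naive_window_sweep


class TestExpWeights:
    def test_equal_distances_give_uniform_weights(self):
        w = exp_weights(np.array([2.0, 2.0, 2.0]))
        assert np.allclose(w, 1 / 3)

    def test_hand_computed_two_neighbor_case(self):
        # u = (e^-1, e^-2); w = u / sum(u)
        w = exp_weights(np.array([1.0, 2.0]))
        expected = np.array([np.e**-1, np.e**-2])
        expected /= expected.sum()
        assert np.allclose(w, expected)
        assert w[0] == pytest.approx(0.73105857863, abs=1e-10)

    def test_zero_nearest_distance_spreads_over_exact_matches(self):
        w = exp_weights(np.array([0.0, 0.0, 5.0]))
        assert np.allclose(w, [0.5, 0.5, 0.0])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            exp_weights(np.array([]))

    def test_unsorted_input_is_an_error(self):
        with pytest.raises(ValueError):
            exp_weights(np.array([2.0, 1.0]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=8)
    )
    @settings(deadline=None, max_examples=60)
    def test_weights_form_a_convex_combination(self, distances):
        w = exp_weights(np.array(sorted(distances)))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestNeighborRank:
    def _manifold(self, values, E=2, tau=1):
        m = embed(TimeSeries(np.asarray(values, float)), EmbeddingParams(E=E, tau=tau))
        return m, pairwise_distances(m)

    def test_nearest_point_found(self):
        m, d = self._manifold([0.0, 0.1, 5.0, 0.2, 9.0])
        lib = Library(start=0, size=len(m))
        (idx, dist), = neighbor_rank(d, target=0, lib=lib, k=1)
        row = d.values[0].copy()
        row[0] = np.inf  # the target itself is never a neighbor
        assert idx == int(np.argmin(row))
        assert dist == pytest.approx(row[idx])

    def test_tie_breaks_toward_earlier_time(self):
        # periodic series -> exactly repeated points, equidistant from target
        m, d = self._manifold([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        lib = Library(start=0, size=len(m))
        ranked = neighbor_rank(d, target=0, lib=lib, k=2)
        # points 2 and 4 coincide with point 0; earlier index first
        assert [i for i, _ in ranked] == [2, 4]

    def test_matches_exhaustive_sort_oracle(self, rng):
        vals = rng.normal(size=21)
        m, d = self._manifold(vals, E=2)
        lib = Library(start=3, size=15)
        for target in (5, 9, 14):
            got = neighbor_rank(d, target, lib, k=4)
            cand = [
                (d.values[target, j], j)
                for j in range(lib.start, lib.stop)
                if j != target
            ]
            cand.sort()
            assert [i for _, i in cand[:4]] == [i for i, _ in got]

    def test_unsatisfiable_k_raises(self):
        m, d = self._manifold([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="minimum library size"):
            neighbor_rank(d, target=0, lib=Library(start=0, size=3), k=3)


class TestSkill:
    def test_perfect_and_anti_perfect(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert skill(obs, obs) == pytest.approx(1.0)
        assert skill(obs, -obs) == pytest.approx(-1.0)

    def test_hand_checked_pearson_value(self):
        # r = 6 / sqrt(5 * 9) = 0.8944271909...
        rho = skill(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 2.0, 5.0]))
        assert rho == pytest.approx(0.894427190999916, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        a, b = rng.normal(size=(2, 50))
        assert skill(a, b) == pytest.approx(pearsonr(a, b).statistic, abs=1e-12)

    def test_zero_variance_yields_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            assert skill(np.ones(5), np.arange(5.0)) == 0.0

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            skill(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCrossmapPoint:
    def test_constant_target_series_predicted_exactly(self, rng):
        y = TimeSeries(rng.normal(size=30), name="Y")
        x = TimeSeries(np.full(30, 3.7), name="X")
        m = embed(y, EmbeddingParams(E=2))
        lib = Library(start=0, size=len(m))
        pred = crossmap_point(m, x, lib, t=10)
        assert pred.predicted == pytest.approx(3.7, abs=1e-12)
        assert pred.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_tau_p_marks_skipped(self, rng):
        y = TimeSeries(rng.normal(size=30), name="Y")
        x = TimeSeries(rng.normal(size=30), name="X")
        m = embed(y, EmbeddingParams(E=2, tau_p=25))
        lib = Library(start=0, size=len(m))
        pred = crossmap_point(m, x, lib, t=5, tau_p=25)
        assert pred.skipped

    def test_self_crossmap_of_chaotic_series_is_accurate(self):
        # deterministic logistic map predicting itself: skill near 1
        vals = np.empty(300)
        vals[0] = 0.41
        for t in range(299):
            vals[t + 1] = 3.9 * vals[t] * (1 - vals[t])
        x = TimeSeries(vals, name="x")
        m = embed(x, EmbeddingParams(E=2))
        d = pairwise_distances(m)
        lib = Library(start=0, size=len(m))
        obs, pred = [], []
        for t in range(50, 150):
            p = crossmap_point(m, x, lib, t=t, distances=d)
            obs.append(p.observed)
            pred.append(p.predicted)
        assert skill(np.array(obs), np.array(pred)) > 0.99

    def test_matches_hand_rolled_simplex_projection(self, rng):
        """One prediction recomputed by explicit loops agrees to 1e-12."""
        xv, yv = rng.normal(size=(2, 30))
        x, y = TimeSeries(xv, "X"), TimeSeries(yv, "Y")
        m = embed(y, EmbeddingParams(E=2, tau_p=1))
        lib = Library(start=0, size=len(m))
        p = crossmap_point(m, x, lib, t=15, tau_p=1)

        target = m.points[m.time_index.tolist().index(15)]
        cand = sorted(
            (float(np.linalg.norm(m.points[i] - target)), int(m.time_index[i]))
            for i in range(len(m))
            if m.time_index[i] != 15
        )[:3]
        raw = [np.exp(-d / cand[0][0]) for d, _ in cand]
        weights = np.array(raw) / np.sum(raw)
        expected = sum(w * xv[u - 1] for w, (_, u) in zip(weights, cand))
        assert p.predicted == pytest.approx(expected, abs=1e-12)


class TestWindowSweep:
    def test_single_window_when_library_fills_manifold(self, logistic_pair):
        x, y = logistic_pair
        P = len(y) - 1  # E=2, tau=1
        res = window_sweep(x, y, EmbeddingParams(E=2), [P])
        assert len(res.rho_windows[0]) == 1
        assert res.rho_mean[0] == pytest.approx(res.rho_windows[0][0])

    def test_window_count_is_points_minus_L_plus_one(self, logistic_pair):
        x, y = logistic_pair
        P = len(y) - 1
        for L in (10, 50, 120):
            res = window_sweep(x, y, EmbeddingParams(E=2), [L])
            assert len(res.rho_windows[0]) == P - L + 1

    def test_direction_label_names_manifold_series_first(self, logistic_pair):
        x, y = logistic_pair
        res = window_sweep(x, y, EmbeddingParams(E=2), [50])
        assert res.direction == "Y xmap X"

    def test_skill_rises_with_library_size_under_forcing(self, logistic_pair):
        """With X driving Y, skill for the true direction grows from L=20 to L=150."""
        x, y = logistic_pair
        res = window_sweep(x, y, EmbeddingParams(E=2), [20, 150])
        assert res.rho_mean[1] > res.rho_mean[0]

    def test_predictions_equal_reference_implementation(self, rng):
        """Fast sweep and naive double-loop oracle agree to 1e-10."""
        from ccm import CoupledLogisticSpec, coupled_logistic

        x, y = coupled_logistic(CoupledLogisticSpec(n=50, seed=5))
        for tau_p in (0, 2):
            params = EmbeddingParams(E=3, tau=1, tau_p=tau_p)
            sizes = [12, 25, 40]
            res = window_sweep(x, y, params, sizes)
            ref = naive_window_sweep(
                x.values, y.values, E=3, tau=1, tau_p=tau_p, lib_sizes=sizes
            )
            for i, L in enumerate(sizes):
                assert res.rho_mean[i] == pytest.approx(ref[L][0], abs=1e-10)
                assert np.allclose(res.rho_windows[i], ref[L][1], atol=1e-10)

    def test_theiler_exclusion_matches_reference(self, rng):
        from ccm import CoupledLogisticSpec, coupled_logistic

        x, y = coupled_logistic(CoupledLogisticSpec(n=40, seed=9))
        res = window_sweep(x, y, EmbeddingParams(E=2), [20], exclusion_window=2)
        ref = naive_window_sweep(
            x.values, y.values, E=2, tau=1, tau_p=0, lib_sizes=[20], exclusion_window=2
        )
        assert np.allclose(res.rho_windows[0], ref[20][1], atol=1e-10)

    def test_no_usable_library_size_is_an_error(self, logistic_pair):
        x, y = logistic_pair
        with pytest.raises(ValueError, match="no usable library sizes"):
            window_sweep(x, y, EmbeddingParams(E=2), [2, 3])

    def test_all_skill_values_bounded(self, logistic_pair):
        x, y = logistic_pair
        res = window_sweep(x, y, EmbeddingParams(E=3, tau_p=2), [15, 60, 190])
        for rhos in res.rho_windows:
            assert np.all(rhos >= -1) and np.all(rhos <= 1)


class TestAssessConvergence:
    def _result(self, rhos):
        sizes = np.arange(10, 10 + len(rhos))
        return CrossMapResult(
            direction="Y xmap X",
            lib_sizes=sizes,
            rho_mean=np.asarray(rhos, float),
            rho_windows=[np.array([r]) for r in rhos],
            params=EmbeddingParams(E=2),
        )

    def test_flat_low_curve_is_not_causal(self):
        conv = assess_convergence(self._result([0.05, 0.05, 0.05]))
        assert conv.delta_rho == 0.0
        assert not conv.converged

    def test_rising_curve_is_causal(self):
        conv = assess_convergence(self._result([0.2, 0.6, 0.9]))
        assert conv.delta_rho == pytest.approx(0.7)
        assert conv.relative_delta == pytest.approx(0.7 / 0.9)
        assert conv.converged

    def test_flat_high_curve_is_not_causal(self):
        """High but non-increasing correlation is static association, not causality."""
        conv = assess_convergence(self._result([0.88, 0.9, 0.89]))
        assert not conv.converged

    def test_requires_two_library_sizes(self):
        with pytest.raises(ValueError):
            assess_convergence(self._result([0.5]))
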