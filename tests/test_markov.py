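"""Transition estimation, weights, averaging, chi-square, KL, chain graphs."""

import math

import numpy as np
import pytest

from rivaldyn.markov import (
    actual_to_posterior_weights,
    average_matrices,
    build_chain_graph,
    chi_square_uniform,
    counts_to_probabilities,
    estimate_transitions,
    hierarchical_average,
    js_divergence,
    kl_divergence,
    matrix_to_frame,
    read_graphml,
    read_matrix,
    transition_counts,
    uniform_null_probability,
    write_dot,
    write_graphml,
    write_matrix,
)
from rivaldyn.records import STATE_INDEX, PerceptState
from rivaldyn.stats import count_flips

from conftest import make_clean, random_clean_sequence

H, V, PM, SI = (PerceptState.HORIZONTAL, PerceptState.VERTICAL,
                PerceptState.PIECEMEAL, PerceptState.SUPERIMPOSED)
iH, iV, iPM, iSI = (STATE_INDEX[s] for s in (H, V, PM, SI))


def brute_force_counts(states):
    """Independent oracle: plain double loop over adjacent pairs."""
    counts = np.zeros((4, 4), dtype=int)
    for k in range(len(states) - 1):
        counts[STATE_INDEX[states[k]], STATE_INDEX[states[k + 1]]] += 1
    return counts


class TestEstimation:
    def test_hand_counted_example(self):
        # H, PM, V, PM, H
        clean = make_clean([(s, 1.0) for s in (H, PM, V, PM, H)])
        counts, probs = estimate_transitions(clean)
        assert counts[iH, iPM] == 1 and counts[iPM, iV] == 1
        assert counts[iV, iPM] == 1 and counts[iPM, iH] == 1
        assert counts.sum() == 4
        assert probs[iH, iPM] == 1.0 and probs[iV, iPM] == 1.0
        assert probs[iPM, iH] == 0.5 and probs[iPM, iV] == 0.5
        assert np.isnan(probs[iSI]).all()  # SI never visited: undefined row

    def test_alternating_sequence(self):
        clean = make_clean([(s, 1.0) for s in (H, V, H, V, H, V)])
        _, probs = estimate_transitions(clean)
        assert probs[iH, iV] == 1.0 and probs[iV, iH] == 1.0

    def test_single_phase_fully_undefined(self):
        _, probs = estimate_transitions(make_clean([(H, 3.0)]))
        assert np.isnan(probs).all()

    def test_mle_equals_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            seq = random_clean_sequence(rng)
            clean = make_clean(seq)
            assert np.array_equal(transition_counts(clean),
                                  brute_force_counts(clean.states()))

    def test_row_sums_equal_flip_bookkeeping(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            clean = make_clean(random_clean_sequence(rng))
            counts = transition_counts(clean)
            assert counts.sum() == count_flips(clean).total

    def test_long_chain_recovers_matrix(self, rng):
        P = np.array(
            [[0, 0.2, 0.5, 0.3], [0.1, 0, 0.6, 0.3],
             [0.45, 0.45, 0, 0.1], [0.25, 0.25, 0.5, 0]]
        )
        states = [H]
        order = (H, V, PM, SI)
        for _ in range(20_000):
            states.append(order[rng.choice(4, p=P[STATE_INDEX[states[-1]]])])
        clean = make_clean([(s, 1.0) for s in states])
        counts, probs = estimate_transitions(clean)
        for i in range(4):
            n = counts[i].sum()
            for j in range(4):
                if i == j:
                    continue
                se = math.sqrt(P[i, j] * (1 - P[i, j]) / n)
                assert abs(probs[i, j] - P[i, j]) <= 3 * se


class TestWeights:
    def test_hand_enumeration(self):
        clean = make_clean([(PM, 3.0), (V, 2.0), (PM, 5.0), (H, 4.0)])
        w = actual_to_posterior_weights(clean)
        assert w[iPM, iV] == 3.0
        assert w[iV, iPM] == 2.0
        assert w[iPM, iH] == 5.0
        assert np.isnan(w[iH]).all()  # final phase has no posterior

    def test_equal_durations(self):
        clean = make_clean([(s, 2.5) for s in (H, PM, V, SI, H)])
        w = actual_to_posterior_weights(clean)
        assert np.all(w[np.isfinite(w)] == 2.5)

    def test_trial_average_equals_pooled_for_equal_counts(self):
        c1 = make_clean([(H, 2.0), (V, 1.0)])
        c2 = make_clean([(H, 4.0), (V, 1.0)])
        w = average_matrices([actual_to_posterior_weights(c) for c in (c1, c2)])
        assert w[iH, iV] == pytest.approx(3.0)

    def test_weights_exceed_cutoff_on_clean_data(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = actual_to_posterior_weights(make_clean(random_clean_sequence(rng)))
            assert np.all(w[np.isfinite(w)] > 0.180)


class TestAveraging:
    def test_identical_matrices(self):
        m = np.array([[np.nan, 0.5], [0.3, np.nan]])
        out = average_matrices([m, m])
        assert np.allclose(out, m, equal_nan=True)

    def test_two_row_arithmetic(self):
        a = np.array([[0.2, 0.8]])
        b = np.array([[0.6, 0.4]])
        assert np.allclose(average_matrices([a, b]), [[0.4, 0.6]])

    def test_masked_cells_averaged_over_defined_only(self):
        # 3-trial fixture, hand computation with NaN holes
        m1 = np.array([[1.0, np.nan], [2.0, 4.0]])
        m2 = np.array([[3.0, 6.0], [np.nan, 8.0]])
        m3 = np.array([[np.nan, np.nan], [np.nan, 12.0]])
        out = average_matrices([m1, m2, m3])
        assert out[0, 0] == pytest.approx(2.0)  # (1+3)/2
        assert out[0, 1] == pytest.approx(6.0)  # only m2
        assert out[1, 0] == pytest.approx(2.0)  # only m1
        assert out[1, 1] == pytest.approx(8.0)  # (4+8+12)/3

    def test_hierarchical_weighting(self):
        # participant A has two trials, B one: B still carries half the weight
        a1 = np.array([[2.0]])
        a2 = np.array([[4.0]])
        b1 = np.array([[10.0]])
        out = hierarchical_average({"A": [a1, a2], "B": [b1]})
        assert out[0, 0] == pytest.approx((3.0 + 10.0) / 2)

    def test_renormalized_rows_are_stochastic(self):
        m1 = counts_to_probabilities(np.array(
            [[0, 1, 2, 1], [1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 1, 0]]))
        m2 = counts_to_probabilities(np.array(
            [[0, 2, 2, 0], [0, 0, 3, 1], [2, 2, 0, 2], [0, 0, 0, 0]]))
        out = average_matrices([m1, m2], renormalize_rows=True)
        sums = np.nansum(out, axis=1)
        assert np.allclose(sums[sums > 0], 1.0)


class TestChiSquare:
    def test_uniform_null_probability(self):
        assert round(uniform_null_probability(4), 2) == 0.33

    def test_equal_counts(self):
        stat, p = chi_square_uniform([10, 10, 10])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_concentrated_counts(self):
        stat, p = chi_square_uniform([30, 0, 0])
        assert stat == pytest.approx(60.0)  # (20^2 + 10^2 + 10^2) / 10
        assert p < 1e-3

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(7)
        reps = 1000
        rej = sum(
            chi_square_uniform(rng.multinomial(300, [1 / 3] * 3))[1] < 0.05
            for _ in range(reps)
        )
        rate = rej / reps
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_zero_departures_flagged(self):
        stat, p = chi_square_uniform([0, 0, 0])
        assert math.isnan(stat) and math.isnan(p)


class TestKL:
    def test_identical_rows_zero(self):
        p = np.array([0.2, 0.5, 0.3])
        assert kl_divergence(p, p) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([0.25, 0.25, 0.5])
        assert kl_divergence(p, q) == pytest.approx(math.log(2))

    def test_nonnegative_on_random_rows(self, rng):
        for _ in range(1000):
            p = rng.dirichlet(np.ones(3))
            q = rng.dirichlet(np.ones(3))
            assert kl_divergence(p, q) >= 0.0
            assert js_divergence(p, q) >= 0.0

    def test_undefined_rows_give_nan(self):
        assert math.isnan(kl_divergence([np.nan] * 3, [np.nan] * 3))


class TestChainGraph:
    def test_single_edge_fixture(self):
        P = np.full((4, 4), np.nan)
        W = np.full((4, 4), np.nan)
        P[iH, iV] = 1.0
        W[iH, iV] = 2.0
        g = build_chain_graph("control", "CBR", P, W, np.array([2.0] * 4))
        assert g.number_of_edges() == 1
        assert g["H"]["V"]["probability"] == 1.0
        assert g["H"]["V"]["weight_s"] == 2.0

    def test_node_size_ordering_matches_mean_durations(self):
        # longer-dwell fixture: PM 3.7 s > H 3.2 > V 1.7 = SI 1.7
        means = np.array([3.2, 1.7, 3.7, 1.7])
        P = np.full((4, 4), 1 / 3)
        np.fill_diagonal(P, np.nan)
        W = np.full((4, 4), 1.0)
        g = build_chain_graph("autism", "IOG", P, W, means)
        sizes = {n: g.nodes[n]["mean_duration_s"] for n in g}
        assert sizes["PM"] > sizes["H"] > sizes["V"] == sizes["SI"]

    def test_graphml_roundtrip(self, tmp_path):
        P = np.full((4, 4), 1 / 3)
        np.fill_diagonal(P, 0.0)
        W = np.full((4, 4), 2.0)
        chi = [("H", 12.0, 0.002), ("V", 8.0, 0.02), ("PM", 5.0, 0.08),
               ("SI", float("nan"), float("nan"))]
        g = build_chain_graph("autism", "CBR", P, W, np.array([1.0, 2.0, 3.0, 4.0]), chi)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        g2 = read_graphml(path)
        assert set(g2.nodes) == set(g.nodes)
        assert set(g2.edges) == set(g.edges)
        for a, b in g.edges:
            assert g2[a][b]["probability"] == pytest.approx(g[a][b]["probability"])
        assert g2.nodes["H"]["chi_square"] == pytest.approx(12.0)
        write_dot(g, tmp_path / "g.dot")  # serialises without error
        assert '"H" -> "V"' in (tmp_path / "g.dot").read_text()


class TestMatrixIO:
    def test_csv_roundtrip_preserves_nan(self, tmp_path):
        m = np.array(
            [[np.nan, 0.2, 0.5, 0.3], [0.1, np.nan, 0.6, 0.3],
             [np.nan] * 4, [0.25, 0.25, 0.5, np.nan]]
        )
        path = tmp_path / "m.csv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert np.allclose(back, m, equal_nan=True)
        assert list(matrix_to_frame(m).columns) == ["H", "V", "PM", "SI"]
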