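"""Basic statistics: proportions, flips, aggregation, t-tests, trait fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from rivaldyn.records import PerceptState
from rivaldyn.stats import (
    CLASS_EXCLUSIVE,
    count_flips,
    group_ttest,
    hierarchical_and_pooled_mean,
    participant_summary,
    phase_stats,
    trait_correlation,
    trial_summary_table,
)

from conftest import STATES, make_clean, random_clean_sequence

H, V, PM, SI = (PerceptState.HORIZONTAL, PerceptState.VERTICAL,
                PerceptState.PIECEMEAL, PerceptState.SUPERIMPOSED)


class TestPhaseStats:
    def test_single_phase(self):
        ps = phase_stats(make_clean([(H, 10.0)]))
        assert ps.proportions[H] == 100.0
        assert ps.mean_durations[H] == 10.0
        assert ps.proportions[V] == 0.0
        assert math.isnan(ps.mean_durations[V])  # absent: no sample, not zero

    def test_four_state_arithmetic(self):
        ps = phase_stats(make_clean([(H, 2.0), (V, 4.0), (PM, 2.0), (SI, 2.0)]))
        assert ps.proportions[H] == pytest.approx(20.0)
        assert ps.proportions[V] == pytest.approx(40.0)
        assert ps.proportions[PM] == pytest.approx(20.0)
        assert ps.proportions[SI] == pytest.approx(20.0)
        assert ps.class_proportions[CLASS_EXCLUSIVE] == pytest.approx(60.0)

    def test_exclusive_class_is_sum_of_h_and_v(self):
        ps = phase_stats(make_clean([(H, 3.0), (PM, 1.0), (H, 2.0)]))
        assert ps.class_proportions[CLASS_EXCLUSIVE] == pytest.approx(
            ps.proportions[H] + ps.proportions[V]
        )

    @given(st.integers(0, 2**32 - 1))
    def test_proportions_sum_to_100(self, seed):
        seq = random_clean_sequence(np.random.default_rng(seed))
        ps = phase_stats(make_clean(seq))
        assert sum(ps.proportions.values()) == pytest.approx(100.0, abs=1e-6)
        # mean duration x count = total per state (exact bookkeeping)
        for s in STATES:
            total = sum(d for st_, d in seq if st_ is s)
            n = sum(1 for st_, _ in seq if st_ is s)
            if n:
                assert ps.mean_durations[s] * n == pytest.approx(total)


class TestFlips:
    @pytest.mark.parametrize(
        "seq,full,half",
        [
            ([H, V, H], 2, 0),
            ([H, PM, V, SI, V], 0, 4),
            ([H, V, PM, H], 1, 2),
            ([H], 0, 0),
        ],
    )
    def test_examples(self, seq, full, half):
        fl = count_flips(make_clean([(s, 1.0) for s in seq]))
        assert (fl.full, fl.half) == (full, half)

    @given(st.integers(0, 2**32 - 1))
    def test_full_plus_half_equals_phase_changes(self, seed):
        seq = random_clean_sequence(np.random.default_rng(seed))
        fl = count_flips(make_clean(seq))
        assert fl.total == len(seq) - 1


class TestAggregation:
    def _trials(self):
        # participant a: 8 trials, participant b: 4 trials, equal per-trial stats
        cleans = []
        for pid, n in (("a", 8), ("b", 4)):
            for k in range(n):
                cleans.append(
                    make_clean([(H, 2.0), (V, 2.0), (PM, 2.0)],
                               participant_id=pid, trial_index=k)
                )
        return cleans

    def test_equal_participant_means_give_group_mean(self):
        df = trial_summary_table(self._trials())
        part = participant_summary(df)
        assert part["mean_dur_all"].nunique() == 1
        assert part["mean_dur_all"].mean() == pytest.approx(2.0)

    def test_hierarchical_differs_from_pooled_when_unbalanced(self):
        cleans = []
        for k in range(8):  # participant a: long phases
            cleans.append(make_clean([(H, 4.0), (V, 4.0)], participant_id="a",
                                     trial_index=k))
        for k in range(2):  # participant b: short phases, fewer trials
            cleans.append(make_clean([(H, 1.0), (V, 1.0)], participant_id="b",
                                     trial_index=k))
        df = trial_summary_table(cleans)
        hier, pooled = hierarchical_and_pooled_mean(df, "mean_dur_all")
        assert hier == pytest.approx(2.5)  # participants weighted equally
        assert pooled == pytest.approx((8 * 4 + 2 * 1) / 10)
        assert hier != pooled

    def test_flips_summed_within_participant(self):
        df = trial_summary_table(self._trials())
        part = participant_summary(df).set_index("participant_id")
        assert part.loc["a", "flips_total"] == 8 * 2
        assert part.loc["b", "flips_total"] == 4 * 2


class TestGroupTTest:
    def test_identical_groups(self):
        r = group_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.t == 0.0 and r.p == 1.0 and r.degenerate

    def test_df_is_pooled(self):
        rng = np.random.default_rng(1)
        r = group_ttest(rng.normal(size=17), rng.normal(size=18))
        assert r.df == 33

    def test_matches_closed_form_oracle(self, rng):
        # pooled-variance formula written out by hand
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(1.0, 2.0, size=rng.integers(3, 20))
            r = group_ttest(a, b)
            n1, n2 = len(a), len(b)
            sp2 = (
                (n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)
            ) / (n1 + n2 - 2)
            t_oracle = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_oracle = 2 * sps.t.sf(abs(t_oracle), n1 + n2 - 2)
            assert r.t == pytest.approx(t_oracle, abs=1e-10)
            assert r.p == pytest.approx(p_oracle, abs=1e-10)

    def test_small_sample_input_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [2.0, 3.0])


class TestTraitCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 11.0)
        fit = trait_correlation(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_slope < 1e-12

    def test_matches_normal_equation_oracle(self):
        x = np.array([10.0, 22.0, 35.0, 47.0])
        y = np.array([3.1, 4.0, 2.2, 5.5])
        X = np.column_stack([x, np.ones_like(x)])
        slope_o, intercept_o = np.linalg.solve(X.T @ X, X.T @ y)
        fit = trait_correlation(x, y)
        assert fit.slope == pytest.approx(slope_o, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept_o, abs=1e-10)
        # CI symmetric about the slope
        assert (fit.ci95_slope[0] + fit.ci95_slope[1]) / 2 == pytest.approx(fit.slope)

    def test_slope_test_type_i_error_rate(self):
        # independent x and y: the slope test should reject at ~5%
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            if trait_correlation(x, y).p_slope < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)

    def test_constant_x_degenerate(self):
        fit = trait_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert fit.degenerate
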