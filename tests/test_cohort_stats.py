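import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cnacall.cohort_stats import (
    CohortTable,
    burden_compare,
    concordance_from_counts,
    efs_analysis,
    fish_concordance,
    fisher_exact_2x2,
    fisher_screen,
    rank_sum_test,
)


def brute_force_fisher(a_pos, a_n, b_pos, b_n):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    n = a_n + b_n
    k = a_pos + b_pos

    def table_prob(x):
        # P(X = x) for hypergeometric draws of a_n from n with k successes
        return (
            math.comb(k, x) * math.comb(n - k, a_n - x) / math.comb(n, a_n)
        )

    p_obs = table_prob(a_pos)
    total = 0.0
    for x in range(max(0, k - b_n), min(k, a_n) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def make_table(groups, calls, extra=None):
    samples = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(len(groups))],
            "patient": [f"p{i}" for i in range(len(groups))],
            "group": groups,
            "recurrence_class": "primary",
            "fish_1p36": "NA",
            "efs_time": 12.0,
            "efs_event": 0,
        }
    )
    if extra:
        for k, v in extra.items():
            samples[k] = v
    calls_df = pd.DataFrame(calls, index=samples["sample"])
    return CohortTable(samples=samples, calls=calls_df)


class TestFisher:
    def test_printed_style_contrast(self):
        # 1 of 20 vs 20 of 64 -> p = .018 at 3 decimals
        _, p = fisher_exact_2x2(1, 20, 20, 64)
        assert round(p, 3) == 0.018

    def test_identical_proportions_p_one(self):
        _, p = fisher_exact_2x2(5, 10, 5, 10)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        for a_pos, a_n, b_pos, b_n in [(2, 5, 1, 6), (0, 7, 3, 5), (4, 9, 2, 11)]:
            _, p = fisher_exact_2x2(a_pos, a_n, b_pos, b_n)
            assert p == pytest.approx(brute_force_fisher(a_pos, a_n, b_pos, b_n), abs=1e-9)

    def test_invariance_to_group_swap_and_transpose(self):
        _, p1 = fisher_exact_2x2(3, 10, 7, 12)
        _, p2 = fisher_exact_2x2(7, 12, 3, 10)
        from scipy.stats import fisher_exact

        _, p3 = fisher_exact(np.array([[3, 7], [7, 5]]).T)
        assert p1 == pytest.approx(p2)
        assert p1 == pytest.approx(p3)

    def test_screen_sorted_with_bh_column(self):
        rng = np.random.default_rng(0)
        groups = ["a"] * 10 + ["b"] * 10
        calls = {
            "x:amp": [1] * 8 + [0] * 2 + [0] * 9 + [1],
            "y:del": rng.integers(0, 2, 20),
        }
        table = make_table(groups, calls)
        out = fisher_screen(table, "a", "b")
        assert list(out.columns[:6]) == ["label", "direction", "a_pos", "a_n", "b_pos", "b_n"]
        assert out["p"].is_monotonic_increasing
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_screen_first_sample_per_patient(self):
        samples = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3"],
                "patient": ["p1", "p1", "p2"],
                "group": ["a", "a", "b"],
                "recurrence_class": ["primary", "recurrence", "primary"],
                "fish_1p36": "NA",
                "efs_time": 10.0,
                "efs_event": 0,
            }
        )
        calls = pd.DataFrame({"x:amp": [1, 1, 0]}, index=samples["sample"])
        table = CohortTable(samples=samples, calls=calls)
        first = fisher_screen(table, "a", "b", first_sample_only=True)
        every = fisher_screen(table, "a", "b", first_sample_only=False)
        assert first.loc[0, "a_n"] == 1
        assert every.loc[0, "a_n"] == 2

    def test_empty_group_rejected(self):
        table = make_table(["a", "a"], {"x:amp": [0, 1]})
        with pytest.raises(ValueError):
            fisher_screen(table, "a", "b")


class TestRankSum:
    def test_exact_enumeration_small_groups(self):
        # {1,2,3} vs {4,5,6}: only 1 of C(6,3)=20 assignments is as
        # extreme in each direction -> two-sided p = 2/20
        p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)

    def test_matches_full_enumeration(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0, 11.0]
        pooled = x + y
        u_obs = sum(xi > yj for xi in x for yj in y) + 0.5 * sum(
            xi == yj for xi in x for yj in y
        )
        n_x = len(x)
        count = 0
        total = 0
        mu = len(x) * len(y) / 2
        for combo in itertools.combinations(range(len(pooled)), n_x):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = sum(xi > yj for xi in xs for yj in ys)
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        assert rank_sum_test(x, y) == pytest.approx(count / total)

    def test_symmetric_interleaved_case_p_one(self):
        assert rank_sum_test([1, 4, 5, 8], [2, 3, 6, 7]) == pytest.approx(1.0)

    def test_power_against_shift_matches_simulation_oracle(self):
        # n=10+10, shift = 1.5 sd: empirical power of the implementation
        # vs an independent oracle using scipy's ranksums statistic
        from scipy.stats import ranksums

        rng = np.random.default_rng(12)
        n_rep = 300
        hits_impl = 0
        hits_oracle = 0
        for _ in range(n_rep):
            x = rng.normal(0, 1, 10)
            y = rng.normal(1.5, 1, 10)
            hits_impl += rank_sum_test(x, y) < 0.05
            hits_oracle += ranksums(x, y).pvalue < 0.05
        p_impl = hits_impl / n_rep
        p_oracle = hits_oracle / n_rep
        assert abs(p_impl - p_oracle) <= 0.05

    def test_burden_compare_reports_medians_and_iqr(self):
        table = make_table(["a"] * 4 + ["b"] * 4, {"x:amp": [0] * 8})
        burden = pd.DataFrame(
            {"pga": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]},
            index=[f"s{i}" for i in range(8)],
        )
        out = burden_compare(burden, table, "pga", "a", "b")
        assert out["median_a"] == pytest.approx(0.25)
        assert out["median_b"] == pytest.approx(0.65)
        assert 0 < out["p"] <= 1


class TestConcordance:
    def test_printed_concordance_counts(self):
        # 4 concordant positive, 13 concordant negative, 2 FISH-only,
        # 1 sequencing-only -> PPV 80%, NPV 87%
        out = concordance_from_counts(tp=4, fp=1, fn=2, tn=13)
        assert out["PPV"] == 80
        assert out["NPV"] == 87

    def test_perfect_agreement(self):
        out = concordance_from_counts(tp=5, fp=0, fn=0, tn=10)
        assert out["PPV"] == 100 and out["NPV"] == 100

    def test_all_negative_calls_ppv_is_na(self):
        out = concordance_from_counts(tp=0, fp=0, fn=3, tn=10)
        assert out["PPV"] is None
        assert out["NPV"] == 77

    def test_from_cohort_table_counts_sum_to_evaluable(self):
        fish = ["pos", "pos", "neg", "neg", "NA", "pos"]
        table = make_table(
            ["a"] * 6, {"1p36.22:del": [1, 0, 1, 0, 1, 1]}, extra={"fish_1p36": fish}
        )
        seq = table.calls["1p36.22:del"].astype(bool)
        out = fish_concordance(table, seq)
        assert out["TP"] + out["FP"] + out["FN"] + out["TN"] == 5
        assert out["TP"] == 2 and out["FP"] == 1 and out["FN"] == 1 and out["TN"] == 1

    def test_sample_order_invariance(self):
        fish = ["pos", "neg", "pos", "neg"]
        table = make_table(["a"] * 4, {"x:del": [1, 0, 0, 1]}, extra={"fish_1p36": fish})
        seq = table.calls["x:del"].astype(bool)
        out1 = fish_concordance(table, seq)
        out2 = fish_concordance(table, seq.iloc[::-1])
        assert out1 == out2

    def test_no_evaluable_samples_rejected(self):
        table = make_table(["a"] * 2, {"x:del": [0, 1]})
        with pytest.raises(ValueError):
            fish_concordance(table, table.calls["x:del"].astype(bool))


class TestEfs:
    def test_identical_survival_statistic_zero(self):
        times = [5.0, 10.0, 15.0, 5.0, 10.0, 15.0]
        events = [1, 1, 0, 1, 1, 0]
        table = make_table(
            ["a"] * 6,
            {"x:amp": [1, 1, 1, 0, 0, 0]},
            extra={"efs_time": times, "efs_event": events},
        )
        res = efs_analysis(table, "x:amp")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_km_and_logrank_match_hand_computation(self):
        # carriers: times (2, 4, 6+); noncarriers: (1, 3+, 5)
        table = make_table(
            ["a"] * 6,
            {"x:del": [1, 1, 1, 0, 0, 0]},
            extra={
                "efs_time": [2.0, 4.0, 6.0, 1.0, 3.0, 5.0],
                "efs_event": [1, 1, 0, 1, 0, 1],
            },
        )
        res = efs_analysis(table, "x:del")
        # hand-computed log-rank: event times 1,2,4,5
        # t=1: n=6 (3+3), d=1 (noncarrier): E_c = 3/6
        # t=2: n=5 (3c,2n), d=1 (carrier):  E_c = 3/5
        # t=4: n=3 (2c,1n), d=1 (carrier):  E_c = 2/3
        # t=5: n=2 (1c,1n), d=1 (noncarrier): E_c = 1/2
        o_c = 2.0
        e_c = 3 / 6 + 3 / 5 + 2 / 3 + 1 / 2
        v = (
            (3 * 3) / (6 * 6)      # t=1: n1*n2*d*(n-d)/(n^2*(n-1)) with d=1
            + (3 * 2) / (5 * 5)
            + (2 * 1) / (3 * 3)
            + (1 * 1) / (2 * 2)
        )
        expected_chi2 = (o_c - e_c) ** 2 / v
        assert res.statistic == pytest.approx(expected_chi2, abs=1e-10)
        # KM steps for carriers: S(2)=2/3, S(4)=1/3
        carrier = res.curves["carrier"].set_index("time")["survival"]
        assert carrier.loc[2.0] == pytest.approx(2 / 3, abs=1e-10)
        assert carrier.loc[4.0] == pytest.approx(1 / 3, abs=1e-10)

    def test_power_under_hazard_ratio_three(self):
        # n=100+100, HR=3, uniform censoring: rejection rate > 80%
        rng = np.random.default_rng(77)
        n_rep = 200
        rejections = 0
        for _ in range(n_rep):
            t_c = rng.exponential(1 / 0.06, 100)
            t_n = rng.exponential(1 / 0.02, 100)
            cens = rng.uniform(0, 60, 200)
            times = np.concatenate([t_c, t_n])
            events = (times <= cens).astype(int)
            times = np.minimum(times, cens)
            table = make_table(
                ["a"] * 200,
                {"x:amp": [1] * 100 + [0] * 100},
                extra={"efs_time": times, "efs_event": events},
            )
            rejections += efs_analysis(table, "x:amp").p < 0.05
        assert rejections / n_rep > 0.80

    def test_empty_stratum_rejected(self):
        table = make_table(["a"] * 3, {"x:amp": [0, 0, 0]})
        with pytest.raises(ValueError, match="stratum"):
            efs_analysis(table, "x:amp")

    def test_nonpositive_time_rejected(self):
        table = make_table(
            ["a"] * 2, {"x:amp": [1, 0]}, extra={"efs_time": [0.0, 5.0]}
        )
        with pytest.raises(ValueError, match="efs_time"):
            efs_analysis(table, "x:amp")


class TestNullCalibration:
    def test_fisher_pvalues_conservative_under_null(self, small_grid, small_cyto):
        # identical region frequencies in both groups: the p-value ECDF
        # must lie at or below the uniform ECDF (discreteness makes the
        # exact test conservative)
        from cnacall.synthetic_data import CohortSpec, NoiseModel, simulate_cohort

        bands = ["18q21.33", "2p15", "9p21.3", "6q16.1", "12q13.13"]
        freqs = {}
        for b in bands:
            freqs[("a", b, "amp")] = 0.2
            freqs[("b", b, "amp")] = 0.2
        pvals = []
        for rep in range(40):
            spec = CohortSpec(n_per_group={"a": 12, "b": 12}, region_freqs=freqs)
            sim = simulate_cohort(
                spec, small_grid, small_cyto, seed=500 + rep,
                noise=NoiseModel(noiseless=True),
            )
            groups = sim.metadata.set_index("sample")["group"]
            for b in bands:
                col = sim.truth_calls[f"{b}:amp"]
                a_pos = int(col[groups == "a"].sum())
                b_pos = int(col[groups == "b"].sum())
                _, p = fisher_exact_2x2(a_pos, 12, b_pos, 12)
                pvals.append(p)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        # ECDF domination with a small Monte-Carlo slack
        assert (ecdf - pvals <= 0.05).all()
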