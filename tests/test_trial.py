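"""Randomized-trial machinery: enrollment, permuted-block randomization,
the imputed primary outcome, sample size, and survival statistics."""

import numpy as np
import pandas as pd
import pytest

from cachemet import synthetic as syn, trial as tr


def _weights(losses_pct, peak=32.0):
    """Weekly observations realizing the given loss-from-peak percentages."""
    w = [peak] + [peak * (1 - l / 100.0) for l in losses_pct]
    days = np.arange(len(w)) * 7.0
    return pd.DataFrame({"animal_id": "A1", "sex": "F", "day": days,
                         "weight_g": w})


class TestEnroll:
    def test_enrolls_at_first_window_entry(self):
        out = tr.enroll(_weights([5, 12, 20]))
        assert out.loc[0, "enroll_day"] == 14.0
        assert out.loc[0, "loss_at_enroll_pct"] == pytest.approx(12.0)
        assert not out.loc[0, "window_skipped"]

    def test_never_losing_not_enrolled(self):
        assert tr.enroll(_weights([2, 5, 8])).empty

    def test_window_overshoot_flagged(self):
        out = tr.enroll(_weights([8, 18]))
        assert out.loc[0, "enroll_day"] == 14.0
        assert out.loc[0, "window_skipped"]


class TestBlockRandomize:
    @staticmethod
    def _subjects(n_f, n_m=0):
        ids = [f"F{i}" for i in range(n_f)] + [f"M{i}" for i in range(n_m)]
        sex = ["F"] * n_f + ["M"] * n_m
        return pd.DataFrame({"animal_id": ids, "sex": sex})

    def test_complete_blocks_exactly_balanced(self):
        arms = ["ctrl", "mab", "combo"]
        out = tr.block_randomize(self._subjects(12), arms, block_size=6, seed=1)
        counts = out["arm"].value_counts()
        assert all(counts[a] == 4 for a in arms)

    def test_every_complete_block_internally_balanced(self):
        arms = ["a", "b", "c"]
        for seed in range(100):
            out = tr.block_randomize(self._subjects(18), arms,
                                     block_size=6, seed=seed)
            seq = out["arm"].tolist()
            for b in range(3):
                block = seq[6 * b:6 * (b + 1)]
                assert all(block.count(a) == 2 for a in arms)

    def test_incomplete_block_counts_differ_by_at_most_one(self):
        arms = ["a", "b", "c"]
        for seed in range(50):
            out = tr.block_randomize(self._subjects(7), arms,
                                     block_size=6, seed=seed)
            counts = [out["arm"].tolist().count(a) for a in arms]
            assert max(counts) - min(counts) <= 1
            assert sum(counts) == 7

    def test_stratified_by_sex(self):
        arms = ["a", "b"]
        subjects = self._subjects(6, 6)
        out = tr.block_randomize(subjects, arms, block_size=6, seed=3)
        merged = out.merge(subjects, on="animal_id")
        for sex in ("F", "M"):
            counts = merged[merged.sex == sex]["arm"].value_counts()
            assert counts["a"] == 3 and counts["b"] == 3

    def test_seed_reproducibility(self):
        arms = ["a", "b", "c"]
        s = self._subjects(10, 9)
        a = tr.block_randomize(s, arms, seed=11)
        b = tr.block_randomize(s, arms, seed=11)
        assert a.equals(b)

    def test_indivisible_block_rejected(self):
        with pytest.raises(tr.TrialError):
            tr.block_randomize(self._subjects(6), ["a", "b", "c", "d"],
                               block_size=6)


class TestPrimaryOutcome:
    @staticmethod
    def _rec(**kw):
        base = dict(animal_id="A1", sex="F", arm="ctrl", enroll_day=35.0,
                    start_weight=25.0, end_weight=None, endpoint_day=None)
        base.update(kw)
        return tr.TrialRecord(**base)

    def test_endpoint_before_end_imputes_minus_30(self):
        rec = self._rec(endpoint_day=45.0)   # day 10 of 14
        out = tr.primary_outcome_table([rec])
        assert out.loc[0, "end_pct_change"] == -30.0
        assert out.loc[0, "imputed"]

    def test_stable_weight_zero_change(self):
        out = tr.primary_outcome_table([self._rec(end_weight=25.0)])
        assert out.loc[0, "end_pct_change"] == pytest.approx(0.0)
        assert not out.loc[0, "imputed"]

    def test_percent_arithmetic(self):
        rec = self._rec(start_weight=30.0, end_weight=27.0)
        out = tr.primary_outcome_table([rec])
        assert out.loc[0, "end_pct_change"] == pytest.approx(-10.0)

    def test_missing_end_without_endpoint_excluded(self):
        recs = [self._rec(), self._rec(animal_id="A2", end_weight=24.0)]
        out = tr.primary_outcome_table(recs)
        assert out.loc[0, "missing"]
        summ = tr.arm_summary(out)
        assert summ.loc[0, "n"] == 1 and summ.loc[0, "n_missing"] == 1

    def test_imputation_dominance(self):
        """Adding an imputed animal can only lower the arm's mean change
        (every realizable End value exceeds -30)."""
        recs = [self._rec(animal_id=f"A{i}", end_weight=25.0 - i)
                for i in range(4)]
        base = tr.arm_summary(tr.primary_outcome_table(recs))
        recs.append(self._rec(animal_id="A9", endpoint_day=40.0))
        after = tr.arm_summary(tr.primary_outcome_table(recs))
        assert after.loc[0, "mean_pct_change"] < base.loc[0, "mean_pct_change"]


class TestSampleSize:
    def test_one_sd_effect_needs_23(self):
        assert tr.sample_size_two_means(1.0, sd=1.0, mean=1.0,
                                        alpha=0.05, power=0.90) == 23

    def test_doubling_sd_quadruples_n(self):
        n1 = tr.sample_size_two_means(0.5, sd=1.0, mean=1.0)
        n2 = tr.sample_size_two_means(0.5, sd=2.0, mean=1.0)
        assert 3.9 <= n2 / n1 <= 4.1   # asymptotic scaling, integer rounding

    def test_minimum_feasible(self):
        n = tr.sample_size_two_means(5.0, sd=0.1, mean=1.0,
                                     alpha=0.5, power=0.5)
        assert n == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(tr.TrialError):
            tr.sample_size_two_means(0.0, sd=1.0, mean=1.0)


class TestKaplanMeier:
    def test_three_deaths_no_censoring(self):
        km = tr.km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = tr.km_estimate([5.0, 8.0], [False, False])
        assert km.times.size == 0
        assert km.at(10.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(30.0, 40)
        km = tr.km_estimate(t, np.ones(40, bool))
        for tau in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = np.mean(t > tau)
            assert km.at(tau) == pytest.approx(emp, abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            t = np.round(rng.exponential(20.0, n), 1) + 0.1
            e = rng.random(n) < 0.7
            if not e.any():
                continue
            km = tr.km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            for ti, si in zip(km.times, km.survival):
                ref = float(kmf.survival_function_at_times(ti).iloc[0])
                assert si == pytest.approx(ref, abs=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(tr.TrialError):
            tr.km_estimate([-1.0], [True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([3.0, 5.0, 9.0])
        e = np.array([True, True, True])
        chi2, df, p = tr.logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_risk_sets(self):
        """n=3+3 with distinct event times; observed-minus-expected and the
        variance tabulated by hand over the six risk sets."""
        t1, e1 = np.array([1.0, 4.0, 6.0]), np.array([True, True, True])
        t2, e2 = np.array([2.0, 5.0, 8.0]), np.array([True, True, True])
        # risk sets: t=1 (3,3) E1=1/2; t=2 (2,3) E1=2/5; t=4 (2,2) E1=1/2;
        # t=5 (1,2) E1=1/3; t=6 (1,1) E1=1/2; t=8 (0,1) E1=0
        o_minus_e = 3 - (0.5 + 0.4 + 0.5 + 1 / 3 + 0.5 + 0.0)
        var = (0.25 + 6 / 25 + 0.25 + 2 / 9 + 0.25 + 0.0)
        chi2, df, p = tr.logrank_test([(t1, e1), (t2, e2)])
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, rel=1e-10)
        assert df == 1

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            groups = []
            for g in range(3):
                t = np.round(rng.exponential(20.0 * (1 + 0.3 * g), n), 1) + 0.1
                e = rng.random(n) < 0.8
                groups.append((t, e))
            if not any(e.any() for _, e in groups):
                continue
            chi2, df, p = tr.logrank_test(groups)
            tt = np.concatenate([t for t, _ in groups])
            ee = np.concatenate([e for _, e in groups])
            gg = np.concatenate([np.full(t.size, i) for i, (t, _) in
                                 enumerate(groups)])
            ref = multivariate_logrank_test(tt, gg, ee)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_zero_events_rejected(self):
        with pytest.raises(tr.TrialError):
            tr.logrank_test([(np.array([1.0]), np.array([False])),
                             (np.array([2.0]), np.array([False]))])

    def test_power_increases_with_effect_size(self):
        """On simulated trials, log-rank power grows with the survival
        benefit (checked over a small effect grid)."""
        rng = np.random.default_rng(3)
        powers = []
        for hr in (1.0, 2.0, 4.0):
            rej = 0
            for _ in range(200):
                t1 = rng.exponential(20.0, 15)
                t2 = rng.exponential(20.0 * hr, 15)
                e = np.ones(15, bool)
                _, _, p = tr.logrank_test([(t1, e), (t2, e)])
                rej += p < 0.05
            powers.append(rej / 200)
        assert powers[0] < powers[1] < powers[2]
        assert powers[0] < 0.15


class TestSurvivalOrigins:
    def test_enrollment_anchor_shifts_times(self):
        df = pd.DataFrame({"arm": ["a", "b"], "time_day": [60.0, 70.0],
                           "event": [True, True], "enroll_day": [40.0, 45.0]})
        ind = tr.survival_from_records(df, origin="induction")
        enr = tr.survival_from_records(df, origin="enrollment")
        assert np.allclose(ind["time_day"], [60, 70])
        assert np.allclose(enr["time_day"], [20, 25])
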