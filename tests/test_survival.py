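"""Survival statistics against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from writersig.datasets import CohortConfig, generate_cohort
from writersig.survival import (km_curve, logrank, logrank_z, cox_fit,
                                prognostic_screen, max_rank_cutpoint,
                                td_auc, c_index)
from writersig.errors import InputError


class TestKM:
    def test_all_censored_flat_curve(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.median is None

    def test_two_events_by_hand(self):
        km = km_curve([1.0, 2.0], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])
        np.testing.assert_array_equal(km.at_risk, [2, 1])
        assert km.median == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(5.0, 200)
        km = km_curve(t, np.ones(200, int))
        counts = np.searchsorted(np.sort(t), km.event_times, side="right")
        np.testing.assert_array_equal(km.survival, (200 - counts) / 200)

    def test_censored_at_event_time_still_at_risk(self):
        # censoring at t=2 is counted in the risk set of the t=2 event
        km = km_curve([1.0, 2.0, 2.0, 3.0], [1, 1, 0, 1])
        np.testing.assert_array_equal(km.at_risk, [4, 3, 1])

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_sample_hand_case(self):
        # A: events at 1, 2; B: events at 3, 4.
        # t=1: O-E = 1 - 2/4, V = (2/4)(2/4)(3/3) = 1/4
        # t=2: O-E = 1 - 1/3, V = (1/3)(2/3)(2/2) = 2/9
        # t=3: O-E = 0, V = 0; t=4: single subject, skipped
        # chi2 = (7/6)^2 / (17/36) = 49/17
        chi2, _ = logrank([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49 / 17, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test
        t = rng.exponential(3, 80)
        e = (rng.random(80) < 0.8).astype(int)
        g = rng.random(80) < 0.5
        chi2, p = logrank(t, e, g)
        ref = logrank_test(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_group_relabel_invariance(self, rng):
        t = rng.exponential(3, 40)
        e = np.ones(40, int)
        g = rng.random(40) < 0.4
        assert logrank(t, e, g)[0] == pytest.approx(logrank(t, e, ~g)[0], rel=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(InputError):
            logrank([1.0, 2.0], [0, 0], [0, 1])


class TestCox:
    def test_null_covariate_small_coefficient(self, rng):
        n = 500
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.8).astype(int)
        x = rng.normal(size=n)
        res = cox_fit(t, e, x)
        assert abs(res.coef[0]) < 3 * res.se[0]

    def test_hazard_ratio_recovery(self):
        """Binary covariate with true HR 2.0, ~20% censoring: the median
        estimate over 10 seeds lies in [1.8, 2.2]."""
        hrs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            x = (rng.random(n) < 0.5).astype(float)
            t_event = rng.exponential(1 / (0.1 * 2.0 ** x))
            t_cens = rng.exponential(1 / 0.035, n)
            t = np.minimum(t_event, t_cens)
            e = (t_event <= t_cens).astype(int)
            hrs.append(cox_fit(t, e, x).hazard_ratio[0])
        assert 1.8 <= np.median(hrs) <= 2.2

    def test_matches_statsmodels_with_ties(self, rng):
        """Efron tie handling against the statsmodels PHReg oracle on
        heavily tied (integer) times."""
        import statsmodels.api as sm
        n = 150
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(X @ [0.5, -0.3, 0.1]))))
        e = (rng.random(n) < 0.75).astype(int)
        ref = sm.PHReg(t, X, status=e, ties="efron").fit()
        mine = cox_fit(t, e, X, names=list("abc"))
        np.testing.assert_allclose(mine.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(mine.se, ref.bse, atol=1e-6)
        assert mine.log_likelihood == pytest.approx(
            float(ref.model.loglike(ref.params)), abs=1e-8)
        assert mine.converged

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter
        n = 200
        X = rng.normal(size=(n, 3))
        t = rng.exponential(1 / (0.1 * np.exp(X @ [0.5, -0.3, 0.0])))
        e = (rng.random(n) < 0.8).astype(int)
        df = pd.DataFrame(X, columns=list("abc")).assign(t=t, e=e)
        ref = CoxPHFitter().fit(df, "t", "e")
        mine = cox_fit(t, e, X, names=list("abc"))
        # lifelines stops at its own coarser convergence tolerance
        np.testing.assert_allclose(mine.coef, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(mine.se, ref.standard_errors_.values, atol=1e-5)

    def test_ci_brackets_hazard_ratio(self, rng):
        t = rng.exponential(3, 100)
        e = np.ones(100, int)
        x = rng.normal(size=100)
        res = cox_fit(t, e, x)
        assert res.ci_low[0] <= res.hazard_ratio[0] <= res.ci_high[0]
        assert res.hazard_ratio[0] == pytest.approx(np.exp(res.coef[0]))

    def test_constant_column_rejected(self, rng):
        with pytest.raises(InputError):
            cox_fit(rng.exponential(1, 20), np.ones(20, int), np.ones(20))

    def test_separation_flagged(self):
        # covariate perfectly orders survival: monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = np.arange(20.0)
        res = cox_fit(t, e, x)
        assert res.separation or not res.converged


class TestScreen:
    def test_planted_risk_gene_power(self):
        """A gene with log-HR 1 per sd at n=300 passes the p<0.001 screen
        in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            t_event = rng.exponential(1 / (0.12 * np.exp(1.0 * x)))
            t_cens = rng.exponential(1 / 0.08, n)
            t = np.minimum(t_event, t_cens)
            e = (t_event <= t_cens).astype(int)
            frame = pd.DataFrame([x], index=["risk_gene"])
            clin = pd.DataFrame({"sample_id": frame.columns,
                                 "os_years": t, "os_event": e})
            hits += prognostic_screen(frame, clin, ["risk_gene"]) == ["risk_gene"]
        assert hits >= 9

    def test_null_gene_excluded(self, rng):
        n = 200
        frame = pd.DataFrame([rng.normal(size=n)], index=["noise"])
        clin = pd.DataFrame({"sample_id": frame.columns,
                             "os_years": rng.exponential(5, n),
                             "os_event": np.ones(n, int)})
        assert prognostic_screen(frame, clin, ["noise"]) == []


class TestCutpoint:
    def test_constant_scores_rejected(self, rng):
        with pytest.raises(InputError):
            max_rank_cutpoint(np.ones(20), rng.exponential(1, 20),
                              np.ones(20, int))

    def test_equals_bruteforce_oracle(self):
        """On instances of <= 50 samples the returned cutpoint must equal
        maximization of the per-split log-rank statistic computed with an
        independent implementation (lifelines)."""
        from lifelines.statistics import logrank_test
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 51))
            s = rng.normal(size=n)
            t = rng.exponential(1 / (0.3 * np.exp(0.5 * s)))
            e = (rng.random(n) < 0.8).astype(int)
            res = max_rank_cutpoint(s, t, e, minprop=0.1)
            best_cut, best_stat = None, -1.0
            for lo, hi in zip(np.unique(s)[:-1], np.unique(s)[1:]):
                cut = (lo + hi) / 2
                high = s > cut
                if min(high.sum(), (~high).sum()) < 0.1 * n:
                    continue
                stat = np.sqrt(logrank_test(t[high], t[~high],
                                            e[high], e[~high]).test_statistic)
                if stat > best_stat + 1e-12:
                    best_cut, best_stat = cut, stat
            assert res.cutpoint == pytest.approx(best_cut)
            assert res.max_statistic == pytest.approx(best_stat, rel=1e-9)

    def test_separated_groups_split_between(self, rng):
        s = np.concatenate([rng.normal(0, 0.1, 25), rng.normal(5, 0.1, 25)])
        t = np.concatenate([rng.exponential(10, 25), rng.exponential(1, 25)])
        e = np.ones(50, int)
        res = max_rank_cutpoint(s, t, e)
        assert 0.5 < res.cutpoint < 4.5

    def test_minprop_respected(self, rng):
        s = rng.normal(size=40)
        t = rng.exponential(2, 40)
        res = max_rank_cutpoint(s, t, np.ones(40, int), minprop=0.25)
        assert min(res.group_sizes) >= 10

    def test_permutation_p_small_for_strong_effect(self, rng):
        s = rng.normal(size=60)
        t = np.exp(-s) * rng.exponential(1, 60) + 1e-3
        res = max_rank_cutpoint(s, t, np.ones(60, int), n_permutations=99, seed=1)
        assert res.p_value is not None and res.p_value < 0.05


class TestTdAUC:
    def test_null_score_near_half(self, rng):
        n = 500
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.8).astype(int)
        s = rng.normal(size=n)
        auc = td_auc(s, t, e, horizon=4.0)
        assert abs(auc - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_no_censoring_equals_mann_whitney(self, rng):
        n = 120
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        s = rng.normal(size=n) + 1 / t
        horizon = float(np.median(t))
        cases = t <= horizon
        u = ((s[cases][:, None] > s[~cases][None, :])
             + 0.5 * (s[cases][:, None] == s[~cases][None, :])).mean()
        assert td_auc(s, t, e, horizon) == pytest.approx(u, abs=1e-12)

    def test_matches_scikit_survival(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        n = 200
        s = rng.normal(size=n)
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * s)))
        e = (rng.random(n) < 0.75).astype(int)
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("e", bool), ("t", float)])
        for h in (2.0, 5.0):
            ref = cumulative_dynamic_auc(y, y, s, [h])[0][0]
            assert td_auc(s, t, e, h) == pytest.approx(ref, abs=1e-10)

    def test_informative_score_beats_chance(self):
        c = generate_cohort(CohortConfig(n_samples=300, n_genes=30,
                                         n_informative=10, effect_size=2.0,
                                         log_hazard_ratio=1.0, seed=6))
        t = c.clinical["os_years"].to_numpy()
        e = c.clinical["os_event"].to_numpy()
        assert td_auc(c.true_risk, t, e, float(np.median(t))) > 0.75

    def test_no_cases_rejected(self, rng):
        t = rng.exponential(5, 20) + 10
        with pytest.raises(InputError):
            td_auc(rng.normal(size=20), t, np.ones(20, int), horizon=1.0)


class TestCIndex:
    def test_perfect_concordance(self):
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        assert c_index(-t, t, np.ones(5, int)) == 1.0

    def test_random_score_near_half(self, rng):
        n = 400
        t = rng.exponential(5, n)
        s = rng.normal(size=n)
        assert abs(c_index(s, t, np.ones(n, int)) - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_five_sample_pair_enumeration(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        s = np.array([3.0, 1.0, 2.0, 2.0, 0.0])
        # usable pairs (shorter time has event): (1,*): 4 pairs; (3,4),(3,5); (4,5)
        # concordant: (1,2) (1,3) (1,4) (1,5) (3,5) (4,5); tied score: (3,4)
        expected = (6 + 0.5) / 7
        assert c_index(s, t, e) == pytest.approx(expected)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index
        n = 150
        s = rng.normal(size=n)
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * s)))
        e = (rng.random(n) < 0.7).astype(int)
        assert c_index(s, t, e) == pytest.approx(concordance_index(t, -s, e), abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(InputError):
            c_index([1.0, 2.0], [5.0, 6.0], [0, 0])
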