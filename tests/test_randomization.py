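"""Letter assignment, threshold arithmetic, enrollment replay, integrity."""

import math
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfrecruit import randomization as rz
from cfrecruit import synth_population as sp

from conftest import STUDY_END, STUDY_START, make_threshold_states


class TestAssignLetters:
    def test_empty_input(self):
        out = rz.assign_letters(pd.DataFrame(columns=["patient_id", "center_id", "block"]))
        assert len(out) == 0

    def test_uniformity_goodness_of_fit(self):
        pats = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(26_000)],
            "center_id": "C01", "block": "adult",
        })
        letters = rz.assign_letters(pats, seed=13)
        counts = np.bincount(letters["letter"], minlength=26)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert stats.chi2.sf(chi2, 25) > 0.001

    def test_blocks_independent(self):
        n = 5000
        pats = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(2 * n)],
            "center_id": "C01",
            "block": ["adult"] * n + ["pediatric"] * n,
        })
        letters = rz.assign_letters(pats, seed=21)
        a = letters["letter"].to_numpy()[:n]
        b = letters["letter"].to_numpy()[n:]
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3.0 / math.sqrt(n)

    def test_duplicate_ids_rejected(self):
        pats = pd.DataFrame({"patient_id": ["a", "a"], "center_id": "C01", "block": "adult"})
        with pytest.raises(ValueError, match="duplicate"):
            rz.assign_letters(pats)

    def test_determinism(self, small_population):
        a = rz.assign_letters(small_population, seed=2)
        b = rz.assign_letters(small_population, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestRequiredThreshold:
    def brute_force(self, N, target, c, s):
        for k in range(27):
            if (k / 26) * N * c * s >= target - 1e-9:
                return k
        return 26

    def test_zero_target(self):
        assert rz.required_threshold(100, 0, 0.5, 0.9).k == 0

    def test_planning_example(self):
        # 53% recruitment rate, 10% no-show, pool 100, target 20.
        dec = rz.required_threshold(100, 20, 0.53, 0.90)
        assert dec.k == self.brute_force(100, 20, 0.53, 0.90) == 11
        assert dec.threshold_letter == "L"  # flagged letters A-K
        assert not dec.insufficient_pool

    @pytest.mark.parametrize("N,target,c,s", [
        (100, 20, 0.53, 0.90), (80, 10, 0.30, 1.0), (1000, 150, 0.53, 0.90),
        (50, 5, 0.25, 0.8), (10, 9, 1.0, 1.0), (0, 0, 0.5, 0.5),
    ])
    def test_matches_brute_force_scan(self, N, target, c, s):
        assert rz.required_threshold(N, target, c, s).k == self.brute_force(N, target, c, s)

    def test_all_letters_boundary(self):
        dec = rz.required_threshold(100, 100, 1.0, 1.0)
        assert dec.k == 26 and not dec.insufficient_pool

    def test_insufficient_pool_warning(self):
        dec = rz.required_threshold(10, 100, 0.5, 0.9)
        assert dec.k == 26 and dec.insufficient_pool

    def test_zero_rate_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            rz.required_threshold(100, 10, 0.0, 0.9)


class TestIsFlagged:
    def test_strict_boundary(self):
        assert not rz.is_flagged(0, 0)      # 'A' with nothing flagged
        assert rz.is_flagged(2, 11)         # 'C' under threshold letter 'L'
        assert not rz.is_flagged(11, 11)    # the threshold letter itself
        assert all(rz.is_flagged(l, 26) for l in range(26))

    def test_range_checks(self):
        with pytest.raises(ValueError):
            rz.is_flagged(26, 10)
        with pytest.raises(ValueError):
            rz.is_flagged(3, 27)

    def test_flagged_fraction_law(self):
        # Empirical flagged fraction ~ k/26 over 10,000 uniform letters.
        rng = np.random.default_rng(17)
        letters = rng.integers(0, 26, size=10_000)
        for k in (5, 11, 20):
            frac = np.mean(letters < k)
            p = k / 26
            assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 10_000)


def _state(k, pool=1000, target=150, c=0.53, s=0.90):
    return rz.ThresholdState(
        block_key="C01:adult", k=k, effective_from=STUDY_START,
        consent_rate_estimate=c, show_rate_estimate=s,
        pool_size=pool, target_total=target, target_remaining=target,
        study_start=STUDY_START, study_end=STUDY_END,
    )


class TestAdjustThreshold:
    def test_on_target_holds(self):
        # Exactly on the pro-rata target with unchanged rate estimates.
        st = _state(11, pool=100, target=20)
        obs = rz.PeriodSummary(scheduled=100, shown=90, approached=20,
                               consented=11, enrolled_cumulative=11,
                               elapsed_fraction=11 / 20)
        new = rz.adjust_threshold(st, obs, STUDY_START + timedelta(days=90))
        assert new.k == st.k

    def test_lagging_recomputes_smallest_k(self):
        # Remaining pool 80, remaining target 10, consent x show = 0.30:
        # brute-force scan gives k = 11.
        st = _state(9, pool=180, target=40, c=0.30, s=1.0)
        obs = rz.PeriodSummary(scheduled=0, shown=0, approached=100,
                               consented=30, enrolled_cumulative=30,
                               elapsed_fraction=0.85)
        new = rz.adjust_threshold(st, obs, STUDY_START + timedelta(days=200),
                                  visits_remaining_per_patient=1.0)
        assert new.k == 11
        assert new.rationale == "speed_adjustment"

    def test_too_rapid_moves_earlier(self):
        st = _state(11, pool=1000, target=100)
        obs = rz.PeriodSummary(scheduled=400, shown=360, approached=150,
                               consented=80, enrolled_cumulative=80,
                               elapsed_fraction=0.5)  # 160% of pro-rata
        new = rz.adjust_threshold(st, obs, STUDY_START + timedelta(days=120))
        assert new.k < st.k

    def test_too_slow_moves_later(self):
        st = _state(11, pool=1000, target=100)
        obs = rz.PeriodSummary(scheduled=400, shown=360, approached=150,
                               consented=20, enrolled_cumulative=20,
                               elapsed_fraction=0.5)
        new = rz.adjust_threshold(st, obs, STUDY_START + timedelta(days=120))
        assert new.k > st.k

    def test_history_appended_and_past_preserved(self):
        st = _state(11)
        obs = rz.PeriodSummary(scheduled=100, shown=90, approached=40,
                               consented=5, enrolled_cumulative=5,
                               elapsed_fraction=0.4)
        new = rz.adjust_threshold(st, obs, STUDY_START + timedelta(days=90))
        assert new.history[-1] is st
        assert st.k == 11  # old state untouched

    def test_review_before_observation_rejected(self):
        st = _state(11)
        obs = rz.PeriodSummary(0, 0, 0, 0, 0, elapsed_fraction=0.0)
        with pytest.raises(ValueError):
            rz.adjust_threshold(st, obs, STUDY_START)


@pytest.fixture(scope="module")
def enrollment_sim(multicenter_population):
    letters = rz.assign_letters(multicenter_population, seed=31)
    visits = sp.generate_visits(multicenter_population, horizon_days=365,
                                no_show_rate=0.10, seed=32, start_date=STUDY_START)
    states = make_threshold_states(multicenter_population, letters, target_total=114)
    trace, history = rz.simulate_enrollment(
        multicenter_population, letters, visits, states,
        consent_rate_true=0.53, seed=33,
    )
    return multicenter_population, letters, visits, states, trace, history


class TestSimulateEnrollment:
    def test_zero_threshold_zero_enrollment(self, small_population):
        letters = rz.assign_letters(small_population, seed=1)
        visits = sp.generate_visits(small_population, seed=2, start_date=STUDY_START)
        bk = letters["block_key"].unique()
        states = {b: _state(0) for b in bk}
        for b, st in states.items():
            st.block_key = b
        trace, _ = rz.simulate_enrollment(small_population, letters, visits, states,
                                          seed=3, review_dates=[])
        assert trace["enrolled"].sum() == 0

    def test_saturation(self, small_population):
        # Every letter flagged, nobody no-shows, consent certain:
        # every eligible patient enrolls at their first visit.
        letters = rz.assign_letters(small_population, seed=4)
        visits = sp.generate_visits(small_population, no_show_rate=0.0, seed=5,
                                    start_date=STUDY_START)
        states = {}
        for b in letters["block_key"].unique():
            s = _state(26)
            s.block_key = b
            s.target_total = 10**6  # never triggers braking within one review
            states[b] = s
        trace, _ = rz.simulate_enrollment(small_population, letters, visits, states,
                                          consent_rate_true=1.0, seed=6,
                                          review_dates=[])
        n_eligible = small_population["eligible"].sum()
        assert trace["enrolled"].sum() == n_eligible
        firsts = trace.sort_values(["visit_date", "patient_id"]).drop_duplicates("patient_id")
        assert firsts["approached"].sum() == n_eligible

    def test_enrollment_count_binomial_oracle(self):
        # Fixed k = 11, one visit each, no reviews: enrollment among
        # first-visit patients is Binomial((11/26) * N * c * s).
        n = 1000
        pats = pd.DataFrame({
            "patient_id": [f"p{i:05d}" for i in range(n)],
            "center_id": "C01", "block": "adult", "eligible": True,
        })
        letters = rz.assign_letters(pats, seed=41)
        visits = sp.generate_visits(pats, horizon_days=91, visit_interval_days=91,
                                    no_show_rate=0.10, seed=42, start_date=STUDY_START)
        assert len(visits) == n  # one visit per patient
        st = _state(11, pool=n, target=10**6)
        trace, _ = rz.simulate_enrollment(pats, letters, visits, {"C01:adult": st},
                                          consent_rate_true=0.53, seed=43,
                                          review_dates=[])
        expect = (11 / 26) * n * 0.53 * 0.90
        se = math.sqrt((11 / 26) * 0.53 * 0.90 * (1 - (11 / 26) * 0.53 * 0.90) * n)
        assert abs(trace["enrolled"].sum() - expect) < 3 * se

    def test_monotone_in_k(self):
        # Enrollment count is non-decreasing in the threshold index.
        n = 400
        pats = pd.DataFrame({
            "patient_id": [f"p{i:04d}" for i in range(n)],
            "center_id": "C01", "block": "adult", "eligible": True,
        })
        letters = rz.assign_letters(pats, seed=51)
        visits = sp.generate_visits(pats, horizon_days=91, visit_interval_days=91,
                                    no_show_rate=0.0, seed=52, start_date=STUDY_START)
        counts = []
        for k in (0, 5, 11, 20, 26):
            st = _state(k, pool=n, target=10**6)
            trace, _ = rz.simulate_enrollment(pats, letters, visits, {"C01:adult": st},
                                              consent_rate_true=1.0, seed=53,
                                              review_dates=[])
            counts.append(trace["enrolled"].sum())
        assert counts == sorted(counts)

    def test_unknown_patient_rejected(self, small_population):
        letters = rz.assign_letters(small_population, seed=1)
        visits = pd.DataFrame({
            "patient_id": ["nobody"], "visit_date": [STUDY_START],
            "showed": [True], "approached": [False], "consented": [False],
        })
        with pytest.raises(ValueError, match="unknown patient"):
            rz.simulate_enrollment(small_population, letters, visits,
                                   {"C01:adult": _state(11)}, seed=1)


class TestIntegrity:
    def test_replay_self_consistency(self, enrollment_sim):
        pats, letters, _, _, trace, history = enrollment_sim
        report = rz.check_randomization_integrity(trace, letters, history, pats)
        assert report.n_mismatches == 0
        assert report.replay_ok

    def test_fault_injection_detected(self, enrollment_sim):
        pats, letters, _, _, trace, history = enrollment_sim
        bad = trace.copy()
        bad.loc[bad.index[100], "flagged"] = not bad.loc[bad.index[100], "flagged"]
        report = rz.check_randomization_integrity(bad, letters, history, pats)
        assert report.n_mismatches == 1

    def test_missing_letters_rejected(self, enrollment_sim):
        _, letters, _, _, trace, history = enrollment_sim
        with pytest.raises(ValueError, match="missing"):
            rz.check_randomization_integrity(trace, letters.iloc[:10], history)

    def test_balance_p_values_reported(self, enrollment_sim):
        pats, letters, _, _, trace, history = enrollment_sim
        report = rz.check_randomization_integrity(trace, letters, history, pats, seed=5)
        assert set(report.balance_p_values) == {
            "age_at_baseline", "fev1pp", "prior_year_exacerbations"}
        assert all(0 < p <= 1 for p in report.balance_p_values.values())


class TestPermutationBalance:
    def test_detects_gross_imbalance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
        flags = np.repeat([True, False], 200)
        p = rz.permutation_balance_test(x, flags, rng=rng)
        assert p < 0.01

    def test_null_p_value_moderate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        flags = rng.random(400) < 0.4
        p = rz.permutation_balance_test(x, flags, rng=rng)
        assert p > 0.001

    def test_degenerate_groups(self):
        x = np.arange(10.0)
        assert rz.permutation_balance_test(x, np.zeros(10, bool)) == 1.0

    def test_agrees_with_scipy_permutation_test(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=150)
        flags = rng.random(150) < 0.42

        def statfn(a, b, axis=-1):
            return np.abs(np.mean(a, axis=axis) - np.mean(b, axis=axis))

        ours = rz.permutation_balance_test(x, flags, n_permutations=1999,
                                           rng=np.random.default_rng(1))
        ref = stats.permutation_test(
            (x[flags], x[~flags]), statfn, permutation_type="independent",
            n_resamples=1999, alternative="greater", vectorized=True,
            rng=np.random.default_rng(2))
        assert abs(ours - ref.pvalue) < 0.05
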