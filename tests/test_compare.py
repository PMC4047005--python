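"""The three tests: oracles, identities and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

from crtests import (TrialDataset, UndefinedStatisticError, gray_test,
                     logrank_cause_specific, peto_reclassify,
                     peto_subtraction_test, preset, reject_at_level,
                     run_all_tests, simulate_trial)
from crtests._kernels import gray_oe

from conftest import make_dataset, random_small_trial


def brute_force_logrank(time, event, group):
    """Independent oracle: build every 2x2 risk table explicitly."""
    oe = v = 0.0
    for t in sorted(set(time[event])):
        at = time >= t
        n = at.sum()
        n1 = (at & (group == 1)).sum()
        now = event & (time == t)
        d, d1 = now.sum(), (now & (group == 1)).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe, v


class TestCauseSpecificLogrank:
    def test_hand_worked_toy_example(self):
        # arm A (treated) deaths at 1, 3; arm B deaths at 2, 4; all cancer.
        # Hand-summed tables: (1 - 2/4) + (0 - 1/3) + (1 - 1/2) + 0 = 2/3,
        # V = 1/4 + 2/9 + 1/4 = 13/18, X2 = (2/3)^2 / (13/18) = 8/13.
        data = make_dataset([1, 3, 2, 4], [1, 1, 1, 1], [1, 1, 0, 0])
        r = logrank_cause_specific(data, "cancer")
        assert r.observed_minus_expected == pytest.approx(2 / 3, abs=1e-12)
        assert r.variance == pytest.approx(13 / 18, abs=1e-12)
        assert r.statistic == pytest.approx(8 / 13, abs=1e-12)

    def test_identical_arms_give_zero_statistic(self):
        data = make_dataset([1, 2, 3, 1, 2, 3], [1, 2, 0, 1, 2, 0],
                            [0, 0, 0, 1, 1, 1])
        assert logrank_cause_specific(data, "cancer").statistic == pytest.approx(0, abs=1e-12)

    def test_matches_brute_force_oracle_on_small_random_data(self):
        from crtests._kernels import logrank_oe
        rng = np.random.default_rng(2024)
        for _ in range(200):
            data = random_small_trial(rng)
            oe, v, _ = logrank_oe(data.time, data.status == 1, data.arm)
            oe_ref, v_ref = brute_force_logrank(data.time, data.status == 1,
                                                data.arm)
            assert oe == pytest.approx(oe_ref, abs=1e-10)
            assert v == pytest.approx(v_ref, abs=1e-10)

    def test_matches_lifelines_on_large_trial(self, censored_trial):
        from lifelines.statistics import logrank_test
        ds = censored_trial
        ev = ds.status == 1
        a, b = ds.arm == 0, ds.arm == 1
        ref = logrank_test(ds.time[a], ds.time[b], event_observed_A=ev[a],
                           event_observed_B=ev[b])
        mine = logrank_cause_specific(ds, "cancer")
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-10)

    def test_competing_and_unknown_deaths_censor(self):
        # unknown-cause deaths must act exactly like censorings for CS
        base = make_dataset([1, 2, 3, 4], [1, 3, 1, 0], [1, 0, 0, 1])
        same = make_dataset([1, 2, 3, 4], [1, 0, 1, 0], [1, 0, 0, 1])
        ra = logrank_cause_specific(base, "cancer")
        rb = logrank_cause_specific(same, "cancer")
        assert ra.statistic == rb.statistic

    def test_no_events_of_cause_is_undefined(self):
        data = make_dataset([1, 2], [1, 1], [0, 1])
        with pytest.raises(UndefinedStatisticError):
            logrank_cause_specific(data, "noncancer")


class TestGray:
    def test_identical_arms_give_zero_statistic(self):
        data = make_dataset([1, 2, 3, 1, 2, 3], [1, 2, 0, 1, 2, 0],
                            [0, 0, 0, 1, 1, 1])
        assert gray_test(data, "cancer").statistic == pytest.approx(0, abs=1e-12)

    def test_equals_cause_specific_without_competing_events(self):
        # single cause, no censoring: subdistribution and cause-specific
        # risk sets coincide, so the tests agree (within 2%; here exactly)
        ds = simulate_trial(preset("scenario3", seed=4, n_subjects=2000), 0)
        ds.status[ds.status == 2] = 1
        g = gray_test(ds, "cancer")
        c = logrank_cause_specific(ds, "cancer")
        assert g.statistic == pytest.approx(c.statistic, rel=0.02)

    def test_extended_risk_set_changes_the_answer(self):
        # a competing event must keep its subject in Gray's risk set:
        # compare against CS on data where that matters
        data = make_dataset([1, 2, 3, 4, 5, 6], [2, 1, 1, 1, 1, 1],
                            [1, 1, 0, 1, 0, 0])
        g = gray_test(data, "cancer")
        c = logrank_cause_specific(data, "cancer")
        assert g.statistic != pytest.approx(c.statistic, rel=1e-6)

    def test_permutation_null_p_values_are_uniform(self):
        ds = simulate_trial(preset("scenario1", seed=6, n_subjects=300), 0)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(2000):
            arm = rng.permutation(ds.arm)
            oe, v, _ = gray_oe(ds.time, ds.status, arm, 1)
            pvals.append(chi2.sf(oe * oe / v, 1))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_unknown_cause_forms_third_competing_group(self):
        # relabelling unknown deaths as noncancer must not change the
        # cancer-cause analysis (both are competing events), but removing
        # them as censorings must
        base = make_dataset([1, 2, 3, 4, 5], [1, 3, 1, 1, 0], [1, 0, 0, 1, 1])
        relab = make_dataset([1, 2, 3, 4, 5], [1, 2, 1, 1, 0], [1, 0, 0, 1, 1])
        cens = make_dataset([1, 2, 3, 4, 5], [1, 0, 1, 1, 0], [1, 0, 0, 1, 1])
        assert gray_test(base, "cancer").statistic == \
            pytest.approx(gray_test(relab, "cancer").statistic, abs=1e-12)
        assert gray_test(base, "cancer").statistic != \
            pytest.approx(gray_test(cens, "cancer").statistic, rel=1e-6)


class TestPeto:
    def test_reclassification_rules(self):
        data = make_dataset([5, 4, 6, 3], [2, 3, 2, 0], [0, 1, 0, 1],
                            rec_time=[3, np.nan, np.nan, 1])
        out = peto_reclassify(data)
        assert out.status[0] == 1   # NCD after recurrence -> cancer
        assert out.status[1] == 1   # unknown cause -> cancer
        assert out.status[2] == 2   # NCD, no recurrence -> unchanged
        assert out.status[3] == 0   # censored untouched
        assert np.array_equal(out.time, data.time)

    def test_subtraction_equals_cause_specific_on_clean_data(self):
        # no recurrences, no unknown causes, no ties: O-E and V are additive
        # over causes, so Pe(CD) == CS(CD) and Pe(NCD) == CS(NCD) exactly
        ds = simulate_trial(preset("scenario3", seed=9), 0)
        ds.rec_time[:] = np.nan
        pe_cd, pe_ncd = peto_subtraction_test(ds)
        assert pe_cd.statistic == pytest.approx(
            logrank_cause_specific(ds, "cancer").statistic, abs=1e-10)
        assert pe_ncd.statistic == pytest.approx(
            logrank_cause_specific(ds, "noncancer").statistic, abs=1e-10)

    def test_identical_arms_give_zero_statistics(self):
        data = make_dataset([1, 2, 3, 1, 2, 3], [1, 2, 0, 1, 2, 0],
                            [0, 0, 0, 1, 1, 1])
        cd, ncd = peto_subtraction_test(data)
        assert cd.statistic == pytest.approx(0, abs=1e-12)
        assert ncd.statistic == pytest.approx(0, abs=1e-12)

    def test_recurrence_reclassified_death_exits_ncd_analysis_at_recurrence(self):
        # a declared NCD with a recurrence becomes a cancer death and leaves
        # the NCD risk set at the recurrence; moving that recurrence across
        # an NCD event time changes the NCD score
        a = make_dataset([5, 3, 4, 6], [2, 2, 2, 1], [0, 1, 0, 1],
                         rec_time=[2.5, np.nan, np.nan, np.nan])
        b = make_dataset([5, 3, 4, 6], [2, 2, 2, 1], [0, 1, 0, 1],
                         rec_time=[3.5, np.nan, np.nan, np.nan])
        ra = peto_subtraction_test(a)[1]
        rb = peto_subtraction_test(b)[1]
        assert ra.observed_minus_expected != rb.observed_minus_expected
        # a declared cancer death keeps its full follow-up in the NCD
        # analysis regardless of its recurrence
        c = make_dataset([5, 3, 4, 6], [1, 2, 2, 1], [0, 1, 0, 1],
                         rec_time=[2.5, np.nan, np.nan, np.nan])
        d = make_dataset([5, 3, 4, 6], [1, 2, 2, 1], [0, 1, 0, 1],
                         rec_time=[np.nan, np.nan, np.nan, np.nan])
        assert peto_subtraction_test(c)[1].observed_minus_expected == \
            peto_subtraction_test(d)[1].observed_minus_expected

    def test_missing_death_class_is_undefined(self):
        data = make_dataset([1, 2, 3, 4], [1, 1, 1, 0], [0, 0, 1, 1])
        with pytest.raises(UndefinedStatisticError):
            peto_subtraction_test(data)


class TestRejectAtLevel:
    def test_chi_square_threshold_at_five_percent(self):
        r = run_all_tests(simulate_trial(preset("scenario1", seed=0), 0))
        some = next(iter(r.values()))
        assert reject_at_level(some, 0.05) == (some.statistic > 3.8415)

    @pytest.mark.parametrize("stat,expect", [(3.9, True), (3.8, False)])
    def test_boundary_statistics(self, stat, expect):
        from crtests.compare import TestResult
        res = TestResult(statistic=stat, df=1, p_value=float(chi2.sf(stat, 1)),
                         observed_minus_expected=1.0, variance=stat)
        assert reject_at_level(res, 0.05) is expect

    def test_p_value_of_printed_statistic(self):
        # X2 = 4.77 on 1 df has upper-tail probability ~0.029
        assert chi2.sf(4.77, 1) == pytest.approx(0.029, abs=0.0005)


@st.composite
def small_trials(draw):
    n = draw(st.integers(6, 14))
    time = draw(st.lists(st.integers(1, 5), min_size=n, max_size=n))
    status = draw(st.lists(st.sampled_from([0, 1, 1, 2]), min_size=n, max_size=n))
    arm = [0, 1] * (n // 2) + [0] * (n % 2)
    if 1 not in status or 2 not in status:
        status = status[:-2] + [1, 2]
    return make_dataset(np.array(time, float), status, arm)


class TestInvariances:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_trials(), st.floats(0.1, 50.0))
    def test_statistics_invariant_under_time_rescaling(self, data, scale):
        scaled = TrialDataset(time=data.time * scale, status=data.status,
                              arm=data.arm, rec_time=data.rec_time * scale)
        for name, res in run_all_tests(data).items():
            other = run_all_tests(scaled)[name]
            assert res.statistic == pytest.approx(other.statistic, rel=1e-9, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_trials())
    def test_arm_swap_preserves_statistic_and_negates_score(self, data):
        swapped = TrialDataset(time=data.time, status=data.status,
                               arm=1 - data.arm, rec_time=data.rec_time)
        base = run_all_tests(data)
        other = run_all_tests(swapped)
        for name, res in base.items():
            assert other[name].statistic == pytest.approx(res.statistic,
                                                          rel=1e-9, abs=1e-12)
            assert other[name].observed_minus_expected == pytest.approx(
                -res.observed_minus_expected, abs=1e-9)

    def test_subject_order_irrelevant(self, null_trial):
        rng = np.random.default_rng(3)
        perm = rng.permutation(null_trial.n)
        shuffled = TrialDataset(time=null_trial.time[perm],
                                status=null_trial.status[perm],
                                arm=null_trial.arm[perm],
                                rec_time=null_trial.rec_time[perm])
        for name, res in run_all_tests(null_trial).items():
            assert run_all_tests(shuffled)[name].statistic == pytest.approx(
                res.statistic, rel=1e-9)
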