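"""Endpoints, Kaplan-Meier, log-rank, Cox regression, ROC and chi-square."""

import datetime as dt
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tests.conftest import km_product_limit_brute
from trimeth.survival import (
    DeathCause,
    Endpoint,
    PatientRecord,
    SurvivalEndpoint,
    build_endpoints,
    covariate_association,
    cox_multivariable,
    cox_univariable,
    km_estimate,
    logrank_test,
    roc_analysis,
)

D0 = dt.date(2021, 1, 1)
CUTOFF = dt.date(2023, 7, 1)


def _record(**kw):
    return PatientRecord(patient_id=kw.pop("pid", "P1"), inclusion_date=D0,
                         data_cutoff=CUTOFF, **kw)


def _ep(pid, time, event, endpoint=Endpoint.RFS):
    return SurvivalEndpoint(pid, float(time), bool(event), endpoint)


def _eps(times, events, endpoint=Endpoint.RFS):
    return [_ep(f"P{i}", t, e, endpoint) for i, (t, e) in enumerate(zip(times, events))]


class TestEndpoints:
    def test_recurrence_then_death(self):
        rec = _record(
            recurrence_date=D0 + dt.timedelta(days=304),
            death_date=D0 + dt.timedelta(days=426),
            death_cause=DeathCause.cancer,
        )
        rfs, os_ = build_endpoints(rec)
        assert rfs.event and rfs.time == pytest.approx(304 / 30.4375)
        assert os_.event and os_.time == pytest.approx(426 / 30.4375)

    def test_event_free_censored_at_cutoff(self):
        rfs, os_ = build_endpoints(_record())
        expected = (CUTOFF - D0).days / 30.4375
        assert not rfs.event and rfs.time == pytest.approx(expected)
        assert not os_.event and os_.time == pytest.approx(expected)

    def test_noncancer_death_censors_rfs_counts_for_os(self):
        rec = _record(death_date=D0 + dt.timedelta(days=365), death_cause=DeathCause.other)
        rfs, os_ = build_endpoints(rec)
        assert not rfs.event and rfs.time == pytest.approx(365 / 30.4375)
        assert os_.event and os_.time == pytest.approx(365 / 30.4375)

    def test_event_after_cutoff_rejected(self):
        rec = _record(recurrence_date=CUTOFF + dt.timedelta(days=1))
        with pytest.raises(ValueError, match="after data cutoff"):
            build_endpoints(rec)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """(1 censored, 2 event, 3 event, 4 censored): S(2)=2/3, S(3)=1/3."""
        km = km_estimate(_eps([1, 2, 3, 4], [False, True, True, False]))
        assert km.survival_at(1.5)[0] == pytest.approx(1.0)
        assert km.survival_at(2)[0] == pytest.approx(2 / 3)
        assert km.survival_at(3)[0] == pytest.approx(1 / 3)
        assert km.survival_at(10)[0] == pytest.approx(1 / 3)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(_eps([1, 2, 3], [False] * 3))
        assert km.survival_at(100.0) == (1.0, 1.0, 1.0)

    def test_single_subject_event_drops_to_zero(self):
        km = km_estimate(_eps([5], [True]))
        assert km.survival_at(5)[0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_matches_brute_force_on_small_instances(self):
        """Product-limit agrees with an explicit loop on any <=10-subject mix
        of events, censorings and ties."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 11))
            times = np.maximum(0.1, np.round(rng.exponential(12, n), 1))
            events = rng.random(n) < 0.7
            if not events.any():
                continue
            km = km_estimate(_eps(times, events))
            bt, bs = km_product_limit_brute(times, events)
            assert np.allclose(km.timeline, bt)
            assert np.allclose(km.survival, bs)

    def test_greenwood_interval_brackets_estimate(self):
        km = km_estimate(_eps(range(1, 9), [True] * 6 + [False] * 2))
        assert np.all(km.ci_low <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_high + 1e-12)

    def test_landmark_invariant_to_input_order(self):
        eps = _eps([3, 8, 12, 20, 25, 30], [1, 1, 0, 1, 0, 0])
        a = km_estimate(eps).survival_at(24.0)
        b = km_estimate(list(reversed(eps))).survival_at(24.0)
        assert a == b


class TestLogrank:
    def test_identical_groups_null_identity(self):
        g = _eps([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test(g, list(g))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self):
        a = _eps([1, 2, 3, 9], [1, 1, 1, 0])
        b = _eps([5, 6, 7, 8], [1, 0, 1, 1])
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_complete_separation_rejects(self):
        """All group-A events precede all group-B events (n=10 each)."""
        a = _eps(range(1, 11), [True] * 10)
        b = _eps(range(100, 110), [True] * 10)
        asym = logrank_test(a, b)
        assert asym.p_value < 0.01
        # exhaustive permutation oracle agrees on rejection (7 per group)
        t = np.array([float(x) for x in [*range(1, 8), *range(100, 107)]])
        d = np.ones(14, bool)
        assert _perm_p_chi2(t, d, 7) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_eps([1], [True]), [])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        for _ in range(5):
            ta, tb = rng.exponential(10, 30), rng.exponential(6, 25)
            da, db = rng.random(30) < 0.8, rng.random(25) < 0.8
            mine = logrank_test(ta, tb, da, db)
            ref = ll_logrank(ta, tb, da, db)
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)


def _perm_p_chi2(t, d, na, max_perms=None):
    """Exhaustive (or truncated) relabeling oracle: recompute the full
    log-rank chi-square for every assignment of na subjects to group A."""
    n = len(t)
    obs = logrank_test(t[:na], t[na:], d[:na], d[na:]).statistic
    cnt = tot = 0
    for c in combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(c)] = True
        s = logrank_test(t[mask], t[~mask], d[mask], d[~mask]).statistic
        cnt += s >= obs - 1e-9
        tot += 1
        if max_perms and tot >= max_perms:
            break
    return cnt / tot


def test_asymptotic_p_tracks_permutation_p_at_small_n():
    """At n=10 the chi-square p sits within the discreteness scale of the
    exact permutation distribution (~0.07, atoms of 1/252); by 10 subjects
    per group the score-statistic permutation p agrees to ~0.025."""
    for seed in range(8):
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(10, 10), 2)
        d = rng.random(10) < 0.8
        asym = logrank_test(t[:5], t[5:], d[:5], d[5:]).p_value
        assert abs(asym - _perm_p_chi2(t, d, 5)) <= 0.075


def _two_group(rng, n, hr, p=0.5, censor=None):
    pos = rng.random(n) < p
    h = np.log(2) / 30 * np.where(pos, hr, 1.0)
    te = rng.exponential(1 / h)
    if censor is None:
        return te, np.ones(n, bool), pos
    return np.minimum(te, censor), te <= censor, pos


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        """Two-group exponential data, n=500, true HR 2.5: the fitted 95%
        CI covers the truth in >=93% of 200 replicates."""
        rng = np.random.default_rng(2024)
        cover = 0
        for _ in range(200):
            t, e, pos = _two_group(rng, 500, 2.5)
            eps = _eps(t, e)
            cov = {f"P{i}": ("b_pos" if pos[i] else "a_neg") for i in range(500)}
            est = cox_univariable(eps, cov, levels=["a_neg", "b_pos"])[0]
            cover += est.ci_low <= 2.5 <= est.ci_high
        assert cover / 200 >= 0.93

    def test_constant_covariate_rejected(self):
        eps = _eps([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="no contrast"):
            cox_univariable(eps, {f"P{i}": "same" for i in range(3)})

    def test_relabeled_covariate_gives_reciprocal_hr(self):
        rng = np.random.default_rng(3)
        t, e, pos = _two_group(rng, 200, 3.0)
        eps = _eps(t, e)
        cov = {f"P{i}": ("b" if pos[i] else "a") for i in range(200)}
        inv = {f"P{i}": ("a" if pos[i] else "b") for i in range(200)}
        hr = cox_univariable(eps, cov, levels=["a", "b"])[0].hr
        hr_inv = cox_univariable(eps, inv, levels=["b", "a"])[0].hr
        assert hr == pytest.approx(hr_inv, rel=1e-6)

    def test_no_events_in_level_flagged_not_crashed(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 1, 1, 0, 0, 0, 0]  # all events in group a
        eps = _eps(times, events)
        cov = {f"P{i}": ("a" if i < 4 else "b") for i in range(8)}
        est = cox_univariable(eps, cov, levels=["a", "b"])[0]
        assert est.flagged
        assert "monotone likelihood" in est.diagnostic


class TestCoxMultivariable:
    @staticmethod
    def _data(seed=9, n=600):
        """Two independent binary effects (HR 2 and 3) plus pure noise."""
        rng = np.random.default_rng(seed)
        x1 = rng.random(n) < 0.5
        x2 = rng.random(n) < 0.5
        noise = rng.random(n) < 0.5
        h = np.log(2) / 30 * np.exp(np.log(2.0) * x1 + np.log(3.0) * x2)
        te = rng.exponential(1 / h)
        eps = _eps(te, np.ones(n, bool))
        covs = {
            "x1": {f"P{i}": ("hi" if x1[i] else "lo") for i in range(n)},
            "x2": {f"P{i}": ("hi" if x2[i] else "lo") for i in range(n)},
            "noise": {f"P{i}": ("hi" if noise[i] else "lo") for i in range(n)},
        }
        lv = {k: ["lo", "hi"] for k in covs}
        return eps, covs, lv

    def test_screen_admits_only_significant_candidates(self):
        eps, covs, lv = self._data()
        ests, entered, screen = cox_multivariable(eps, covs, entry_p=0.05, levels_map=lv)
        assert set(entered) == {"x1", "x2"}
        assert screen["noise"] >= 0.05
        assert {e.variable for e in ests} == {"x1", "x2"}

    def test_both_true_effects_recovered_within_ci(self):
        eps, covs, lv = self._data()
        ests, _, _ = cox_multivariable(eps, covs, entry_p=0.05, levels_map=lv)
        by_var = {e.variable: e for e in ests}
        assert by_var["x1"].ci_low <= 2.0 <= by_var["x1"].ci_high
        assert by_var["x2"].ci_low <= 3.0 <= by_var["x2"].ci_high

    def test_single_candidate_reduces_to_univariable(self):
        eps, covs, lv = self._data()
        multi, _, _ = cox_multivariable(
            eps, {"x2": covs["x2"]}, entry_p=0.05, levels_map=lv
        )
        uni = cox_univariable(eps, covs["x2"], name="x2", levels=lv["x2"])
        assert multi[0].hr == pytest.approx(uni[0].hr, rel=1e-9)

    def test_no_qualifying_candidate_is_an_error(self):
        eps, covs, lv = self._data()
        with pytest.raises(ValueError, match="screen"):
            cox_multivariable(eps, {"noise": covs["noise"]}, entry_p=0.05, levels_map=lv)


class TestROC:
    def test_perfect_separation(self):
        *_, auc = roc_analysis([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auc == pytest.approx(1.0)

    def test_negated_scores_mirror_auc(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.4
        *_, auc = roc_analysis(s, y)
        *_, auc_neg = roc_analysis(-s, y)
        assert auc_neg == pytest.approx(1.0 - auc)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(5)
        *_, auc = roc_analysis(rng.normal(size=1000), rng.random(1000) < 0.5)
        assert abs(auc - 0.5) < 0.04

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [True, True])


class TestChiSquare:
    def test_independent_table_null(self):
        stat, p = covariate_association([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        """Diagonal 2x2 table of 20s: chi-square = N = 40."""
        stat, p = covariate_association([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 0.001

    def test_transpose_invariant(self):
        tab = [[12, 5, 9], [3, 14, 7]]
        assert covariate_association(tab)[0] == pytest.approx(
            covariate_association(np.transpose(tab))[0]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            covariate_association([[5, 0], [7, 0]])
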