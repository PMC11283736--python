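"""Meta-analysis layer: effect estimates, pooling, cumulative series,
decision rule, evidence filters."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import approvoi as av
from approvoi.core import EmptyEvidenceError, InputError, UndefinedEffectError
from approvoi.evidence import MetaConfig, MetaResult, publication_groups
from approvoi.synthetic import SimSpec, gen_trials


def trial(a, n1, c, n2, day=1, **kw):
    return av.TrialComparison(
        kw.pop("id", f"T{day}"), dt.date(2020, 1, day), a, n1, c, n2, **kw
    )


class TestStudyEffect:
    def test_identical_arms_give_null_effect(self):
        e = av.study_effect(trial(5, 50, 5, 50))
        assert e.log_rr == 0.0
        assert not e.continuity_corrected

    def test_closed_form_se(self):
        # RR = (10/100)/(20/100) = 0.5; se = sqrt(1/10 - 1/100 + 1/20 - 1/100)
        e = av.study_effect(trial(10, 100, 20, 100))
        assert math.exp(e.log_rr) == pytest.approx(0.5, abs=1e-12)
        assert e.se_log_rr == pytest.approx(math.sqrt(0.13), abs=1e-12)

    def test_zero_cell_applies_continuity_correction(self):
        e = av.study_effect(trial(0, 20, 2, 20), cc=0.5)
        assert e.continuity_corrected
        # corrected cells: (0.5/21) / (2.5/21)
        assert math.exp(e.log_rr) == pytest.approx(0.5 / 2.5, abs=1e-12)

    def test_double_zero_without_correction_is_undefined(self):
        with pytest.raises(UndefinedEffectError):
            av.study_effect(trial(0, 20, 0, 20), cc=0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            trial(30, 20, 2, 20)
        with pytest.raises(InputError):
            av.TrialComparison("x", dt.date(2020, 1, 1), 0, 0, 1, 10)

    @given(
        a=st.integers(0, 50), c=st.integers(0, 50),
        n1=st.integers(50, 200), n2=st.integers(50, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_effect_invariants(self, a, c, n1, n2):
        t = trial(a, n1, c, n2)
        if t.double_zero:
            return
        e = av.study_effect(t)
        assert e.se_log_rr > 0
        assert math.isfinite(e.log_rr)


def _oracle_pool(studies, hk=True):
    """Independent spreadsheet-style computation: per-study log-RR and
    variance, IV Q, DL tau2, random-effects mean, HK rescaling, plus the
    Mantel-Haenszel fixed-effect RR — all in plain Python."""
    y, v = [], []
    for a, n1, c, n2 in studies:
        y.append(math.log((a / n1) / (c / n2)))
        v.append(1 / a - 1 / n1 + 1 / c - 1 / n2)
    k = len(y)
    w = [1 / vi for vi in v]
    mu_iv = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mu_iv) ** 2 for wi, yi in zip(w, y))
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    ws = [1 / (vi + tau2) for vi in v]
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws)
    var = 1 / sum(ws)
    if hk:
        qhk = sum(wi * (yi - mu) ** 2 for wi, yi in zip(ws, y)) / (k - 1)
        se = math.sqrt(max(1.0, qhk) * var)
        crit = stats.t.ppf(0.975, k - 1)
        p = 2 * stats.t.sf(abs(mu) / se, k - 1)
    else:
        se = math.sqrt(var)
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(mu) / se)
    num = sum(a * n2 / (n1 + n2) for a, n1, c, n2 in studies)
    den = sum(c * n1 / (n1 + n2) for a, n1, c, n2 in studies)
    return {
        "mu": mu, "se": se, "lo": math.exp(mu - crit * se),
        "hi": math.exp(mu + crit * se), "p": p, "tau2": tau2,
        "i2": max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0,
        "q": q, "rr_mh": num / den,
    }


class TestPooling:
    def test_single_study_passthrough(self):
        t = trial(10, 100, 20, 100)
        m = av.pool_random_effects([t])
        e = av.study_effect(t)
        assert m.k == 1
        assert m.log_rr_pooled == pytest.approx(e.log_rr, abs=1e-12)
        assert m.se_pooled == pytest.approx(e.se_log_rr, abs=1e-12)
        assert m.tau2 == 0.0 and m.i2 == 0.0
        assert not m.hk_applied

    def test_identical_copies_have_zero_heterogeneity(self):
        t1 = trial(10, 100, 20, 100, day=1)
        t2 = trial(10, 100, 20, 100, day=2)
        m = av.pool_random_effects([t1, t2])
        assert m.log_rr_pooled == pytest.approx(av.study_effect(t1).log_rr, abs=1e-12)
        assert m.q == pytest.approx(0.0, abs=1e-12)
        assert m.tau2 == 0.0 and m.i2 == 0.0

    @pytest.mark.parametrize("hk", [True, False])
    def test_three_study_hand_oracle(self, three_trials, hk):
        """MH/DL/HK pooling agrees with an independent spreadsheet-style
        hand computation to 1e-10."""
        studies = [(t.events_treat, t.n_treat, t.events_ctrl, t.n_ctrl)
                   for t in three_trials]
        exp = _oracle_pool(studies, hk=hk)
        m = av.pool_random_effects(three_trials, MetaConfig(hartung_knapp=hk))
        assert m.log_rr_pooled == pytest.approx(exp["mu"], abs=1e-10)
        assert m.se_pooled == pytest.approx(exp["se"], abs=1e-10)
        assert m.ci_low == pytest.approx(exp["lo"], abs=1e-10)
        assert m.ci_high == pytest.approx(exp["hi"], abs=1e-10)
        assert m.p_value == pytest.approx(exp["p"], abs=1e-10)
        assert m.tau2 == pytest.approx(exp["tau2"], abs=1e-10)
        assert m.i2 == pytest.approx(exp["i2"], abs=1e-8)
        assert m.q == pytest.approx(exp["q"], abs=1e-10)
        assert m.rr_mh == pytest.approx(exp["rr_mh"], rel=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            av.pool_random_effects([])

    def test_double_zero_tables_are_excluded(self):
        ok = trial(10, 100, 20, 100, day=1)
        dz = trial(0, 50, 0, 50, day=2)
        m = av.pool_random_effects([ok, dz])
        assert m.k == 1
        with pytest.raises(EmptyEvidenceError):
            av.pool_random_effects([dz])

    def test_hk_interval_never_narrower_than_normal(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            k = int(rng.integers(2, 8))
            trials = []
            for i in range(k):
                n = int(rng.integers(50, 400))
                p0 = rng.uniform(0.1, 0.4)
                trials.append(trial(
                    int(rng.binomial(n, p0 * rng.uniform(0.5, 1.2))) or 1, n,
                    int(rng.binomial(n, p0)) or 1, n, day=i + 1,
                ))
            mh = av.pool_random_effects(trials, MetaConfig(hartung_knapp=True))
            mn = av.pool_random_effects(trials, MetaConfig(hartung_knapp=False))
            w_h = math.log(mh.ci_high) - math.log(mh.ci_low)
            w_n = math.log(mn.ci_high) - math.log(mn.ci_low)
            assert w_h >= w_n - 1e-12

    def test_result_invariants(self, pooled_meta):
        m = pooled_meta
        assert m.ci_low <= m.rr <= m.ci_high
        assert 0 <= m.i2 <= 100
        assert m.tau2 >= 0
        assert 0 <= m.p_value <= 1
        assert m.k == 22


class TestCumulativeSeries:
    def test_single_trial_series(self):
        t = trial(10, 100, 20, 100)
        series = av.cumulative_series([t])
        assert len(series) == 1
        assert series[0].log_rr_pooled == pytest.approx(
            av.study_effect(t).log_rr, abs=1e-12
        )

    def test_each_element_matches_direct_pooling(self, packaged_trials):
        series = av.cumulative_series(packaged_trials)
        groups = publication_groups(packaged_trials)
        acc = []
        for j, g in enumerate(groups):
            acc.extend(g)
            direct = av.pool_random_effects(acc)
            assert series[j].log_rr_pooled == pytest.approx(
                direct.log_rr_pooled, abs=1e-12
            )
            assert series[j].se_pooled == pytest.approx(direct.se_pooled, abs=1e-12)
        assert len(series) == len(groups)

    def test_same_date_comparisons_enter_together(self):
        trials = [
            trial(5, 50, 6, 50, day=1, id="A"),
            trial(7, 60, 8, 60, day=2, id="B1"),
            trial(6, 55, 9, 55, day=2, id="B2"),
        ]
        groups = publication_groups(trials)
        assert [len(g) for g in groups] == [1, 2]
        series = av.cumulative_series(trials)
        assert [m.k for m in series] == [1, 3]

    def test_ci_width_shrinks_in_expectation(self):
        """Average CI log-width is non-increasing along the stream
        (normal intervals; the Knapp-Hartung t(1) interval at k=2 is by
        design much wider than k=1, so the HK check starts at k=2)."""
        reps, k = 120, 8
        for hk, start in ((False, 0), (True, 1)):
            widths = np.zeros((reps, k))
            for r in range(reps):
                spec = SimSpec(true_rr=0.8, k_trials=k,
                               size_range=(200, 2000), master_seed=3000 + r)
                series = av.cumulative_series(
                    gen_trials(spec), MetaConfig(hartung_knapp=hk))
                widths[r] = [math.log(m.ci_high / m.ci_low) for m in series]
            mean_w = widths.mean(axis=0)[start:]
            assert np.all(np.diff(mean_w) <= 1e-9)


def _meta(rr, p):
    return MetaResult(
        k=5, log_rr_pooled=math.log(rr), se_pooled=0.1,
        ci_low=rr * 0.8, ci_high=rr * 1.2, p_value=p,
        tau2=0.0, i2=0.0, q=0.0,
    )


class TestDecisionRule:
    @pytest.mark.parametrize(
        "rr,p,expect",
        [
            (0.81, 0.08, av.Strategy.AWR),
            (0.90, 0.05, av.Strategy.APPROVE),
            (0.90, 0.01, av.Strategy.APPROVE),
            (1.2, 0.5, av.Strategy.OIR),
            (1.3, 0.01, av.Strategy.REJECT),
            (1.0, 0.9, av.Strategy.OIR),
        ],
    )
    def test_quadrants(self, rr, p, expect):
        assert av.cma_decision(_meta(rr, p)) is expect


class TestFilters:
    def test_all_is_identity(self, packaged_trials):
        assert av.filter_evidence(packaged_trials, "all") == list(packaged_trials)

    def test_fda_subset_returns_the_four_flagged_trials(self, packaged_trials):
        sel = av.filter_evidence(packaged_trials, "fda_subset")
        assert sorted(t.id for t in sel) == [
            "COVACTA", "EMPACTA", "RECOVERY", "REMDACTA",
        ]

    def test_il6_subset_matches_flags(self, packaged_trials):
        sel = av.filter_evidence(packaged_trials, "il6_subset")
        assert sel and all(t.drug_class == "il6" for t in sel)

    def test_single_study_k_returns_one(self, packaged_trials):
        sel = av.filter_evidence(packaged_trials, "single_study_k", k=3)
        assert len(sel) == 1

    def test_empty_subset_is_loud(self):
        t = trial(5, 50, 6, 50, drug_class="other")
        with pytest.raises(EmptyEvidenceError):
            av.filter_evidence([t], "il6_subset")
        with pytest.raises(InputError):
            av.filter_evidence([t], "nonsense")
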