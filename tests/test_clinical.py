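"""Kaplan-Meier estimator, log-rank test, median-split survival, and the
threshold differential-expression filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from clockscape import AnalysisConfig, OmicsMatrix, SurvivalTable
from clockscape.clinical import (
    differential_expression,
    km_estimate,
    logrank_test,
    restricted_mean_survival,
    significant_de,
    survival_by_median_split,
)
from clockscape.simulate import PlantedTruth, generate_cohort


def table(times, events):
    return SurvivalTable(
        pd.DataFrame(
            {"sample": [f"s{i}" for i in range(len(times))], "time": times, "event": events}
        )
    )


def km_oracle(times, events):
    """Risk-set enumeration oracle: S at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = sum(ti >= t for ti in times)
        d = sum((ti == t) and e for ti, e in zip(times, events))
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


def logrank_oracle(ta, ea, tb, eb):
    """Per-event-time O-E / hypergeometric-variance enumeration."""
    all_t = sorted(set([t for t, e in zip(ta, ea) if e] + [t for t, e in zip(tb, eb) if e]))
    oe, var = 0.0, 0.0
    for t in all_t:
        n1 = sum(ti >= t for ti in ta)
        n2 = sum(ti >= t for ti in tb)
        d1 = sum((ti == t) and e for ti, e in zip(ta, ea))
        d2 = sum((ti == t) and e for ti, e in zip(tb, eb))
        n, d = n1 + n2, d1 + d2
        if n1 == 0 or n2 == 0 or n < 2:
            continue
        oe += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return 0.0 if var <= 0 else oe**2 / var


class TestKmEstimate:
    def test_three_events_hand_computation(self):
        curve = km_estimate(table([5, 8, 12], [1, 1, 1]))
        assert list(curve.times) == [5, 8, 12]
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(table([3, 6, 9], [0, 0, 0]))
        assert curve.times.size == 0  # no event times; S stays at 1

    def test_six_subject_mixed_hand_computation(self):
        # events at 3, 6, 9; censored at 4, 7, 10
        curve = km_estimate(table([3, 4, 6, 7, 9, 10], [1, 0, 1, 0, 1, 0]))
        assert list(curve.times) == [3, 6, 9]
        assert np.allclose(curve.survival, [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2])

    def test_matches_lifelines_on_random_data(self, rng):
        times = rng.exponential(10, size=80).round(1)
        events = rng.integers(0, 2, size=80)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(table(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(table([-1, 2], [1, 1]))

    def test_exhaustive_small_configs_match_oracle(self):
        for n in range(1, 6):
            times = list(range(1, n + 1))
            for events in itertools.product([0, 1], repeat=n):
                if sum(events) == 0:
                    continue
                curve = km_estimate(table(times, list(events)))
                ot, os_ = km_oracle(times, list(events))
                assert list(curve.times) == ot
                assert np.allclose(curve.survival, os_)


class TestLogrank:
    def test_identical_groups_null(self):
        a = table([2, 4, 6, 8], [1, 0, 1, 1])
        chi2, p = logrank_test(a, a)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        a = table(rng.exponential(5, 30), rng.integers(0, 2, 30))
        b = table(rng.exponential(8, 30), rng.integers(0, 2, 30))
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_time_rescaling_invariance(self, rng):
        ta, ea = rng.exponential(5, 25), rng.integers(0, 2, 25)
        tb, eb = rng.exponential(9, 25), rng.integers(0, 2, 25)
        chi1, _ = logrank_test(table(ta, ea), table(tb, eb))
        chi2, _ = logrank_test(table(7.3 * ta, ea), table(7.3 * tb, eb))
        assert chi1 == pytest.approx(chi2)

    def test_matches_lifelines(self, rng):
        ta, ea = rng.exponential(5, 50).round(1), rng.integers(0, 2, 50)
        tb, eb = rng.exponential(9, 50).round(1), rng.integers(0, 2, 50)
        chi2, p = logrank_test(table(ta, ea), table(tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test(table([1, 2], [0, 0]), table([3], [0]))

    def test_exhaustive_small_configs_match_oracle(self):
        times = [1, 2, 3, 4, 5]
        for events in itertools.product([0, 1], repeat=5):
            if sum(events) == 0:
                continue
            for mask in itertools.product([0, 1], repeat=5):
                if sum(mask) in (0, 5):
                    continue
                ta = [t for t, m in zip(times, mask) if m]
                ea = [e for e, m in zip(events, mask) if m]
                tb = [t for t, m in zip(times, mask) if not m]
                eb = [e for e, m in zip(events, mask) if not m]
                chi2, _ = logrank_test(table(ta, ea), table(tb, eb))
                assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-12)


class TestMedianSplitSurvival:
    def test_planted_hazardous_gene_detected(self):
        # HR > 1 for high expression => high arm does worse
        truth = PlantedTruth(prognostic_genes=[("RORA", 2.0)])
        cfg = AnalysisConfig(seed=17)
        b = generate_cohort(cfg, truth=truth)
        res = survival_by_median_split(
            b.expression.subset_samples(b.tumor_ids), b.survival, cfg
        )
        rora = [r for r in res if r.gene == "RORA"][0]
        assert rora.p_value < 0.05
        assert rora.direction == "low_better"
        assert rora.n_high + rora.n_low == 200

    def test_protective_gene_direction(self):
        truth = PlantedTruth(prognostic_genes=[("CRY2", 0.4)])
        cfg = AnalysisConfig(seed=19)
        b = generate_cohort(cfg, truth=truth)
        res = survival_by_median_split(
            b.expression.subset_samples(b.tumor_ids), b.survival, cfg
        )
        cry2 = [r for r in res if r.gene == "CRY2"][0]
        assert cry2.p_value < 0.05
        assert cry2.direction == "high_better"

    def test_requires_overlap(self, rng):
        expr = OmicsMatrix(
            pd.DataFrame([rng.normal(size=5)], index=["CLOCK"], columns=[f"s{i}" for i in range(5)]),
            kind="expression",
        )
        surv = table(rng.exponential(5, 5), [1] * 5)
        with pytest.raises(ValueError, match="20 overlapping"):
            survival_by_median_split(expr, surv, AnalysisConfig())


def test_restricted_mean_of_flat_curve_is_horizon():
    curve = km_estimate(table([3, 6], [0, 0]))
    assert restricted_mean_survival(curve, 10.0) == pytest.approx(10.0)


class TestDifferentialExpression:
    @staticmethod
    def _matrix(rows, n_a=6, n_b=6):
        cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        df = pd.DataFrame(rows, columns=cols)
        df.index = [f"g{i}" for i in range(len(df))]
        return OmicsMatrix(df, kind="expression"), cols[:n_a], cols[n_a:]

    def test_identical_groups_not_significant(self):
        row = [[5.0, 6, 7, 8, 9, 10, 5, 6, 7, 8, 9, 10]]
        m, a, b = self._matrix(row)
        rec = differential_expression(m, a, b, AnalysisConfig())[0]
        assert rec.effect == pytest.approx(0.0)
        assert significant_de([rec], AnalysisConfig()) == []

    def test_doubling_group_a_adds_one_to_effect(self, rng):
        vals = np.abs(rng.normal(10, 2, size=(4, 12)))
        m, a, b = self._matrix(vals.tolist())
        doubled = vals.copy()
        doubled[:, :6] *= 2
        m2, _, _ = self._matrix(doubled.tolist())
        r1 = differential_expression(m, a, b, AnalysisConfig())
        r2 = differential_expression(m2, a, b, AnalysisConfig())
        for x, y in zip(r1, r2):
            # exact up to the epsilon pseudocount
            assert y.effect - x.effect == pytest.approx(1.0, abs=1e-3)

    def test_toy_fixture_exactly_three_pass_joint_filter(self):
        # 3 genes with a clean 4-fold shift and tiny variance; 7 null genes
        rows = []
        for i in range(3):
            base = 10.0 + i
            rows.append([4 * base + 0.01 * j for j in range(6)] + [base + 0.01 * j for j in range(6)])
        for i in range(7):
            base = 20.0 + i
            rows.append([base + 0.1 * j for j in range(6)] + [base + 0.1 * j for j in range(6)])
        m, a, b = self._matrix(rows)
        cfg = AnalysisConfig()
        recs = differential_expression(m, a, b, cfg)
        sig = significant_de(recs, cfg)
        assert sorted(r.gene for r in sig) == ["g0", "g1", "g2"]

    def test_group_size_precondition(self):
        m, a, b = self._matrix([[1.0] * 12])
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(m, a[:2], b, AnalysisConfig())
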