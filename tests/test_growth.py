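"""Volumes, threshold crossings, ANOVA/Tukey, Brown-Forsythe, KM, log-rank.

Frozen reference statistics for the fixed three-group table were computed
independently in R (stats::anova, stats::TukeyHSD, car::leveneTest, and the
Brown-Forsythe F* formula with Satterthwaite degrees of freedom).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasnorm import growth as gr
from vasnorm import simulate as sim

# fixed table shared by the ANOVA / Tukey / Brown-Forsythe oracle tests
TABLE = {
    "a": [10.2, 11.5, 9.8, 12.1, 10.9],
    "b": [14.1, 13.2, 15.0, 14.8],
    "c": [9.9, 10.4, 11.1, 10.0, 9.5, 10.8],
}


class TestCalliperVolume:
    def test_worked_example(self):
        assert gr.calliper_volume(6, 5, 4) == pytest.approx(20 * np.pi)

    def test_equal_dimensions_give_sphere_volume(self):
        d = 7.3
        assert gr.calliper_volume(d, d, d) == pytest.approx(np.pi * d**3 / 6)

    def test_any_zero_dimension_gives_zero(self):
        assert gr.calliper_volume(0, 5, 4) == 0.0
        assert gr.calliper_volume(6, 0, 4) == 0.0

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            gr.calliper_volume(-1, 2, 3)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0.1, 50),
           st.floats(0.5, 3))
    def test_scales_cubically(self, length, width, height, c):
        scaled = gr.calliper_volume(c * length, c * width, c * height)
        assert scaled == pytest.approx(c**3 * gr.calliper_volume(length, width, height))


class TestTimeToThreshold:
    def test_stated_interpolation_example(self):
        t, event = gr.time_to_threshold([0, 3, 6], [100, 200, 450], 400)
        assert event
        assert t == pytest.approx(3 + 3 * (400 - 200) / (450 - 200))  # 5.4 days

    def test_first_measurement_already_at_threshold(self):
        t, event = gr.time_to_threshold([2, 4], [450, 500], 400)
        assert (t, event) == (2.0, True)

    def test_never_reached_censored_at_last_day(self):
        t, event = gr.time_to_threshold([0, 3, 6], [100, 200, 300], 400)
        assert (t, event) == (6.0, False)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gr.time_to_threshold([], [], 400)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(110, 390), st.floats(110, 390))
    def test_monotone_in_threshold(self, thr_a, thr_b):
        days = [0.0, 2.0, 4.0, 6.0, 8.0]
        volumes = [100.0, 150.0, 240.0, 330.0, 400.0]
        lo, hi = sorted([thr_a, thr_b])
        t_lo, _ = gr.time_to_threshold(days, volumes, lo)
        t_hi, _ = gr.time_to_threshold(days, volumes, hi)
        assert t_lo <= t_hi + 1e-12

    def test_invariant_to_redundant_collinear_measurements(self):
        t1, _ = gr.time_to_threshold([0, 4], [100, 500], 300)
        t2, _ = gr.time_to_threshold([0, 2, 4], [100, 300, 500], 300)
        assert t1 == pytest.approx(t2)


class TestRegrowthInterval:
    def test_exponential_closed_form(self):
        k = 0.25
        days = np.linspace(0, 40, 4001)
        volumes = 150 * np.exp(k * days)
        interval, event = gr.regrowth_interval(days, volumes, 150, 400)
        assert event
        assert interval == pytest.approx(np.log(400 / 150) / k, abs=1e-3)

    def test_equal_thresholds_give_zero(self):
        interval, event = gr.regrowth_interval([0, 5], [100, 500], 300, 300)
        assert (interval, event) == (0.0, True)

    def test_identical_trajectories_identical_intervals(self):
        days, volumes = [0, 3, 6, 9], [120, 180, 300, 480]
        a = gr.regrowth_interval(days, volumes)
        b = gr.regrowth_interval(list(days), list(volumes))
        assert a == b

    def test_from_volume_never_reached_is_an_error(self):
        with pytest.raises(ValueError, match="never reaches"):
            gr.regrowth_interval([0, 3], [100, 140], 150, 400)

    def test_to_volume_never_reached_censored(self):
        interval, event = gr.regrowth_interval([0, 3, 6], [100, 200, 300], 150, 400)
        assert not event


class TestAnovaTukey:
    def test_all_observations_equal(self):
        res = gr.anova_tukey({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0]})
        assert (res.f, res.p) == (0.0, 1.0)

    def test_two_groups_f_equals_t_squared(self):
        from scipy import stats
        a = np.array([10.0, 12.0, 11.5, 9.8])
        b = np.array([14.0, 13.2, 15.1])
        res = gr.anova_tukey({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, rel=1e-10)

    def test_three_group_table_matches_r(self):
        res = gr.anova_tukey(TABLE)
        assert res.f == pytest.approx(34.1746420799, rel=1e-9)
        assert res.p == pytest.approx(1.10967398501e-05, rel=1e-6)
        padj = res.tukey.set_index(["group_a", "group_b"]).p_adj
        assert padj[("a", "b")] == pytest.approx(8.540953e-05, rel=1e-4)
        assert padj[("a", "c")] == pytest.approx(0.4176973, rel=1e-4)
        assert padj[("b", "c")] == pytest.approx(1.124155e-05, rel=1e-4)

    def test_undersized_group_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            gr.anova_tukey({"a": [1.0, 2.0], "tiny": [3.0]})


class TestBrownForsythe:
    def test_identical_spread_about_medians_gives_zero(self):
        res = gr.brown_forsythe({"a": [0.0, 1.0, 2.0], "b": [10.0, 11.0, 12.0]},
                                kind="variances")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_doubling_deviations_increases_statistic(self):
        base = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.5, 2.0, 2.5, 3.0]}
        wide = {"a": [0.0, 2.0, 4.0, 6.0], "b": base["b"]}
        r1 = gr.brown_forsythe(base, kind="variances")
        r2 = gr.brown_forsythe(wide, kind="variances")
        assert r2.statistic > r1.statistic

    def test_variance_kind_matches_r_levene(self):
        res = gr.brown_forsythe(TABLE, kind="variances")
        assert res.statistic == pytest.approx(0.4973900734, rel=1e-9)
        assert res.p == pytest.approx(0.6201173161, rel=1e-8)

    def test_means_kind_matches_r_fstar(self):
        res = gr.brown_forsythe(TABLE, kind="means")
        assert res.statistic == pytest.approx(32.2811777841, rel=1e-9)
        assert res.df[1] == pytest.approx(9.5286487922, rel=1e-9)
        assert res.p == pytest.approx(5.70497e-05, rel=1e-4)

    def test_deviation_anova_identity(self):
        """kind='variances' equals a plain one-way ANOVA on |x - median|."""
        from scipy import stats
        devs = [np.abs(np.array(v) - np.median(v)) for v in TABLE.values()]
        f_hand, p_hand = stats.f_oneway(*devs)
        res = gr.brown_forsythe(TABLE, kind="variances")
        assert res.statistic == pytest.approx(f_hand, rel=1e-10)
        assert res.p == pytest.approx(p_hand, rel=1e-10)


def km_product_limit_oracle(times, events):
    """Hand product-limit bookkeeping: S(t) after each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        curve = gr.km_estimate([2, 4, 6], [True, True, True])
        assert curve.survival_at(2) == pytest.approx(2 / 3)
        assert curve.survival_at(4) == pytest.approx(1 / 3)
        assert curve.survival_at(6) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = gr.km_estimate([3, 5, 8], [False, False, False])
        for t in (0, 4, 10):
            assert curve.survival_at(t) == 1.0

    def test_censoring_reduces_risk_set_without_step(self):
        curve = gr.km_estimate([2, 3, 4], [True, False, True])
        assert curve.survival_at(2) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(2 / 3)  # no step at censor
        assert curve.survival_at(4) == pytest.approx(0.0)    # 2/3 * (1 - 1/1)

    def test_exhaustive_small_configurations_match_oracle(self):
        """All censoring patterns over 1..4 animals with distinct times."""
        for n in range(1, 5):
            times = list(range(1, n + 1))
            for pattern in itertools.product([True, False], repeat=n):
                curve = gr.km_estimate(times, list(pattern))
                oracle = km_product_limit_oracle(times, pattern)
                for t, s in oracle.items():
                    assert curve.survival_at(t) == pytest.approx(s), (
                        n, pattern, t
                    )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gr.km_estimate([], [])


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Brute-force Mantel-Cox: hypergeometric O-E accumulation per event time."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(all_t[all_e])):
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        n = n1 + n2
        d = np.sum((all_t == t) & all_e)
        d1 = np.sum((ta == t) & ea)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [2, 4, 6, 9]
        e = [True, True, False, True]
        res = gr.logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_hypergeometric_oracle(self):
        ta, ea = [3, 5, 7, 12], [True, True, False, True]
        tb, eb = [2, 4, 6, 8], [True, True, True, True]
        res = gr.logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                              rel=1e-9)

    def test_no_events_flagged_undefined(self):
        res = gr.logrank_test([3, 4], [False, False], [5, 6], [False, False])
        assert np.isnan(res.statistic)
        assert "no events" in res.note

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gr.logrank_test([], [], [1], [True])


class TestPValueCalibration:
    def test_logrank_p_uniform_under_null(self):
        rng = np.random.default_rng(12)
        from scipy import stats
        pvals = []
        for _ in range(400):
            t1 = rng.exponential(10, 8)
            t2 = rng.exponential(10, 8)
            pvals.append(gr.logrank_test(t1, np.ones(8, bool),
                                         t2, np.ones(8, bool)).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_anova_p_uniform_under_null(self):
        rng = np.random.default_rng(13)
        from scipy import stats
        pvals = [
            gr.anova_tukey({
                "a": rng.normal(0, 1, 7), "b": rng.normal(0, 1, 7),
                "c": rng.normal(0, 1, 7),
            }).p
            for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGrowthDelayReport:
    def _study(self, arrest, cv, seed=0, n=6, interval=2.0):
        params = sim.GrowthSimParams(
            groups=[
                sim.GrowthGroupSpec("control", n, 0.15),
                sim.GrowthGroupSpec("treated", n, 0.15, arrest_days=arrest),
            ],
            start_volume_range=(110.0, 110.0),
            calliper_cv=cv, measurement_interval=interval, seed=seed,
        )
        return sim.generate_growth_study(params)

    def test_noiseless_arrest_recovered_exactly(self):
        report = gr.growth_delay_report(self._study(arrest=10.0, cv=0.0))
        assert report.delay_vs_control("treated") == pytest.approx(10.0, abs=1e-9)

    def test_noisy_arrest_recovered_within_one_day(self):
        estimates = [
            gr.growth_delay_report(
                self._study(arrest=10.0, cv=0.05, seed=s, n=10)
            ).delay_vs_control("treated")
            for s in (1, 2, 3)
        ]
        assert all(abs(e - 10.0) <= 1.0 for e in estimates)

    def test_missing_control_label_rejected(self):
        study = self._study(arrest=0.0, cv=0.0)
        with pytest.raises(ValueError, match="control group"):
            gr.growth_delay_report(study, control="sham")

    def test_censored_animals_flagged_and_kept_in_km(self):
        records = []
        for i, (end, event_vol) in enumerate([(400, 450), (400, 450), (400, 300)]):
            d = (6 * 110 / np.pi) ** (1 / 3)
            d_end = (6 * event_vol / np.pi) ** (1 / 3)
            records += [
                {"animal_id": f"c-{i}", "group": "control", "day": 0,
                 "length_mm": d, "width_mm": d, "height_mm": d},
                {"animal_id": f"c-{i}", "group": "control", "day": 10,
                 "length_mm": d_end, "width_mm": d_end, "height_mm": d_end},
            ]
        for i in range(3):
            d = (6 * 110 / np.pi) ** (1 / 3)
            d_end = (6 * 500 / np.pi) ** (1 / 3)
            records += [
                {"animal_id": f"t-{i}", "group": "treated", "day": 0,
                 "length_mm": d, "width_mm": d, "height_mm": d},
                {"animal_id": f"t-{i}", "group": "treated", "day": 20,
                 "length_mm": d_end, "width_mm": d_end, "height_mm": d_end},
            ]
        study = gr.GrowthStudy(records=pd.DataFrame(records))
        with pytest.warns(UserWarning, match="censored"):
            report = gr.growth_delay_report(study)
        assert report.censored_excluded == ["c-2"]
        km_control = report.km_curves["control"]
        assert km_control.table.n_censored.sum() == 1
        assert "c-2" in report.summary()

    def test_summary_is_printable_and_complete(self):
        report = gr.growth_delay_report(self._study(arrest=8.0, cv=0.05, n=5))
        text = report.summary()
        for token in ("ANOVA", "Tukey", "Log-rank", "control"):
            assert token in text

    def test_km_plot_renders_one_step_curve_per_group(self):
        import matplotlib
        matplotlib.use("Agg")
        report = gr.growth_delay_report(self._study(arrest=8.0, cv=0.05, n=5))
        ax = report.plot_km()
        labels = {line.get_label() for line in ax.lines}
        assert {"control", "treated"} <= labels
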