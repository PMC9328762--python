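import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from urgentsaccade import race, trials as tr
from urgentsaccade.tachometric import compute


class TestParams:
    def test_default_loads(self, default_params):
        assert default_params.threshold > 0
        assert default_params.exo_latency_ms == pytest.approx(80.0)
        assert default_params.eri_duration_ms == pytest.approx(25.0)

    @pytest.mark.parametrize(
        "field,value",
        [("threshold", -1.0), ("build_corr", 1.5), ("bias", 0.7),
         ("halt_ms", 30.0), ("eri_duration_ms", -1.0)],
    )
    def test_invalid_rejected(self, default_params, field, value):
        with pytest.raises(ValueError):
            default_params.replace(**{field: value})

    def test_from_file_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.toml"
        lines = ["[race]"] + [
            f"{k} = {getattr(default_params, k)}"
            for k in default_params.__dataclass_fields__
        ]
        path.write_text("\n".join(lines) + "\n")
        assert race.RaceParams.from_file(path) == default_params

    def test_low_luminance_preset(self, default_params):
        low = default_params.low_luminance()
        assert low.exo_latency_ms > default_params.exo_latency_ms
        assert low.exo_accel < default_params.exo_accel


class TestBuildupRates:
    @pytest.mark.parametrize("bias,expected", [(0.1, 0.6), (0.0, 0.5)])
    def test_assignment_probability(self, default_params, bias, expected):
        """Bias b puts the larger rate on the cue side with p = 0.5 + b."""
        rng = np.random.default_rng(7)
        p = default_params.replace(bias=bias)
        rc, ra = race.draw_buildup_rates(p, rng, n=10_000)
        k = int((rc > ra).sum())
        n_informative = int((rc != ra).sum())
        assert binomtest(k, n_informative, expected).pvalue > 1e-3

    def test_full_bias_always_cue(self, default_params):
        rng = np.random.default_rng(8)
        p = default_params.replace(bias=0.5)
        rc, ra = race.draw_buildup_rates(p, rng, n=10_000)
        assert np.all(rc >= ra)

    def test_rates_nonnegative(self, default_params):
        rng = np.random.default_rng(9)
        p = default_params.replace(build_mean=0.5, build_sd=3.0)
        rc, ra = race.draw_buildup_rates(p, rng, n=5000)
        assert rc.min() >= 0 and ra.min() >= 0


class TestSingleTrial:
    def test_cas_cps_identical_through_eri(self, default_params):
        """With the same seed the two models share every sample up to the end
        of the ERI; they may diverge only once endogenous steering begins."""
        gap = 150.0
        rec_a, tr_a = race.simulate_trial(
            default_params, "anti", "L", gap, np.random.default_rng(42))
        rec_p, tr_p = race.simulate_trial(
            default_params, "pro", "L", gap, np.random.default_rng(42))
        eri_end = gap + default_params.exo_latency_ms + default_params.eri_duration_ms
        n = min(tr_a.t.size, tr_p.t.size)
        within = tr_a.t[:n] <= eri_end
        np.testing.assert_array_equal(tr_a.r_left[:n][within],
                                      tr_p.r_left[:n][within])
        np.testing.assert_array_equal(tr_a.r_right[:n][within],
                                      tr_p.r_right[:n][within])

    def test_activity_nonnegative(self, default_params):
        for seed in range(20):
            _, trace = race.simulate_trial(
                default_params, "anti", "L", 100.0,
                np.random.default_rng(seed))
            assert trace.r_left.min() >= 0
            assert trace.r_right.min() >= 0

    def test_trace_reports_winner_and_rt(self, default_params):
        rec, trace = race.simulate_trial(
            default_params, "anti", "L", 100.0, np.random.default_rng(1))
        assert trace.winner in ("L", "R")
        assert rec["choice_side"] == trace.winner
        assert rec["rt_ms"] == trace.crossing_time_ms + default_params.efferent_delay_ms
        assert rec["rpt_ms"] == rec["rt_ms"] - rec["gap_ms"]


class TestSession:
    def test_deterministic_under_seed(self, default_params):
        a = race.simulate_session(default_params, "anti", n_trials=300, seed=5)
        b = race.simulate_session(default_params, "anti", n_trials=300, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_gap_rpt_equals_rt(self, default_params):
        t = race.simulate_session(default_params, "pro", gap_set=(0,),
                                  n_trials=200, seed=3)
        ok = t["aborted"] == 0
        np.testing.assert_allclose(t.loc[ok, "rpt_ms"], t.loc[ok, "rt_ms"])

    def test_cue_sides_balanced(self, default_params):
        t = race.simulate_session(default_params, "anti", n_trials=10_000, seed=4)
        k = int((t["cue_side"] == "L").sum())
        assert binomtest(k, len(t), 0.5).pvalue > 1e-3

    def test_empty_gap_set_rejected(self, default_params):
        with pytest.raises(ValueError):
            race.simulate_session(default_params, "anti", gap_set=(), n_trials=10)

    def test_symmetric_race_is_fair(self, default_params):
        """With all modulations off and no bias, choices are 50/50."""
        p = default_params.replace(exo_accel=0.0, endo_accel=0.0, endo_decel=0.0)
        t = race.simulate_session(p, "anti", n_trials=10_000, seed=6)
        ok = t[t["aborted"] == 0]
        k = int((ok["choice_side"] == "L").sum())
        assert binomtest(k, len(ok), 0.5).pvalue > 1e-3

    def test_large_gap_trials_are_guesses(self, default_params):
        """Crossings before the ERI are unmodulated: accuracy at chance."""
        t = race.simulate_session(default_params, "anti", gap_set=(350,),
                                  n_trials=8000, seed=7)
        ok = tr.filter_urgent(t)
        guesses = ok[ok["rpt_ms"] < default_params.exo_latency_ms]
        assert len(guesses) > 500
        k = int(guesses["correct"].sum())
        assert binomtest(k, len(guesses), 0.5).pvalue > 1e-3

    def test_mirror_symmetry_of_side_labels(self, default_params):
        """The bias acts relative to the cue, not to a fixed side, so
        left-cue and right-cue trials perform identically in distribution."""
        p = default_params.replace(bias=0.2)
        t = tr.filter_urgent(race.simulate_session(p, "anti", n_trials=8000, seed=8))
        left = t[t["cue_side"] == "L"]["correct"]
        right = t[t["cue_side"] == "R"]["correct"]
        se = np.sqrt(0.25 / len(left) + 0.25 / len(right))
        assert abs(left.mean() - right.mean()) < 4 * se


class TestPredictedTachometric:
    def test_unmodulated_race_flat_at_chance(self, default_params):
        """With the exogenous response (halts + acceleration) and endogenous
        steering disabled the race never sees the cue: guessing at all rPT."""
        p = default_params.replace(exo_accel=0.0, endo_accel=0.0,
                                   endo_decel=0.0, halt_ms=0.0,
                                   eri_duration_ms=0.0)
        c = race.predicted_tachometric(p, "anti", n_trials=20_000, seed=10)
        m = c.defined()
        inside = (c.ci_low[m] <= 0.5) & (0.5 <= c.ci_high[m])
        assert inside.mean() >= 0.90

    def test_cas_dip_and_recovery(self, cas_curve):
        g, f, d = cas_curve.rpt_grid, cas_curve.frac_correct, cas_curve.defined()
        dip = f[(g >= 90) & (g <= 140) & d]
        assert np.nanmin(dip) < 0.2
        tail = f[(g > 220) & d]
        assert tail.size > 0 and np.nanmin(tail) > 0.9

    def test_cps_above_chance_and_rising(self, cps_curve):
        g, f, d = cps_curve.rpt_grid, cps_curve.frac_correct, cps_curve.defined()
        vals = f[d]
        assert np.nanmin(vals) >= 0.45
        # nondecreasing within CI noise: smoothed curve never drops much
        smooth = np.convolve(vals, np.ones(15) / 15, mode="valid")
        assert np.min(np.diff(smooth)) > -0.02

    def test_exo_gain_monotonicity(self, default_params):
        """More exogenous drive deepens the CAS dip and lifts the CPS curve
        in the capture band."""
        cas_mins, cps_mins = [], []
        for k, gain in enumerate((0.4, 0.8, 1.2)):
            p = default_params.replace(exo_accel=gain)
            cas = race.predicted_tachometric(p, "anti", n_trials=15_000, seed=20)
            cps = race.predicted_tachometric(p, "pro", n_trials=15_000, seed=21)
            band = lambda c: c.frac_correct[
                (c.rpt_grid >= 90) & (c.rpt_grid <= 140) & c.defined()]
            cas_mins.append(np.nanmin(band(cas)))
            cps_mins.append(np.nanmean(band(cps)))
        assert cas_mins[0] >= cas_mins[1] >= cas_mins[2]
        assert cps_mins[0] <= cps_mins[1] + 0.02 <= cps_mins[2] + 0.04

    def test_low_luminance_shifts_capture_later(self, default_params, cas_curve):
        low = race.predicted_tachometric(default_params.low_luminance(),
                                         "anti", n_trials=30_000, seed=22)
        def first_below(c, thr=0.35):
            g, f, d = c.rpt_grid, c.frac_correct, c.defined()
            idx = np.where((f < thr) & d)[0]
            return g[idx[0]]
        assert first_below(low) > first_below(cas_curve) + 15
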