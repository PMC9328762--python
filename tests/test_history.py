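import numpy as np
import pandas as pd
import pytest

from urgentsaccade import history
from urgentsaccade.fitting import AntiFit, ProFit
from urgentsaccade.synth import GeneratorSpec, anti_truth, generate


def tiny_table(targets, aborted=None, participant="p", block="single_task"):
    n = len(targets)
    aborted = aborted or [0] * n
    cue = [t if i % 2 == 0 else ("L" if t == "R" else "R")
           for i, t in enumerate(targets)]  # irrelevant detail
    return pd.DataFrame(
        {
            "participant_id": [participant] * n,
            "task": ["anti"] * n,
            "block": [block] * n,
            "luminance": ["high"] * n,
            "trial_index": list(range(n)),
            "gap_ms": [100] * n,
            "cue_side": ["L"] * n,
            "target_side": targets,
            "choice_side": ["L"] * n,
            "rt_ms": [200.0] * n,
            "rpt_ms": [100.0] * n,
            "correct": [1.0] * n,
            "aborted": aborted,
        }
    )


class TestLabelHistory:
    def test_one_back_repeat_and_switch(self):
        t = tiny_table(["L", "L", "R"])
        lab = history.label_history(t, 1)["history"].tolist()
        assert lab == ["", "repeat", "switch"]

    def test_first_trial_unlabeled(self):
        t = tiny_table(["L"])
        assert history.label_history(t, 1)["history"].tolist() == [""]

    def test_depth_two_requires_uniform_history(self):
        t = tiny_table(["L", "R", "L", "L", "L"])
        lab = history.label_history(t, 2)["history"].tolist()
        # trial 2: prev targets L,R mixed -> unlabeled; trial 3: R,L -> unlabeled
        # trial 4: prev L,L uniform, current L -> repeat
        assert lab == ["", "", "", "", "repeat"]

    def test_abort_breaks_history(self):
        t = tiny_table(["L", "L", "L"], aborted=[0, 1, 0])
        lab = history.label_history(t, 1)["history"].tolist()
        assert lab == ["", "repeat", ""]

    def test_conservation_each_trial_once(self):
        table = generate(GeneratorSpec(task="anti", n_trials=2000, seed=9))
        for depth in (1, 2, 3):
            lab = history.label_history(table, depth)["history"]
            assert len(lab) == len(table)
            assert set(lab.unique()) <= {"", "repeat", "switch"}

    def test_blocks_are_independent(self):
        a = tiny_table(["L", "L"], block="single_task")
        b = tiny_table(["L", "L"], block="interleaved")
        both = pd.concat([a, b], ignore_index=True)
        lab = history.label_history(both, 1)["history"].tolist()
        assert lab == ["", "repeat", "", "repeat"]

    def test_missing_order_rejected(self):
        t = tiny_table(["L", "L"]).drop(columns=["trial_index"])
        with pytest.raises(ValueError, match="trial_index"):
            history.label_history(t, 1)


class TestRiseVsChanceSlope:
    def test_one_back_worked_example(self):
        """Chance 0.36 -> rise 154 ms and chance 0.64 -> 143 ms give a drop
        of ~39 ms per full chance unit, i.e. 3.9 ms per 0.1."""
        slope = history.rise_vs_chance_slope({0.36: 154.0, 0.64: 143.0})
        assert slope == pytest.approx(11 / 0.28, abs=1e-9)
        assert slope == pytest.approx(39.3, abs=0.1)
        assert 0.1 * slope == pytest.approx(3.9, abs=0.05)

    def test_equal_rise_points_zero_slope(self):
        assert history.rise_vs_chance_slope({0.3: 150.0, 0.7: 150.0}) == 0.0

    def test_collinear_three_points(self):
        slope = history.rise_vs_chance_slope({0.3: 160.0, 0.5: 150.0, 0.7: 140.0})
        assert slope == pytest.approx(50.0, abs=0.01)

    def test_equal_chance_rejected(self):
        with pytest.raises(ValueError):
            history.rise_vs_chance_slope({0.5: 150.0})


@pytest.fixture(scope="module")
def biased_anti():
    spec = GeneratorSpec(
        true_curve=anti_truth(), task="anti", n_trials=40_000, seed=13,
        history_bias_per_repeat=0.14, history_bias_cap=0.14)
    return generate(spec)


class TestConditionedAnalysis:
    def test_chance_offsets_recovered(self, biased_anti):
        """A +0.14 guessing bias toward the previous target yields chance
        levels near 0.64 (repeat) and 0.36 (switch)."""
        rep, sw = history.conditioned_analysis(biased_anti, "anti", depth=1)
        assert rep.chance_level == pytest.approx(0.64, abs=0.03)
        assert sw.chance_level == pytest.approx(0.36, abs=0.03)
        assert rep.pattern == "AA" and sw.pattern == "AB"

    def test_chance_offsets_complementary(self, biased_anti):
        rep, sw = history.conditioned_analysis(biased_anti, "anti", depth=1)
        assert rep.chance_level + sw.chance_level == pytest.approx(1.0, abs=0.05)

    def test_no_bias_null(self):
        t = generate(GeneratorSpec(true_curve=anti_truth(), task="anti",
                                   n_trials=30_000, seed=14))
        rep, sw = history.conditioned_analysis(t, "anti", depth=1)
        assert rep.chance_level == pytest.approx(0.5, abs=0.04)
        assert sw.chance_level == pytest.approx(0.5, abs=0.04)
        assert rep.rise_point_ms == pytest.approx(sw.rise_point_ms, abs=6.0)

    def test_cumulative_bias_grows_with_depth(self):
        spec = GeneratorSpec(
            true_curve=anti_truth(), task="anti", n_trials=60_000, seed=15,
            history_bias_per_repeat=0.07, history_bias_cap=0.3)
        t = generate(spec)
        offsets = []
        for depth in (1, 2, 3):
            rep, _ = history.conditioned_analysis(t, "anti", depth=depth)
            offsets.append(rep.chance_level - 0.5)
        assert offsets[2] > offsets[0] + 0.02


class TestParticipantTable:
    def test_rows_and_exclusions(self):
        fits = {
            "p1": {"anti": AntiFit(0.5, 1, 0.05, 95, 150, 5, 10, 0),
                   "pro": ProFit(1, 0.5, 90, 8, 0)},
            "p2": {"anti": AntiFit(0.5, 1, 0.05, 90, 160, 5, 10, 0,
                                   degenerate=True),
                   "pro": ProFit(1, 0.5, 85, 8, 0)},
            "p3": {"anti": AntiFit(0.5, 1, 0.05, 88, 170, 5, 10, 0)},
        }
        table = history.participant_timing_table(fits)
        assert list(table["participant_id"]) == ["p1"]
        assert table.attrs["underpowered"]

    def test_columns(self):
        fits = {f"p{i}": {"anti": AntiFit(0.5, 1, 0.05, 90 + i, 150 + 2 * i,
                                          5, 10, 0),
                          "pro": ProFit(1, 0.5, 85 + i, 8, 0)}
                for i in range(4)}
        table = history.participant_timing_table(fits)
        assert not table.attrs["underpowered"]
        assert table["anti_drop_ms"].tolist() == [90.0, 91.0, 92.0, 93.0]
        assert table["pro_rise_ms"].tolist() == [85.0, 86.0, 87.0, 88.0]
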