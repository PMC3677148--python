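"""Descriptive statistics on tidy trial tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opmomentum import metrics, synthetic


def arith_table(rows):
    """Minimal trial table: (subject, task, correct, chosen [, range, alts])."""
    recs = []
    for r in rows:
        sid, task, correct, chosen = r[:4]
        rf = r[4] if len(r) > 4 else "low"
        alts = r[5] if len(r) > 5 else ";".join(
            str(v) for v in sorted({chosen, correct} | {1, 2, 3, 4, 5, 6})[:6])
        recs.append({
            "subject_id": sid, "group": "adult", "task": task,
            "operand1": correct, "operand2": 0, "correct": correct,
            "range_flag": rf, "area_mode": "fixed_dot_size",
            "alternatives": alts, "chosen": chosen, "rt_ms": 1000.0,
            "response_correct": chosen == correct,
        })
    return pd.DataFrame(recs)


class TestOmBias:
    def test_perfect_responses_zero_bias(self):
        t = arith_table([("s1", "addition", 8, 8), ("s1", "subtraction", 10, 10)])
        out = metrics.om_bias(t)
        assert out["bias_addition"].iloc[0] == 0
        assert out["om_difference"].iloc[0] == 0

    def test_doubling_gives_log10_two(self):
        t = arith_table([("s1", "addition", 8, 16), ("s1", "subtraction", 10, 20)])
        out = metrics.om_bias(t)
        assert out["bias_addition"].iloc[0] == pytest.approx(math.log10(2))

    def test_om_difference_arithmetic(self):
        t = arith_table([
            ("s1", "addition", 100, round(100 * 10 ** 0.05)),
            ("s1", "subtraction", 100, round(100 * 10 ** -0.02)),
        ])
        out = metrics.om_bias(t)
        add = math.log10(112) - 2  # 0.0492
        sub = math.log10(95) - 2  # -0.0223
        assert out["om_difference"].iloc[0] == pytest.approx(add - sub)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(2, 50), st.integers(2, 50)), min_size=2, max_size=10))
    def test_antisymmetric_under_swap(self, pairs):
        rows = [("s1", task, c, ch)
                for (c, ch), task in zip(pairs, ["addition", "subtraction"] * 5)]
        swapped = [("s1", task, ch, c)
                   for (c, ch), task in zip(pairs, ["addition", "subtraction"] * 5)]
        if not {"addition", "subtraction"} <= {r[1] for r in rows}:
            return
        a = metrics.om_bias(arith_table(rows))
        b = metrics.om_bias(arith_table(swapped))
        assert a["om_difference"].iloc[0] == pytest.approx(
            -b["om_difference"].iloc[0])

    def test_subject_missing_operation_dropped(self, caplog):
        t = arith_table([
            ("s1", "addition", 8, 8), ("s1", "subtraction", 8, 8),
            ("s2", "addition", 8, 8),
        ])
        with caplog.at_level("WARNING"):
            out = metrics.om_bias(t)
        assert list(out["subject_id"]) == ["s1"]
        assert "s2" in caplog.text

    def test_rejects_nonpositive_values(self):
        t = arith_table([("s1", "addition", 8, 8)])
        t.loc[0, "chosen"] = 0
        with pytest.raises(ValueError):
            metrics.om_bias(t)


class TestCvProfile:
    def test_constant_responses_zero_cv(self):
        t = arith_table([("s1", "addition", 8, 9)] * 4)
        out = metrics.cv_profile(t)
        assert out["cv"].iloc[0] == 0

    def test_scale_invariance(self):
        rows = [("s1", "addition", 8, ch) for ch in (6, 7, 9, 12)]
        base = metrics.cv_profile(arith_table(rows))
        scaled = metrics.cv_profile(
            arith_table([("s1", "addition", 8, 3 * ch) for ch in (6, 7, 9, 12)]))
        assert scaled["cv"].iloc[0] == pytest.approx(base["cv"].iloc[0])

    def test_lognormal_choices_match_weber_prediction(self, rng):
        # CV of a lognormal with log-SD w is sqrt(exp(w^2) - 1)
        w = 0.2
        chosen = np.round(50 * np.exp(w * rng.standard_normal(40_000)))
        t = arith_table([("s1", "addition", 50, int(c)) for c in chosen])
        out = metrics.cv_profile(t)
        assert out["cv"].iloc[0] == pytest.approx(math.sqrt(math.exp(w * w) - 1),
                                                  abs=0.01)

    def test_single_trial_cell_missing(self):
        out = metrics.cv_profile(arith_table([("s1", "addition", 8, 9)]))
        assert np.isnan(out["cv"].iloc[0])


class TestRankDistribution:
    ALTS = "4;5;6;7;8;10"

    def test_all_choices_one_rank(self):
        t = arith_table([("s1", "addition", 8, 5, "low", self.ALTS)] * 10)
        out = metrics.rank_distribution(t)
        row = out[(out["rank"] == 2)].iloc[0]
        assert row["proportion"] == 1.0
        assert row["arcsine"] == pytest.approx(math.pi / 2)
        assert out[out["rank"] != 2]["proportion"].eq(0).all()

    def test_proportions_sum_to_one(self, default_cohort):
        trials, _, _ = default_cohort
        out = metrics.rank_distribution(trials)
        sums = out.groupby(["task", "range_flag"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_uniform_choices_flat(self, rng):
        alts = [4, 5, 6, 7, 8, 10]
        rows = [("s1", "addition", 8, int(rng.choice(alts)), "low", self.ALTS)
                for _ in range(60_000)]
        out = metrics.rank_distribution(arith_table(rows))
        assert np.allclose(out["proportion"], 1 / 6, atol=0.01)

    def test_undisplayed_choice_rejected(self, caplog):
        t = arith_table([
            ("s1", "addition", 8, 8, "low", self.ALTS),
            ("s1", "addition", 8, 99, "low", self.ALTS),
        ])
        with caplog.at_level("WARNING"):
            out = metrics.rank_distribution(t)
        assert "rejected 1 rows" in caplog.text
        assert out["proportion"].sum() == pytest.approx(1.0)


class TestMemoryRegression:
    @staticmethod
    def mem_table(points, n_subjects=3):
        rows = []
        for s in range(n_subjects):
            rows += [(f"s{s}", "memorization", x, y) for x, y in points]
        return arith_table(rows)

    def test_identity_data(self):
        res = metrics.memory_regression(self.mem_table([(6, 6), (19, 19), (25, 25)]))
        assert np.allclose(res.per_subject["intercept"], 0, atol=1e-12)
        assert np.allclose(res.per_subject["slope"], 1, atol=1e-12)

    def test_constant_shift(self):
        res = metrics.memory_regression(self.mem_table([(6, 8), (19, 21), (25, 27)]))
        assert np.allclose(res.per_subject["intercept"], 2, atol=1e-10)
        assert np.allclose(res.per_subject["slope"], 1, atol=1e-10)

    def test_three_point_closed_form(self):
        # OLS on (6,7), (19,21), (25,27): b = 199.333/188.667, a = ybar - b*xbar
        res = metrics.memory_regression(self.mem_table([(6, 7), (19, 21), (25, 27)]))
        assert res.per_subject["slope"].iloc[0] == pytest.approx(1.0565371, abs=1e-6)
        assert res.per_subject["intercept"].iloc[0] == pytest.approx(0.7243816,
                                                                     abs=1e-6)

    def test_slope_null_selectable(self):
        data = self.mem_table([(6, 6), (19, 19), (25, 25)])
        res0 = metrics.memory_regression(data, slope_null=1.0)
        assert res0.slope_null == 1.0

    def test_degenerate_subject_skipped(self, caplog):
        t = pd.concat([
            self.mem_table([(6, 7), (19, 21), (25, 27)], n_subjects=2),
            arith_table([("odd", "memorization", 6, 7)] * 3),
        ], ignore_index=True)
        with caplog.at_level("WARNING"):
            res = metrics.memory_regression(t)
        assert "odd" not in set(res.per_subject["subject_id"])


class TestCueingEffects:
    @staticmethod
    def cue_table(rows):
        return pd.DataFrame([
            {"subject_id": sid, "group": "child", "task": "cueing",
             "validity": v, "soa_ms": 200, "target_side": "left",
             "rt_ms": rt, "response_correct": ok}
            for sid, v, rt, ok in rows
        ])

    def test_equal_rts_give_zero_effects(self):
        rows = [("s1", v, 500.0, True)
                for v in ("valid", "invalid", "neutral") for _ in range(3)]
        out = metrics.cueing_effects(self.cue_table(rows))
        assert out["orienting"].iloc[0] == 0
        assert out["reorienting"].iloc[0] == 0

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("s1", v, float(500 + 50 * rng.standard_normal()), True)
                for v in ("valid", "invalid", "neutral") for _ in range(20)]
        base = metrics.cueing_effects(self.cue_table(rows))
        shifted = metrics.cueing_effects(self.cue_table(
            [(s, v, rt + 250.0, ok) for s, v, rt, ok in rows]))
        assert shifted["orienting"].iloc[0] == pytest.approx(
            base["orienting"].iloc[0])
        assert shifted["reorienting"].iloc[0] == pytest.approx(
            base["reorienting"].iloc[0])

    def test_incorrect_trials_excluded(self):
        rows = [("s1", v, 500.0, True)
                for v in ("valid", "invalid", "neutral") for _ in range(3)]
        rows.append(("s1", "invalid", 99999.0, False))
        out = metrics.cueing_effects(self.cue_table(rows))
        assert out["reorienting"].iloc[0] == 0

    def test_missing_condition_excluded(self, caplog):
        rows = [("s1", "valid", 500.0, True), ("s1", "neutral", 520.0, True)]
        with caplog.at_level("WARNING"):
            out = metrics.cueing_effects(self.cue_table(rows))
        assert len(out) == 0

    def test_generative_ratio_recovery(self):
        # rt_orient = 30, rt_reorient = 60 should appear as a 1:2 magnitude
        # ratio of orienting to reorienting on the z scale
        from opmomentum import design

        params = synthetic.SubjectParams(
            subject_id="s1", group="child", weber=0.2, bias_add=0.0,
            bias_sub=0.0, bias_mem=0.0, lapse=0.0, rt_base=math.log(700.0),
            rt_orient=30.0, rt_reorient=60.0, rt_noise=0.02, error_rate=0.0)
        frames = [
            synthetic.simulate_cueing(
                params, design.build_cueing_schedule(s),
                np.random.default_rng(s))
            for s in range(90)  # ~5,400 trials
        ]
        big = pd.concat(frames, ignore_index=True)
        big["subject_id"] = "s1"
        out = metrics.cueing_effects(big)
        ratio = -out["reorienting"].iloc[0] / out["orienting"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestCorrelate:
    def test_identity(self):
        r, p = metrics.correlate([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_perfect_linearity(self):
        r, _ = metrics.correlate([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        r, _ = metrics.correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        r, p = metrics.correlate([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            metrics.correlate([1, 2], [1, 2])
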