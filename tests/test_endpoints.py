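"""Endpoint arithmetic: weight gains, organ coefficients, temperature
differentials, water-maze summaries and passive-swimmer lists."""

import numpy as np
import pandas as pd
import pytest

import rfcohort.calibration as cal
from rfcohort.cohort import (animals_to_frame, default_calibration,
                             generate_cohort, trials_to_frame, zero_dispersion)
from rfcohort.endpoints import (mwm_daily_summary, organ_weight_coefficient,
                                passive_swimmers, summarize_organs,
                                summarize_temperatures, summarize_weights,
                                temperature_differential, weekly_weight_gain)


def _frames(zero_disp_cohorts, age, arm):
    animals, trials = zero_disp_cohorts[(age, arm)]
    return animals_to_frame(animals), trials_to_frame(trials)


class TestWeeklyWeightGain:
    def test_printed_juvenile_gains(self, zero_disp_cohorts):
        adf, _ = _frames(zero_disp_cohorts, "juvenile", "control")
        gains = weekly_weight_gain(adf).data.set_index("timepoint")["mean"]
        # 273.8 - 227.4 in the first week of growth
        assert gains["baseline_to_week1"] == pytest.approx(46.4, abs=1e-9)

        adf, _ = _frames(zero_disp_cohorts, "juvenile", "exposed")
        gains = weekly_weight_gain(adf).data.set_index("timepoint")["mean"]
        # 344.3 - 327.0 in the final week
        assert gains["week4_to_week5"] == pytest.approx(17.3, abs=1e-9)

    def test_constant_trajectory_gains_zero(self):
        row = {"animal_id": "1-1", "age_group": "juvenile", "arm": "control"}
        row.update({f"weight_{tp}_g": 300.0 for tp in cal.WEIGHT_TIMEPOINTS})
        gains = weekly_weight_gain(pd.DataFrame([row])).data
        assert (gains["mean"] == 0).all()

    def test_gains_telescope(self, juvenile_control_cohort):
        animals, _ = juvenile_control_cohort
        adf = animals_to_frame(animals)
        gains = weekly_weight_gain(adf).data
        total = gains["mean"].sum()
        expected = adf["weight_week5_g"].mean() - adf["weight_baseline_g"].mean()
        assert total == pytest.approx(expected, abs=1e-9)

    def test_missing_timepoint_diagnosed(self, juvenile_control_cohort):
        adf = animals_to_frame(juvenile_control_cohort[0]).drop(columns=["weight_week3_g"])
        with pytest.raises(ValueError, match="weight"):
            weekly_weight_gain(adf)


class TestOrganCoefficient:
    def test_brain_example(self):
        assert organ_weight_coefficient(1.8, 340.0) == pytest.approx(0.529, abs=5e-4)

    def test_one_percent_exact(self):
        assert organ_weight_coefficient(3.4, 340.0) == 1.0

    def test_unit_rescaling_invariant(self):
        assert organ_weight_coefficient(1.8, 340.0) == pytest.approx(
            organ_weight_coefficient(0.0018, 0.340), rel=1e-12)

    def test_organ_exceeding_body_rejected(self):
        with pytest.raises(ValueError):
            organ_weight_coefficient(400.0, 340.0)


class TestTemperatureDifferential:
    def test_printed_juvenile_control_cells(self, zero_disp_cohorts):
        adf, _ = _frames(zero_disp_cohorts, "juvenile", "control")
        diff = temperature_differential(
            summarize_temperatures(adf, "rectal"),
            summarize_temperatures(adf, "skin")).data.set_index("timepoint")["mean"]
        assert diff["week4"] == pytest.approx(1.5, abs=1e-9)   # 37.7 - 36.2
        assert diff["week1"] == pytest.approx(2.2, abs=1e-9)   # 37.5 - 35.3

    def test_identical_tables_give_zero(self, zero_disp_cohorts):
        adf, _ = _frames(zero_disp_cohorts, "adult", "control")
        rectal = summarize_temperatures(adf, "rectal")
        diff = temperature_differential(rectal, rectal).data
        assert (diff["mean"] == 0).all()

    def test_key_mismatch_diagnosed(self, zero_disp_cohorts):
        adf, _ = _frames(zero_disp_cohorts, "adult", "control")
        rectal = summarize_temperatures(adf, "rectal")
        skin = summarize_temperatures(adf, "skin")
        skin.data = skin.data.iloc[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            temperature_differential(rectal, skin)


class TestPrintedTablesExactlyReproduced:
    """Degenerate-noise cohorts reproduce the published summary cells."""

    @pytest.mark.parametrize("age,arm", [(a, b) for a in cal.AGE_GROUPS
                                         for b in cal.ARMS])
    def test_weights_organs_temperatures(self, zero_disp_cohorts, age, arm):
        key = (age, arm)
        adf, _ = _frames(zero_disp_cohorts, age, arm)
        w = summarize_weights(adf).data.set_index("timepoint")
        for tp, (mean, _) in zip(cal.WEIGHT_TIMEPOINTS, cal.BODY_WEIGHT_G[key]):
            assert w.loc[tp, "mean"] == pytest.approx(mean, abs=1e-9)
            assert w.loc[tp, "dispersion"] == pytest.approx(0.0, abs=1e-9)
        for kind, table in (("rectal", cal.RECTAL_C), ("skin", cal.SKIN_C)):
            s = summarize_temperatures(adf, kind).data.set_index("timepoint")
            for tp, (mean, _) in zip(cal.TEMP_TIMEPOINTS, table[key]):
                assert s.loc[tp, "mean"] == pytest.approx(mean, abs=1e-9)
        org = summarize_organs(adf).data.set_index("timepoint")
        for organ, (mean, _) in cal.ORGAN_COEFF_PCT[key].items():
            assert org.loc[organ, "mean"] == pytest.approx(mean, abs=1e-9)


class TestMwmDailySummary:
    @staticmethod
    def _trials(latencies, successes, day=1):
        rows = []
        for i, (lat, suc) in enumerate(zip(latencies, successes)):
            rows.append({"animal_id": f"1-{i % 10 + 1}", "age_group": "adult",
                         "arm": "control", "day": day,
                         "trial_index": i % 4 + 1, "latency_s": lat,
                         "success": suc, "passive": False})
        return pd.DataFrame(rows)

    def test_all_successful_uniform(self):
        df = self._trials([20.0] * 40, [True] * 40)
        out = mwm_daily_summary(df).iloc[0]
        assert out["mean_successful_latency_s"] == 20.0
        assert out["percent_successful"] == 100.0

    def test_26_of_40_matches_printed_percentage(self):
        # adult-control day 1 prints 65.0% successful swims
        succ = [True] * 26 + [False] * 14
        lats = [20.0 if s else 60.0 for s in succ]
        out = mwm_daily_summary(self._trials(lats, succ)).iloc[0]
        assert out["percent_successful"] == 65.0
        assert out["n_successful"] == 26 and out["n_attempted"] == 40

    def test_censored_failures_excluded_from_latency(self):
        out = mwm_daily_summary(self._trials([10.0, 60.0], [True, False])).iloc[0]
        assert out["mean_successful_latency_s"] == 10.0
        assert out["percent_successful"] == 50.0

    def test_zero_success_day_flagged(self):
        out = mwm_daily_summary(self._trials([60.0] * 4, [False] * 4)).iloc[0]
        assert not out["latency_defined"]
        assert np.isnan(out["mean_successful_latency_s"])
        assert out["percent_successful"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mwm_daily_summary(pd.DataFrame(columns=["age_group", "arm", "day",
                                                    "success", "latency_s"]))

    def test_counts_reproducible_from_trials(self, juvenile_control_cohort):
        _, trials = juvenile_control_cohort
        tdf = trials_to_frame(trials)
        out = mwm_daily_summary(tdf)
        for _, row in out.iterrows():
            sub = tdf[tdf["day"] == row["day"]]
            assert row["n_attempted"] == len(sub)
            assert row["n_successful"] == int(sub["success"].sum())
            assert row["percent_successful"] == 100.0 * row["n_successful"] / row["n_attempted"]


class TestPassiveSwimmers:
    def test_no_flags_no_listings(self):
        df = pd.DataFrame([{"animal_id": "1-1", "age_group": "adult",
                            "arm": "control", "day": d, "trial_index": 1,
                            "latency_s": 30.0, "success": True, "passive": False}
                           for d in (1, 2)])
        assert passive_swimmers(df) == {1: [], 2: []}

    def test_repeat_offender_listed_once(self):
        rows = [{"animal_id": "1-2", "age_group": "adult", "arm": "control",
                 "day": 1, "trial_index": k, "latency_s": 60.0,
                 "success": False, "passive": True} for k in (2, 3, 4)]
        assert passive_swimmers(pd.DataFrame(rows)) == {1: ["1-2"]}

    def test_mixed_cohorts_rejected(self):
        rows = [{"animal_id": "1-1", "age_group": g, "arm": "control", "day": 1,
                 "trial_index": 1, "latency_s": 60.0, "success": False,
                 "passive": False} for g in ("adult", "juvenile")]
        with pytest.raises(ValueError):
            passive_swimmers(pd.DataFrame(rows))

    def test_day1_lists_longer_than_day4_under_decaying_propensity(self):
        # the generator concentrates passivity on day 1; over 200 seeded
        # cohorts the day-1 list should beat day 4 nearly always
        spec = default_calibration("presenile", "control")
        wins = 0
        for seed in range(200):
            _, trials = generate_cohort(spec, seed)
            lists = passive_swimmers(trials_to_frame(trials))
            if len(lists[1]) > len(lists[4]):
                wins += 1
        assert wins >= 190
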