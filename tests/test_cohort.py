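"""Synthetic-cohort generator: moment matching, determinism, logical
invariants, and recovery of the published calibration."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

import rfcohort.calibration as cal
from rfcohort.cohort import (AnimalRecord, MomentMatchError, TrialRecord,
                             animals_to_frame, default_calibration,
                             generate_cohort, match_truncated_normal_moments,
                             read_table_csv, trials_to_frame, write_animals_csv,
                             write_trials_csv, zero_dispersion)


class TestMomentMatching:
    def test_negligible_truncation_limit(self):
        loc, scale = match_truncated_normal_moments(30.0, 1.0, 0.0, 60.0)
        assert loc == pytest.approx(30.0, abs=1e-6)
        assert scale == pytest.approx(1.0, abs=1e-6)

    def test_heavy_truncation_cell_verified_by_quadrature(self):
        # the day-1 juvenile-control latency cell
        loc, scale = match_truncated_normal_moments(28.9, 15.4, 0.0, 60.0)
        norm = sps.norm(loc, scale)
        z, _ = quad(norm.pdf, 0, 60)
        m, _ = quad(lambda x: x * norm.pdf(x) / z, 0, 60)
        ex2, _ = quad(lambda x: x * x * norm.pdf(x) / z, 0, 60)
        assert m == pytest.approx(28.9, abs=1e-6)
        assert math.sqrt(ex2 - m * m) == pytest.approx(15.4, abs=1e-6)

    @pytest.mark.parametrize("key", list(cal.MWM_LATENCY_S))
    def test_all_published_cells_are_feasible(self, key):
        for day, (mean, sd) in cal.MWM_LATENCY_S[key].items():
            loc, scale = match_truncated_normal_moments(mean, sd, 0.0, 60.0)
            a, b = (0 - loc) / scale, (60 - loc) / scale
            m, v = sps.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
            assert m == pytest.approx(mean, abs=1e-6)
            assert math.sqrt(v) == pytest.approx(sd, abs=1e-6)

    def test_impossible_dispersion_raises(self):
        # no variable on an interval of width 60 can have sd 40
        with pytest.raises(MomentMatchError):
            match_truncated_normal_moments(30.0, 40.0, 0.0, 60.0)

    def test_mean_outside_interval_raises(self):
        with pytest.raises(MomentMatchError):
            match_truncated_normal_moments(70.0, 5.0, 0.0, 60.0)


class TestGeneratorContracts:
    def test_same_seed_is_bit_identical(self, juvenile_control_spec):
        a1, t1 = generate_cohort(juvenile_control_spec, 99)
        a2, t2 = generate_cohort(juvenile_control_spec, 99)
        assert a1 == a2 and t1 == t2

    def test_different_seeds_differ(self, juvenile_control_spec):
        a1, _ = generate_cohort(juvenile_control_spec, 1)
        a2, _ = generate_cohort(juvenile_control_spec, 2)
        assert a1 != a2

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError):
            default_calibration("neonate", "control")

    def test_zero_dispersion_reproduces_printed_means(self, zero_disp_cohorts):
        for (age, arm), (animals, _) in zero_disp_cohorts.items():
            key = (age, arm)
            for a in animals:
                for w, (mean, _) in zip(a.weights_g, cal.BODY_WEIGHT_G[key]):
                    assert w == pytest.approx(mean, abs=1e-9)
                for t, (mean, _) in zip(a.rectal_c, cal.RECTAL_C[key]):
                    assert t == pytest.approx(mean, abs=1e-9)
                for organ, (mean, _) in cal.ORGAN_COEFF_PCT[key].items():
                    coeff = 100 * a.organ_masses_g[organ] / a.terminal_weight_g
                    assert coeff == pytest.approx(mean, abs=1e-9)

    def test_trial_invariants_hold(self, juvenile_control_cohort):
        _, trials = juvenile_control_cohort
        for t in trials:
            if t.success:
                assert 0 < t.latency_s < 60
            else:
                assert t.latency_s == 60.0
            if t.passive:
                assert not t.success

    def test_trial_record_rejects_inconsistency(self):
        with pytest.raises(ValueError):
            TrialRecord("1-1", "juvenile", "control", 1, 1, 60.0, True, False)
        with pytest.raises(ValueError):
            TrialRecord("1-1", "juvenile", "control", 1, 1, 30.0, False, False)
        with pytest.raises(ValueError):
            TrialRecord("1-1", "juvenile", "control", 1, 1, 30.0, True, True)

    def test_ear_tag_ids_split_across_cages(self):
        animals, _ = generate_cohort(default_calibration("presenile", "exposed"), 0)
        cages = sorted({a.cage for a in animals})
        assert cages == [1, 3]  # presenile exposed: cages 1 and 3, five each
        assert sum(a.cage == 1 for a in animals) == 5
        assert animals[0].animal_id == "1-1"
        assert animals[-1].animal_id == "3-5"

    def test_infeasible_calibration_reported(self, juvenile_control_spec):
        from dataclasses import replace
        bad = dict(juvenile_control_spec.mwm_calibration)
        bad[1] = (30.0, 31.0, 0.5)  # sd beyond any bounded variable on (0, 60)
        spec = replace(juvenile_control_spec, mwm_calibration=bad)
        with pytest.raises(MomentMatchError):
            generate_cohort(spec, 0)

    def test_csv_round_trip(self, tmp_path, juvenile_control_cohort):
        animals, trials = juvenile_control_cohort
        adf, tdf = animals_to_frame(animals), trials_to_frame(trials)
        write_animals_csv(adf, tmp_path / "a.csv", "seed=12345")
        write_trials_csv(tdf, tmp_path / "t.csv", "seed=12345")
        adf2 = read_table_csv(tmp_path / "a.csv")
        tdf2 = read_table_csv(tmp_path / "t.csv")
        assert list(adf2.columns) == list(adf.columns)
        np.testing.assert_allclose(
            adf2.select_dtypes("number").to_numpy(),
            adf.select_dtypes("number").to_numpy(), rtol=0, atol=1e-12)
        assert (tdf2["success"] == tdf["success"]).all()
        assert (tdf2["passive"] == tdf["passive"]).all()


class TestCalibrationRecovery:
    """Empirical means over many cohorts recover every published cell.

    For each cohort the per-cell grand mean over 200 replicates is compared
    to the printed value within 3 standard errors of that grand mean.
    """

    N_REPS = 200

    @pytest.mark.parametrize("age,arm", [(a, b) for a in cal.AGE_GROUPS
                                         for b in cal.ARMS])
    def test_published_cells_recovered(self, age, arm):
        key = (age, arm)
        spec = default_calibration(age, arm)
        weights, rectal, skin = [], [], []
        organs = {o: [] for o in cal.ORGANS}
        lat = {d: [] for d in cal.MWM_DAYS}
        succ = {d: [] for d in cal.MWM_DAYS}
        for rep in range(self.N_REPS):
            animals, trials = generate_cohort(spec, seed=1000 + rep)
            for a in animals:
                weights.append(a.weights_g)
                rectal.append(a.rectal_c)
                skin.append(a.skin_c)
                for o in cal.ORGANS:
                    organs[o].append(100 * a.organ_masses_g[o] / a.terminal_weight_g)
            for t in trials:
                succ[t.day].append(t.success)
                if t.success:
                    lat[t.day].append(t.latency_s)

        def assert_recovered(samples, printed, label):
            samples = np.asarray(samples, float)
            se = samples.std(ddof=1) / math.sqrt(len(samples))
            assert abs(samples.mean() - printed) <= 3 * max(se, 1e-12), (
                f"{key} {label}: mean {samples.mean():.3f} vs printed {printed} "
                f"(se {se:.4f})")

        weights = np.asarray(weights)
        for j, (mean, _) in enumerate(cal.BODY_WEIGHT_G[key]):
            assert_recovered(weights[:, j], mean, f"weight[{j}]")
        rectal, skin = np.asarray(rectal), np.asarray(skin)
        for j, (mean, _) in enumerate(cal.RECTAL_C[key]):
            assert_recovered(rectal[:, j], mean, f"rectal[{j}]")
        for j, (mean, _) in enumerate(cal.SKIN_C[key]):
            assert_recovered(skin[:, j], mean, f"skin[{j}]")
        for o in cal.ORGANS:
            assert_recovered(organs[o], cal.ORGAN_COEFF_PCT[key][o][0], o)
        for d in cal.MWM_DAYS:
            assert_recovered(lat[d], cal.MWM_LATENCY_S[key][d][0], f"latency day {d}")
            assert_recovered(np.asarray(succ[d], float),
                             cal.MWM_SUCCESS_PCT[key][d] / 100.0,
                             f"success day {d}")
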