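"""Synthetic-study generator: distributions, shared generation/fitting
code path, pedaling simulation, and the MF observer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pitchsync import mfpsy, motor, pipeline, synth


class TestGenSubjects:
    def test_pitch_index_moments(self):
        df = synth.gen_subjects(10000, seed=0)
        assert df["pitch_index"].mean() == pytest.approx(0.36, abs=0.02)
        assert df["pitch_index"].std() == pytest.approx(0.33, abs=0.02)
        assert stats.skew(df["pitch_index"]) < 0  # left-skewed

    def test_support_and_determinism(self):
        a = synth.gen_subjects(200, seed=4)
        b = synth.gen_subjects(200, seed=4)
        assert (a["pitch_index"].abs() <= 1).all()
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_moments_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth.gen_subjects(10, seed=0, truth=synth.TruthParams(pitch_sd=1.5))


class TestGenRecall:
    def test_null_truth_centers_at_half_of_trials(self):
        truth = synth.TruthParams(
            intercept=0.0,
            condition_beta=0.0,
            day_beta=0.0,
            session_beta=0.0,
            pitch_beta=0.0,
            music_beta=0.0,
            sleep_between_beta=0.0,
            sleep_within_beta=0.0,
            lang_beta=0.0,
            sd_intercept=0.0,
            sd_condition=0.0,
            sd_day=0.0,
            sd_sleep_c=0.0,
        )
        bundle = synth.generate_study(truth, n_subjects=500, seed=8, with_motor=False)
        assert bundle.study_table["recalled"].mean() == pytest.approx(20.0, abs=0.5)

    def test_day_effect_direction(self):
        # positive day coefficient on the contrast = higher recall on day 1
        truth = synth.TruthParams(day_beta=0.4, sd_day=0.0)
        bundle = synth.generate_study(truth, n_subjects=300, seed=9, with_motor=False)
        st = bundle.study_table
        assert st[st.day == 1].recalled.mean() > st[st.day == 2].recalled.mean()

    def test_support_bounds(self):
        bundle = synth.generate_study(n_subjects=50, seed=10, with_motor=False)
        r = bundle.study_table["recalled"]
        assert (r >= 0).all() and (r <= 40).all()

    def test_generator_uses_fitting_design(self):
        # the truth vector is packed for the same built model the pipeline
        # fits: regenerating eta through that model reproduces the recall
        # probabilities exactly
        bundle = synth.generate_study(n_subjects=20, seed=3, with_motor=False)
        model, th = bundle.model, bundle.theta_true
        assert th.shape == (model.n_params,)
        assert "day.c1" in model.colnames
        eta = model.eta(th, include_random=True)
        assert np.all(np.isfinite(eta))


class TestGenPedaling:
    def _subjects(self, n, seed=0):
        return synth.gen_subjects(n, seed)

    def test_zero_jitter_gives_zero_cv_and_constant_ibd(self):
        truth = synth.TruthParams(
            cv_iso=0.0, cv_self=0.0, subject_speed_sd=0.0, subject_cv_spread=0.0
        )
        ts = synth.gen_pedaling(self._subjects(3), truth, seed=1, n_revolutions=50)
        summ = synth.motor_summaries(ts)
        iso = summ[summ.condition == "isochronous"]
        np.testing.assert_allclose(iso["cv"], 0.0, atol=1e-12)
        # speed = 1.07 Hz -> duration 1/1.07; IBD = |1/1.07 - 1|
        np.testing.assert_allclose(iso["ibd_s"], abs(1 / 1.07 - 1), atol=1e-9)

    def test_condition_cv_ordering(self):
        truth = synth.TruthParams()  # iso dispersion < self-initiated
        subjects = self._subjects(10, seed=2)
        cond_map = {
            s: {1: "isochronous", 2: "self_initiated"} for s in subjects.subject_id
        }
        ts = synth.gen_pedaling(subjects, truth, seed=3, n_revolutions=1500,
                                conditions_by_session=cond_map)
        summ = synth.motor_summaries(ts)
        wide = summ.pivot(index="subject_id", columns="condition", values="cv")
        assert (wide["isochronous"] < wide["self_initiated"]).sum() >= 9

    def test_trace_round_trip(self):
        truth = synth.TruthParams()
        ts = synth.gen_pedaling(self._subjects(2), truth, seed=5, n_revolutions=30)
        one = ts[(ts.subject_id == ts.subject_id.iloc[0]) & (ts.session == 1)]
        times = one["time_s"].to_numpy()
        trace = motor.synthesize_trace(times)
        got = motor.detect_crossings(trace).times_s
        assert len(got) == len(times)
        assert np.max(np.abs(got - times)) <= 0.01


class TestMfObserver:
    @pytest.fixture(scope="class")
    def small_battery(self):
        return mfpsy.build_battery(order_seed=0)

    def _subjects_with_pitch(self, pitch_values):
        n = len(pitch_values)
        df = synth.gen_subjects(n, seed=0)
        df["pitch_index"] = pitch_values
        return df

    def test_saturation(self, small_battery):
        truth = synth.TruthParams()
        subj = self._subjects_with_pitch([0.999, -0.999])
        resp = synth.simulate_mf_responses(subj, small_battery, truth, seed=1)
        scores = synth.score_mf_responses(small_battery, resp).set_index("subject_id")
        assert scores.loc["s000", "delta_p"] > 0.9  # extreme spectral listener
        assert scores.loc["s001", "delta_p"] < -0.9  # extreme fundamental listener

    def test_latent_rank_correlation(self, small_battery):
        truth = synth.TruthParams()
        subj = synth.gen_subjects(50, seed=6)
        resp = synth.simulate_mf_responses(subj, small_battery, truth, seed=7)
        scores = synth.score_mf_responses(small_battery, resp)
        merged = subj.merge(scores, on="subject_id")
        rho = stats.spearmanr(merged["pitch_index"], merged["delta_p"]).statistic
        assert rho > 0.9

    def test_all_pairs_answered(self, small_battery):
        truth = synth.TruthParams()
        subj = self._subjects_with_pitch([0.2, -0.1])
        resp = synth.simulate_mf_responses(subj, small_battery, truth, seed=2)
        assert len(resp) == 2 * 162
        scored = synth.score_mf_responses(small_battery, resp)
        assert (scored["n_classified"] == 162).all()


class TestStudyBundle:
    def test_regenerable_byte_identical(self):
        a = synth.generate_study(n_subjects=8, seed=21, n_revolutions=100)
        b = synth.generate_study(n_subjects=8, seed=21, n_revolutions=100)
        assert a.study_table.to_csv() == b.study_table.to_csv()
        assert a.pedal_timestamps.to_csv() == b.pedal_timestamps.to_csv()
        np.testing.assert_array_equal(a.theta_true, b.theta_true)

    def test_all_finite_and_consistent_ids(self, small_study):
        st = small_study.study_table
        num = st.select_dtypes(include=[np.number])
        assert np.isfinite(num.to_numpy()).all()
        assert set(st.subject_id) == set(small_study.pedal_timestamps.subject_id)

    def test_truth_yaml_round_trip(self, tmp_path):
        t = synth.TruthParams(day_beta=0.42)
        synth.save_truth(t, tmp_path / "t.yaml")
        back = synth.load_truth(tmp_path / "t.yaml")
        assert back == t


class TestRecoveryBookkeeping:
    def test_table_shape_and_columns(self):
        tab = synth.recovery_experiment(
            n_subjects=8,
            reps=2,
            seed=1,
            fit_config={"chains": 2, "iterations": 100},
            monitor=("day.c1",),
        )
        assert len(tab) == 2  # reps x monitored parameters
        for col in ("covered", "pd", "estimate", "truth", "status"):
            assert col in tab.columns

    def test_too_few_reps(self):
        with pytest.raises(ValueError):
            synth.recovery_experiment(reps=1)
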