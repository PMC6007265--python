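"""Synthetic responders: choice rule, response times, timelines, optics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from socialpref.cohort import (AgentSpec, CohortConfig, RTCurve,
                               SessionTimeline, deterministic_rt,
                               simulate_choice, simulate_cohort,
                               simulate_optics, simulate_session)
from socialpref.models import PreferenceParams
from socialpref.nirs import extract_windows, od_to_concentration
from socialpref.task import InequalityClass, TaskConfig


def _agent(p_reward=0.02, alpha=0.06, beta=-0.5, p_rt=25.0, **kw):
    params = PreferenceParams("FS_RT", dict(
        p_reward_responder=p_reward, alpha=alpha, beta=beta, p_rt=p_rt))
    return AgentSpec(participant_id=0, true_params=params, **kw)


class TestChoice:
    def test_pure_self_interest_never_punishes(self, task_cfg, rng):
        ag = _agent(p_reward=1.0, alpha=0.0, beta=0.0, p_rt=0.0,
                    choice_temperature=0.0)
        for transfer in task_cfg.transfer_levels:
            p, _ = simulate_choice(transfer, ag, task_cfg, rng)
            assert p == 0

    def test_strong_ai_seeker_zeroes_the_proposer(self, task_cfg, rng):
        """beta=-1, alpha=0, tiny own-reward weight: the argmax punishment at
        transfer 20 is exactly the 22 points that zero the proposer (verified
        against an exhaustive utility scan)."""
        ag = _agent(p_reward=0.01, alpha=0.0, beta=-1.0, p_rt=0.0,
                    choice_temperature=0.0)
        p, _ = simulate_choice(20, ag, task_cfg, rng)
        assert p == 22

    def test_fixed_seed_reproducible(self, task_cfg):
        ag = _agent()
        a = [simulate_choice(20, ag, task_cfg, np.random.default_rng(5))
             for _ in range(3)]
        assert a[0] == a[1] == a[2]

    def test_rt_within_response_window(self, task_cfg, rng):
        ag = _agent()
        for _ in range(50):
            _, rt = simulate_choice(0, ag, task_cfg, rng)
            assert 0 < rt <= task_cfg.response_window


class TestRTCurve:
    def test_bump_is_concave_with_max_at_t_peak(self):
        curve = RTCurve()
        rts = [deterministic_rt(t, InequalityClass.E, 0, curve)
               for t in (0, 10, 20, 30, 40, 50)]
        assert max(rts) == rts[2]  # t_peak = 20
        diffs = np.diff(rts)
        assert np.all(np.diff(np.sign(diffs)) <= 0)  # single interior peak

    def test_unequal_outcomes_are_slower(self):
        curve = RTCurve()
        for cls in (InequalityClass.AI, InequalityClass.DI):
            assert (deterministic_rt(20, cls, 0, curve)
                    > deterministic_rt(20, InequalityClass.E, 0, curve))

    def test_larger_punishments_take_longer(self):
        curve = RTCurve()
        rts = [deterministic_rt(20, InequalityClass.E, p, curve)
               for p in (0, 10, 20, 30)]
        assert np.all(np.diff(rts) > 0)


class TestTimeline:
    def test_onsets_increasing_with_minimum_spacing(self, rng):
        tl = SessionTimeline.generate(60, rng)
        gaps = np.diff(tl.onsets)
        assert np.all(gaps >= 17.0 - 1e-9)  # 5 + 7 + 5 s minimum
        assert tl.onsets[0] == pytest.approx(60.0)  # event-free baseline
        assert tl.duration > tl.onsets[-1] + 12.0


class TestOptics:
    def test_null_forward_model_is_flat(self, task_cfg):
        ag = _agent(neural_gain_dlpfc=0.0, neural_gain_dmpfc=0.0,
                    dmpfc_extra_noise=0.0, noise_sd_optical=0.0,
                    drift_slope_sd=0.0, cardiac_amplitude=0.0)
        rng = np.random.default_rng(0)
        trials = simulate_session(ag, task_cfg, rng, n_trials=5)
        tl = SessionTimeline.generate(5, rng)
        rec = simulate_optics(trials, tl, ag, rng, task_cfg)
        assert np.allclose(rec.od, 0.0)

    def test_single_event_peaks_at_hrf_peak(self, task_cfg):
        """A noiseless session's dlPFC O2Hb response to one trial peaks 6 s
        after that trial's onset."""
        ag = _agent(noise_sd_optical=0.0, drift_slope_sd=0.0,
                    cardiac_amplitude=0.0, dmpfc_extra_noise=0.0)
        rng = np.random.default_rng(1)
        trials = simulate_session(ag, task_cfg, rng, n_trials=2)
        tl = SessionTimeline.generate(2, rng)
        rec = simulate_optics(trials, tl, ag, rng, task_cfg)
        series = od_to_concentration(rec)
        onset = int(round(tl.onsets[0] * 10))
        seg = np.abs(series.o2hb[onset:onset + 120, 0])
        assert np.argmax(seg) / 10.0 == pytest.approx(6.0, abs=0.15)

    def test_forward_inverse_round_trip(self, task_cfg):
        """Noise-free forward optics inverted by the preprocessing module
        recovers the generating concentrations to <= 1e-9 relative error."""
        ag = _agent(noise_sd_optical=0.0, drift_slope_sd=0.0,
                    cardiac_amplitude=0.0, dmpfc_extra_noise=0.0)
        rng = np.random.default_rng(2)
        trials = simulate_session(ag, task_cfg, rng, n_trials=3)
        tl = SessionTimeline.generate(3, rng)
        rec = simulate_optics(trials, tl, ag, rng, task_cfg)
        series = od_to_concentration(rec)
        assert np.allclose(series.hhb, -series.o2hb / 3.0,
                           rtol=1e-9, atol=1e-12)


class TestCohort:
    def test_same_seed_bitwise_identical(self):
        cc = dataclasses.replace(CohortConfig(), n_participants=2)
        a = simulate_cohort(cc, seed=42)
        b = simulate_cohort(cc, seed=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for pid in a.recordings:
            assert np.array_equal(a.recordings[pid].od, b.recordings[pid].od)

    def test_different_seeds_differ(self):
        cc = dataclasses.replace(CohortConfig(), n_participants=2,
                                 with_optics=False)
        a = simulate_cohort(cc, seed=1)
        b = simulate_cohort(cc, seed=2)
        assert not a.trials.punishment.equals(b.trials.punishment)

    def test_ai_seeking_cohort_creates_ai_states(self, behavioral_cohort):
        """With beta drawn from [-1, 0], punishment creates advantageous
        inequality in a substantial share of trials."""
        classes = behavioral_cohort.trials.inequality_class
        assert (classes == "AI").mean() > 0.0
        assert (behavioral_cohort.trials.punishment > 0).mean() > 0.5

    def test_truth_table_records_generating_parameters(self, behavioral_cohort):
        truth = behavioral_cohort.truth
        assert {"true_alpha", "true_beta", "true_p_rt",
                "true_p_reward_responder"} <= set(truth.columns)
        assert truth.true_alpha.between(-0.033, 0.153).all()
        assert truth.true_beta.between(-1.0, 0.0).all()

    def test_rt_is_longest_at_intermediate_transfers(self, behavioral_cohort):
        """Inverted-U response times: the slowest mean RT occurs at an
        interior transfer, and both extremes are faster."""
        mean_rt = behavioral_cohort.trials.groupby("transfer").rt_s.mean()
        peak = mean_rt.idxmax()
        assert peak in (10, 20, 30, 40)
        assert mean_rt[peak] > mean_rt[0] and mean_rt[peak] > mean_rt[50]
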