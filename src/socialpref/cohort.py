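"""Synthetic responders: punishment choices, response times and optics.

Each simulated agent holds true Fehr–Schmidt-with-RT preferences and chooses
a punishment by softmax over the 31-point grid of its utility.  The response
time entering the utility is the *deterministic* time the agent would need
for that punishment: an inverted-U function of the transfer (decision
difficulty peaks at intermediate unfairness), a slowdown whenever the chosen
outcome leaves the players unequal, and a movement-time component that grows
quadratically with the punishment slider distance.  The realized RT adds
Gaussian jitter on top.  Only the punishment-dependent RT components (the
slider movement and the inequality slowdown) can shape choice; through the
RT weight of the utility the movement time acts as an effort cost, which is
what makes optimal punishments graded in the preference weights instead of
corner solutions.

Prefrontal optics are generated by a forward model: per-trial neural
amplitude proportional to the standardized valuation of the chosen outcome
(the agent's inequity-weighted payoff terms plus a moderate neural
difficulty component, distinct from the large choice-effort RT weight),
convolved
with a canonical double-gamma HRF into dO2Hb (dHHb = −dO2Hb/3), pushed
through the forward modified Beer–Lambert law, and contaminated with linear
drift, a 1 Hz cardiac sinusoid and white noise.  dlPFC channels (1-8) carry
a stronger utility coupling than dmPFC channels (9-16).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .models import PreferenceParams, get_model, utility
from .nirs import (DLPFC_CHANNELS, DMPFC_CHANNELS, BeerLambertConstants,
                   ChromophoreSeries, OpticalRecording, canonical_hrf,
                   concentration_to_od)
from .task import InequalityClass, TaskConfig, Trial

__all__ = [
    "RTCurve",
    "AgentSpec",
    "SessionTimeline",
    "CohortConfig",
    "CohortData",
    "deterministic_rt",
    "simulate_choice",
    "simulate_session",
    "simulate_optics",
    "simulate_cohort",
]

TRIAL_COLUMNS = ["participant_id", "trial_index", "transfer", "punishment",
                 "rt_s", "payoff_responder", "payoff_proposer",
                 "inequality_class"]


@dataclass(frozen=True)
class RTCurve:
    """Inverted-U response-time profile over transfers.

    ``r_base``/``r_peak`` are the floor and peak RT in seconds, ``t_peak``
    the transfer (points) of maximal difficulty, ``width`` the Gaussian
    width in points, and ``ai_di_slowdown`` the extra seconds incurred when
    the chosen outcome is unequal (AI or DI).
    """

    r_peak: float = 4.0
    r_base: float = 2.0
    t_peak: float = 20.0
    width: float = 15.0
    ai_di_slowdown: float = 0.5
    #: extra seconds at a full-endowment punishment: moving the slider
    #: further takes longer, and superlinearly so (settling time grows with
    #: distance).  Through the RT term of the utility this is also the
    #: effort cost that makes optimal punishments interior rather than
    #: corner solutions.
    movement_scale: float = 2.0


@dataclass(frozen=True)
class AgentSpec:
    """Generating truth for one synthetic responder."""

    participant_id: int
    true_params: PreferenceParams
    choice_temperature: float = 0.2  # softmax noise, utility units
    alpha_jitter_sd: float = 0.0  # trial-to-trial preference variability
    beta_jitter_sd: float = 0.0
    rt_curve: RTCurve = field(default_factory=RTCurve)
    rt_noise_sd: float = 0.3  # s, jitter on realized RT
    #: RT weight of the *neural* valuation signal.  The choice-effort RT
    #: weight (true_params["p_rt"]) prices slider effort and is large; the
    #: hemodynamic signal instead carries the social valuation of the chosen
    #: outcome plus a moderate difficulty component with this weight.
    neural_rt_weight: float = 8.0
    neural_gain_dlpfc: float = 1.0  # concentration a.u. per unit utility
    neural_gain_dmpfc: float = 0.3
    dmpfc_extra_noise: float = 0.8  # extra amplitude noise on dmPFC trials
    noise_sd_optical: float = 2e4  # OD units, white sensor noise
    drift_slope_sd: float = 50.0  # OD units per second
    cardiac_amplitude: float = 5e3  # OD units, 1 Hz sinusoid

    def __post_init__(self) -> None:
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be >= 0")
        if not (0 < self.rt_curve.r_base <= self.rt_curve.r_peak):
            raise ValueError("rt_curve must satisfy 0 < r_base <= r_peak")


@dataclass(frozen=True)
class SessionTimeline:
    """Trial onsets (transfer screen) on the 10 Hz recording clock."""

    onsets: np.ndarray
    fs: float = 10.0
    transfer_duration: float = 5.0
    response_window: float = 7.0
    baseline_duration: float = 60.0
    tail: float = 20.0

    @classmethod
    def generate(cls, n_trials: int, rng: np.random.Generator,
                 iti_fixed: float = 5.0, jitter_max: float = 10.0,
                 **kw) -> "SessionTimeline":
        """Onsets separated by transfer + response + 5 s + U(0, 10) jitter.

        The uniform jitter has mean 5 s; the first 60 s are event-free
        baseline.
        """
        tl = cls(onsets=np.empty(0), **kw)
        gaps = (tl.transfer_duration + tl.response_window + iti_fixed
                + rng.uniform(0.0, jitter_max, size=n_trials))
        onsets = tl.baseline_duration + np.concatenate(
            [[0.0], np.cumsum(gaps[:-1])])
        # snap to the sampling grid so window extraction is exact
        onsets = np.round(onsets * tl.fs) / tl.fs
        return replace(tl, onsets=onsets)

    @property
    def duration(self) -> float:
        return float(self.onsets[-1] + self.transfer_duration
                     + self.response_window + self.tail)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def deterministic_rt(transfer: int, inequality: InequalityClass,
                     punishment: int, curve: RTCurve,
                     max_punishment: int = 30) -> float:
    """Noise-free RT for a transfer, punishment and resulting inequality.

    Difficulty bump (inverted U over transfers) + slowdown for unequal
    outcomes + quadratic movement time in the punishment slider distance.
    """
    bump = (curve.r_peak - curve.r_base) * np.exp(
        -((transfer - curve.t_peak) / curve.width) ** 2)
    slow = curve.ai_di_slowdown if inequality != InequalityClass.E else 0.0
    move = curve.movement_scale * (punishment / max_punishment) ** 2
    return float(curve.r_base + bump + slow + move)


def _candidate_trials(transfer: int, agent: AgentSpec, cfg: TaskConfig,
                      ) -> List[Trial]:
    out = []
    for p in range(cfg.max_punishment + 1):
        t = Trial.build(transfer, p, rt=0.0, cfg=cfg)
        rt = deterministic_rt(transfer, t.inequality_class, p, agent.rt_curve,
                              cfg.max_punishment)
        out.append(replace(t, rt=rt))
    return out


def simulate_choice(transfer: int, agent: AgentSpec, cfg: TaskConfig,
                    rng: np.random.Generator) -> Tuple[int, float]:
    """Sample one (punishment, rt) pair.

    Punishment: softmax over p in {0..max} of the agent's true utility at
    temperature tau (tau -> 0 gives the argmax, ties broken toward smaller
    p).  RT: the deterministic curve value for the chosen outcome plus
    Gaussian jitter, clipped to (0, response_window].
    """
    cands = _candidate_trials(transfer, agent, cfg)
    params = agent.true_params
    if agent.alpha_jitter_sd > 0 or agent.beta_jitter_sd > 0:
        # trial-to-trial preference variability (random-utility noise)
        vals = dict(params.values)
        if "alpha" in vals:
            vals["alpha"] += rng.normal(0.0, agent.alpha_jitter_sd)
        if "beta" in vals:
            vals["beta"] += rng.normal(0.0, agent.beta_jitter_sd)
        params = PreferenceParams(params.model_id, vals)
    u = np.array([utility(t, params) for t in cands])
    tau = agent.choice_temperature
    if tau < 1e-12:
        p = int(np.argmax(u))  # argmax takes the first (smallest p) on ties
    else:
        logits = (u - u.max()) / tau
        prob = np.exp(logits)
        prob /= prob.sum()
        p = int(rng.choice(len(u), p=prob))
    rt_det = cands[p].rt
    rt = rt_det + rng.normal(0.0, agent.rt_noise_sd)
    rt = float(np.clip(rt, 1e-3, cfg.response_window))
    return p, rt


def simulate_session(agent: AgentSpec, cfg: TaskConfig,
                     rng: np.random.Generator,
                     n_trials: int = 60) -> pd.DataFrame:
    """One participant's trial table: equal transfer counts, shuffled order."""
    levels = np.repeat(cfg.transfer_levels,
                       int(np.ceil(n_trials / len(cfg.transfer_levels))))
    transfers = rng.permutation(levels[:n_trials])
    rows = []
    for i, tr in enumerate(transfers):
        p, rt = simulate_choice(int(tr), agent, cfg, rng)
        trial = Trial.build(int(tr), p, rt, cfg)
        rows.append({
            "participant_id": agent.participant_id, "trial_index": i,
            "transfer": trial.transfer, "punishment": trial.punishment,
            "rt_s": trial.rt, "payoff_responder": trial.payoff_responder,
            "payoff_proposer": trial.payoff_proposer,
            "inequality_class": trial.inequality_class.value})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def trials_from_frame(df: pd.DataFrame, cfg: TaskConfig | None = None,
                      ) -> List[Trial]:
    """Rebuild Trial objects from a trial-table DataFrame."""
    cfg = cfg or TaskConfig()
    return [Trial.build(int(r.transfer), int(r.punishment), float(r.rt_s), cfg)
            for r in df.itertuples()]


def _standardize_signed(u: np.ndarray) -> np.ndarray:
    """Map utilities to [-1, 1] per participant (constant -> zeros)."""
    lo, hi = u.min(), u.max()
    if hi == lo:
        return np.zeros_like(u)
    return 2.0 * (u - lo) / (hi - lo) - 1.0


def simulate_optics(trials: pd.DataFrame, timeline: SessionTimeline,
                    agent: AgentSpec, rng: np.random.Generator,
                    cfg: TaskConfig | None = None,
                    constants: BeerLambertConstants | None = None,
                    ) -> OpticalRecording:
    """Forward-model a 16-channel two-wavelength recording for one session.

    The per-trial neural amplitude is the standardized valuation signal of
    the chosen outcome: the agent's inequity-weighted payoff terms plus a
    difficulty component ``-neural_rt_weight * RT``.
    """
    cfg = cfg or TaskConfig()
    if len(trials) != len(timeline.onsets):
        raise ValueError("trials and timeline lengths differ")
    fs = timeline.fs
    n = timeline.n_samples
    n_channels = len(DLPFC_CHANNELS) + len(DMPFC_CHANNELS)

    neural_params = agent.true_params
    if "p_rt" in neural_params.values:
        vals = dict(neural_params.values)
        vals["p_rt"] = agent.neural_rt_weight
        neural_params = PreferenceParams(neural_params.model_id, vals)
    u = np.array([utility(t, neural_params)
                  for t in trials_from_frame(trials, cfg)])
    amp = _standardize_signed(u)

    hrf = canonical_hrf(fs=fs)
    onset_idx = np.round(timeline.onsets * fs).astype(int)

    o2hb = np.zeros((n, n_channels))
    for ch in range(n_channels):
        stick = np.zeros(n)
        if ch in DLPFC_CHANNELS:
            gain = agent.neural_gain_dlpfc
            trial_amp = amp
        else:
            gain = agent.neural_gain_dmpfc
            trial_amp = amp + rng.normal(0.0, agent.dmpfc_extra_noise,
                                         size=amp.shape)
        stick[onset_idx] = gain * trial_amp
        o2hb[:, ch] = np.convolve(stick, hrf)[:n]
    hhb = -o2hb / 3.0

    rec = concentration_to_od(ChromophoreSeries(o2hb, hhb, fs=fs), constants)
    od = rec.od
    t = np.arange(n) / fs
    for ch in range(n_channels):
        slope = rng.normal(0.0, agent.drift_slope_sd)
        phase = rng.uniform(0, 2 * np.pi)
        nuisance = (slope * t
                    + agent.cardiac_amplitude * np.sin(2 * np.pi * 1.0 * t
                                                       + phase))
        od[:, ch, :] += nuisance[:, None]
        od[:, ch, :] += rng.normal(0.0, agent.noise_sd_optical, size=(n, 2))
    return OpticalRecording(od=od, fs=fs)


@dataclass(frozen=True)
class CohortConfig:
    """Population the agents are drawn from.

    Disadvantageous-inequality weights alpha are drawn uniformly from the
    behavioral range [-0.033, 0.153] and advantageous-inequality weights
    beta from [-1, 0] (predominantly AI-seeking).  The own-reward weight is
    small (0.02/point) relative to the inequity terms, and the RT weight is
    large (15-35 utility/second): at the fitted-coefficient scale of the
    inequity weights, slider effort rather than own-payoff loss is the
    binding marginal cost of punishing, which is what keeps optimal
    punishments graded rather than all-or-nothing.
    """

    n_participants: int = 24
    n_trials: int = 60
    task: TaskConfig = field(default_factory=TaskConfig)
    alpha_range: Tuple[float, float] = (-0.033, 0.153)
    beta_range: Tuple[float, float] = (-1.0, 0.0)
    p_reward: float = 0.02
    p_rt_range: Tuple[float, float] = (20.0, 30.0)
    generating_model: str = "FS_RT"
    choice_temperature: float = 0.2
    alpha_jitter_sd: float = 0.0
    beta_jitter_sd: float = 0.0
    rt_curve: RTCurve = field(default_factory=RTCurve)
    rt_noise_sd: float = 0.3
    neural_rt_weight: float = 8.0
    neural_gain_dlpfc: float = 1.0
    neural_gain_dmpfc: float = 0.3
    dmpfc_extra_noise: float = 0.8
    noise_sd_optical: float = 2e4
    with_optics: bool = True


@dataclass
class CohortData:
    """Everything a downstream analysis needs, plus the generating truth."""

    trials: pd.DataFrame  # all participants stacked
    recordings: Dict[int, OpticalRecording]
    timelines: Dict[int, SessionTimeline]
    truth: pd.DataFrame  # one row per participant, generating parameters

    def participant_trials(self, pid: int) -> pd.DataFrame:
        return (self.trials[self.trials.participant_id == pid]
                .reset_index(drop=True))


def _draw_agent(pid: int, cc: CohortConfig, rng: np.random.Generator,
                ) -> AgentSpec:
    spec = get_model(cc.generating_model)
    vals = {}
    if "alpha" in spec.param_names:
        vals["alpha"] = rng.uniform(*cc.alpha_range)
    if "beta" in spec.param_names:
        vals["beta"] = rng.uniform(*cc.beta_range)
    if "p_reward_responder" in spec.param_names:
        vals["p_reward_responder"] = cc.p_reward
    if "p_rt" in spec.param_names:
        vals["p_rt"] = rng.uniform(*cc.p_rt_range)
    for name in spec.param_names:
        vals.setdefault(name, 0.0)
    return AgentSpec(
        participant_id=pid,
        true_params=PreferenceParams(cc.generating_model, vals),
        choice_temperature=cc.choice_temperature,
        alpha_jitter_sd=cc.alpha_jitter_sd,
        beta_jitter_sd=cc.beta_jitter_sd,
        rt_curve=cc.rt_curve, rt_noise_sd=cc.rt_noise_sd,
        neural_rt_weight=cc.neural_rt_weight,
        neural_gain_dlpfc=cc.neural_gain_dlpfc,
        neural_gain_dmpfc=cc.neural_gain_dmpfc,
        dmpfc_extra_noise=cc.dmpfc_extra_noise,
        noise_sd_optical=cc.noise_sd_optical)


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> CohortData:
    """Simulate an independent, fully seeded cohort."""
    cc = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    tables, recordings, timelines, truth_rows = [], {}, {}, []
    for pid, child in enumerate(root.spawn(cc.n_participants)):
        rng = np.random.Generator(np.random.PCG64(child))
        agent = _draw_agent(pid, cc, rng)
        trials = simulate_session(agent, cc.task, rng, cc.n_trials)
        tables.append(trials)
        if cc.with_optics:
            tl = SessionTimeline.generate(cc.n_trials, rng)
            recordings[pid] = simulate_optics(trials, tl, agent, rng, cc.task)
            timelines[pid] = tl
        row = {"participant_id": pid,
               "model_id": cc.generating_model,
               "choice_temperature": agent.choice_temperature}
        row.update({f"true_{k}": v for k, v in agent.true_params.values.items()})
        truth_rows.append(row)
    return CohortData(trials=pd.concat(tables, ignore_index=True),
                      recordings=recordings, timelines=timelines,
                      truth=pd.DataFrame(truth_rows))
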