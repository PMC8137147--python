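"""Synthetic mice, labs, and training histories.

The generative choice model is the same logistic trial-history model that the
analysis fits (see :mod:`choicelab.glm`): visual evidence enters through
per-contrast signed weights, the previous trial through rewarded/unrewarded
choice weights, and (full task) the block prior through a block weight.
Learning is modeled as a saturating-exponential scaling of the visual
weights with cumulative trial count; history weights and bias are constant.

Lab identity affects ONLY learning speed.  Trained-state (asymptotic)
psychometric parameters are drawn per mouse from a single cross-lab
distribution, so a trained cohort carries no lab signature by construction.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import truncnorm

from . import status as status_mod
from . import task as task_mod
from .psychometrics import PsychometricParams, psych_eval
from .task import (BlockSchedule, SessionBrief, TrainingStage,
                   advance_training_stage, build_session_schedule,
                   sample_trial_stimulus, stage_from_index)

__all__ = [
    "AgentParams",
    "LearningTrajectory",
    "LabProfile",
    "CohortConfig",
    "CohortData",
    "DEFAULT_ASYMPTOTE",
    "BASIC_HISTORY_WEIGHTS",
    "FULL_HISTORY_WEIGHTS",
    "DEFAULT_BLOCK_WEIGHT",
    "calibrate_visual_weights",
    "agent_choice_prob",
    "default_agent",
    "sample_trial_duration",
    "sample_session_length",
    "simulate_session",
    "simulate_training_course",
    "simulate_cohort",
]

# Trained-state psychometric summaries used as cross-lab defaults:
# total lapse ~ 9.5 +- 3.6 % (split evenly over the two sides),
# threshold ~ 14.3 +- 3.8 % contrast, bias ~ 0.3 +- 8.4 % contrast.
DEFAULT_ASYMPTOTE = PsychometricParams(gamma=0.0475, lambda_=0.0475,
                                       mu=0.3, sigma=14.3)

# Fitted history weights used as generative defaults (basic / full task).
BASIC_HISTORY_WEIGHTS = (0.19, 0.33)  # (W_r, W_u)
FULL_HISTORY_WEIGHTS = (0.42, 0.46)

# Block-prior weight, calibrated so that the simulated 0%-contrast bias shift
# between 20:80 and 80:20 blocks lands near 28.5 percentage points.
DEFAULT_BLOCK_WEIGHT = 0.30

_Prev = namedtuple("_Prev", "signed_contrast stim_side choice correct")


@dataclass(frozen=True)
class AgentParams:
    """Generative log-odds weights of a simulated mouse."""

    visual_weights: dict  # contrast magnitude -> W_c
    w_rewarded: float
    w_unrewarded: float
    w_bias: float
    w_block: Optional[float] = None  # None outside the full task

    def __post_init__(self) -> None:
        vals = list(self.visual_weights.values()) + [
            self.w_rewarded, self.w_unrewarded, self.w_bias]
        if self.w_block is not None:
            vals.append(self.w_block)
        if not np.all(np.isfinite(vals)):
            raise ValueError("all agent weights must be finite")
        if 0.0 in self.visual_weights:
            raise ValueError("0% contrast must not carry a visual weight")

    def scaled(self, s: float) -> "AgentParams":
        """Visual weights multiplied by ``s`` (learning state); rest unchanged."""
        return replace(self, visual_weights={c: w * s for c, w in
                                             self.visual_weights.items()})


@dataclass(frozen=True)
class LearningTrajectory:
    rate: float  # trials to half... time constant tau of the saturating exponential
    initial_scale: float  # fraction of asymptotic visual weights at trial 0
    asymptote_params: PsychometricParams

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 0.0 <= self.initial_scale < 1.0:
            raise ValueError("initial_scale must lie in [0, 1)")

    def scale_at(self, cumulative_trials: float) -> float:
        return self.initial_scale + (1.0 - self.initial_scale) * (
            1.0 - np.exp(-cumulative_trials / self.rate))


@dataclass(frozen=True)
class LabProfile:
    lab_id: str
    n_mice: int
    learning_rate_mean: float  # mean tau (trials) across the lab's mice
    learning_rate_sd: float
    timezone_group: str

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.learning_rate_sd < 0:
            raise ValueError("learning_rate_sd must be >= 0")


@dataclass
class CohortConfig:
    n_labs: int = 7
    n_mice_per_lab: int = 10
    mode: str = "training"  # "training" (full histories) or "trained_only"
    max_days: int = 40
    continue_to_full: bool = False
    n_full_days: int = 3
    # lab-level learning-speed profile (tau, in trials); cycled over labs
    lab_tau_means: tuple = (1200.0, 1800.0, 2500.0, 3200.0, 4200.0, 5200.0, 2100.0)
    lab_tau_rel_sd: float = 0.35
    initial_scale: float = 0.15
    # cross-lab asymptote distribution (means / sds)
    lapse_mean: float = 0.0475
    lapse_sd: float = 0.018
    sigma_mean: float = 14.3
    sigma_sd: float = 3.8
    mu_mean: float = 0.3
    mu_sd: float = 8.4
    # per-lab mean shifts for injecting an artificial lab effect, e.g.
    # {"lab2": {"mu": 16.8}} shifts lab2's bias distribution by +16.8
    lab_asymptote_shift: dict = field(default_factory=dict)
    trials_mean: float = 719.0
    trials_sd: float = 223.0
    trials_lo: float = 50.0
    trials_hi: float = 1400.0
    duration_median: float = 0.468
    duration_sigma: float = 0.42
    p_repeat: float = 0.9


@dataclass
class CohortData:
    labs: list  # of LabProfile
    trials: pd.DataFrame  # concatenated trials tables, io schema
    ground_truth: dict  # mouse_id -> {"lab_id", "agent", "trajectory"}
    statuses: dict  # mouse_id -> status dict from the criteria engine
    config: CohortConfig

    @property
    def mouse_ids(self) -> list:
        return sorted(self.ground_truth)


def calibrate_visual_weights(target: PsychometricParams,
                             magnitudes: Sequence[float]) -> tuple[dict, float]:
    """Visual weights and bias that make a history-free logistic agent
    reproduce ``target``'s choice probabilities at the given contrasts.

    For each magnitude c:  W_c = [logit P(+c) - logit P(-c)] / 2, and the
    bias W_0 is the average of [logit P(+c) + logit P(-c)] / 2 over
    magnitudes.
    """
    mags = [m for m in magnitudes if m != 0.0]
    if not mags:
        raise ValueError("need at least one nonzero magnitude")
    if target.gamma >= 0.5 or target.lambda_ >= 0.5:
        raise ValueError("target lapses must be < 0.5")
    weights = {}
    biases = []
    for m in mags:
        p_pos = psych_eval(target, m)
        p_neg = psych_eval(target, -m)
        if p_pos in (0.0, 1.0) or p_neg in (0.0, 1.0):
            raise ValueError(f"target probability saturates at contrast {m}")
        weights[m] = float((logit(p_pos) - logit(p_neg)) / 2.0)
        biases.append(float((logit(p_pos) + logit(p_neg)) / 2.0))
    return weights, float(np.mean(biases))


def default_agent(variant: str = "basic",
                  asymptote: PsychometricParams = DEFAULT_ASYMPTOTE,
                  magnitudes: Sequence[float] = task_mod.ALL_CONTRASTS,
                  block_weight: float = DEFAULT_BLOCK_WEIGHT) -> AgentParams:
    """The package's default generative parameter set for a trained mouse."""
    vw, w0 = calibrate_visual_weights(asymptote, magnitudes)
    w_r, w_u = BASIC_HISTORY_WEIGHTS if variant == "basic" else FULL_HISTORY_WEIGHTS
    return AgentParams(visual_weights=vw, w_rewarded=w_r, w_unrewarded=w_u,
                       w_bias=w0,
                       w_block=block_weight if variant == "full" else None)


def agent_choice_prob(agent: AgentParams, signed_contrast: float,
                      prev, block_label: int = 0) -> float:
    """Probability of a rightward choice under the logistic history model."""
    z = agent.w_bias
    if signed_contrast != 0.0:
        m = abs(signed_contrast)
        if m not in agent.visual_weights:
            raise KeyError(f"no visual weight for contrast {m}")
        z += agent.visual_weights[m] * np.sign(signed_contrast)
    if prev is not None and prev.choice != 0:
        if prev.correct:
            z += agent.w_rewarded * prev.choice
        else:
            z += agent.w_unrewarded * prev.choice
    if agent.w_block is not None:
        z += agent.w_block * block_label
    return float(1.0 / (1.0 + np.exp(-z)))


def sample_trial_duration(rng: np.random.Generator, *, median: float = 0.468,
                          sigma: float = 0.42, floor: float = 0.05,
                          size=None):
    """Log-normal trial durations (stimulus onset to feedback), floored."""
    if sigma == 0.0:
        d = np.full(size if size is not None else (), median)
    else:
        d = np.exp(rng.normal(np.log(median), sigma, size=size))
    out = np.maximum(d, floor)
    return float(out) if size is None else out


def sample_session_length(rng: np.random.Generator, *, mean: float = 719.0,
                          sd: float = 223.0, lo: float = 50.0,
                          hi: float = 1400.0) -> int:
    """Empirical trials-per-session model: truncated normal 719 +- 223."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return int(round(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)))


def simulate_session(agent: AgentParams, stage: TrainingStage,
                     schedule: BlockSchedule, rng: np.random.Generator, *,
                     variant: str = "basic", n_trials: int = 700,
                     lab_id: str = "lab0", mouse_id: str = "m0",
                     session_day: int = 1, duration_median: float = 0.468,
                     duration_sigma: float = 0.42,
                     p_repeat: float = 0.9,
                     use_session_rules: bool = False,
                     max_mechanistic_trials: int = 5000) -> pd.DataFrame:
    """Simulate one session of sequential trials.

    Choices are Bernoulli draws from :func:`agent_choice_prob`; a trial is
    correct when the choice side matches the stimulus side (for 0%-contrast
    trials, a hidden side drawn from the block prior).

    By default the session runs exactly ``n_trials`` trials (the empirical
    trials-per-session model draws that budget).  With
    ``use_session_rules=True`` the session instead ends mechanistically via
    :func:`choicelab.task.should_end_session`, accumulating quiescence,
    trial durations and feedback intervals on a session clock.
    """
    cols = {k: [] for k in ("trial_index", "signed_contrast", "block_p_left",
                            "choice", "correct", "is_repeat",
                            "trial_duration_s")}
    prev = None
    budget = max_mechanistic_trials if use_session_rules else n_trials
    uni = rng.random(budget)
    elapsed = 0.0
    durations: list[float] = []
    for i in range(budget):
        p_left = schedule.p_left_at(i)
        spec = sample_trial_stimulus(stage, p_left, prev, rng,
                                     task_variant=variant, p_repeat=p_repeat)
        block_label = 1 if p_left == 0.2 else (-1 if p_left == 0.8 else 0)
        p_right = agent_choice_prob(agent, spec.signed_contrast, prev, block_label)
        choice = 1 if uni[i] < p_right else -1
        correct = int(choice == spec.stim_side)
        duration = sample_trial_duration(rng, median=duration_median,
                                         sigma=duration_sigma)
        cols["trial_index"].append(i + 1)
        cols["signed_contrast"].append(spec.signed_contrast)
        cols["block_p_left"].append(p_left)
        cols["choice"].append(choice)
        cols["correct"].append(correct)
        cols["is_repeat"].append(int(spec.is_repeat))
        cols["trial_duration_s"].append(duration)
        prev = _Prev(spec.signed_contrast, spec.stim_side, choice, correct)

        if use_session_rules:
            durations.append(duration)
            # feedback interval: ~0.5 s on reward, 2 s timeout on error
            elapsed += spec.quiescence_s + duration + (0.5 if correct else 2.0)
            baseline = (float(np.median(durations[:20]))
                        if len(durations) >= 20 else None)
            clock = task_mod.SessionClock(
                elapsed_s=elapsed, n_completed=i + 1,
                baseline_duration_s=baseline,
                rolling_durations=tuple(durations[-10:]))
            end, _reason = task_mod.should_end_session(clock)
            if end:
                break

    df = pd.DataFrame(cols)
    df.insert(0, "session_day", session_day)
    df.insert(0, "mouse_id", mouse_id)
    df.insert(0, "lab_id", lab_id)
    df["stage_id"] = stage.stage_id
    return df


def _draw_session_count(rng, cfg: CohortConfig) -> int:
    return sample_session_length(rng, mean=cfg.trials_mean, sd=cfg.trials_sd,
                                 lo=cfg.trials_lo, hi=cfg.trials_hi)


def simulate_training_course(trajectory: LearningTrajectory,
                             rng: np.random.Generator, max_days: int = 40, *,
                             lab_id: str = "lab0", mouse_id: str = "m0",
                             config: Optional[CohortConfig] = None,
                             continue_to_full: bool = False,
                             n_full_days: int = 3,
                             stop_at_proficiency: bool = True) -> dict:
    """Run a mouse through staged training, day by day.

    Visual weights grow along the saturating exponential of cumulative
    trials; the stage ladder follows :func:`advance_training_stage`.
    Returns a dict with the session tables, per-day summaries, and the
    proficiency status.
    """
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    cfg = config or CohortConfig()
    asym_agent = default_agent("basic", asymptote=trajectory.asymptote_params)
    sessions: list[pd.DataFrame] = []
    summaries: list = []
    briefs: list[SessionBrief] = []
    cum_trials = 0
    trained_day = None
    status = "in_training"

    for day in range(1, max_days + 1):
        stage = advance_training_stage(briefs)
        n = _draw_session_count(rng, cfg)
        # learning continues within the session: use the mid-session state
        agent = asym_agent.scaled(trajectory.scale_at(cum_trials + n / 2.0))
        schedule = build_session_schedule("basic", n, rng)
        trials = simulate_session(agent, stage, schedule, rng, variant="basic",
                                  n_trials=n, lab_id=lab_id, mouse_id=mouse_id,
                                  session_day=day,
                                  duration_median=cfg.duration_median,
                                  duration_sigma=cfg.duration_sigma,
                                  p_repeat=cfg.p_repeat)
        sessions.append(trials)
        summary = status_mod.summarize_session(trials)
        summaries.append(summary)
        briefs.append(SessionBrief(summary.n_trials, summary.perf_easy))
        cum_trials += n

        if trained_day is None and len(summaries) >= 3:
            prof = status_mod.evaluate_basic_proficiency(summaries, version="1a")
            if prof.status == "trained_1a":
                trained_day = day
                status = "trained_1a"
                if stop_at_proficiency and not continue_to_full:
                    break

    if trained_day is None:
        status = "not_trained"

    full_sessions: list[pd.DataFrame] = []
    if continue_to_full and trained_day is not None:
        full_agent = default_agent("full", asymptote=trajectory.asymptote_params)
        stage = stage_from_index(task_mod.TRAINED_STAGE_ID, gain=4.0,
                                 reward_volume=1.5, debias_active=False)
        day = trained_day
        for _ in range(n_full_days):
            day += 1
            n = _draw_session_count(rng, cfg)
            schedule = build_session_schedule("full", n, rng)
            trials = simulate_session(full_agent, stage, schedule, rng,
                                      variant="full", n_trials=n,
                                      lab_id=lab_id, mouse_id=mouse_id,
                                      session_day=day,
                                      duration_median=cfg.duration_median,
                                      duration_sigma=cfg.duration_sigma)
            full_sessions.append(trials)

    return {
        "sessions": sessions,
        "full_sessions": full_sessions,
        "summaries": summaries,
        "status": status,
        "days_to_proficiency": trained_day,
        "trials_to_proficiency": (
            int(sum(len(s) for s in sessions[:trained_day]))
            if trained_day is not None else None),
    }


def _timezone_groups(n_labs: int) -> list[str]:
    """Assign labs to timezone groups in fixed sizes {3, 2, 2} (cycled)."""
    pattern = [0, 0, 0, 1, 1, 2, 2]
    return [f"tz{pattern[i % len(pattern)]}" for i in range(n_labs)]


def _draw_asymptote(rng: np.random.Generator, cfg: CohortConfig,
                    shift: dict) -> PsychometricParams:
    gamma = float(np.clip(rng.normal(cfg.lapse_mean + shift.get("gamma", 0.0),
                                     cfg.lapse_sd), 0.005, 0.18))
    lam = float(np.clip(rng.normal(cfg.lapse_mean + shift.get("lambda_", 0.0),
                                   cfg.lapse_sd), 0.005, 0.18))
    sigma = float(np.clip(rng.normal(cfg.sigma_mean + shift.get("sigma", 0.0),
                                     cfg.sigma_sd), 5.0, 25.0))
    mu = float(np.clip(rng.normal(cfg.mu_mean + shift.get("mu", 0.0),
                                  cfg.mu_sd), -25.0, 25.0))
    return PsychometricParams(gamma=gamma, lambda_=lam, mu=mu, sigma=sigma)


def simulate_cohort(config: Optional[CohortConfig] = None,
                    rng: Optional[np.random.Generator] = None) -> CohortData:
    """Generate a multi-lab cohort.

    mode="training": every mouse runs the staged training course (slow but
    complete).  mode="trained_only": each mouse contributes three trained
    basic-task sessions (plus, with continue_to_full, three full-task
    sessions) directly at its asymptote, with days-to-proficiency derived
    from the learning trajectory; this is the fast path for trained-state
    analyses.
    """
    cfg = config or CohortConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if cfg.n_labs < 2 or cfg.n_mice_per_lab < 2:
        raise ValueError("need >= 2 labs and >= 2 mice per lab")

    tz = _timezone_groups(cfg.n_labs)
    labs = []
    for i in range(cfg.n_labs):
        mean_tau = cfg.lab_tau_means[i % len(cfg.lab_tau_means)]
        labs.append(LabProfile(lab_id=f"lab{i}", n_mice=cfg.n_mice_per_lab,
                               learning_rate_mean=mean_tau,
                               learning_rate_sd=cfg.lab_tau_rel_sd * mean_tau,
                               timezone_group=tz[i]))

    all_trials, ground_truth, statuses = [], {}, {}
    for lab in labs:
        shift = cfg.lab_asymptote_shift.get(lab.lab_id, {})
        for j in range(lab.n_mice):
            mouse_id = f"{lab.lab_id}_m{j:02d}"
            tau = float(np.clip(rng.normal(lab.learning_rate_mean,
                                           lab.learning_rate_sd), 200.0, 4e4))
            asym = _draw_asymptote(rng, cfg, shift)
            traj = LearningTrajectory(rate=tau, initial_scale=cfg.initial_scale,
                                      asymptote_params=asym)
            if cfg.mode == "training":
                course = simulate_training_course(
                    traj, rng, cfg.max_days, lab_id=lab.lab_id,
                    mouse_id=mouse_id, config=cfg,
                    continue_to_full=cfg.continue_to_full,
                    n_full_days=cfg.n_full_days)
                tables = course["sessions"] + course["full_sessions"]
                st = {
                    "status": course["status"],
                    "days_to_proficiency": course["days_to_proficiency"],
                    "trials_to_proficiency": course["trials_to_proficiency"],
                    "proficiency_days": (
                        list(range(course["days_to_proficiency"] - 2,
                                   course["days_to_proficiency"] + 1))
                        if course["days_to_proficiency"] else []),
                    "full_days": [int(t["session_day"].iloc[0])
                                  for t in course["full_sessions"]],
                }
            else:
                tables, st = _trained_only_course(traj, rng, cfg, lab, mouse_id)
            all_trials.extend(tables)
            ground_truth[mouse_id] = {"lab_id": lab.lab_id, "trajectory": traj,
                                      "agent": default_agent("basic", asymptote=asym)}
            statuses[mouse_id] = st

    trials = pd.concat(all_trials, ignore_index=True)
    return CohortData(labs=labs, trials=trials, ground_truth=ground_truth,
                      statuses=statuses, config=cfg)


def _trained_only_course(traj: LearningTrajectory, rng: np.random.Generator,
                         cfg: CohortConfig, lab: LabProfile,
                         mouse_id: str) -> tuple[list, dict]:
    """Three trained basic sessions (+ optional full sessions) at asymptote."""
    # analytic days-to-proficiency: first day whose cumulative-trial scale
    # exceeds 0.85, plus the three consecutive passing sessions
    scale_crit = 0.85
    t_star = -traj.rate * np.log((1.0 - scale_crit) / (1.0 - traj.initial_scale))
    days = int(np.ceil(t_star / cfg.trials_mean)) + 3
    days = max(3, days)
    trained = days <= cfg.max_days

    agent = default_agent("basic", asymptote=traj.asymptote_params)
    stage = stage_from_index(task_mod.TRAINED_STAGE_ID, gain=4.0,
                             reward_volume=1.5)
    tables = []
    prof_days = list(range(days - 2, days + 1))
    for day in prof_days:
        n = _draw_session_count(rng, cfg)
        schedule = build_session_schedule("basic", n, rng)
        tables.append(simulate_session(
            agent, stage, schedule, rng, variant="basic", n_trials=n,
            lab_id=lab.lab_id, mouse_id=mouse_id, session_day=day,
            duration_median=cfg.duration_median,
            duration_sigma=cfg.duration_sigma, p_repeat=cfg.p_repeat))

    full_days = []
    if cfg.continue_to_full:
        full_agent = default_agent("full", asymptote=traj.asymptote_params)
        full_stage = stage_from_index(task_mod.TRAINED_STAGE_ID, gain=4.0,
                                      reward_volume=1.5, debias_active=False)
        for k in range(cfg.n_full_days):
            day = days + 1 + k
            n = _draw_session_count(rng, cfg)
            schedule = build_session_schedule("full", n, rng)
            tables.append(simulate_session(
                full_agent, full_stage, schedule, rng, variant="full",
                n_trials=n, lab_id=lab.lab_id, mouse_id=mouse_id,
                session_day=day, duration_median=cfg.duration_median,
                duration_sigma=cfg.duration_sigma))
            full_days.append(day)

    st = {
        "status": "trained_1a" if trained else "not_trained",
        "days_to_proficiency": days if trained else None,
        "trials_to_proficiency": (int(days * cfg.trials_mean) if trained else None),
        "proficiency_days": prof_days if trained else [],
        "full_days": full_days,
    }
    return tables, st
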