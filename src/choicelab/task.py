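"""Trial-by-trial structure of the 2AFC wheel task.

Generates everything the rig decides independently of the animal: stimulus
contrasts and sides, block schedules of biased stimulus priors, debiasing
repeat trials, pre-trial quiescence periods, staged introduction of
contrasts during training, and session-ending rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ALL_CONTRASTS",
    "TrainingStage",
    "BlockSchedule",
    "TrialSpec",
    "SessionClock",
    "SessionBrief",
    "stage_from_index",
    "sample_block_lengths",
    "truncated_geometric_mean",
    "build_session_schedule",
    "sample_trial_stimulus",
    "sample_quiescence",
    "advance_training_stage",
    "should_end_session",
]

#: Full vocabulary of contrast magnitudes (percent).
ALL_CONTRASTS = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)

#: Contrast sets for each training stage, in order of introduction.
#: Stage 4 is the transient mid-training stage in which the 50% contrast is
#: dropped to boost low-contrast exposure; stage 5 (trained) restores it.
_STAGE_CONTRASTS: tuple[frozenset, ...] = (
    frozenset({50.0, 100.0}),
    frozenset({25.0, 50.0, 100.0}),
    frozenset({12.5, 25.0, 50.0, 100.0}),
    frozenset({0.0, 6.25, 12.5, 25.0, 50.0, 100.0}),
    frozenset({0.0, 6.25, 12.5, 25.0, 100.0}),
    frozenset({0.0, 6.25, 12.5, 25.0, 50.0, 100.0}),
)

N_STAGES = len(_STAGE_CONTRASTS)
TRAINED_STAGE_ID = N_STAGES - 1


@dataclass(frozen=True)
class TrainingStage:
    """One rung of the automated training ladder."""

    stage_id: int
    contrast_magnitudes: frozenset
    gain: float  # degrees of visual angle per mm of wheel travel
    reward_volume: float  # microlitres
    debias_active: bool = True

    def __post_init__(self) -> None:
        if not self.contrast_magnitudes <= set(ALL_CONTRASTS):
            raise ValueError(
                f"contrast magnitudes {sorted(self.contrast_magnitudes)} "
                f"not a subset of {ALL_CONTRASTS}"
            )
        if self.gain not in (8.0, 4.0):
            raise ValueError(f"gain must be 8 or 4 deg/mm, got {self.gain}")
        if not 1.5 <= self.reward_volume <= 3.0:
            raise ValueError(f"reward volume {self.reward_volume} outside [1.5, 3.0] uL")

    @property
    def all_contrasts_introduced(self) -> bool:
        return self.stage_id >= 3


def stage_from_index(stage_id: int, gain: float = 8.0, reward_volume: float = 3.0,
                     debias_active: bool = True) -> TrainingStage:
    """Build the :class:`TrainingStage` for a given ladder index."""
    if not 0 <= stage_id < N_STAGES:
        raise ValueError(f"stage_id must be in [0, {N_STAGES - 1}]")
    return TrainingStage(stage_id, _STAGE_CONTRASTS[stage_id], gain, reward_volume,
                         debias_active)


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered (p_left, length) blocks of a session."""

    blocks: tuple  # of (float, int)

    def p_left_at(self, trial_index: int) -> float:
        """Block prior for a 0-based trial index; last block extends forever."""
        i = trial_index
        for p_left, length in self.blocks:
            if i < length:
                return p_left
            i -= length
        return self.blocks[-1][0]


@dataclass(frozen=True)
class TrialSpec:
    """The rig's plan for one trial."""

    signed_contrast: float  # percent; negative = left, positive = right
    stim_side: int  # -1 left / +1 right; for 0% contrast, the hidden rewarded side
    p_left: float
    is_repeat: bool
    quiescence_s: float


@dataclass
class SessionClock:
    """Running state consulted by the session-ending rules."""

    elapsed_s: float = 0.0
    n_completed: int = 0
    baseline_duration_s: Optional[float] = None
    rolling_durations: tuple = ()


@dataclass(frozen=True)
class SessionBrief:
    """Minimal per-session record driving stage advancement."""

    n_trials: int
    perf_easy: float  # fraction correct on |contrast| >= 50%


def truncated_geometric_mean(p: float, lo: int, hi: int) -> float:
    """Exact mean of a geometric({1,2,...}) variable conditioned on [lo, hi]."""
    q = 1.0 - p
    m = hi - lo + 1
    # shifted support {1..m}: mean = 1/p - m q^m / (1 - q^m)
    qm = q ** m
    return (lo - 1) + 1.0 / p - m * qm / (1.0 - qm)


def truncated_geometric_pmf(p: float, lo: int, hi: int) -> np.ndarray:
    """Renormalized pmf of the geometric distribution on {lo..hi}."""
    k = np.arange(lo, hi + 1)
    logpmf = (k - 1) * np.log1p(-p) + np.log(p)
    pmf = np.exp(logpmf - logpmf.max())
    return pmf / pmf.sum()


def sample_block_lengths(n: int, p: float, lo: int, hi: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` biased-block lengths from a truncated geometric distribution.

    The geometric distribution on {1, 2, ...} with success probability ``p``
    is conditioned on the interval [lo, hi] (renormalized pmf — equivalent to
    rejection sampling, NOT clipping).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    if lo < 1:
        raise ValueError("lo must be >= 1")
    if not 0.0 < p < 1.0:
        if p >= 1.0 and lo > 1:
            raise ValueError("geometric with p >= 1 has no mass on [lo, hi] with lo > 1")
        raise ValueError(f"p must be in (0, 1), got {p}")
    pmf = truncated_geometric_pmf(p, lo, hi)
    return rng.choice(np.arange(lo, hi + 1), size=n, p=pmf)


def build_session_schedule(task_variant: str, max_trials: int,
                           rng: np.random.Generator, *,
                           p_geometric: float = 1.0 / 60.0,
                           block_min: int = 20, block_max: int = 100,
                           first_block_len: int = 90) -> BlockSchedule:
    """Lay out the block structure covering at least ``max_trials`` trials.

    Full task: one 90-trial unbiased block, then biased blocks that strictly
    alternate between p_left = 0.8 and 0.2 (first side uniform at random),
    with truncated-geometric lengths.  Basic task: a single unbiased block.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    if task_variant == "basic":
        return BlockSchedule(((0.5, max_trials),))
    if task_variant != "full":
        raise ValueError(f"unknown task variant {task_variant!r}")

    blocks = [(0.5, first_block_len)]
    total = first_block_len
    p_left = 0.8 if rng.random() < 0.5 else 0.2
    while total < max_trials:
        length = int(sample_block_lengths(1, p_geometric, block_min, block_max, rng)[0])
        blocks.append((p_left, length))
        total += length
        p_left = 0.2 if p_left == 0.8 else 0.8  # exact constants, no float drift
    return BlockSchedule(tuple(blocks))


def _magnitude_weights(magnitudes: Sequence[float], task_variant: str) -> np.ndarray:
    """Sampling weight per contrast magnitude.

    Signed-stimulus-uniform baseline: each nonzero magnitude can appear on
    two sides so carries weight 2, the zero-contrast stimulus weight 1.  In
    the full task the zero weight is doubled so that P(0%) matches each
    nonzero magnitude.
    """
    w = np.array([1.0 if m == 0.0 else 2.0 for m in magnitudes])
    if task_variant == "full":
        w[np.asarray(magnitudes) == 0.0] = 2.0
    return w / w.sum()


def sample_trial_stimulus(stage: TrainingStage, block_p_left: float,
                          prev, rng: np.random.Generator, *,
                          task_variant: str = "basic",
                          p_repeat: float = 0.9) -> TrialSpec:
    """Draw the stimulus plan for the next trial.

    ``prev`` is the previous trial's record (any object with
    ``signed_contrast``, ``stim_side`` and ``correct`` attributes) or None.
    If debiasing is active and the previous response was an error on an easy
    (|contrast| >= 50%) trial, the same stimulus is repeated with
    probability ``p_repeat``.
    """
    magnitudes = sorted(stage.contrast_magnitudes)
    if not magnitudes:
        raise ValueError("stage has an empty contrast set")

    quiescence = sample_quiescence(rng)

    if (stage.debias_active and task_variant == "basic" and prev is not None
            and not prev.correct and abs(prev.signed_contrast) >= 50.0
            and rng.random() < p_repeat):
        return TrialSpec(prev.signed_contrast, prev.stim_side, block_p_left,
                         True, quiescence)

    weights = _magnitude_weights(magnitudes, task_variant)
    magnitude = float(rng.choice(magnitudes, p=weights))
    side = -1 if rng.random() < block_p_left else 1
    return TrialSpec(magnitude * side, side, block_p_left, False, quiescence)


def sample_quiescence(rng: np.random.Generator, *, mean_s: float = 0.55,
                      lo_s: float = 0.4, hi_s: float = 0.7) -> float:
    """Pre-trial hold period: Exp(mean 550 ms), rejected until in [0.4, 0.7] s."""
    while True:
        x = rng.exponential(mean_s)
        if lo_s <= x <= hi_s:
            return x


def advance_training_stage(history: Sequence[SessionBrief], *,
                           advance_perf: float = 0.7,
                           trained_perf: float = 0.8,
                           gain_trial_threshold: int = 200,
                           reward_decrement: float = 0.25) -> TrainingStage:
    """Deterministic stage for the *next* session given past session briefs.

    Contrast ladder: one step per past session with easy-trial performance
    above ``advance_perf``, up to the dropped-50% stage; the trained stage
    (50% restored) unlocks once the three latest sessions all exceed
    ``trained_perf``.  The wheel gain halves (8 -> 4 deg/mm) after the first
    session with more than ``gain_trial_threshold`` completed trials, and the
    reward volume steps down from 3.0 uL by ``reward_decrement`` per
    qualifying session, floored at 1.5 uL.
    """
    qualifying = sum(1 for s in history if s.n_trials > gain_trial_threshold)
    gain = 4.0 if qualifying >= 1 else 8.0
    reward = max(1.5, 3.0 - reward_decrement * qualifying)

    # each passing session climbs one rung; an excellent one (perf > 0.9)
    # climbs two, letting the fastest mice see every contrast by session 3
    steps = sum((2 if s.perf_easy > 0.9 else 1)
                for s in history if s.perf_easy > advance_perf)
    stage_id = min(steps, TRAINED_STAGE_ID - 1)
    if stage_id == TRAINED_STAGE_ID - 1 and any(
            all(s.perf_easy > trained_perf for s in history[i:i + 3])
            for i in range(len(history) - 2)):
        stage_id = TRAINED_STAGE_ID  # sticky: stages never regress
    return stage_from_index(stage_id, gain=gain, reward_volume=reward)


def should_end_session(clock: SessionClock, *,
                       session_max_min: float = 90.0,
                       low_count_min: float = 45.0,
                       low_count_threshold: int = 400,
                       slowdown_factor: float = 5.0,
                       rolling_window: int = 10) -> tuple[bool, Optional[str]]:
    """Session-ending rules, evaluated in priority order.

    1. "max_time":       >= 90 min elapsed.
    2. "low_count":      >= 45 min elapsed with fewer than 400 completed trials.
    3. "slow_responses": rolling median of the last 10 trial durations exceeds
                         5x the session's baseline duration (rule inactive
                         until a baseline and a full window exist).
    """
    if clock.elapsed_s >= session_max_min * 60.0:
        return True, "max_time"
    if clock.elapsed_s >= low_count_min * 60.0 and clock.n_completed < low_count_threshold:
        return True, "low_count"
    if (clock.baseline_duration_s is not None
            and len(clock.rolling_durations) >= rolling_window):
        recent = np.median(np.asarray(clock.rolling_durations[-rolling_window:]))
        if recent > slowdown_factor * clock.baseline_duration_s:
            return True, "slow_responses"
    return False, None
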