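"""Automated training-proficiency criteria and cohort learning summaries.

Two consecutive criteria sets declare basic-task proficiency ("1a", "1b"),
each requiring three consecutive passing sessions; a separate set declares
full-task proficiency from three full-task sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .psychometrics import PsychometricParams, fit_psychometric_trials

__all__ = [
    "SessionSummary",
    "ProficiencyStatus",
    "CRITERIA",
    "summarize_session",
    "evaluate_basic_proficiency",
    "evaluate_full_proficiency",
    "training_summary",
]

# Basic-task criteria thresholds, version 1a / 1b.  All comparisons strict,
# matching the printed "<" / ">" symbols.
CRITERIA = {
    "1a": {"n_trials": 200, "perf_easy": 0.80, "abs_bias": 16.0,
           "threshold": 19.0, "lapse": 0.2, "lapse_rule": "sum",
           "rt_zero_max": None},
    "1b": {"n_trials": 400, "perf_easy": 0.90, "abs_bias": 10.0,
           "threshold": 20.0, "lapse": 0.1, "lapse_rule": "each",
           "rt_zero_max": 2.0},
}


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    perf_easy: float  # fraction correct on |contrast| >= 50 (no-response = wrong)
    fit: Optional[PsychometricParams]
    median_rt_zero: Optional[float]  # median duration on 0%-contrast trials
    all_contrasts: bool = True  # stage had introduced every contrast level
    n_trial_types: int = 0  # distinct signed contrasts shown
    perf_100: Optional[float] = None  # fraction correct at |contrast| = 100
    is_full_task: bool = False
    session_day: Optional[int] = None


@dataclass(frozen=True)
class ProficiencyStatus:
    status: str  # in_training | trained_1a | trained_1b | full_proficient | not_trained
    day_reached: Optional[int]
    reasons: dict = field(default_factory=dict)


def summarize_session(trials: pd.DataFrame) -> SessionSummary:
    """Per-session metrics feeding the criteria engine.

    No-response trials (choice == 0) count as incorrect.  The psychometric
    fit is omitted when the session has fewer than two distinct contrasts.
    """
    if len(trials) == 0:
        raise ValueError("empty trials table")
    c = trials["signed_contrast"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy()

    easy = np.abs(c) >= 50.0
    perf_easy = float(correct[easy].mean()) if easy.any() else 0.0
    hardest = np.abs(c) == 100.0
    perf_100 = float(correct[hardest].mean()) if hardest.any() else None

    zero = np.abs(c) == 0.0
    median_rt_zero = (float(trials.loc[zero, "trial_duration_s"].median())
                      if zero.any() else None)

    n_types = len(np.unique(c))
    fit = None
    if n_types >= 2:
        fit = fit_psychometric_trials(trials).params

    all_contrasts = True
    if "stage_id" in trials.columns:
        all_contrasts = bool(trials["stage_id"].iloc[0] >= 3)

    is_full = bool((trials["block_p_left"] != 0.5).any()) \
        if "block_p_left" in trials.columns else False
    day = int(trials["session_day"].iloc[0]) if "session_day" in trials.columns else None
    return SessionSummary(n_trials=len(trials), perf_easy=perf_easy, fit=fit,
                          median_rt_zero=median_rt_zero,
                          all_contrasts=all_contrasts, n_trial_types=n_types,
                          perf_100=perf_100, is_full_task=is_full,
                          session_day=day)


def _session_passes(s: SessionSummary, crit: dict) -> dict:
    checks = {
        "n_trials": s.n_trials > crit["n_trials"],
        "perf_easy": s.perf_easy > crit["perf_easy"],
        "fit_available": s.fit is not None,
    }
    if s.fit is not None:
        # bias/threshold are only identifiable once the session shows six or
        # more trial types (low contrasts present); before that the checks
        # pass vacuously
        identifiable = s.n_trial_types >= 6
        checks["bias"] = (abs(s.fit.mu) < crit["abs_bias"]) or not identifiable
        checks["threshold"] = (s.fit.sigma < crit["threshold"]) or not identifiable
        if crit["lapse_rule"] == "sum":
            checks["lapse"] = (s.fit.gamma + s.fit.lambda_) < crit["lapse"]
        else:
            checks["lapse"] = (s.fit.gamma < crit["lapse"]
                               and s.fit.lambda_ < crit["lapse"])
    return checks


def evaluate_basic_proficiency(last_sessions: Sequence[SessionSummary],
                               version: str = "1a", *,
                               lapse_rule: Optional[str] = None
                               ) -> ProficiencyStatus:
    """Apply the 1a / 1b criteria to the three most recent sessions.

    Trained iff all three consecutive sessions pass every per-session check;
    for 1b, additionally the median across the three sessions of the
    0%-contrast median reaction time must be below 2 s.
    """
    if version not in CRITERIA:
        raise ValueError(f"unknown criteria version {version!r}")
    crit = dict(CRITERIA[version])
    if lapse_rule is not None:
        crit["lapse_rule"] = lapse_rule
    if len(last_sessions) < 3:
        return ProficiencyStatus("in_training", None,
                                 {"insufficient_sessions": False})

    window = list(last_sessions)[-3:]
    reasons: dict = {}
    # the stage precondition (every contrast level introduced) applies to
    # the mouse's current state, i.e. the most recent session
    reasons["all_contrasts"] = bool(window[-1].all_contrasts)
    for i, s in enumerate(window):
        for name, ok in _session_passes(s, crit).items():
            reasons[f"session{i}:{name}"] = bool(ok)

    if crit["rt_zero_max"] is not None:
        rts = [s.median_rt_zero for s in window if s.median_rt_zero is not None]
        reasons["median_rt_zero"] = bool(
            len(rts) > 0 and float(np.median(rts)) < crit["rt_zero_max"])

    passed = all(reasons.values())
    status = f"trained_{version}" if passed else "in_training"
    day = window[-1].session_day if passed else None
    return ProficiencyStatus(status, day, reasons)


def evaluate_full_proficiency(sessions: Sequence[pd.DataFrame], *,
                              rt_rule: str = "below",
                              bias_shift_min: float = 5.0) -> ProficiencyStatus:
    """Full-task proficiency from three full-task sessions.

    Per session: >= 400 trials and >= 90% correct on 100%-contrast trials.
    Pooling all three sessions: left and right lapses below 0.1 within each
    biased block type; between-block psychometric bias shift
    |mu_2080 - mu_8020| above 5; and the 0%-contrast median-reaction-time
    criterion (default "below" 2 s; rt_rule="above" keeps the literal
    protocol wording).
    """
    if len(sessions) != 3:
        raise ValueError("full-task proficiency is assessed on exactly 3 sessions")
    for t in sessions:
        if not (t["block_p_left"] != 0.5).any():
            raise ValueError("received a session with no biased blocks "
                             "(not a full-task session)")
    reasons: dict = {}
    for i, t in enumerate(sessions):
        c = t["signed_contrast"].to_numpy(dtype=float)
        hard = np.abs(c) == 100.0
        perf100 = float(t["correct"].to_numpy()[hard].mean()) if hard.any() else 0.0
        reasons[f"session{i}:n_trials"] = bool(len(t) >= 400)
        reasons[f"session{i}:perf_100"] = bool(perf100 >= 0.90)

    pooled = pd.concat(sessions, ignore_index=True)
    mus = {}
    for label, p_left in (("2080", 0.2), ("8020", 0.8)):
        blk = pooled[pooled["block_p_left"] == p_left]
        fit = fit_psychometric_trials(blk).params
        mus[label] = fit.mu
        reasons[f"lapse_left_{label}"] = bool(fit.gamma < 0.1)
        reasons[f"lapse_right_{label}"] = bool(fit.lambda_ < 0.1)
    reasons["bias_shift"] = bool(abs(mus["2080"] - mus["8020"]) > bias_shift_min)

    zero = pooled[np.abs(pooled["signed_contrast"]) == 0.0]
    med_rt = float(zero["trial_duration_s"].median()) if len(zero) else None
    if med_rt is None:
        reasons["median_rt_zero"] = False
    elif rt_rule == "below":
        reasons["median_rt_zero"] = bool(med_rt < 2.0)
    else:
        reasons["median_rt_zero"] = bool(med_rt > 2.0)

    passed = all(reasons.values())
    day = int(sessions[-1]["session_day"].iloc[0]) if passed and \
        "session_day" in sessions[-1].columns else None
    return ProficiencyStatus("full_proficient" if passed else "in_training",
                             day, reasons)


def training_summary(cohort) -> dict:
    """Cohort learning summaries.

    Returns per-mouse days/trials to proficiency, per-lab median/quartiles,
    and the product-limit (Kaplan-Meier) cumulative proportion trained by
    training day, censoring non-learners at their last training day.
    """
    rows = []
    for mouse_id, st in cohort.statuses.items():
        lab = cohort.ground_truth[mouse_id]["lab_id"]
        days = st.get("days_to_proficiency")
        trained = days is not None
        if trained:
            observed_day = days
        else:
            mouse_trials = cohort.trials[cohort.trials["mouse_id"] == mouse_id]
            observed_day = int(mouse_trials["session_day"].max())
        rows.append({"mouse_id": mouse_id, "lab_id": lab, "trained": trained,
                     "days_to_proficiency": days,
                     "trials_to_proficiency": st.get("trials_to_proficiency"),
                     "observed_day": observed_day})
    per_mouse = pd.DataFrame(rows)

    kmf = KaplanMeierFitter()
    kmf.fit(per_mouse["observed_day"], event_observed=per_mouse["trained"])
    km = pd.DataFrame({
        "day": kmf.survival_function_.index.to_numpy(dtype=float),
        "cum_proportion_trained":
            1.0 - kmf.survival_function_.iloc[:, 0].to_numpy(),
    })

    trained_rows = per_mouse[per_mouse["trained"]]
    per_lab = trained_rows.groupby("lab_id")["days_to_proficiency"].describe(
        percentiles=[0.25, 0.5, 0.75])[["count", "25%", "50%", "75%"]]
    overall = {
        "mean_days": float(trained_rows["days_to_proficiency"].mean())
        if len(trained_rows) else np.nan,
        "n_trained": int(trained_rows.shape[0]),
        "n_total": int(per_mouse.shape[0]),
    }
    return {"per_mouse": per_mouse, "per_lab": per_lab,
            "kaplan_meier": km, "overall": overall}
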