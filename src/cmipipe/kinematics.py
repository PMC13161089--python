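"""Reach-trial kinematic scoring.

Turns sampled finger/cursor trajectories into the seven outcome measures
of a center-out visuomotor task:

1. RT   — reaction time, go cue to movement onset (ms)
2. MTf  — full movement time, onset to final offset (ms)
3. PV   — peak tangential velocity of the ballistic movement (mm/ms)
4. PLb / PLf — ballistic and full path lengths (mm)
5. AE   — absolute error: distance of the mean endpoint from the target
6. VE   — variable error: dispersion of endpoints about their own mean
7. %DR  — percentage of direction-reversal trials (initial movement more
          than 45 deg off the straight line to the target)

Movement onsets and ballistic offsets are scored at 10 % of peak
velocity; the full offset is the final 10 %-of-peak crossing after which
the position plateaus within the peripheral target.  Trials violating
any of four timing filters (left home early, RT < 150 ms, RT > 8,000 ms,
MTf > 10,000 ms) are errors and carry no kinematic outcomes.  Session
summaries drop trials deviating more than 2 SD from the participant mean
on any outcome (single pass), and cohort-level composites average
within-condition z-scores: timing = mean(z_RT, z_MTf, -z_PV),
trajectory = mean(z_PLf, z_AE, z_VE).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .inference import zscore
from .synthetic import DIRECTIONS, TaskGeometry, TrialRecord

__all__ = [
    "ErrorCode",
    "ErrorFilters",
    "VelocityProfile",
    "MovementMarks",
    "TrialOutcomes",
    "SessionSummary",
    "compute_velocity_profile",
    "score_marks",
    "classify_error",
    "classify_direction_reversal",
    "score_trial",
    "summarize_session",
    "score_cohort",
    "compute_composites",
    "cronbach_alpha",
]

OUTCOME_COLS = ["RT", "MTf", "PV", "PLb", "PLf"]


class ErrorCode(Enum):
    NONE = "none"
    LEFT_HOME_EARLY = "left_home_early"
    RT_TOO_SHORT = "rt_too_short"
    RT_TOO_LONG = "rt_too_long"
    MT_TOO_LONG = "mt_too_long"
    UNSCORABLE = "unscorable"


@dataclass(frozen=True)
class ErrorFilters:
    """Timing filters; a trial violating any is an error trial."""

    hold_ms: float = 2000.0
    rt_min_ms: float = 150.0
    rt_max_ms: float = 8000.0
    mt_max_ms: float = 10000.0


@dataclass
class VelocityProfile:
    t: np.ndarray
    speed: np.ndarray
    pv: float
    peak_index: int


@dataclass
class MovementMarks:
    onset_idx: int
    ballistic_offset_idx: int
    full_offset_idx: int
    onset_ms: float
    ballistic_offset_ms: float
    full_offset_ms: float


@dataclass
class TrialOutcomes:
    participant: str
    condition: str
    trial: int
    target: str
    is_error: bool
    error_code: ErrorCode
    is_dr: bool
    RT: float = np.nan
    MTf: float = np.nan
    PV: float = np.nan
    PLb: float = np.nan
    PLf: float = np.nan
    endpoint_x: float = np.nan
    endpoint_y: float = np.nan


@dataclass
class SessionSummary:
    participant: str
    condition: str
    means: dict
    sds: dict
    AE: float
    VE: float
    pct_DR: float
    n_valid: int
    n_error: int
    n_trimmed: int
    n_dr: int


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    pad = window // 2
    xp = np.pad(x, (pad, window - 1 - pad), mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def compute_velocity_profile(
    trial: TrialRecord, smoothing: int = 5
) -> VelocityProfile:
    """Resultant tangential speed via central differences.

    Positions are smoothed with a moving average before differentiation
    (raw differencing of tablet data produces spurious threshold
    crossings); ``smoothing=1`` disables it.
    """
    t = np.asarray(trial.t_ms, dtype=float)
    if t.size < 3:
        raise ValueError("trial too short to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps")
    x = _moving_average(np.asarray(trial.x_mm, dtype=float), smoothing)
    y = _moving_average(np.asarray(trial.y_mm, dtype=float), smoothing)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    peak = int(np.argmax(speed))
    return VelocityProfile(t=t, speed=speed, pv=float(speed[peak]), peak_index=peak)


def _cross_time(t0, t1, v0, v1, thr) -> float:
    # linear interpolation of the threshold crossing, clamped to the
    # sample interval (near-equal speeds would otherwise extrapolate)
    if v1 == v0:
        return t1
    return float(np.clip(t0 + (thr - v0) * (t1 - t0) / (v1 - v0), t0, t1))


def score_marks(
    profile: VelocityProfile,
    trial: TrialRecord,
    geometry: TaskGeometry | None = None,
    plateau_tol_mm: float = 2.0,
) -> MovementMarks:
    """Movement onset and offsets at 10 % of peak velocity.

    Onset: first upward crossing of 0.1*PV after the go cue — the start
    of the initial (ballistic) movement, which on a direction-reversal
    trial is the wrong-direction excursion rather than the later, larger
    corrective movement.  Ballistic offset: the first downward crossing
    after the onset, i.e. the end of that first supra-threshold burst.
    Full offset: the final downward crossing after which every sample
    stays within (target radius + plateau_tol) of the trial's terminal
    position — the operational reading of "plateaued within the
    peripheral target".  Crossing times are interpolated between samples;
    indices are reported at the nearest scored sample.
    """
    geometry = geometry or TaskGeometry()
    v = profile.speed
    t = profile.t
    pv = profile.pv
    if pv <= 0:
        raise ValueError("no movement: peak velocity is zero")
    thr = 0.10 * pv
    start = 0
    if trial.go_cue_ms is not None:
        start = int(np.searchsorted(t, trial.go_cue_ms))
    up = np.flatnonzero((v[start:-1] < thr) & (v[start + 1 :] >= thr)) + start
    if up.size == 0:
        if v[start] >= thr:
            up = np.array([max(start - 1, 0)])  # already moving at the cue
        else:
            raise ValueError("speed never crosses the onset threshold")
    i0 = int(up[0])
    onset_ms = _cross_time(t[i0], t[i0 + 1], v[i0], v[i0 + 1], thr)

    after = np.flatnonzero((v[i0 + 1 : -1] >= thr) & (v[i0 + 2 :] < thr)) + i0 + 1
    if after.size == 0:
        after = np.array([v.size - 2])
    bo = int(after[0])
    ballistic_ms = _cross_time(t[bo], t[bo + 1], v[bo], v[bo + 1], thr)

    pos = trial.positions
    terminal = pos[-1]
    radius = geometry.target_radius + plateau_tol_mm
    full = None
    for cand in after[::-1]:
        tail = pos[cand + 1 :]
        if tail.size == 0 or np.all(np.linalg.norm(tail - terminal, axis=1) <= radius):
            full = int(cand)
            break
    if full is None:
        full = int(after[-1])
    full_ms = _cross_time(t[full], t[full + 1], v[full], v[full + 1], thr)
    return MovementMarks(
        onset_idx=i0 + 1,
        ballistic_offset_idx=bo + 1,
        full_offset_idx=full + 1,
        onset_ms=float(onset_ms),
        ballistic_offset_ms=float(ballistic_ms),
        full_offset_ms=float(full_ms),
    )


def _left_home_early(trial: TrialRecord, geometry: TaskGeometry) -> bool:
    pos = trial.positions
    pre_go = trial.t_ms < trial.go_cue_ms
    return bool(
        np.any(
            np.linalg.norm(pos[pre_go] - pos[0], axis=1)
            > geometry.central_radius + 1.0
        )
    )


def classify_error(
    trial: TrialRecord,
    marks: MovementMarks,
    filters: ErrorFilters | None = None,
    geometry: TaskGeometry | None = None,
) -> ErrorCode:
    """First violated timing filter, in the stated order; NONE if clean."""
    filters = filters or ErrorFilters()
    geometry = geometry or TaskGeometry()
    if _left_home_early(trial, geometry):
        return ErrorCode.LEFT_HOME_EARLY
    rt = marks.onset_ms - trial.go_cue_ms
    if rt < filters.rt_min_ms:
        return ErrorCode.RT_TOO_SHORT
    if rt > filters.rt_max_ms:
        return ErrorCode.RT_TOO_LONG
    if marks.full_offset_ms - marks.onset_ms > filters.mt_max_ms:
        return ErrorCode.MT_TOO_LONG
    return ErrorCode.NONE


def classify_direction_reversal(
    trial: TrialRecord,
    marks: MovementMarks,
    geometry: TaskGeometry | None = None,
    space: str = "cursor",
) -> bool:
    """Direction reversal: initial movement > 45 deg off the target line.

    The trajectory from onset is walked until it first exits the central
    target region; the angle between (exit - start) and (target - start)
    flags a reversal when strictly greater than 45 deg.  Assessed in
    cursor space by default (the behavioral goal is cursor-to-target);
    ``space='finger'`` uses the finger trace instead.
    """
    geometry = geometry or TaskGeometry()
    if space == "cursor":
        pos = trial.positions
    elif space == "finger":
        pos = np.column_stack([trial.finger_x_mm, trial.finger_y_mm])
    else:
        raise ValueError("space must be 'cursor' or 'finger'")
    start = pos[marks.onset_idx]
    disp = np.linalg.norm(pos[marks.onset_idx :] - start, axis=1)
    out = np.flatnonzero(disp > geometry.central_radius)
    if out.size == 0:
        raise ValueError("trial never exits the central target")
    exit_vec = pos[marks.onset_idx + out[0]] - start
    goal_vec = geometry.target_position(trial.target) - start
    cosang = float(
        np.dot(exit_vec, goal_vec)
        / (np.linalg.norm(exit_vec) * np.linalg.norm(goal_vec))
    )
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return angle > 45.0 + 1e-9  # strict: exactly 45 deg is not a reversal


def _path_length(pos: np.ndarray, i0: int, i1: int) -> float:
    seg = pos[i0 : i1 + 1]
    return float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))


def score_trial(
    trial: TrialRecord,
    geometry: TaskGeometry | None = None,
    filters: ErrorFilters | None = None,
    smoothing: int = 5,
    dr_space: str = "cursor",
) -> TrialOutcomes:
    """Score one trial into its kinematic outcomes.

    Error trials (timing-filter violations, or unscorable trajectories)
    carry the error flag and no kinematic outcomes.  Direction-reversal
    trials are flagged and scored, to be analyzed separately from the
    correct trials.
    """
    geometry = geometry or TaskGeometry()
    base = dict(
        participant=trial.participant,
        condition=trial.condition,
        trial=trial.trial,
        target=trial.target,
    )
    # the home-hold violation is detectable without velocity marks, and
    # early-movement trials are often unscorable by the mark rules anyway
    if _left_home_early(trial, geometry):
        return TrialOutcomes(
            **base, is_error=True, error_code=ErrorCode.LEFT_HOME_EARLY, is_dr=False
        )
    try:
        prof = compute_velocity_profile(trial, smoothing=smoothing)
        marks = score_marks(prof, trial, geometry)
    except ValueError:
        return TrialOutcomes(
            **base, is_error=True, error_code=ErrorCode.UNSCORABLE, is_dr=False
        )
    code = classify_error(trial, marks, filters, geometry)
    if code is not ErrorCode.NONE:
        return TrialOutcomes(**base, is_error=True, error_code=code, is_dr=False)
    try:
        is_dr = classify_direction_reversal(trial, marks, geometry, space=dr_space)
    except ValueError:
        return TrialOutcomes(
            **base, is_error=True, error_code=ErrorCode.UNSCORABLE, is_dr=False
        )
    pos = trial.positions
    # PV is the ballistic-movement maximum; the endpoint is the mean
    # position over the terminal plateau (from the full offset on), which
    # is robust to sensor jitter on any single sample.
    pv_ballistic = float(
        prof.speed[marks.onset_idx : marks.ballistic_offset_idx + 1].max()
    )
    endpoint = pos[marks.full_offset_idx :].mean(axis=0)
    return TrialOutcomes(
        **base,
        is_error=False,
        error_code=ErrorCode.NONE,
        is_dr=is_dr,
        RT=marks.onset_ms - trial.go_cue_ms,
        MTf=marks.full_offset_ms - marks.onset_ms,
        PV=pv_ballistic,
        PLb=_path_length(pos, marks.onset_idx, marks.ballistic_offset_idx),
        PLf=_path_length(pos, marks.onset_idx, marks.full_offset_idx),
        endpoint_x=float(endpoint[0]),
        endpoint_y=float(endpoint[1]),
    )


def summarize_session(
    outcomes: list[TrialOutcomes],
    geometry: TaskGeometry | None = None,
    trim_k: float = 2.0,
) -> SessionSummary:
    """Per-participant, per-condition summary with 2-SD trimming.

    A correct trial is dropped when ANY of its outcomes deviates more
    than ``trim_k`` SD from the participant-condition mean (one pass, no
    iteration).  AE is the distance from the mean endpoint to the true
    target location, averaged over targets; VE is the root mean squared
    distance of endpoints from their per-target mean (pooled, so units
    stay in mm).  %DR uses all non-error attempts as the denominator.
    """
    geometry = geometry or TaskGeometry()
    if not outcomes:
        raise ValueError("empty session")
    participant = outcomes[0].participant
    condition = outcomes[0].condition
    errors = [o for o in outcomes if o.is_error]
    scored = [o for o in outcomes if not o.is_error]
    dr = [o for o in scored if o.is_dr]
    correct = [o for o in scored if not o.is_dr]
    if len(correct) < 2:
        raise ValueError("degenerate session: fewer than 2 correct trials")

    mat = np.array([[getattr(o, c) for c in OUTCOME_COLS] for o in correct])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        dev = np.abs(mat - mean) > trim_k * np.where(sd > 0, sd, np.inf)
    keep = ~dev.any(axis=1)
    if not keep.any():
        raise ValueError("degenerate session: all trials trimmed")
    kept = [o for o, k in zip(correct, keep) if k]
    kmat = mat[keep]

    # endpoint accuracy/precision, per target then pooled
    ae_terms, ve_sq = [], []
    for tgt in sorted({o.target for o in kept}):
        eps = np.array(
            [[o.endpoint_x, o.endpoint_y] for o in kept if o.target == tgt]
        )
        mean_ep = eps.mean(axis=0)
        ae_terms.append(np.linalg.norm(mean_ep - geometry.target_position(tgt)))
        ve_sq.extend(np.sum((eps - mean_ep) ** 2, axis=1))
    AE = float(np.mean(ae_terms))
    VE = float(np.sqrt(np.mean(ve_sq)))

    return SessionSummary(
        participant=participant,
        condition=condition,
        means={c: float(m) for c, m in zip(OUTCOME_COLS, kmat.mean(axis=0))},
        sds={c: float(s) for c, s in zip(OUTCOME_COLS, kmat.std(axis=0, ddof=1))},
        AE=AE,
        VE=VE,
        pct_DR=100.0 * len(dr) / len(scored),
        n_valid=len(scored),
        n_error=len(errors),
        n_trimmed=int((~keep).sum()),
        n_dr=len(dr),
    )


def score_cohort(
    trials: list[TrialRecord],
    geometry: TaskGeometry | None = None,
    filters: ErrorFilters | None = None,
    smoothing: int = 5,
    trim_k: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every trial and summarize every participant x condition.

    Returns (per-trial outcomes, per-session summaries) as DataFrames.
    """
    geometry = geometry or TaskGeometry()
    outs = [score_trial(t, geometry, filters, smoothing) for t in trials]
    trial_df = pd.DataFrame(
        [
            {
                "participant": o.participant,
                "condition": o.condition,
                "trial": o.trial,
                "target": o.target,
                "is_error": o.is_error,
                "error_code": o.error_code.value,
                "is_dr": o.is_dr,
                **{c: getattr(o, c) for c in OUTCOME_COLS},
                "endpoint_x": o.endpoint_x,
                "endpoint_y": o.endpoint_y,
            }
            for o in outs
        ]
    )
    rows = []
    for (pid, cond), _ in trial_df.groupby(["participant", "condition"]):
        sess = [
            o for o in outs if o.participant == pid and o.condition == cond
        ]
        s = summarize_session(sess, geometry, trim_k)
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                **{c: s.means[c] for c in OUTCOME_COLS},
                "AE": s.AE,
                "VE": s.VE,
                "pct_DR": s.pct_DR,
                "n_valid": s.n_valid,
                "n_error": s.n_error,
                "n_trimmed": s.n_trimmed,
            }
        )
    return trial_df, pd.DataFrame(rows)


def compute_composites(
    session_df: pd.DataFrame, by_condition: bool = False
) -> pd.DataFrame:
    """Timing and trajectory composite scores from session summaries.

    Raw session means are z-scored across the cohort and averaged:
    timing = mean(z_RT, z_MTf, -z_PV) — slower is positive; trajectory =
    mean(z_PLf, z_AE, z_VE) — longer/less accurate is positive.  By
    default standardization pools both conditions, which puts the two
    conditions on one scale and keeps their paired contrast informative;
    ``by_condition=True`` standardizes within condition instead (each
    condition's composite then has mean exactly 0 by construction).
    """
    need = {"RT", "MTf", "PV", "PLf", "AE", "VE"}
    if not need.issubset(session_df.columns):
        raise ValueError(f"missing columns: {need - set(session_df.columns)}")
    out = session_df[["participant", "condition"]].copy()
    z = {}
    for col in sorted(need):
        if by_condition:
            z[col] = session_df.groupby("condition")[col].transform(
                lambda v: zscore(v.to_numpy())
            )
        else:
            z[col] = pd.Series(
                zscore(session_df[col].to_numpy()), index=session_df.index
            )
    out["timing_score"] = (z["RT"] + z["MTf"] - z["PV"]) / 3.0
    out["trajectory_score"] = (z["PLf"] + z["AE"] + z["VE"]) / 3.0
    return out


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a participants x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item
    sum), with sample variances (ddof=1).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 participants and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))
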