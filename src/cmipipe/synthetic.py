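"""Synthetic cohort generator.

Emulates the data structure of a concussion visuomotor study so every
downstream stage — kinematic scoring, questionnaire severity scoring,
within-network connectivity, along-tract statistics and the shared
regression layer — can be exercised end to end without any external data.

What is emulated
----------------
* Center-out reach trials on a touchscreen: four peripheral targets at
  55 mm eccentricity, a 2,000 ms pre-go hold, minimum-jerk ballistic
  movements, optional corrective sub-movements, a terminal hold, and two
  visuomotor mappings (standard, and plane-change + 180 deg feedback
  reversal).  Direction-reversal errors and timing-filter violations can
  be injected at configurable rates.
* 16-item post-concussion symptom ratings (0-4) and 25-item dizziness
  handicap ratings (0/2/4) driven by a latent severity.
* Parcellated BOLD time-series with block within-network covariance over
  a 7-network, 200-parcel layout.
* Along-tract FA/MD profiles: a smooth baseline, AR(1) noise along the
  tract, and a localized linear covariate effect.

Reproducibility: one global integer seed is fanned out to per-participant,
per-component substreams through a counter-based key, so cohorts are
extensible without reshuffling existing participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tract_stats import TractProfile

__all__ = [
    "TaskGeometry",
    "MappingCondition",
    "STANDARD",
    "PC_FR",
    "CohortSpec",
    "TrialRecord",
    "SyntheticCohort",
    "DIRECTIONS",
    "DEFAULT_NETWORK_SIZES",
    "minimum_jerk_position",
    "minimum_jerk_peak_speed",
    "generate_trial",
    "generate_session",
    "generate_questionnaires",
    "generate_parcel_timeseries",
    "generate_tract_profiles",
    "generate_cohort",
    "default_network_labels",
]

# Screen-centred frame, x rightward, y upward, millimetres.
DIRECTIONS: dict[str, np.ndarray] = {
    "up": np.array([0.0, 1.0]),
    "down": np.array([0.0, -1.0]),
    "left": np.array([-1.0, 0.0]),
    "right": np.array([1.0, 0.0]),
}


@dataclass(frozen=True)
class TaskGeometry:
    """Center-out task layout and timing constants.

    Defaults: peripheral targets 55 mm from the central target, central
    target 7.5 mm in diameter, 500 ms terminal hold, 2,000 ms delay
    between center acquisition and the go cue.
    """

    target_distance: float = 55.0
    target_diameter: float = 7.5
    central_diameter: float = 7.5
    hold_duration: float = 500.0
    go_delay: float = 2000.0

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")

    @property
    def central_radius(self) -> float:
        return self.central_diameter / 2.0

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0

    def target_position(self, direction: str) -> np.ndarray:
        return DIRECTIONS[direction] * self.target_distance


@dataclass(frozen=True)
class MappingCondition:
    """Visuomotor mapping between finger motion and cursor motion."""

    name: str
    plane_change: bool
    feedback_rotation: float  # degrees, 0 or 180

    def __post_init__(self) -> None:
        if self.name == "standard" and (self.plane_change or self.feedback_rotation):
            raise ValueError("standard mapping must be direct")
        if self.name == "pc_fr" and not (
            self.plane_change and self.feedback_rotation == 180.0
        ):
            raise ValueError("pc_fr mapping requires plane change and 180 deg rotation")


STANDARD = MappingCondition("standard", plane_change=False, feedback_rotation=0.0)
PC_FR = MappingCondition("pc_fr", plane_change=True, feedback_rotation=180.0)
CONDITIONS = {"standard": STANDARD, "pc_fr": PC_FR}


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort.

    ``dr_probability`` and ``correction_probability`` are per-condition:
    the decoupled mapping produces more direction reversals and more
    corrective sub-movements than the direct one, which is what drives
    the expected condition differences in %DR and full path length.
    """

    n_participants: int = 22
    trials_per_target: int = 5
    sampling_rate: float = 200.0  # Hz
    dr_probability: dict = field(
        default_factory=lambda: {"standard": 0.02, "pc_fr": 0.30}
    )
    correction_probability: dict = field(
        default_factory=lambda: {"standard": 0.10, "pc_fr": 0.40}
    )
    error_probability: float = 0.03
    endpoint_bias_sd: float = 1.0  # mm, per participant systematic
    endpoint_noise_sd: float = 2.0  # mm, per trial
    position_noise_sd: float = 0.1  # mm, sensor jitter on every sample
    reaction_mean_ms: float = 320.0
    reaction_sd_ms: float = 50.0
    movement_mean_ms: float = 550.0
    movement_sd_ms: float = 60.0
    dr_excursion_frac: float = 0.3  # off-goal amplitude as fraction of distance
    latent_severity_distribution: tuple[float, float] = (2.0, 1.0)
    effect_map: list = field(default_factory=list)  # (measure, covariate, slope)
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.dr_probability, self.correction_probability):
            for cond, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {cond!r} outside [0, 1]")
        if not 0.0 <= self.error_probability <= 1.0:
            raise ValueError("error_probability outside [0, 1]")
        if self.trials_per_target < 1:
            raise ValueError("trials_per_target must be >= 1")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "latent_severity_distribution" in d:
            d["latent_severity_distribution"] = tuple(d["latent_severity_distribution"])
        return cls(**d)


@dataclass
class TrialRecord:
    """One reach trial: uniformly sampled cursor positions.

    ``x_mm``/``y_mm`` are cursor-space positions (what the participant
    sees); ``finger_x_mm``/``finger_y_mm`` the corresponding finger-space
    trace, identical under the standard mapping and point-reflected under
    feedback reversal.  ``nominal_rt_ms`` is the reaction time the scorer
    should recover on a noiseless trial: the go-cue-to-threshold-crossing
    interval implied by the injected reaction period and the 10 %-of-peak
    onset convention on the minimum-jerk speed profile.
    """

    participant: str
    condition: str
    trial: int
    target: str
    t_ms: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    finger_x_mm: np.ndarray
    finger_y_mm: np.ndarray
    go_cue_ms: float
    phase: np.ndarray | None = None
    injected_dr: bool = False
    injected_error: str | None = None
    nominal_rt_ms: float | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_peak_speed(amplitude: float, duration_ms: float) -> float:
    """Peak tangential speed of a minimum-jerk segment, mm/ms.

    The speed profile 30 tau^2 (1 - tau)^2 * D/T peaks at tau = 1/2 with
    value 30/16 = 1.875 times D/T.
    """
    return 1.875 * amplitude / duration_ms


# tau at which minimum-jerk speed first reaches 10% of its peak:
# 30 t^2 (1-t)^2 = 0.1 * 1.875  =>  t(1-t) = sqrt(0.00625)
_TAU_10PCT = 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(0.1 * 1.875 / 30.0)))


def _segment(
    start: np.ndarray, end: np.ndarray, duration_ms: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk positions sampled every dt over [0, duration]."""
    n = max(int(round(duration_ms / dt)), 2)
    t = np.arange(n + 1) * dt
    s = minimum_jerk_position(t / duration_ms)
    pos = start[None, :] + s[:, None] * (end - start)[None, :]
    return t, pos


def generate_trial(
    direction: str,
    condition: MappingCondition,
    geometry: TaskGeometry,
    spec: CohortSpec,
    rng: np.random.Generator,
    participant: str = "p000",
    trial: int = 0,
    endpoint_bias: np.ndarray | None = None,
    force_dr: bool | None = None,
    force_error: str | None = None,
) -> TrialRecord:
    """Simulate one center-out reach in cursor space.

    The trial covers: a pre-go hold at the center, a reaction period, a
    ballistic minimum-jerk segment of amplitude ``target_distance`` toward
    the goal, an optional corrective sub-movement, and a terminal hold of
    at least ``hold_duration``.  With probability ``dr_probability`` the
    ballistic segment first departs 180 deg off-goal (a direction
    reversal) before correcting; with probability ``error_probability``
    the trial violates one of the four timing filters.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if spec.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    dt = 1000.0 / spec.sampling_rate
    goal = geometry.target_position(direction)
    bias = np.zeros(2) if endpoint_bias is None else endpoint_bias
    endpoint = goal + bias + rng.normal(0.0, spec.endpoint_noise_sd, size=2)

    dr = force_dr if force_dr is not None else bool(
        rng.random() < spec.dr_probability.get(condition.name, 0.0)
    )
    error = force_error
    if error is None and rng.random() < spec.error_probability:
        error = rng.choice(
            ["left_home_early", "rt_too_short", "rt_too_long", "mt_too_long"]
        )

    reaction = float(
        np.clip(rng.normal(spec.reaction_mean_ms, spec.reaction_sd_ms), 180.0, 1500.0)
    )
    move_T = float(
        np.clip(rng.normal(spec.movement_mean_ms, spec.movement_sd_ms), 300.0, 2000.0)
    )
    if error == "rt_too_short":
        reaction = 60.0
    elif error == "rt_too_long":
        reaction = 8600.0
    elif error == "mt_too_long":
        # scored MTf spans only the supra-threshold part (~83 %) of the
        # segment, so the raw duration must overshoot the 10 s filter
        move_T = 13000.0

    go_cue = geometry.go_delay
    move_start = go_cue + reaction
    if error == "left_home_early":
        move_start = go_cue - 500.0  # finger leaves home before the go cue

    chunks_t: list[np.ndarray] = []
    chunks_p: list[np.ndarray] = []
    chunks_phase: list[np.ndarray] = []

    def push(t, p, phase):
        chunks_t.append(t)
        chunks_p.append(p)
        chunks_phase.append(np.full(len(t), phase, dtype=object))

    # pre-go hold + reaction period: stationary at the center
    n_pre = max(int(round(move_start / dt)), 1)
    t_pre = np.arange(n_pre) * dt
    push(t_pre, np.zeros((n_pre, 2)), "hold")

    t_cursor = move_start
    pos = np.zeros(2)
    segs: list[tuple[np.ndarray, np.ndarray, str]] = []
    if dr:
        # initial ballistic segment aimed 180 deg off-goal, then correction
        excursion = -DIRECTIONS[direction] * spec.dr_excursion_frac * geometry.target_distance
        segs.append((pos.copy(), pos + excursion, "ballistic"))
        segs.append((pos + excursion, endpoint, "correction"))
    else:
        segs.append((pos.copy(), endpoint, "ballistic"))
        if rng.random() < spec.correction_probability.get(condition.name, 0.0):
            # deliberate miss then corrective sub-movement
            miss = rng.normal(0.0, 3.0, size=2)
            miss += np.sign(miss) * 2.0  # keep the miss visible (>2 mm)
            segs[-1] = (pos.copy(), endpoint + miss, "ballistic")
            segs.append((endpoint + miss, endpoint, "correction"))

    first_T = move_T
    nominal_rt = reaction + _TAU_10PCT * first_T
    for i, (a, b, label) in enumerate(segs):
        T = move_T if label == "ballistic" else max(0.45 * move_T, 200.0)
        if dr and i == 0:
            T = max(0.35 * move_T, 200.0)
            first_T = T
            nominal_rt = reaction + _TAU_10PCT * T
        ts, ps = _segment(a, b, T, dt)
        push(ts[1:] + t_cursor, ps[1:], label)
        t_cursor += ts[-1]

    n_hold = max(int(round(geometry.hold_duration / dt)) + 1, 2)
    t_hold = (np.arange(n_hold) + 1) * dt + t_cursor
    push(t_hold, np.tile(chunks_p[-1][-1], (n_hold, 1)), "hold_end")

    t = np.concatenate(chunks_t)
    p = np.concatenate(chunks_p)
    phase = np.concatenate(chunks_phase)
    if spec.position_noise_sd > 0:
        p = p + rng.normal(0.0, spec.position_noise_sd, size=p.shape)

    if condition.feedback_rotation == 180.0:
        finger = -p  # finger moves opposite to the cursor
    else:
        finger = p
    return TrialRecord(
        participant=participant,
        condition=condition.name,
        trial=trial,
        target=direction,
        t_ms=t,
        x_mm=p[:, 0],
        y_mm=p[:, 1],
        finger_x_mm=finger[:, 0],
        finger_y_mm=finger[:, 1],
        go_cue_ms=go_cue,
        phase=phase,
        injected_dr=dr,
        injected_error=error,
        nominal_rt_ms=nominal_rt,
    )


def _participant_rng(seed: int, participant_index: int, stream: int) -> np.random.Generator:
    # Counter-based substream: (seed, participant, stream) keys the PRNG, so
    # adding participants or components never reshuffles existing draws.
    return np.random.default_rng([seed, participant_index, stream])


def generate_session(
    participant: str,
    participant_index: int,
    condition: MappingCondition,
    geometry: TaskGeometry,
    spec: CohortSpec,
) -> list[TrialRecord]:
    """One session: trials_per_target trials for each of the 4 targets,
    balanced and order-randomized."""
    stream = 10 if condition.name == "standard" else 11
    rng = _participant_rng(spec.seed, participant_index, stream)
    bias = rng.normal(0.0, spec.endpoint_bias_sd, size=2)
    order = [d for d in DIRECTIONS for _ in range(spec.trials_per_target)]
    rng.shuffle(order)
    return [
        generate_trial(
            d, condition, geometry, spec, rng,
            participant=participant, trial=i, endpoint_bias=bias,
        )
        for i, d in enumerate(order)
    ]


def generate_questionnaires(
    latent_severity: np.ndarray,
    rng: np.random.Generator,
    loading: float = 1.0,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordinal symptom ratings driven by a latent severity.

    RPQ items are drawn on 0-4 by discretizing severity*loading + noise;
    DHI items on {0, 2, 4} (No / Sometimes / Always).  Ratings are
    monotone in severity in expectation.  Returns (rpq_items, dhi_items)
    in long format with one row per participant x item.
    """
    from .questionnaires import RPQ_ITEMS, DHI_SCHEMES

    sev = np.asarray(latent_severity, dtype=float)
    n = sev.size
    rpq_rows = []
    for i, item in enumerate(RPQ_ITEMS):
        raw = sev * loading + rng.normal(0.0, noise_sd, size=n)
        rating = np.clip(np.rint(raw), 0, 4).astype(int)
        for j in range(n):
            rpq_rows.append(
                {"participant": f"p{j:03d}", "instrument": "RPQ", "item": item,
                 "item_index": i + 1, "rating": int(rating[j]), "domain": ""}
            )
    dhi_rows = []
    scheme = DHI_SCHEMES["paper"]
    for i, (item, domain) in enumerate(scheme.items):
        raw = sev * loading + rng.normal(0.0, noise_sd, size=n)
        rating = 2 * np.clip(np.rint(raw / 2.0), 0, 2).astype(int)  # {0,2,4}
        for j in range(n):
            dhi_rows.append(
                {"participant": f"p{j:03d}", "instrument": "DHI", "item": item,
                 "item_index": i + 1, "rating": int(rating[j]), "domain": domain}
            )
    return pd.DataFrame(rpq_rows), pd.DataFrame(dhi_rows)


DEFAULT_NETWORK_SIZES = {
    "VN": 30,
    "SMN": 34,
    "DAN": 26,
    "SVAN": 24,
    "limbic": 12,
    "FPCN": 30,
    "DMN": 44,
}  # 200 parcels total, 7-network layout


def default_network_labels(sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Parcel -> network label table; FPCN parcels get a/b/c sublabels."""
    sizes = dict(DEFAULT_NETWORK_SIZES if sizes is None else sizes)
    rows = []
    pid = 0
    for net, k in sizes.items():
        for i in range(k):
            sub = ""
            if net == "FPCN":
                sub = "abc"[i % 3]
            rows.append({"parcel_id": pid, "network": net, "sublabel": sub})
            pid += 1
    return pd.DataFrame(rows)


def generate_parcel_timeseries(
    labels: pd.DataFrame,
    within_r: Mapping[str, float] | float,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parcel x timepoint series with block within-network correlation.

    Each parcel is sqrt(r)*shared + sqrt(1-r)*private noise, giving an
    expected pairwise correlation of ``within_r`` inside a network and 0
    across networks.  Rows are standardized to zero mean, unit variance.
    """
    nets = labels["network"].to_numpy()
    P = len(labels)
    if np.isscalar(within_r):
        within_r = {n: float(within_r) for n in np.unique(nets)}
    for n, r in within_r.items():
        if not -1.0 < r < 1.0:
            raise ValueError(f"within_r for {n!r} must be in (-1, 1)")
    out = np.empty((P, T))
    for net in np.unique(nets):
        idx = np.flatnonzero(nets == net)
        r = within_r.get(net, 0.0)
        shared = rng.standard_normal(T)
        private = rng.standard_normal((idx.size, T))
        out[idx] = np.sqrt(abs(r)) * np.sign(r) * shared + np.sqrt(1 - abs(r)) * private
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_tract_profiles(
    n: int,
    L: int,
    covariate: np.ndarray,
    effect_window: tuple[int, int],
    slope: float,
    noise: tuple[float, float],
    rng: np.random.Generator,
    tract: str = "synthetic_tract",
    hemisphere: str = "left",
    measure: str = "FA",
    baseline: np.ndarray | None = None,
    point_spacing_mm: float = 1.0,
) -> TractProfile:
    """Along-tract profiles with a localized linear covariate effect.

    profile(i, j) = baseline(j) + slope*covariate(i)*[j in window] +
    AR(1) noise along j.  ``noise`` is (sd, rho); the AR(1) innovations
    are scaled so the marginal SD equals sd.  ``effect_window`` is a
    half-open index range [start, stop).
    """
    if L < 2:
        raise ValueError("need at least 2 cross-sections")
    covariate = np.asarray(covariate, dtype=float)
    if covariate.size != n:
        raise ValueError("covariate length must equal n")
    w0, w1 = effect_window
    if not (0 <= w0 <= w1 <= L):
        raise ValueError("effect window outside [0, L)")
    sd, rho = noise
    if not -1.0 < rho < 1.0:
        raise ValueError("AR(1) rho must be in (-1, 1)")
    j = np.arange(L)
    if baseline is None:
        if measure == "FA":
            baseline = 0.45 + 0.08 * np.sin(2 * np.pi * j / L) + 0.04 * np.cos(4 * np.pi * j / L)
        else:  # MD-like scale, 1e-3 mm^2/s
            baseline = 0.8e-3 + 0.05e-3 * np.sin(2 * np.pi * j / L)
    vals = np.tile(np.asarray(baseline, dtype=float), (n, 1))
    vals[:, w0:w1] += slope * covariate[:, None]
    if sd > 0:
        eps = np.empty((n, L))
        innov_sd = sd * np.sqrt(1 - rho**2)
        eps[:, 0] = rng.normal(0.0, sd, size=n)
        for jj in range(1, L):
            eps[:, jj] = rho * eps[:, jj - 1] + rng.normal(0.0, innov_sd, size=n)
        vals += eps
    if measure == "FA":
        vals = np.clip(vals, 0.0, 1.0)
    return TractProfile(
        tract=tract,
        hemisphere=hemisphere,
        measure=measure,
        values=vals,
        point_spacing_mm=point_spacing_mm,
        participants=[f"p{i:03d}" for i in range(n)],
    )


@dataclass
class SyntheticCohort:
    """Everything one study visit would produce, keyed by participant."""

    spec: CohortSpec
    geometry: TaskGeometry
    trials: list[TrialRecord]
    rpq_items: pd.DataFrame
    dhi_items: pd.DataFrame
    covariates: pd.DataFrame
    parcel_timeseries: dict[str, np.ndarray]
    network_labels: pd.DataFrame
    tract_profiles: dict[str, TractProfile]
    roi_thickness: pd.DataFrame
    latent_severity: np.ndarray

    @property
    def participants(self) -> list[str]:
        return list(self.covariates["participant"])

    # ---- writers: plain-text tabular outputs ---------------------------
    def write_trials_tsv(self, path: str | Path) -> None:
        rows = []
        for tr in self.trials:
            rows.append(
                pd.DataFrame(
                    {
                        "participant": tr.participant,
                        "condition": tr.condition,
                        "trial": tr.trial,
                        "target": tr.target,
                        "t_ms": tr.t_ms,
                        "x_mm": tr.x_mm,
                        "y_mm": tr.y_mm,
                        "phase": tr.phase,
                        "go_cue_ms": tr.go_cue_ms,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )

    def write_questionnaires_csv(self, path: str | Path) -> None:
        pd.concat([self.rpq_items, self.dhi_items], ignore_index=True).to_csv(
            path, index=False
        )

    def write_covariates_csv(self, path: str | Path) -> None:
        self.covariates.to_csv(path, index=False, float_format="%.6f")

    def write_profiles_tsv(self, path: str | Path) -> None:
        rows = []
        for key, prof in self.tract_profiles.items():
            n, L = prof.values.shape
            for i in range(n):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": prof.participants[i] if prof.participants else f"p{i:03d}",
                            "tract": prof.tract,
                            "hemisphere": prof.hemisphere,
                            "measure": prof.measure,
                            "point_index": np.arange(L),
                            "value": prof.values[i],
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )

    def write_timeseries_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pid, ts in self.parcel_timeseries.items():
            pd.DataFrame(ts).to_csv(
                outdir / f"{pid}_timeseries.tsv", sep="\t", index=False,
                header=False, float_format="%.6f",
            )


def generate_cohort(
    spec: CohortSpec | None = None,
    geometry: TaskGeometry | None = None,
    *,
    timeseries_T: int = 300,
    tract_length: int = 60,
    with_timeseries: bool = True,
    with_tracts: bool = True,
) -> SyntheticCohort:
    """Generate a full synthetic cohort from a single seed.

    ``effect_map`` entries of the spec couple measures to covariates:
    ``("tract:<name>", "<covariate>", slope)`` injects a localized
    along-tract effect of the named covariate (``rpq3_latent`` couples to
    the latent severity); other measures are currently uncoupled.
    """
    spec = spec or CohortSpec()
    geometry = geometry or TaskGeometry()
    n = spec.n_participants
    pids = [f"p{i:03d}" for i in range(n)]

    cov_rng = _participant_rng(spec.seed, 0, 1)
    sev_rng = _participant_rng(spec.seed, 0, 2)
    mu, sd = spec.latent_severity_distribution
    severity = np.clip(sev_rng.normal(mu, sd, size=n), 0.0, 4.0)
    covariates = pd.DataFrame(
        {
            "participant": pids,
            "age": np.round(cov_rng.uniform(29, 63, size=n), 1),
            "sex": np.where(cov_rng.random(n) < 0.7727, "female", "male"),
            "sport_experience": cov_rng.integers(0, 2, size=n),
            "videogame_experience": cov_rng.integers(0, 2, size=n),
            "days_since_concussion": np.round(
                np.exp(cov_rng.normal(6.0, 0.8, size=n))
            ).astype(int),
            "latent_severity": severity,
        }
    )

    trials: list[TrialRecord] = []
    for i, pid in enumerate(pids):
        for cond in (STANDARD, PC_FR):
            trials.extend(generate_session(pid, i, cond, geometry, spec))

    q_rng = _participant_rng(spec.seed, 0, 3)
    rpq_items, dhi_items = generate_questionnaires(severity, q_rng)

    labels = default_network_labels()
    parcel_ts: dict[str, np.ndarray] = {}
    if with_timeseries:
        within = {"VN": 0.35, "SMN": 0.35, "DAN": 0.30, "SVAN": 0.30,
                  "FPCN": 0.30, "DMN": 0.35, "limbic": 0.20}
        for i, pid in enumerate(pids):
            ts_rng = _participant_rng(spec.seed, i, 4)
            parcel_ts[pid] = generate_parcel_timeseries(
                labels, within, timeseries_T, ts_rng
            )

    profiles: dict[str, TractProfile] = {}
    if with_tracts:
        tract_layout = [
            ("ILF", "left", "FA"), ("ILF", "right", "FA"),
            ("SLF2", "left", "MD"), ("SLF2", "right", "MD"),
            ("CC_splenium", "commissural", "MD"),
        ]
        t_rng = _participant_rng(spec.seed, 0, 5)
        effects = {
            m.split(":", 1)[1]: (c, s)
            for (m, c, s) in spec.effect_map
            if m.startswith("tract:")
        }
        for tname, hemi, measure in tract_layout:
            key = f"{tname}_{hemi}"
            cov_name, slope = effects.get(key, (None, 0.0))
            if cov_name == "latent_severity" or cov_name == "rpq3_latent":
                covv = severity
            elif cov_name is not None:
                covv = covariates[cov_name].to_numpy(dtype=float)
            else:
                covv = np.zeros(n)
            w = (tract_length // 3, tract_length // 3 + max(tract_length // 6, 4))
            base_sd = 0.03 if measure == "FA" else 0.04e-3
            profiles[key] = generate_tract_profiles(
                n, tract_length, covv, w, slope, (base_sd, 0.5), t_rng,
                tract=tname, hemisphere=hemi, measure=measure,
            )

    th_rng = _participant_rng(spec.seed, 0, 6)
    rois = [
        f"{h}_{r}"
        for h in ("lh", "rh")
        for r in (
            "superior_parietal", "inferior_parietal", "precuneus", "precentral",
            "superior_frontal", "rostral_middle_frontal", "caudal_middle_frontal",
            "cuneus",
        )
    ]
    thick = pd.DataFrame(
        {"participant": pids}
        | {r: np.round(th_rng.normal(2.4, 0.15, size=n), 4) for r in rois}
    )

    return SyntheticCohort(
        spec=spec,
        geometry=geometry,
        trials=trials,
        rpq_items=rpq_items,
        dhi_items=dhi_items,
        covariates=covariates,
        parcel_timeseries=parcel_ts,
        network_labels=labels,
        tract_profiles=profiles,
        roi_thickness=thick,
        latent_severity=severity,
    )


def dump_default_config() -> str:
    """JSON document of all generator defaults (CLI --dump-config)."""
    return json.dumps(
        {"cohort": CohortSpec().to_dict(), "geometry": asdict(TaskGeometry())},
        indent=2,
    )
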