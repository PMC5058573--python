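"""Session configuration and stochastic-input generation.

A week of clinic operation is 12 bounded consultation sessions (5 sports,
4 trauma, 3 hand-and-foot team sessions) between 8:30 and 22:00.  Each
session is described by a :class:`SessionConfig`: patient volumes, a
piecewise-constant walk-in arrival intensity, late/no-show/special/
examination rates, and service-time distributions given as (mean, CV).

Generation notes
----------------
Walk-in arrivals come from a nonhomogeneous Poisson process simulated by
thinning against a fixed dominating rate sized for the whole calibration
bracket, so scaling the intensity up only *adds* arrivals under common
random numbers (the accepted sets are nested).  Every patient's service
durations are drawn as unit-mean multipliers times the configured mean, so
scaling a mean rescales durations smoothly without reshuffling randomness
— which makes the bisection calibration well behaved.

The hospital's raw per-session arrival and duration data are not public;
the defaults here are design choices anchored to the clinic-level facts
that service averages about 14 minutes while waiting averages about 104
minutes, and they are fully overridable in scenario files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import Patient, WALK_IN, SCHEDULED

__all__ = [
    "ServiceDist",
    "SessionConfig",
    "CalibrationError",
    "generate_arrivals",
    "calibrate",
    "default_sessions",
    "session_to_dict",
    "session_from_dict",
]

TEAMS = ("sports", "trauma", "hand_and_foot")
#: Calibration knobs scale within this bracket; the walk-in thinning
#: dominating rate is sized for its upper end so scaled processes nest.
SCALE_BRACKET = (0.1, 10.0)

DAY_OPEN_S = 8 * 3600 + 30 * 60    # 8:30
DAY_CLOSE_S = 22 * 3600            # 22:00


@dataclass(frozen=True)
class ServiceDist:
    """Service-time distribution: family plus mean (seconds) and CV.

    ``lognormal`` (right-skewed clinical times) honors both mean and CV;
    ``exponential`` has CV fixed at 1; ``fixed`` is degenerate.  A zero
    mean means the step takes no time.
    """

    family: str
    mean_s: float
    cv: float = 0.5

    def __post_init__(self):
        if self.family not in ("lognormal", "exponential", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.mean_s < 0:
            raise ValueError("mean must be nonnegative")

    def draw_unit(self, rng: np.random.Generator) -> float:
        """One draw with unit mean; multiply by the (scaled) mean."""
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + self.cv ** 2)
            return float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))
        if self.family == "exponential":
            return float(rng.exponential(1.0))
        return 1.0


@dataclass(frozen=True)
class SessionConfig:
    """One weekly consultation session and all its stochastic inputs."""

    session_id: int
    team: str
    session_start_s: float              # seconds of day
    session_end_s: float
    n_scheduled: int
    walkin_rate_profile: tuple[tuple[float, float, float], ...]  # (t0, t1, per-hour)
    appointment_grid: Optional[tuple[float, ...]] = None  # seconds from start
    appointment_template: str = "even"  # or "bailey_welch"
    late_rate: float = 0.15
    lateness_mean_s: float = 900.0
    no_show_rate: float = 0.08
    special_rate: float = 0.05
    exam_rate: float = 0.25
    registration: ServiceDist = ServiceDist("exponential", 90.0)
    consultation: ServiceDist = ServiceDist("lognormal", 660.0, 0.5)
    examination: ServiceDist = ServiceDist("lognormal", 600.0, 0.5)
    pharmacy: ServiceDist = ServiceDist("exponential", 90.0)
    consult_mean_by_class: Optional[dict] = None
    move_time_s: float = 60.0
    n_doctors: int = 1
    n_registration: int = 2
    exam_capacity: int = 3
    pharmacy_capacity: int = 2
    late_grace_s: float = 0.0
    walkin_rate_scale: float = 1.0
    consult_mean_scale: float = 1.0

    @property
    def duration_s(self) -> float:
        return self.session_end_s - self.session_start_s

    def consult_mean_for(self, ptype: str) -> float:
        base = self.consultation.mean_s
        if self.consult_mean_by_class:
            base = self.consult_mean_by_class.get(ptype, base)
        return base * self.consult_mean_scale

    def grid(self) -> tuple[float, ...]:
        if self.appointment_grid is not None:
            return self.appointment_grid
        n, dur = self.n_scheduled, self.duration_s
        if n == 0:
            return ()
        if self.appointment_template == "bailey_welch":
            # two patients at the start, then evenly at the mean service time
            step = self.consult_mean_for(SCHEDULED)
            times = [0.0, 0.0] + [i * step for i in range(1, n - 1)]
            return tuple(min(t, dur) for t in times[:n])
        return tuple(i * dur / n for i in range(n))

    def validate(self) -> None:
        problems = []
        if self.team not in TEAMS:
            problems.append(f"team {self.team!r} not in {TEAMS}")
        if not (DAY_OPEN_S <= self.session_start_s < self.session_end_s <= DAY_CLOSE_S):
            problems.append("session hours must fall within 8:30-22:00 and be nonempty")
        for name in ("late_rate", "no_show_rate", "special_rate", "exam_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0, 1]")
        if self.n_scheduled < 0:
            problems.append("n_scheduled must be >= 0")
        for t0, t1, rate in self.walkin_rate_profile:
            if t1 <= t0 or rate < 0:
                problems.append(f"bad walk-in profile piece ({t0}, {t1}, {rate})")
        for t in self.grid():
            if not 0 <= t <= self.duration_s:
                problems.append(f"appointment at {t} s outside the session")
        for cap in ("n_doctors", "n_registration", "exam_capacity", "pharmacy_capacity"):
            if getattr(self, cap) < 1:
                problems.append(f"{cap} must be >= 1")
        if problems:
            raise ValueError("invalid session config: " + "; ".join(problems))


def _profile_rate(profile, t: float) -> float:
    for t0, t1, rate in profile:
        if t0 <= t < t1:
            return rate
    return 0.0


def generate_arrivals(config: SessionConfig, streams) -> list[Patient]:
    """Generate one replication's patient population for a session.

    Scheduled patients sit on the appointment grid with independent
    no-show and lateness marks (late arrival = appointment + exponential
    delay); walk-ins come from the thinned Poisson process.  Registration
    numbers are odd for walk-ins (arrival order) and even for scheduled
    patients (appointment order).  All service randomness is attached to
    the patient here, before any queueing happens.
    """
    dur = config.duration_s
    patients: list[Patient] = []

    # scheduled patients, in appointment order
    for i, appt in enumerate(sorted(config.grid())):
        no_show = bool(streams["no_show"].random() < config.no_show_rate)
        late_u = streams["lateness"].random()
        delay = float(streams["lateness"].exponential(config.lateness_mean_s))
        is_late = late_u < config.late_rate
        arrival = appt + delay if is_late else float(appt)
        p = _new_patient(
            config, streams, pid=f"s{i + 1}", ptype=SCHEDULED,
            arrival=arrival, reg_number=2 * (i + 1),
        )
        p.appointment_time = float(appt)
        p.no_show = no_show
        p.is_late = is_late and (arrival - appt) > config.late_grace_s
        patients.append(p)

    # walk-ins: thinning against a dominating rate covering the whole bracket
    max_rate = max((r for _, _, r in config.walkin_rate_profile), default=0.0)
    lam_dom = SCALE_BRACKET[1] * max_rate / 3600.0  # per second
    arr_rng = streams["walkin_arrivals"]
    n_walk = 0
    if lam_dom > 0:
        t = 0.0
        while True:
            t += float(arr_rng.exponential(1.0 / lam_dom))
            if t >= dur:
                break
            u = arr_rng.random()
            accept = u < (config.walkin_rate_scale
                          * _profile_rate(config.walkin_rate_profile, t) / 3600.0
                          ) / lam_dom
            # draw the candidate's whole bundle either way so the accepted
            # patients' randomness does not shift when the rate scale moves
            p = _new_patient(
                config, streams, pid=f"w{n_walk + 1}", ptype=WALK_IN,
                arrival=t, reg_number=2 * n_walk + 1,
            )
            if accept:
                n_walk += 1
                patients.append(p)
    return patients


def _new_patient(config, streams, pid, ptype, arrival, reg_number) -> Patient:
    special = bool(streams["special"].random() < config.special_rate)
    age_rng = streams["age"]
    if special and age_rng.random() < 0.5:
        age = float(age_rng.uniform(86.0, 100.0))  # over-85 route to priority
    else:
        age = float(age_rng.uniform(18.0, 84.0))
    cmean = config.consult_mean_for(ptype)
    reg_dur = (config.registration.mean_s * config.registration.draw_unit(streams["registration"])
               if ptype == WALK_IN else 0.0)
    c1 = cmean * config.consultation.draw_unit(streams["consult"])
    c2 = cmean * config.consultation.draw_unit(streams["consult"])
    needs_exam = bool(streams["exam_decision"].random() < config.exam_rate)
    exam_dur = config.examination.mean_s * config.examination.draw_unit(streams["exam"])
    pharm_dur = config.pharmacy.mean_s * config.pharmacy.draw_unit(streams["pharmacy"])
    if ptype == WALK_IN and reg_number % 2 == 0:
        raise AssertionError("walk-in must get an odd registration number")
    return Patient(
        id=pid, ptype=ptype, special=special, age=age,
        arrival_time=float(arrival), registration_number=reg_number,
        reg_duration=reg_dur, consult_durations=(c1, c2),
        needs_exam=needs_exam, exam_duration=exam_dur,
        pharmacy_duration=pharm_dur, expected_consult_mean=cmean,
    )


class CalibrationError(RuntimeError):
    pass


def calibrate(config: SessionConfig, target_mean_wait: float, knob: str,
              tol: float = 0.02, reps: int = 10, seed: int = 0,
              max_steps: int = 40) -> SessionConfig:
    """Tune one monotone knob until simulated mean waiting hits a target.

    ``knob`` is ``walkin_rate_scale`` or ``consult_mean_scale``; the scale
    factor is searched by bisection in [0.1, 10] (relative to the config's
    current value).  Evaluations reuse the same seed (common random
    numbers), so the objective is a deterministic nondecreasing function
    of the scale and bisection converges cleanly.  Stops when the achieved
    mean waiting is within ``tol`` (relative) of ``target_mean_wait``.
    """
    from .policies import PolicySpec, evaluate_policy

    if tol <= 0:
        raise ValueError("tol must be positive")
    if knob not in ("walkin_rate_scale", "consult_mean_scale"):
        raise ValueError(f"unknown calibration knob {knob!r}")
    base = getattr(config, knob)
    policy = PolicySpec("baseline_alternating")

    def achieved(scale: float) -> float:
        cfg = replace(config, **{knob: base * scale})
        return evaluate_policy(cfg, policy, reps, seed).mean_waiting

    lo, hi = SCALE_BRACKET
    f_lo, f_hi = achieved(lo), achieved(hi)
    if not (f_lo <= target_mean_wait <= f_hi):
        raise CalibrationError(
            f"target {target_mean_wait:.1f} s outside the reachable bracket: "
            f"scale {lo} gives {f_lo:.1f} s, scale {hi} gives {f_hi:.1f} s"
        )
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        f_mid = achieved(mid)
        if abs(f_mid - target_mean_wait) <= tol * target_mean_wait:
            return replace(config, **{knob: base * mid})
        if f_mid < target_mean_wait:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach the target within {max_steps} steps; "
        f"final bracket scales [{lo:.4f}, {hi:.4f}]"
    )


# Per-session load defaults (scheduled count, walk-in rate per hour).  Not
# measurements: chosen so the baseline discipline yields session mean waits
# spanning roughly one to two and a half hours across the week, the range
# the validation targets occupy.
_SESSION_LOADS = {
    1: (14, 5.0), 2: (14, 5.1), 3: (10, 4.6), 4: (9, 4.4),
    5: (10, 4.7), 6: (13, 5.6), 7: (11, 4.6), 8: (15, 5.8),
    9: (10, 4.5), 10: (13, 6.1), 11: (15, 6.1), 12: (11, 4.7),
}
_SESSION_STARTS = (9 * 3600, 13 * 3600 + 30 * 60, 18 * 3600 + 30 * 60)


def default_sessions() -> list[SessionConfig]:
    """The 12 weekly sessions: 5 sports, 4 trauma, 3 hand-and-foot."""
    teams = ["sports"] * 5 + ["trauma"] * 4 + ["hand_and_foot"] * 3
    out = []
    for sid in range(1, 13):
        n_sched, rate = _SESSION_LOADS[sid]
        start = float(_SESSION_STARTS[(sid - 1) % 3])
        dur = 3 * 3600.0
        cfg = SessionConfig(
            session_id=sid, team=teams[sid - 1],
            session_start_s=start, session_end_s=start + dur,
            n_scheduled=n_sched,
            walkin_rate_profile=((0.0, dur, rate),),
        )
        cfg.validate()
        out.append(cfg)
    return out


# -- (de)serialization for scenario files ----------------------------------

_DIST_FIELDS = ("registration", "consultation", "examination", "pharmacy")


def session_to_dict(cfg: SessionConfig) -> dict:
    d = {
        "session_id": cfg.session_id, "team": cfg.team,
        "session_start_s": cfg.session_start_s, "session_end_s": cfg.session_end_s,
        "n_scheduled": cfg.n_scheduled,
        "walkin_rate_profile": [list(p) for p in cfg.walkin_rate_profile],
        "appointment_grid": (None if cfg.appointment_grid is None
                             else list(cfg.appointment_grid)),
        "appointment_template": cfg.appointment_template,
        "late_rate": cfg.late_rate, "lateness_mean_s": cfg.lateness_mean_s,
        "no_show_rate": cfg.no_show_rate, "special_rate": cfg.special_rate,
        "exam_rate": cfg.exam_rate,
        "consult_mean_by_class": cfg.consult_mean_by_class,
        "move_time_s": cfg.move_time_s,
        "n_doctors": cfg.n_doctors, "n_registration": cfg.n_registration,
        "exam_capacity": cfg.exam_capacity, "pharmacy_capacity": cfg.pharmacy_capacity,
        "late_grace_s": cfg.late_grace_s,
        "walkin_rate_scale": cfg.walkin_rate_scale,
        "consult_mean_scale": cfg.consult_mean_scale,
    }
    for name in _DIST_FIELDS:
        dist: ServiceDist = getattr(cfg, name)
        d[name] = {"family": dist.family, "mean_s": dist.mean_s, "cv": dist.cv}
    return d


def session_from_dict(d: dict) -> SessionConfig:
    kw = dict(d)
    kw["walkin_rate_profile"] = tuple(tuple(p) for p in d["walkin_rate_profile"])
    if d.get("appointment_grid") is not None:
        kw["appointment_grid"] = tuple(d["appointment_grid"])
    for name in _DIST_FIELDS:
        if name in d and isinstance(d[name], dict):
            kw[name] = ServiceDist(**d[name])
    cfg = SessionConfig(**kw)
    cfg.validate()
    return cfg
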