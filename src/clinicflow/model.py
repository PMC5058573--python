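"""Agent layer and process flow of the outpatient clinic.

Patients move registration -> waiting room -> consultation, with an
optional single examination loop (consult -> examination -> consult) and a
final pharmacy stop before departure.  Walk-in patients must register on
arrival; scheduled patients go straight to the waiting room.  Every
stochastic quantity a patient will need (service durations, the
examination decision) is drawn when the patient is generated, never during
the run, so the realized randomness is identical under every queue
discipline — the basis for common-random-number policy comparison.

Waiting time is time spent in queues only; movement between zones and
service itself count toward throughput, not waiting.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from . import policies as _policies

__all__ = [
    "Patient",
    "Doctor",
    "ServiceStation",
    "ClinicModel",
    "waiting_time",
    "throughput_time",
    "service_time",
    "utilization",
]

WALK_IN = "walk_in"
SCHEDULED = "scheduled"


@dataclass
class Patient:
    """One outpatient and their full timestamp trail.

    Registration-number parity encodes the registration stream: odd numbers
    are walk-ins, even numbers are scheduled patients.  ``special`` marks
    patients over 85 or with a special condition; they hold first priority.
    All durations are in seconds; ``consult_durations`` holds the realized
    lengths of the (at most two) consultation visits and ``needs_exam`` the
    pre-drawn examination decision, applied at the first visit only.
    """

    id: str
    ptype: str
    special: bool
    age: float
    arrival_time: float
    registration_number: int
    appointment_time: Optional[float] = None
    is_late: bool = False
    no_show: bool = False

    # pre-drawn stochastic inputs
    reg_duration: float = 0.0
    consult_durations: tuple[float, float] = (0.0, 0.0)
    needs_exam: bool = False
    exam_duration: float = 0.0
    pharmacy_duration: float = 0.0
    expected_consult_mean: float = 0.0

    # timestamp trail (seconds from session start)
    registration_start: Optional[float] = None
    registration_end: Optional[float] = None
    queue_joins: list[float] = field(default_factory=list)
    dispatch_times: list[float] = field(default_factory=list)
    consult_starts: list[float] = field(default_factory=list)
    consult_ends: list[float] = field(default_factory=list)
    exam_queue_join: Optional[float] = None
    exam_start: Optional[float] = None
    exam_end: Optional[float] = None
    pharmacy_queue_join: Optional[float] = None
    pharmacy_start: Optional[float] = None
    pharmacy_end: Optional[float] = None
    departure: Optional[float] = None
    n_moves: int = 0
    dropped_at_close: bool = False

    def trail(self) -> list[float]:
        """All recorded timestamps along the visited path, in path order."""
        out: list[float] = [self.arrival_time]
        for t in (self.registration_start, self.registration_end):
            if t is not None:
                out.append(t)
        # interleave waiting-room visits with the exam loop
        for i in range(len(self.queue_joins)):
            out.append(self.queue_joins[i])
            if i < len(self.dispatch_times):
                out.append(self.dispatch_times[i])
            if i < len(self.consult_starts):
                out.append(self.consult_starts[i])
            if i < len(self.consult_ends):
                out.append(self.consult_ends[i])
            if i == 0 and self.exam_queue_join is not None:
                out.extend(t for t in (self.exam_queue_join, self.exam_start,
                                       self.exam_end) if t is not None)
        for t in (self.pharmacy_queue_join, self.pharmacy_start,
                  self.pharmacy_end, self.departure):
            if t is not None:
                out.append(t)
        return out


@dataclass
class Doctor:
    id: str
    team: str
    busy_intervals: list[tuple[float, float]] = field(default_factory=list)
    idle: bool = True
    _pending: Optional[Patient] = None
    _pending_start: Optional[float] = None


class ServiceStation:
    """Capacity-constrained FIFO station (registration, examination, pharmacy)."""

    def __init__(self, name: str, capacity: int, done_kind: str) -> None:
        if capacity < 1:
            raise ValueError(f"{name} capacity must be >= 1")
        self.name = name
        self.capacity = capacity
        self.done_kind = done_kind
        self.queue: deque[tuple] = deque()  # (patient, duration, start_attr)
        self.in_service = 0

    def join(self, p: Patient, sim, duration: float, start_attr: str) -> None:
        if self.in_service < self.capacity:
            self._start(p, sim, duration, start_attr)
        else:
            self.queue.append((p, duration, start_attr))

    def _start(self, p: Patient, sim, duration: float, start_attr: str) -> None:
        self.in_service += 1
        setattr(p, start_attr, sim.clock)
        sim.schedule(sim.clock + duration, self.done_kind, payload=p,
                     resource=self.name)

    def release(self, sim) -> None:
        self.in_service -= 1
        if self.queue:
            p, duration, start_attr = self.queue.popleft()
            self._start(p, sim, duration, start_attr)


class ClinicModel:
    """Process-flow model for one consultation session.

    Drives patients through the stations on top of the event kernel.  The
    session stops admitting at its scheduled end; patients already checked
    in (including those still queueing) are served to completion, patients
    who would arrive later are dropped.
    """

    def __init__(self, config, patients: list[Patient], policy=None) -> None:
        from .policies import PolicySpec  # local: avoid import cycle

        self.config = config
        self.patients = list(patients)
        self.policy = policy if policy is not None else PolicySpec("baseline_alternating")
        self.queue_state = _policies.QueueState()
        self.doctors = [
            Doctor(id=f"doc{i + 1}", team=config.team)
            for i in range(config.n_doctors)
        ]
        self.registration = ServiceStation("registration", config.n_registration,
                                           "registration_done")
        self.examination = ServiceStation("examination", config.exam_capacity,
                                          "exam_done")
        self.pharmacy = ServiceStation("pharmacy", config.pharmacy_capacity,
                                       "pharmacy_done")
        self._admitted: set[str] = set()
        self.served: list[Patient] = []
        #: one record per dispatch decision, for auditing the queue rules
        self.dispatch_audit: list[dict] = []

    # -- kernel hooks ------------------------------------------------------

    def start(self, sim) -> None:
        until = self.config.duration_s
        for p in self.patients:
            if p.no_show:
                continue
            if p.arrival_time >= until:
                p.dropped_at_close = True
                continue
            sim.schedule(p.arrival_time, "arrival", payload=p)

    def handle(self, ev, sim) -> None:
        handler = getattr(self, f"_on_{ev.kind}", None)
        if handler is not None:
            handler(ev, sim)

    # -- event handlers ----------------------------------------------------

    def _on_arrival(self, ev, sim) -> None:
        p: Patient = ev.payload
        if p.id in self._admitted:
            raise ValueError(f"patient {p.id!r} admitted twice")
        self._admitted.add(p.id)
        if p.ptype == WALK_IN:
            self.registration.join(p, sim, p.reg_duration, "registration_start")
        else:
            if p.is_late:
                sim.schedule(sim.clock, "late_checkin", payload=p)
            self._join_waiting_room(p, sim)

    def _on_registration_done(self, ev, sim) -> None:
        p: Patient = ev.payload
        p.registration_end = sim.clock
        self.registration.release(sim)
        self._move(p, sim, "waiting_join")

    def _on_waiting_join(self, ev, sim) -> None:
        self._join_waiting_room(ev.payload, sim)

    def _join_waiting_room(self, p: Patient, sim) -> None:
        p.queue_joins.append(sim.clock)
        returning = len(p.consult_ends) > 0
        self.queue_state.add(p, sim.clock, returning=returning)
        if p.is_late and not returning:
            self.queue_state.start_late_tracker(p)
        self._try_dispatch(sim)

    def _try_dispatch(self, sim) -> None:
        for doc in self.doctors:
            if not doc.idle:
                continue
            p = _policies.next_patient(self.queue_state, self.policy, sim.clock)
            if p is None:
                return
            qs = self.queue_state
            self.dispatch_audit.append({
                "time": sim.clock,
                "patient_id": p.id,
                "special": p.special,
                "returning": p in qs.returning_queue,
                "ptype": p.ptype,
                "prev_class": qs.last_served_class,
                "eligible_special_waiting": qs.eligible_head(qs.special_queue) is not None,
                "eligible_returning_waiting": qs.eligible_head(qs.returning_queue) is not None,
                "eligible_walkin_waiting": qs.eligible_head(qs.walkin_queue) is not None,
                "eligible_scheduled_waiting": qs.eligible_head(qs.scheduled_queue) is not None,
                "late_tracker_active": p.id in qs.late_trackers,
                "via_fallback": not any(qs.eligible(q) for q in qs.all_waiting()),
            })
            self.queue_state.on_dispatch(p)
            p.dispatch_times.append(sim.clock)
            doc.idle = False
            doc._pending = p
            self._move(p, sim, "consult_start", resource=doc.id)

    def _on_consult_start(self, ev, sim) -> None:
        p: Patient = ev.payload
        doc = self._doctor(ev.resource)
        p.consult_starts.append(sim.clock)
        doc._pending_start = sim.clock
        visit = len(p.consult_starts) - 1
        dur = p.consult_durations[visit]
        sim.schedule(sim.clock + dur, "consult_end", payload=p, resource=doc.id)

    def _on_consult_end(self, ev, sim) -> None:
        p: Patient = ev.payload
        doc = self._doctor(ev.resource)
        p.consult_ends.append(sim.clock)
        doc.busy_intervals.append((doc._pending_start, sim.clock))
        doc.idle, doc._pending, doc._pending_start = True, None, None
        first_visit = len(p.consult_ends) == 1
        if first_visit and p.needs_exam:
            self._move(p, sim, "exam_join")
        else:
            self._move(p, sim, "pharmacy_join")
        self._try_dispatch(sim)

    def _on_exam_join(self, ev, sim) -> None:
        p: Patient = ev.payload
        p.exam_queue_join = sim.clock
        self.examination.join(p, sim, p.exam_duration, "exam_start")

    def _on_exam_done(self, ev, sim) -> None:
        p: Patient = ev.payload
        p.exam_end = sim.clock
        self.examination.release(sim)
        self._move(p, sim, "waiting_join")

    def _on_pharmacy_join(self, ev, sim) -> None:
        p: Patient = ev.payload
        p.pharmacy_queue_join = sim.clock
        self.pharmacy.join(p, sim, p.pharmacy_duration, "pharmacy_start")

    def _on_pharmacy_done(self, ev, sim) -> None:
        p: Patient = ev.payload
        p.pharmacy_end = sim.clock
        self.pharmacy.release(sim)
        p.departure = sim.clock
        self.served.append(p)
        sim.schedule(sim.clock, "departure", payload=p)

    # -- helpers -----------------------------------------------------------

    def _move(self, p: Patient, sim, next_kind: str, resource=None) -> None:
        p.n_moves += 1
        sim.schedule(sim.clock + self.config.move_time_s, next_kind,
                     payload=p, resource=resource)

    def _doctor(self, doc_id: str) -> Doctor:
        for d in self.doctors:
            if d.id == doc_id:
                return d
        raise KeyError(doc_id)


# -- per-patient performance measures -------------------------------------

def waiting_time(p: Patient) -> float:
    """Total in-queue seconds across every station, excluding service and moves."""
    if p.departure is None:
        raise ValueError(f"patient {p.id!r} has not departed; waiting time undefined")
    w = 0.0
    if p.registration_start is not None:
        w += p.registration_start - p.arrival_time
    for join, disp in zip(p.queue_joins, p.dispatch_times):
        w += disp - join
    if p.exam_start is not None:
        w += p.exam_start - p.exam_queue_join
    if p.pharmacy_start is not None:
        w += p.pharmacy_start - p.pharmacy_queue_join
    return w


def service_time(p: Patient) -> float:
    s = sum(p.consult_durations[: len(p.consult_ends)])
    if p.registration_end is not None:
        s += p.registration_end - p.registration_start
    if p.exam_end is not None:
        s += p.exam_end - p.exam_start
    if p.pharmacy_end is not None:
        s += p.pharmacy_end - p.pharmacy_start
    return s


def throughput_time(p: Patient) -> float:
    """Elapsed arrival-to-departure time: waiting + service + move time."""
    if p.departure is None:
        raise ValueError(f"patient {p.id!r} has not departed; throughput undefined")
    return p.departure - p.arrival_time


def utilization(doctor: Doctor, session_duration: float) -> float:
    """Fraction of the session the doctor spends in consultation.

    The denominator is the scheduled session length extended by any drain
    overrun (consultations running past closing), which keeps the value in
    [0, 1].
    """
    if session_duration <= 0:
        raise ValueError("session duration must be positive")
    busy = sum(b - a for a, b in doctor.busy_intervals)
    end = max([session_duration] + [b for _, b in doctor.busy_intervals])
    return busy / end
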