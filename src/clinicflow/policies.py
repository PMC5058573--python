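"""Queue disciplines for the consultation waiting room.

The clinic's house rules are layered on top of each discipline:

* special patients (over 85 or with a special condition) hold first
  priority;
* patients returning from the examination center are seen next, ahead of
  alternation but behind special patients;
* a late scheduled patient is postponed until three further patients have
  been seen (any class counts), then becomes eligible again.

The baseline discipline alternates one walk-in, one scheduled patient —
the registered-number parity rule.  Alternatives (plain FIFO,
shortest-expected-consultation-first, block alternation) share the same
dispatch interface so they can be compared under common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "QueueState",
    "PolicySpec",
    "POLICY_NAMES",
    "next_patient",
    "evaluate_policy",
    "policy_search",
]

POLICY_NAMES = ("baseline_alternating", "fifo", "sps_first", "block_interval")

WALK_IN = "walk_in"
SCHEDULED = "scheduled"


@dataclass(frozen=True)
class PolicySpec:
    """A named queue discipline plus its scalar parameters."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in POLICY_NAMES:
            raise ValueError(
                f"unknown policy {self.name!r}; registered: {POLICY_NAMES}"
            )


class QueueState:
    """The partitioned waiting room a policy inspects.

    Four FIFO queues (special / returning / walk-in / scheduled; a patient
    sits in exactly one), the alternation pointer ``last_served_class``,
    and the late-postponement trackers: one counter per late patient,
    incremented on every dispatch and removed at 3, at which point the
    patient becomes eligible.
    """

    def __init__(self) -> None:
        self.special_queue: list = []
        self.returning_queue: list = []
        self.walkin_queue: list = []
        self.scheduled_queue: list = []
        self.last_served_class: Optional[str] = None
        self.block_count: int = 0
        self.late_trackers: dict[str, int] = {}
        self._join_clock: dict[str, float] = {}

    # -- membership --------------------------------------------------------

    def add(self, p, clock: float, returning: bool = False) -> None:
        self._join_clock[p.id] = clock
        if p.special:
            self.special_queue.append(p)
        elif returning:
            self.returning_queue.append(p)
        elif p.ptype == WALK_IN:
            self.walkin_queue.append(p)
        else:
            self.scheduled_queue.append(p)

    def start_late_tracker(self, p) -> None:
        self.late_trackers[p.id] = 0

    def eligible(self, p) -> bool:
        return p.id not in self.late_trackers

    def eligible_head(self, queue: list):
        for p in queue:
            if self.eligible(p):
                return p
        return None

    def all_waiting(self) -> list:
        return (self.special_queue + self.returning_queue
                + self.walkin_queue + self.scheduled_queue)

    def join_time(self, p) -> float:
        return self._join_clock[p.id]

    # -- dispatch bookkeeping ----------------------------------------------

    def on_dispatch(self, p) -> None:
        for q in (self.special_queue, self.returning_queue,
                  self.walkin_queue, self.scheduled_queue):
            if p in q:
                was_class = q is self.walkin_queue or q is self.scheduled_queue
                q.remove(p)
                break
        else:
            raise ValueError(f"patient {p.id!r} not waiting")
        self.late_trackers.pop(p.id, None)
        # every dispatch counts toward every active late tracker
        for pid in list(self.late_trackers):
            self.late_trackers[pid] += 1
            if self.late_trackers[pid] >= 3:
                del self.late_trackers[pid]
        if was_class:
            if p.ptype == self.last_served_class:
                self.block_count += 1
            else:
                self.block_count = 1
            self.last_served_class = p.ptype


# -- disciplines -----------------------------------------------------------

def _priority_layers(state: QueueState):
    """Special first, then returning-from-examination."""
    p = state.eligible_head(state.special_queue)
    if p is not None:
        return p
    return state.eligible_head(state.returning_queue)


def _class_head(state: QueueState, cls: str):
    q = state.walkin_queue if cls == WALK_IN else state.scheduled_queue
    return state.eligible_head(q)


def _other(cls: str) -> str:
    return SCHEDULED if cls == WALK_IN else WALK_IN


def _late_fallback(state: QueueState):
    """No eligible patient anywhere: see the earliest-postponed late patient.

    Without this the clinic would deadlock (trackers only advance on
    dispatches), so when only postponed patients remain the longest-waiting
    one is seen.
    """
    waiting = state.all_waiting()
    if not waiting:
        return None
    return min(waiting, key=lambda p: (state.join_time(p), p.registration_number))


def _baseline(state: QueueState, clock: float, block: int = 1):
    p = _priority_layers(state)
    if p is not None:
        return p
    if state.last_served_class is None:
        preferred = WALK_IN
    elif state.block_count < block:
        preferred = state.last_served_class
    else:
        preferred = _other(state.last_served_class)
    p = _class_head(state, preferred)
    if p is None:  # non-idling: serve the other class rather than wait
        p = _class_head(state, _other(preferred))
    if p is None:
        p = _late_fallback(state)
    return p


def _fifo(state: QueueState, clock: float):
    best = None
    for p in state.all_waiting():
        if not state.eligible(p):
            continue
        if best is None or state.join_time(p) < state.join_time(best):
            best = p
    if best is None:
        best = _late_fallback(state)
    return best


def _sps_first(state: QueueState, clock: float):
    p = _priority_layers(state)
    if p is not None:
        return p
    heads = [h for h in (_class_head(state, WALK_IN), _class_head(state, SCHEDULED))
             if h is not None]
    if not heads:
        return _late_fallback(state)
    return min(heads, key=lambda h: (h.expected_consult_mean, state.join_time(h)))


def next_patient(state: QueueState, policy: PolicySpec, clock: float):
    """Pick the next patient for an idle doctor, or None if nobody waits."""
    if policy.name == "baseline_alternating":
        return _baseline(state, clock, block=1)
    if policy.name == "block_interval":
        return _baseline(state, clock, block=int(policy.params.get("block_size", 2)))
    if policy.name == "fifo":
        return _fifo(state, clock)
    if policy.name == "sps_first":
        return _sps_first(state, clock)
    raise ValueError(f"unknown policy {policy.name!r}")


# -- replication-level evaluation ------------------------------------------

def evaluate_policy(config, policy: PolicySpec, reps: int, seed: int):
    """Run independent replications of one session under a policy.

    Uses common random numbers: at equal ``seed`` the generated patients
    (arrivals, durations, examination decisions) are identical whatever the
    policy, so policy differences are not confounded with sampling noise.
    Returns a ``SessionStats`` with 95% confidence intervals over
    replication means.
    """
    from . import model as _model
    from . import scenarios as _scenarios
    from . import stats as _stats
    from .engine import RandomStreams, Simulator

    if reps < 2:
        raise ValueError(f"need at least 2 replications for a CI, got {reps}")
    waits, thrus, utils = [], [], []
    for rep in range(int(reps)):
        streams = RandomStreams(seed, rep=rep)
        patients = _scenarios.generate_arrivals(config, streams)
        m = _model.ClinicModel(config, patients, policy)
        sim = Simulator()
        sim.run(m, config.duration_s)
        served = m.served
        if not served:
            waits.append(0.0)
            thrus.append(0.0)
        else:
            waits.append(sum(_model.waiting_time(p) for p in served) / len(served))
            thrus.append(sum(_model.throughput_time(p) for p in served) / len(served))
        utils.append(
            sum(_model.utilization(d, config.duration_s) for d in m.doctors)
            / len(m.doctors)
        )
    return _stats.make_session_stats(config.session_id, waits, thrus, utils)


def policy_search(config, candidates: list[PolicySpec], reps: int, seed: int):
    """Evaluate candidate disciplines under common random numbers.

    Returns ``(best_policy, best_stats)`` minimizing mean waiting time;
    ties go to the earlier candidate in the list.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    best = None
    for cand in candidates:
        st = evaluate_policy(config, cand, reps, seed)
        if best is None or st.mean_waiting < best[1].mean_waiting:
            best = (cand, st)
    return best
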