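"""Deterministic, seedable discrete-event kernel.

The kernel is deliberately small: an event calendar ordered by
``(time, seq)``, a simulation clock, and a set of named random substreams.
Models plug in by implementing ``start(sim)`` and ``handle(event, sim)``;
the kernel owns ordering, time, and the event log, nothing else.

Determinism contract: two runs with the same master seed (and the same
model configuration) produce byte-identical serialized event logs.
"""

from __future__ import annotations

import csv
import heapq
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Event",
    "EventCalendar",
    "PastEventError",
    "RandomStreams",
    "Simulator",
    "serialize_event_log",
    "write_event_log",
    "EVENT_LOG_COLUMNS",
]

#: Stable column order of the event-log CSV.
EVENT_LOG_COLUMNS = ("time_s", "seq", "kind", "patient_id", "resource_id")

#: One independent substream per stochastic element of the clinic model.
#: Drawing from one never perturbs another, so e.g. switching the queue
#: discipline (which consumes no randomness) cannot reshuffle arrivals.
STREAM_NAMES = (
    "walkin_arrivals",
    "lateness",
    "no_show",
    "special",
    "age",
    "registration",
    "consult",
    "exam_decision",
    "exam",
    "pharmacy",
)


class PastEventError(ValueError):
    """Raised when an event is scheduled before the current clock."""


@dataclass(frozen=True)
class Event:
    """A single instantaneous state change.

    ``time`` is in simulated seconds from session start; ``seq`` is a
    monotone insertion counter that breaks time ties in FIFO order.
    ``payload`` is an opaque reference to the subject entity (a patient,
    usually); ``resource`` names the station or doctor involved.
    """

    time: float
    seq: int
    kind: str
    payload: object = None
    resource: Optional[str] = None

    @property
    def patient_id(self) -> str:
        pid = getattr(self.payload, "id", None)
        return "" if pid is None else str(pid)


class EventCalendar:
    """Priority queue of events, dispatched in (time, seq) order."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, Event]] = []
        self._seq = 0

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, time: float, kind: str, *, now: float = 0.0,
                 payload: object = None, resource: Optional[str] = None) -> Event:
        if time < now:
            raise PastEventError(
                f"cannot schedule {kind!r} at t={time:g} (clock is at t={now:g})"
            )
        ev = Event(time=float(time), seq=self._seq, kind=kind,
                   payload=payload, resource=resource)
        self._seq += 1
        heapq.heappush(self._heap, (ev.time, ev.seq, ev))
        return ev

    def pop(self) -> Event:
        return heapq.heappop(self._heap)[2]


class RandomStreams:
    """Named independent random substreams under one master seed.

    Each (replication, stream-name) pair gets its own ``numpy`` generator
    spawned from ``SeedSequence(master_seed, spawn_key=(rep, index))``, so
    replications and substreams are mutually independent while the whole
    family is reproducible from ``master_seed`` alone.
    """

    def __init__(self, master_seed: int, rep: int = 0) -> None:
        self.master_seed = int(master_seed)
        self.rep = int(rep)
        self._gens = {
            name: np.random.default_rng(
                np.random.SeedSequence(self.master_seed, spawn_key=(self.rep, i))
            )
            for i, name in enumerate(STREAM_NAMES)
        }

    def __getitem__(self, name: str) -> np.random.Generator:
        try:
            return self._gens[name]
        except KeyError:
            raise KeyError(
                f"unknown random stream {name!r}; known: {STREAM_NAMES}"
            ) from None


class Simulator:
    """Event loop: pops events in (time, seq) order and hands them to a model.

    A run is terminating: ``run(model, until)`` plants ``session_start`` at 0
    and ``session_end`` at ``until``; the model stops admitting work at
    ``session_end`` but in-progress and checked-in patients are drained to
    completion, so the clock may pass ``until`` before the calendar empties.
    """

    def __init__(self) -> None:
        self.clock = 0.0
        self.calendar = EventCalendar()
        self.log: list[Event] = []

    def schedule(self, time: float, kind: str, *, payload: object = None,
                 resource: Optional[str] = None) -> Event:
        return self.calendar.schedule(time, kind, now=self.clock,
                                      payload=payload, resource=resource)

    def run(self, model, until: float) -> list[Event]:
        if until <= 0:
            raise ValueError(f"session length must be positive, got {until!r}")
        self.schedule(0.0, "session_start")
        self.schedule(float(until), "session_end")
        model.start(self)
        while len(self.calendar):
            ev = self.calendar.pop()
            assert ev.time >= self.clock  # monotone clock
            self.clock = ev.time
            self.log.append(ev)
            model.handle(ev, self)
        return self.log


def serialize_event_log(log: Iterable[Event]) -> str:
    """Render an event log as CSV text (stable column order, header row)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(EVENT_LOG_COLUMNS)
    for ev in log:
        w.writerow([f"{ev.time:.6f}", ev.seq, ev.kind, ev.patient_id,
                    ev.resource or ""])
    return buf.getvalue()


def write_event_log(log: Iterable[Event], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(serialize_event_log(log))
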