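"""Shared builders for the test suite.

Everything here generates inputs programmatically; there are no stored
fixtures beyond the packaged before/after waiting-time table.
"""

from __future__ import annotations

import numpy as np
import pytest

from clinicflow.engine import RandomStreams, Simulator
from clinicflow.model import ClinicModel
from clinicflow.policies import PolicySpec
from clinicflow.scenarios import ServiceDist, SessionConfig, generate_arrivals


def mm1_session(duration_h: float = 8.0, rate_per_h: float = 6.0,
                consult_mean_s: float = 480.0) -> SessionConfig:
    """Reduce the clinic to a textbook M/M/1 queue.

    Single doctor, Poisson walk-ins, exponential consultations, and every
    other stage (registration, examination, pharmacy, movement) switched
    off, so the consultation queue is the whole system.
    """
    dur = duration_h * 3600.0
    return SessionConfig(
        session_id=1, team="sports",
        session_start_s=9 * 3600.0, session_end_s=9 * 3600.0 + dur,
        n_scheduled=0, walkin_rate_profile=((0.0, dur, rate_per_h),),
        late_rate=0.0, no_show_rate=0.0, special_rate=0.0, exam_rate=0.0,
        registration=ServiceDist("fixed", 0.0),
        consultation=ServiceDist("exponential", consult_mean_s),
        examination=ServiceDist("fixed", 0.0),
        pharmacy=ServiceDist("fixed", 0.0),
        move_time_s=0.0,
    )


def simple_session(**overrides) -> SessionConfig:
    """A small 2-hour mixed session; keyword overrides tweak any field."""
    base = dict(
        session_id=1, team="sports",
        session_start_s=9 * 3600.0, session_end_s=11 * 3600.0,
        n_scheduled=8, walkin_rate_profile=((0.0, 2 * 3600.0, 4.0),),
        consultation=ServiceDist("lognormal", 480.0, 0.5),
    )
    base.update(overrides)
    return SessionConfig(**base)


def random_session(rng: np.random.Generator) -> SessionConfig:
    """One randomized scenario for rule-property checks."""
    dur = float(rng.uniform(1.5, 2.5)) * 3600.0
    return SessionConfig(
        session_id=1,
        team=str(rng.choice(["sports", "trauma", "hand_and_foot"])),
        session_start_s=9 * 3600.0, session_end_s=9 * 3600.0 + dur,
        n_scheduled=int(rng.integers(0, 12)),
        walkin_rate_profile=((0.0, dur, float(rng.uniform(0.0, 8.0))),),
        late_rate=float(rng.uniform(0.0, 0.5)),
        lateness_mean_s=float(rng.uniform(300.0, 1800.0)),
        no_show_rate=float(rng.uniform(0.0, 0.3)),
        special_rate=float(rng.uniform(0.0, 0.3)),
        exam_rate=float(rng.uniform(0.0, 0.5)),
        registration=ServiceDist("exponential", float(rng.uniform(0.0, 180.0))),
        consultation=ServiceDist("lognormal", float(rng.uniform(240.0, 720.0)), 0.5),
        examination=ServiceDist("lognormal", float(rng.uniform(300.0, 900.0)), 0.5),
        pharmacy=ServiceDist("exponential", float(rng.uniform(0.0, 180.0))),
        move_time_s=float(rng.choice([0.0, 30.0, 60.0])),
        n_doctors=int(rng.integers(1, 3)),
    )


def run_session(config: SessionConfig, policy_name: str = "baseline_alternating",
                seed: int = 0, rep: int = 0, params: dict | None = None):
    """Generate one replication, run it, return (patients, model, simulator)."""
    streams = RandomStreams(seed, rep=rep)
    patients = generate_arrivals(config, streams)
    model = ClinicModel(config, patients, PolicySpec(policy_name, params or {}))
    sim = Simulator()
    sim.run(model, config.duration_s)
    return patients, model, sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
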