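"""Patient-flow mechanics: admission paths, the examination loop, the
performance measures, and the queueing-theory oracle."""

import numpy as np
import pytest

from clinicflow.engine import RandomStreams, Simulator
from clinicflow.model import (ClinicModel, Doctor, Patient, throughput_time,
                              service_time, utilization, waiting_time)
from clinicflow.policies import PolicySpec
from clinicflow.scenarios import ServiceDist, generate_arrivals
from conftest import mm1_session, run_session, simple_session


def make_patient(pid="p1", ptype="walk_in", arrival=0.0, consult=600.0,
                 reg_number=1, **kw):
    return Patient(id=pid, ptype=ptype, special=False, age=50.0,
                   arrival_time=arrival, registration_number=reg_number,
                   consult_durations=(consult, consult), **kw)


def run_manual(cfg, patients, policy="fifo"):
    model = ClinicModel(cfg, patients, PolicySpec(policy))
    sim = Simulator()
    sim.run(model, cfg.duration_s)
    return model, sim


class TestAdmission:
    def test_walkin_passes_registration_then_waiting_room(self):
        cfg = simple_session(move_time_s=30.0)
        p = make_patient(arrival=600.0, reg_duration=120.0)
        run_manual(cfg, [p])
        assert p.registration_start == 600.0       # clerk free on arrival
        assert p.registration_end == 720.0
        assert p.queue_joins[0] == 750.0           # after the move to the room

    def test_scheduled_goes_straight_to_waiting_room(self):
        cfg = simple_session()
        p = make_patient(ptype="scheduled", arrival=300.0, reg_number=2)
        p.appointment_time = 300.0
        run_manual(cfg, [p])
        assert p.registration_start is None
        assert p.queue_joins[0] == 300.0

    def test_no_show_is_never_admitted(self):
        cfg = simple_session()
        p = make_patient(ptype="scheduled", arrival=300.0, reg_number=2,
                         no_show=True)
        model, sim = run_manual(cfg, [p])
        assert p.queue_joins == [] and p.departure is None
        assert all(ev.patient_id != p.id for ev in sim.log)

    def test_duplicate_admission_is_an_error(self):
        cfg = simple_session()
        p = make_patient()
        model = ClinicModel(cfg, [p, p], PolicySpec("fifo"))
        with pytest.raises(ValueError, match="admitted twice"):
            Simulator().run(model, cfg.duration_s)

    def test_arrivals_after_close_are_dropped(self):
        cfg = simple_session()
        late_arrival = cfg.duration_s + 100.0
        p = make_patient(ptype="scheduled", arrival=late_arrival, reg_number=2)
        run_manual(cfg, [p])
        assert p.dropped_at_close and p.departure is None


class TestExaminationLoop:
    @pytest.mark.parametrize("exam_rate,visits", [(0.0, 1), (1.0, 2)])
    def test_degenerate_exam_rates_fix_visit_count(self, exam_rate, visits):
        cfg = simple_session(exam_rate=exam_rate)
        _, model, _ = run_session(cfg, seed=4)
        assert model.served
        for p in model.served:
            assert len(p.consult_ends) == visits

    def test_exam_fraction_matches_binomial(self):
        """With decision probability 0.3 the examined fraction over 10,000
        generated patients sits inside the 3-sigma binomial band."""
        cfg = simple_session(exam_rate=0.3,
                             walkin_rate_profile=((0.0, 7200.0, 4.0),))
        flags = []
        rep = 0
        while len(flags) < 10_000:
            pats = generate_arrivals(cfg, RandomStreams(99, rep=rep))
            flags.extend(p.needs_exam for p in pats)
            rep += 1
        frac = np.mean(flags[:10_000])
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_examined_patients_return_to_the_same_flow(self):
        cfg = simple_session(exam_rate=1.0)
        _, model, _ = run_session(cfg, seed=4)
        for p in model.served:
            assert p.exam_start is not None
            assert len(p.queue_joins) == 2          # first visit + return
            assert p.exam_end <= p.queue_joins[1]


class TestMeasures:
    def test_unqueued_patient_waits_zero(self):
        cfg = simple_session(registration=ServiceDist("fixed", 60.0),
                             move_time_s=0.0)
        p = make_patient(arrival=0.0)
        run_manual(cfg, [p])
        assert waiting_time(p) == 0.0

    def test_undeparted_patient_has_no_waiting_time(self):
        p = make_patient()
        with pytest.raises(ValueError):
            waiting_time(p)
        with pytest.raises(ValueError):
            throughput_time(p)

    def test_second_of_two_simultaneous_patients_waits_one_consultation(self):
        cfg = simple_session(registration=ServiceDist("fixed", 0.0),
                             pharmacy=ServiceDist("fixed", 0.0),
                             move_time_s=0.0, exam_rate=0.0)
        c = 600.0
        a = make_patient("a", arrival=0.0, consult=c, reg_number=1)
        b = make_patient("b", arrival=0.0, consult=c, reg_number=3)
        run_manual(cfg, [a, b])
        assert waiting_time(a) == 0.0
        assert waiting_time(b) == pytest.approx(c)

    def test_throughput_decomposes_into_wait_service_move(self):
        cfg = simple_session(exam_rate=0.4, move_time_s=45.0)
        _, model, _ = run_session(cfg, seed=6)
        assert model.served
        for p in model.served:
            total = (waiting_time(p) + service_time(p)
                     + p.n_moves * cfg.move_time_s)
            assert throughput_time(p) == pytest.approx(total)

    def test_utilization_is_busy_time_over_session(self):
        doc = Doctor(id="d", team="sports",
                     busy_intervals=[(0.0, 110.59 * 60.0)])
        assert utilization(doc, 120.0 * 60.0) == pytest.approx(0.9216, abs=1e-4)
        assert utilization(Doctor(id="d", team="sports"), 7200.0) == 0.0
        full = Doctor(id="d", team="sports", busy_intervals=[(0.0, 7200.0)])
        assert utilization(full, 7200.0) == 1.0
        with pytest.raises(ValueError):
            utilization(doc, 0.0)

    def test_drain_overrun_extends_the_utilization_denominator(self):
        doc = Doctor(id="d", team="sports", busy_intervals=[(0.0, 9000.0)])
        assert utilization(doc, 7200.0) == 1.0   # ran 1800 s past closing


class TestSystemProperties:
    def test_patients_are_conserved(self):
        cfg = simple_session(no_show_rate=0.2, late_rate=0.4)
        patients, model, _ = run_session(cfg, seed=13)
        n_no_show = sum(p.no_show for p in patients)
        n_dropped = sum(p.dropped_at_close for p in patients)
        assert len(patients) == len(model.served) + n_no_show + n_dropped

    def test_timestamp_trails_are_monotone(self):
        cfg = simple_session(exam_rate=0.5, move_time_s=30.0)
        _, model, _ = run_session(cfg, seed=13)
        for p in model.served:
            trail = p.trail()
            assert all(a <= b + 1e-9 for a, b in zip(trail, trail[1:]))

    def test_mm1_waits_equal_lindley_recursion(self):
        """Pathwise agreement with the independent Lindley-recursion oracle
        on the same arrival and service realizations."""
        cfg = mm1_session()
        patients, model, _ = run_session(cfg, "fifo", seed=42)
        arr = np.array([p.arrival_time for p in patients])
        svc = np.array([p.consult_durations[0] for p in patients])
        w = np.zeros(len(arr))
        for i in range(1, len(arr)):
            w[i] = max(0.0, w[i - 1] + svc[i - 1] - (arr[i] - arr[i - 1]))
        sim_w = np.array([waiting_time(p) for p in patients])
        np.testing.assert_allclose(sim_w, w, atol=1e-9)

    def test_mm1_steady_state_wait_matches_closed_form(self):
        """lambda=6/h, mu=1/480 s: Wq = lambda/(mu(mu-lambda)) = 1920 s.
        Long sessions with the initial transient deleted estimate the
        steady-state wait; the estimate must sit within Monte-Carlo error
        of the closed form."""
        cfg = mm1_session(duration_h=64.0)
        warm = 16.0 * 3600.0
        means = []
        for rep in range(200):
            _, model, _ = run_session(cfg, "fifo", seed=5, rep=rep)
            ws = [waiting_time(p) for p in model.served if p.arrival_time >= warm]
            means.append(np.mean(ws))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 1920.0) < max(3 * se, 0.05 * 1920.0)

    def test_littles_law_on_a_long_session(self):
        """Time-average consultation-queue length sampled on a fixed grid
        agrees with lambda times the mean queue wait within 5%."""
        cfg = mm1_session(duration_h=1700.0, rate_per_h=60.0, consult_mean_s=48.0)
        _, model, _ = run_session(cfg, "fifo", seed=17)
        served = model.served
        assert len(served) >= 100_000
        joins = np.array([p.queue_joins[0] for p in served])
        disps = np.array([p.dispatch_times[0] for p in served])
        # step trajectory of the queue length, sampled on a 60 s grid
        times = np.concatenate([joins, disps])
        steps = np.concatenate([np.ones_like(joins), -np.ones_like(disps)])
        order = np.argsort(times, kind="stable")
        times, traj = times[order], np.cumsum(steps[order])
        horizon = float(disps.max())
        grid = np.arange(0.0, horizon, 60.0)
        idx = np.searchsorted(times, grid, side="right") - 1
        q_len = np.where(idx >= 0, traj[np.maximum(idx, 0)], 0.0)
        lam = len(served) / horizon
        mean_wait = float(np.mean(disps - joins))
        assert q_len.mean() == pytest.approx(lam * mean_wait, rel=0.05)
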