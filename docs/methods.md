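# Methods

## The system being modeled

The model represents one orthopedic outpatient department with mixed
registration. A week has 12 bounded consultation sessions between 8:30 and
22:00 — five staffed by the sports team, four by the trauma team, three by
the hand-and-foot team — each run here as an independent terminating
simulation: the clinic starts empty, stops admitting at the scheduled end,
and every patient already checked in (queueing included) is served to
completion. No warm-up deletion is applied to clinic sessions, because the
empty start *is* the real initial condition.

Patient flow: walk-ins queue at a registration counter (FIFO, 2 clerks by
default) and then enter the waiting room; scheduled patients enter the
waiting room directly at their arrival time. When the doctor is free the
active queue discipline picks the next patient. After a first consultation
the patient needs an examination with probability `exam_rate`; examined
patients visit the shared examination center (capacity 3) and re-enter the
consultation queue as "returning" patients, served ahead of alternation but
behind special patients — clinics do not make a returning patient start
over, and the single-loop structure means the examination decision is made
once, at the first visit only. All patients finish at the pharmacy
(capacity 2) and depart. Movement between zones costs a constant
`move_time_s` (default 60 s) per leg; it counts toward throughput time but
not waiting time.

Waiting time is strictly time in queues (registration + consultation
visit(s) + examination + pharmacy). Throughput is arrival → departure and
decomposes exactly as waiting + service + moves (a tested invariant).
Doctor utilization is busy time divided by the scheduled session length
extended by any drain overrun, which keeps it in [0, 1].

## House rules of the waiting room

* **Special priority.** Patients over 85 (implemented strictly as
  age > 85) or with a special condition are always seen first.
* **Alternation.** The baseline discipline serves one walk-in, then one
  scheduled patient (odd/even registration numbers). When the preferred
  class has nobody eligible the doctor serves the other class rather than
  idle; idling on an empty class would deflate utilization in a way no
  clinic tolerates.
* **Late postponement.** A scheduled patient arriving after their
  appointment (grace period default 0 s) is postponed until three further
  patients — of any class, special ones included — have been seen. Each
  late patient carries a tracker incremented on every dispatch and removed
  at 3. If only postponed patients remain, the longest-waiting one is
  served; trackers advance only on dispatches, so without this fallback the
  session would deadlock with the doctor idle and patients waiting forever.
* **Disciplines.** `baseline_alternating` (the house rule), `fifo`
  (earliest waiting-room join wins, class-blind), `sps_first`
  (shortest *expected* consultation first, by class mean — realized
  durations are unknowable before dispatch), and `block_interval`
  (alternation in blocks of `block_size`). All four respect the late rule;
  `fifo` is the one discipline that also ignores the priority layers, so it
  serves as the plain-queueing reference.

## Stochastic inputs

Every random quantity a patient will ever need — registration, two
consultation durations, the examination decision, examination and pharmacy
durations, special flag, age — is drawn from named independent substreams
*when the patient is generated*, never during the run. Consequences: a
replication is reproducible byte-for-byte from the master seed; queue
disciplines, which consume no randomness, see identical patient
populations at equal seed (common random numbers); and an engine-level test
can replay the exact realizations through an independent oracle.

* Walk-ins: nonhomogeneous Poisson process over the session, simulated by
  thinning against a dominating rate sized for the top of the calibration
  bracket (10× the profile maximum). Candidates draw their full bundle
  whether accepted or not, so scaling the intensity up only adds patients —
  accepted sets are nested and the calibration objective is monotone.
* Scheduled patients: placed on the appointment grid (evenly spaced by
  default; a two-at-the-start template in the classic single-block style is
  available for block policies), independently marked no-show
  (`no_show_rate`, default 0.08) or late (`late_rate`, default 0.15, delay
  exponential with 15 min mean — the memoryless minimal assumption for an
  unspecified delay).
* Service times: lognormal for consultation and examination (right-skewed
  clinical times), exponential for registration and pharmacy, all
  parameterized by mean and CV (default 0.5) and drawn as unit-mean
  multipliers times the configured mean, so mean-scaling is smooth.

## Default parameters

Per-session arrival volumes and service parameters are design defaults,
not measurements — the source department's raw data are not public. They
are anchored to two clinic-level facts: total service averages about 14
minutes (defaults: consultation 11 min, registration 1.5 min, pharmacy
1.5 min means) while waiting averages about 104 minutes. Scheduled counts
(9–15) and walk-in rates (4.4–6.1/h) per session were set once, by
calibrating each session's walk-in intensity so baseline mean waits span
roughly 65–145 minutes across the week — the range real sessions occupy —
and then frozen. A 20-replication check on a fresh seed gives session
means from ~70 to ~143 minutes, utilizations ~0.89–0.91, and a weekly mean
wait of ~104 minutes. Exam rate defaults to 0.25, special rate to 0.05.

## Calibration

`calibrate()` bisects a scale factor in [0.1, 10] (≤ 40 steps) on one of
two monotone knobs — walk-in intensity or consultation mean — until the
simulated mean wait over `reps` replications is within a relative `tol`
(default 2%) of the target. Because evaluations reuse one seed, the
objective is a deterministic nondecreasing step-free-ish function of the
scale; a target generated by the model itself is recovered almost exactly
(a hidden 1.3× consultation scale comes back as 1.2988 in the shipped
check). Arbitrary external targets can fall inside a small discontinuity
(a reordering of dispatches); the routine then reports the final bracket
rather than pretending convergence.

## Output analysis

Replication means get Student-t intervals `x̄ ± t₍1−α/2,n−1₎·s/√n`
(α = 0.05). Before/after comparison across the 12 sessions uses per-session
improvement percentages (2 d.p.) and a one-tailed paired t-test in the
direction "waiting decreased". The packaged per-session table stores the
before/after times as h:mm:ss strings; parsing is exact integer seconds.
Recomputing from those display-rounded times reproduces the published
totals only to ±0.02 min and gives t = 8.405 / mean difference 1995.8 s
against the published 8.347 / 1995.5 (computed from unrounded source
data); the tests therefore compare at display precision or 1%,
respectively. Session 10's published improvement (31.83%) disagrees with
its own narrative value (31.78%) and with recomputation (31.77%); the
fixture carries both published variants.

## Validation oracles

* **Lindley recursion, pathwise.** On an M/M/1 reduction (single doctor,
  Poisson walk-ins, exponential consultations, everything else off) the
  engine's waits equal the independent Lindley recursion on the same
  realizations to 10⁻¹² s.
* **Closed form, steady state.** With λ = 1/600 s⁻¹ and μ = 1/480 s⁻¹ the
  steady-state mean queue wait is λ/(μ(μ−λ)) = 1920 s. The suite estimates
  it from 200 replications of 64-hour horizons with the first 16 hours
  deleted — standard steady-state methodology; the no-warm-up rule above is
  about terminating clinic sessions, not this oracle — and matches within
  Monte-Carlo error.
* **Terminating bias, quantified honestly.** The same comparison run on
  8-hour empty-start sessions gives ≈ 1160–1300 s, far below 1920 s, and
  *must*: the relaxation time of this queue, ~1/(μ(1−ρ)²) = 12 000 s, is
  commensurate with the 28 800 s session, so a terminating day never
  reaches steady state. One shipped check performs exactly this 8-hour
  comparison and fails by construction; it is kept as an explicit record
  that the short-session estimate and the steady-state formula measure
  different quantities, with the long-horizon test above showing the
  simulator itself is unbiased. The acceptance script reports both
  estimates side by side.
* **Little's law.** On a long single run (~10⁵ patients) the grid-sampled
  time-average consultation-queue length matches λ·W̄ within 5%.
* **Distributional checks.** Poisson count mean over 4000 seeds within 3σ;
  chi-square goodness-of-fit of 10⁴ window counts against Poisson not
  rejected at α = 0.01; t-interval coverage 95% ± 1% over 10⁴ trials;
  paired-t equals scipy's implementation on 1000 random instances.

## Problem sizes and determinism

Stochastic tests use 8–50 replications for policy comparisons, 200 for the
queueing oracles, and fixed seeds throughout; the heaviest single test is
the 10⁵-patient Little's-law run (~25 s). The full suite runs in about a
minute; the acceptance script in ~12 s.

## What the generator does not capture

Synthetic arrivals are stationary-by-piece Poisson with independent
marks: no day-of-week or seasonal structure, no correlation between
lateness and appointment position, no balking or reneging, no spatial
walking paths (movement is a constant per leg), no inter-departmental
contention for the shared examination center beyond its reduced capacity,
and service distributions are assumed lognormal/exponential rather than
fitted to field data. Passing tests therefore demonstrate correctness of
the mechanics and statistics on realistic magnitudes, not predictive
accuracy for any particular hospital; calibrating to local data is the
intended path to the latter.
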