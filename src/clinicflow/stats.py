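"""Output analysis for terminating-simulation replications.

Replication means get Student-t 95% confidence intervals; validation
against field-collected session averages uses absolute percent
differences plus CI containment; before/after waiting times across the 12
weekly sessions are compared with per-session improvement percentages and
a one-tailed paired t-test.

Also houses the hh:mm:ss parsing used by the packaged per-session
before/after waiting-time table (``data/table2.csv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SessionStats",
    "ComparisonResult",
    "hms_to_seconds",
    "seconds_to_hms",
    "improvement_pct",
    "summarize",
    "percent_difference",
    "paired_t",
    "waiting_fraction",
    "make_session_stats",
    "load_table2",
]

_HMS_RE = re.compile(r"^(\d+):([0-5]\d):([0-5]\d)$")


@dataclass(frozen=True)
class SessionStats:
    """Point estimates and 95% CIs over a session's replication means."""

    session_id: int
    n_reps: int
    mean_waiting: float
    mean_throughput: float
    mean_utilization: float
    ci_waiting: tuple[float, float]
    ci_throughput: tuple[float, float]
    ci_utilization: tuple[float, float]
    alpha: float = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """Paired before/after comparison across sessions.

    Differences are before - after in seconds; the one-tail p-value tests
    the direction "waiting time decreased".
    """

    differences: tuple[float, ...]
    mean_difference: float
    dof: int
    t_value: float
    one_tail_p: float
    improvement_pct: tuple[float, ...]
    total_before_min: float
    total_after_min: float


def hms_to_seconds(text: str) -> int:
    """Parse an ``h:mm:ss`` duration into whole seconds."""
    m = _HMS_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed h:mm:ss duration: {text!r}")
    h, mi, s = (int(g) for g in m.groups())
    return 3600 * h + 60 * mi + s


def seconds_to_hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def improvement_pct(before: float, after: float) -> float:
    """Waiting-time improvement percentage, rounded to 2 decimals."""
    if before <= 0:
        raise ValueError(f"'before' must be positive, got {before!r}")
    return round(100.0 * (before - after) / before, 2)


def summarize(replication_means, alpha: float = 0.05):
    """Student-t confidence interval: mean +/- t_{1-a/2,n-1} * s/sqrt(n)."""
    x = np.asarray(list(replication_means), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need >= 2 replication means for a CI, got {n}")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    half = float(sps.t.ppf(1 - alpha / 2, n - 1)) * s / np.sqrt(n)
    return mean, mean - half, mean + half


def percent_difference(simulated: float, collected: float) -> float:
    """Absolute percent difference of a simulated estimate from a target."""
    if collected == 0:
        raise ValueError("collected value must be nonzero")
    return 100.0 * abs(simulated - collected) / abs(collected)


def paired_t(before, after) -> ComparisonResult:
    """One-tailed paired t-test that waiting time decreased (before > after)."""
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if b.size != a.size:
        raise ValueError(f"length mismatch: {b.size} before vs {a.size} after")
    if b.size < 2:
        raise ValueError("need at least 2 paired sessions")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(sps.t.sf(t, n - 1))
    return ComparisonResult(
        differences=tuple(float(v) for v in d),
        mean_difference=float(d.mean()),
        dof=n - 1,
        t_value=t,
        one_tail_p=p,
        improvement_pct=tuple(improvement_pct(x, y) for x, y in zip(b, a)),
        total_before_min=float(b.sum() / 60.0),
        total_after_min=float(a.sum() / 60.0),
    )


def waiting_fraction(waiting_min: float, service_min: float) -> float:
    """Share of total process time spent waiting, in percent."""
    return 100.0 * waiting_min / (waiting_min + service_min)


def make_session_stats(session_id, waits, throughputs, utilizations,
                       alpha: float = 0.05) -> SessionStats:
    mw, lw, hw = summarize(waits, alpha)
    mt, lt, ht = summarize(throughputs, alpha)
    mu, lu, hu = summarize(utilizations, alpha)
    return SessionStats(
        session_id=session_id, n_reps=len(list(waits)),
        mean_waiting=mw, mean_throughput=mt, mean_utilization=mu,
        ci_waiting=(lw, hw), ci_throughput=(lt, ht), ci_utilization=(lu, hu),
        alpha=alpha,
    )


def load_table2() -> pd.DataFrame:
    """Packaged per-session before/after waiting times (hh:mm:ss strings).

    Columns: session, before_hms, after_hms, printed_improvement_pct (the
    table as published) and discussion_improvement_pct (the narrative's
    per-session value, which differs for session 10); before_s / after_s
    parsed seconds are added on load.
    """
    with resources.files("clinicflow").joinpath("data/table2.csv").open() as fh:
        df = pd.read_csv(fh)
    df["before_s"] = df["before_hms"].map(hms_to_seconds)
    df["after_s"] = df["after_hms"].map(hms_to_seconds)
    return df
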