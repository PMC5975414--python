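"""Kaplan–Meier estimation with expression-cutoff grouping.

Patients are split into low/high groups by an isoform-expression cutoff
(default: the midpoint of the observed expression range; ties go to the high
group), optionally filtered by a survival start time, and each group's
survival is summarized by the product-limit estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass(frozen=True)
class SurvivalSample:
    sample_id: str
    time: float
    event: int
    expression: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")
        if self.expression < 0:
            raise ValueError(f"{self.sample_id}: negative expression")


@dataclass
class KMCurve:
    """Product-limit curve evaluated at the distinct event times.

    ``times`` are the event times in increasing order; ``survival[k]`` is
    S(times[k]) just after the events at that time; ``at_risk[k]`` the number
    at risk just before it.  ``censor_times`` records censoring times for tick
    marks.  S starts at 1 before the first event.
    """

    group_label: str
    n: int
    times: list[float] = field(default_factory=list)
    survival: list[float] = field(default_factory=list)
    at_risk: list[int] = field(default_factory=list)
    censor_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("event times must be strictly increasing")
        s = [1.0] + list(self.survival)
        if any(b > a + 1e-12 for a, b in zip(s, s[1:])):
            raise ValueError("survival must be non-increasing from 1")
        if any(v < 0 or v > 1 for v in self.survival):
            raise ValueError("survival values must lie in [0, 1]")


def split_by_cutoff(
    samples: list[SurvivalSample], cutoff: float | str = "default"
) -> tuple[list[SurvivalSample], list[SurvivalSample], float]:
    """Partition samples into low (< cutoff) and high (>= cutoff) groups.

    The default cutoff is the midpoint of the expression range,
    (min + max) / 2.  Either group may be empty (with a warning); the caller
    still gets both lists plus the cutoff used.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    expr = [s.expression for s in samples]
    if cutoff == "default":
        cutoff_value = (min(expr) + max(expr)) / 2.0
    else:
        cutoff_value = float(cutoff)
    low = [s for s in samples if s.expression < cutoff_value]
    high = [s for s in samples if s.expression >= cutoff_value]
    if not low or not high:
        warnings.warn(
            f"cutoff {cutoff_value:g} leaves an empty group "
            f"(low n={len(low)}, high n={len(high)})",
            stacklevel=2,
        )
    return low, high, cutoff_value


def filter_start_time(
    samples: list[SurvivalSample], start_time: float
) -> list[SurvivalSample]:
    """Keep samples with time >= start_time; re-zero retained times.

    This is a plain filter (the time axis restarts at the start time), not a
    delayed-entry risk-set adjustment.
    """
    if start_time < 0:
        raise ValueError("start_time must be non-negative")
    return [
        SurvivalSample(s.sample_id, s.time - start_time, s.event, s.expression)
        for s in samples
        if s.time >= start_time
    ]


def km_estimate(samples: list[SurvivalSample], group_label: str = "") -> KMCurve:
    """Product-limit survival estimate for one group.

    At each distinct event time t_k with d_k deaths among r_k at risk,
    S <- S * (1 - d_k / r_k); times with only censorings shrink the risk set
    but add no step.
    """
    if not samples:
        raise ValueError("need at least 1 sample")
    times = np.array([s.time for s in samples], dtype=float)
    events = np.array([s.event for s in samples], dtype=int)

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table  # indexed by time: removed, observed, censored, at_risk

    event_rows = tbl[tbl["observed"] > 0]
    ev_times = [float(t) for t in event_rows.index]
    at_risk = [int(v) for v in event_rows["at_risk"]]
    sf = kmf.survival_function_["KM_estimate"]
    survival = [float(sf.loc[t]) for t in event_rows.index]

    censor_times = sorted(float(t) for t, e in zip(times, events) if e == 0)
    return KMCurve(
        group_label=group_label,
        n=len(samples),
        times=ev_times,
        survival=survival,
        at_risk=at_risk,
        censor_times=censor_times,
    )


def build_survival_samples(
    expression: pd.Series | dict[str, float],
    harmonized: pd.DataFrame,
) -> tuple[list[SurvivalSample], dict]:
    """Join isoform expression with harmonized survival by sample_id.

    Inner-join semantics: samples missing from either side, or lacking a
    survival time, are dropped and tallied in the reconciliation report.
    """
    if isinstance(expression, dict):
        expression = pd.Series(expression)
    clin = harmonized.set_index("sample_id") if "sample_id" in harmonized else harmonized
    expr_ids = set(map(str, expression.index))
    clin_ids = set(map(str, clin.index))
    shared = sorted(expr_ids & clin_ids)
    samples = []
    n_no_survival = 0
    for sid in shared:
        t = clin.loc[sid, "survival_time"]
        e = clin.loc[sid, "survival_event"]
        if t is None or (isinstance(t, float) and np.isnan(t)):
            n_no_survival += 1
            continue
        samples.append(
            SurvivalSample(
                sample_id=sid,
                time=float(t),
                event=int(e),
                expression=float(expression.loc[sid]),
            )
        )
    report = {
        "n_expression_only": len(expr_ids - clin_ids),
        "n_clinical_only": len(clin_ids - expr_ids),
        "n_joined": len(shared),
        "n_without_survival": n_no_survival,
        "n_used": len(samples),
    }
    return samples, report


def curves_to_tsv(curves: list[KMCurve], path) -> None:
    """Export curves as TSV columns: group, time, survival, at_risk."""
    with open(path, "w") as fh:
        fh.write("group\ttime\tsurvival\tat_risk\n")
        for c in curves:
            for t, s, r in zip(c.times, c.survival, c.at_risk):
                fh.write(f"{c.group_label}\t{t:.10g}\t{s:.10g}\t{r}\n")


def logrank(group_a: list[SurvivalSample], group_b: list[SurvivalSample]) -> float:
    """Two-group log-rank p-value.

    Convenience extra beyond the plotted curves; the figures themselves carry
    no test statistic.
    """
    from lifelines.statistics import logrank_test

    res = logrank_test(
        [s.time for s in group_a],
        [s.time for s in group_b],
        event_observed_A=[s.event for s in group_a],
        event_observed_B=[s.event for s in group_b],
    )
    return float(res.p_value)
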