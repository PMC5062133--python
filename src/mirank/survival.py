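"""Survival stratification by extreme miRNA expression.

For a candidate miRNA, samples whose expression falls in the bottom 10% of
values form the under-expressed group and the top 10% the over-expressed
group; Kaplan-Meier survival curves are estimated per group and compared
with a two-group log-rank test (chi-square, 1 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import ClinicalTable

__all__ = [
    "StepFunction",
    "SurvivalResult",
    "split_extremes",
    "kaplan_meier",
    "logrank_test",
    "analyze_mirna",
    "survival_table",
]


@dataclass
class StepFunction:
    """Right-continuous survival step function S(t): starts at 1, drops at
    event times."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalResult:
    mirna_id: str
    group_assignment: dict[str, str]  # sample -> under / over / excluded
    km_under: StepFunction
    km_over: StepFunction
    logrank_stat: float
    p: float

    @property
    def n_under(self) -> int:
        return sum(1 for g in self.group_assignment.values() if g == "under")

    @property
    def n_over(self) -> int:
        return sum(1 for g in self.group_assignment.values() if g == "over")


def split_extremes(
    expr_row: pd.Series, clinical: ClinicalTable, fraction: float = 0.10
) -> dict[str, str]:
    """Assign clinical samples to under/over-expressed extreme groups.

    Boundaries are nearest-rank quantiles of the expression values among
    samples with clinical records: the lowest ceil(fraction*n) values set
    the under threshold, the highest set the over threshold; boundary ties
    are all included. Overlapping groups (degenerate, e.g. constant
    expression) raise an error.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    samples = [s for s in clinical.sample_ids if s in expr_row.index]
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples with clinical records")
    values = expr_row.loc[samples].to_numpy(dtype=float)
    k = math.ceil(fraction * n)
    sorted_vals = np.sort(values)
    lo_thr = sorted_vals[k - 1]
    hi_thr = sorted_vals[n - k]
    under = {s for s, v in zip(samples, values) if v <= lo_thr}
    over = {s for s, v in zip(samples, values) if v >= hi_thr}
    if under & over:
        raise ValueError("degenerate expression: extreme groups overlap")
    if not under or not over:
        raise ValueError("empty extreme group")
    assignment = {}
    for s in samples:
        assignment[s] = "under" if s in under else "over" if s in over else "excluded"
    return assignment


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> StepFunction:
    """Product-limit estimate of the survival function.

    Censored subjects leave the risk set without contributing a death
    factor; the curve starts at S(0) = 1 and is right-continuous.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    res = _ll_logrank(
        np.asarray(times_a, float),
        np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, int),
        event_observed_B=np.asarray(events_b, int),
    )
    return float(res.test_statistic), float(res.p_value)


def analyze_mirna(
    mirna_id: str,
    expr_row: pd.Series,
    clinical: ClinicalTable,
    fraction: float = 0.10,
) -> SurvivalResult:
    """Full survival analysis of one miRNA: split, KM per group, log-rank."""
    assignment = split_extremes(expr_row, clinical, fraction)
    groups = {"under": [], "over": []}
    for s, g in assignment.items():
        if g in groups:
            groups[g].append(s)
    t_u = clinical.data.loc[groups["under"], "time"].to_numpy()
    e_u = clinical.data.loc[groups["under"], "event"].to_numpy()
    t_o = clinical.data.loc[groups["over"], "time"].to_numpy()
    e_o = clinical.data.loc[groups["over"], "event"].to_numpy()
    stat, p = logrank_test(t_u, e_u, t_o, e_o)
    return SurvivalResult(
        mirna_id=mirna_id,
        group_assignment=assignment,
        km_under=kaplan_meier(t_u, e_u),
        km_over=kaplan_meier(t_o, e_o),
        logrank_stat=stat,
        p=p,
    )


def survival_table(results: Sequence[SurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [r.mirna_id for r in results],
            "n_under": [r.n_under for r in results],
            "n_over": [r.n_over for r in results],
            "logrank_stat": [r.logrank_stat for r in results],
            "p": [r.p for r in results],
        }
    ).set_index("mirna")


def write_survival(results: Sequence[SurvivalResult], path: str | Path) -> None:
    survival_table(results).to_csv(path, sep="\t")
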