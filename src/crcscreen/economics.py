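"""Cost-effectiveness comparison of screening strategies.

Strategies are compared by incremental cost-effectiveness ratios (ICERs,
USD per QALY gained) against the no-screening baseline and against the
next-most-effective strategy in the QALY ordering, then classified against
willingness-to-pay thresholds (3x per-capita GDP and the chronic-disease
threshold of 1.76x GDP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort_engine import StrategyOutcome
from .util import round_half_up_int

__all__ = [
    "IcerResult",
    "IcerRow",
    "ThresholdSet",
    "compute_icer",
    "rank_and_compare",
    "classify_against_threshold",
    "ThresholdReport",
    "efficiency_frontier",
    "reference_table",
    "icer_consistency",
]

DOMINATED = "dominated"
DOMINANT = "dominant"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class IcerResult:
    """An ICER in USD/QALY, or a dominance flag instead of a ratio."""

    value: Optional[int]
    status: str  # "icer", "dominated", "dominant", "undefined"

    @property
    def is_ratio(self) -> bool:
        return self.status == "icer"

    def __str__(self) -> str:
        return str(self.value) if self.is_ratio else self.status


def compute_icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Incremental cost-effectiveness ratio, rounded to the nearest dollar.

    A strategy that loses QALYs without saving money is ``dominated``; one
    that gains QALYs and saves money (or is free) is ``dominant``; both
    deltas zero is ``undefined``.  A sign-flipped ratio is never reported
    for a dominated strategy.
    """
    if delta_cost == 0 and delta_qaly == 0:
        return IcerResult(value=None, status=UNDEFINED)
    if delta_qaly > 0 and delta_cost <= 0:
        return IcerResult(value=None, status=DOMINANT)
    if delta_qaly <= 0 and delta_cost >= 0:
        return IcerResult(value=None, status=DOMINATED)
    return IcerResult(value=round_half_up_int(delta_cost / delta_qaly), status="icer")


@dataclass(frozen=True)
class ThresholdSet:
    """Willingness-to-pay thresholds anchored on per-capita GDP (2023 USD)."""

    per_capita_gdp: float = 17_745.0
    gdp_multiple: float = 3.0
    chronic_multiple: float = 1.76

    def __post_init__(self) -> None:
        if self.per_capita_gdp <= 0:
            raise ValueError("per-capita GDP must be positive")
        if not 0 < self.chronic_multiple <= self.gdp_multiple:
            raise ValueError("thresholds must be positive and ordered")

    @property
    def three_gdp(self) -> float:
        return self.gdp_multiple * self.per_capita_gdp

    @property
    def chronic_disease(self) -> float:
        return self.chronic_multiple * self.per_capita_gdp

    def as_dict(self) -> dict[str, float]:
        return {"three_gdp": self.three_gdp, "chronic_disease": self.chronic_disease}


@dataclass
class IcerRow:
    """One strategy's comparison row (Table-4 shaped)."""

    label: str
    qalys: float
    cost: float
    inc_qaly_vs_baseline: float
    inc_cost_vs_baseline: float
    icer_vs_baseline: IcerResult
    inc_qaly_vs_next: float
    inc_cost_vs_next: float
    icer_vs_next: IcerResult
    cost_effective: dict = field(default_factory=dict)


_OutcomeLike = Union[StrategyOutcome, tuple]


def _as_qaly_cost(item: _OutcomeLike) -> tuple[str, float, float]:
    if isinstance(item, StrategyOutcome):
        return item.strategy.label, item.qalys, item.cost
    label, qalys, cost = item
    return str(label), float(qalys), float(cost)


def rank_and_compare(
    outcomes: Sequence[_OutcomeLike],
    baseline: _OutcomeLike,
) -> list[IcerRow]:
    """ICER rows vs the baseline and vs the next-most-effective strategy.

    Strategies are ordered by ascending QALYs (ties by ascending cost);
    each row's "next" comparator is its predecessor in that ordering, the
    baseline for the least effective strategy.  No dominance pruning is
    applied: every strategy is compared to its QALY-predecessor regardless
    of frontier status (use :func:`efficiency_frontier` for a pruned view).
    """
    base_label, base_q, base_c = _as_qaly_cost(baseline)
    triples = [_as_qaly_cost(o) for o in outcomes]
    labels = [t[0] for t in triples]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")
    triples.sort(key=lambda t: (t[1], t[2]))
    rows: list[IcerRow] = []
    prev_q, prev_c = base_q, base_c
    for label, q, c in triples:
        rows.append(
            IcerRow(
                label=label,
                qalys=q,
                cost=c,
                inc_qaly_vs_baseline=q - base_q,
                inc_cost_vs_baseline=c - base_c,
                icer_vs_baseline=compute_icer(c - base_c, q - base_q),
                inc_qaly_vs_next=q - prev_q,
                inc_cost_vs_next=c - prev_c,
                icer_vs_next=compute_icer(c - prev_c, q - prev_q),
            )
        )
        prev_q, prev_c = q, c
    return rows


@dataclass
class ThresholdReport:
    rows: list
    max_icer: Optional[int]
    all_cost_effective: dict


def classify_against_threshold(rows: Sequence[IcerRow], thresholds: ThresholdSet) -> ThresholdReport:
    """Flag each row against each threshold (ICER <= threshold convention).

    Dominant strategies are cost-effective at any threshold, dominated ones
    at none.  The report carries the maximum ratio ICER and whether every
    strategy passes each threshold.
    """
    ratio_values = []
    for row in rows:
        flags = {}
        for name, wtp in thresholds.as_dict().items():
            res = row.icer_vs_baseline
            if res.status == DOMINANT:
                flags[name] = True
            elif res.is_ratio:
                flags[name] = res.value <= wtp
            else:
                flags[name] = False
        row.cost_effective = flags
        if row.icer_vs_baseline.is_ratio:
            ratio_values.append(row.icer_vs_baseline.value)
    all_ce = {
        name: all(r.cost_effective[name] for r in rows) for name in thresholds.as_dict()
    }
    return ThresholdReport(
        rows=list(rows),
        max_icer=max(ratio_values) if ratio_values else None,
        all_cost_effective=all_ce,
    )


def efficiency_frontier(outcomes: Sequence[_OutcomeLike]) -> list[str]:
    """Labels on the cost-effectiveness frontier (strict + extended dominance)."""
    triples = sorted((_as_qaly_cost(o) for o in outcomes), key=lambda t: (t[2], t[1]))
    # strict dominance: drop anything with no QALY gain over a cheaper option
    frontier = []
    best_q = -np.inf
    for label, q, c in triples:
        if q > best_q:
            frontier.append([label, q, c])
            best_q = q
    # extended dominance: ICERs along the frontier must be increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            l0, q0, c0 = frontier[i - 1]
            l1, q1, c1 = frontier[i]
            l2, q2, c2 = frontier[i + 1]
            icer_prev = (c1 - c0) / (q1 - q0)
            icer_next = (c2 - c1) / (q2 - q1)
            if icer_prev >= icer_next:
                frontier.pop(i)
                changed = True
                break
    return [f[0] for f in frontier]


def rows_to_frame(rows: Sequence[IcerRow], cost_in_thousands: bool = True) -> pd.DataFrame:
    """Export comparison rows as a table (costs in thousands, as published)."""
    recs = []
    scale = 1e-3 if cost_in_thousands else 1.0
    for r in rows:
        recs.append(
            {
                "strategy": r.label,
                "qalys": r.qalys,
                "cost_thousand" if cost_in_thousands else "cost": r.cost * scale,
                "inc_qaly_vs_baseline": r.inc_qaly_vs_baseline,
                "inc_cost_vs_baseline": r.inc_cost_vs_baseline * scale,
                "icer_vs_baseline": str(r.icer_vs_baseline),
                "inc_qaly_vs_next": r.inc_qaly_vs_next,
                "inc_cost_vs_next": r.inc_cost_vs_next * scale,
                "icer_vs_next": str(r.icer_vs_next),
                **{f"ce_{k}": v for k, v in r.cost_effective.items()},
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# published reference table (internal-consistency suite)
# ---------------------------------------------------------------------------


def reference_table() -> pd.DataFrame:
    """The published strategy-comparison table (QALYs, costs, increments,
    ICERs; costs in thousands of USD) shipped with the package."""
    ref = resources.files("crcscreen.data").joinpath("cost_effectiveness_reference.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def icer_consistency(reference: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Recompute each reference row's vs-baseline ICER from its printed
    increments and report the deviation from the printed ICER.

    Also carries the deviation bound propagated from the printed precision
    (increments rounded to 1 QALY and 1 thousand USD), against which every
    row of a correctly transcribed table must be consistent.
    """
    df = (reference if reference is not None else reference_table()).copy()
    df = df.dropna(subset=["inc_qaly_vs_ns"]).reset_index(drop=True)
    out = []
    for _, r in df.iterrows():
        dq = float(r["inc_qaly_vs_ns"])
        dc = float(r["inc_cost_vs_ns_thousand"]) * 1000.0
        computed = compute_icer(dc, dq)
        ratio = dc / dq
        printed = float(r["icer_vs_ns"])
        # deviation the printed precision alone can induce: the increments
        # are rounded to 1 QALY / 1 thousand USD and the printed ICER to 1 USD
        bound = (abs(ratio) * 0.5 + 500.0) / max(dq - 0.5, 1e-9) + 0.5
        out.append(
            {
                "age_group": r["age_group"],
                "strategy": r["strategy"],
                "icer_printed": printed,
                "icer_recomputed": computed.value,
                "deviation": computed.value - printed,
                "ratio_deviation": ratio - printed,
                "precision_bound": bound,
            }
        )
    return pd.DataFrame(out)
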