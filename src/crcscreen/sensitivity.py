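"""Deterministic and probabilistic sensitivity analysis.

One-way sweeps re-run the full model with a single parameter moved across
its plausible range; the probabilistic sensitivity analysis (PSA) samples
all parameters jointly from their distributions and re-evaluates the
strategy grid per draw, summarising decision uncertainty with
cost-effectiveness acceptability curves (CEACs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import ScreeningStrategy, StrategyOutcome, run_cohort
from .economics import ThresholdSet
from .natural_history import TransitionModel, aged_distribution
from .parameters import ParameterSet

__all__ = [
    "one_way_sweep",
    "OneWayResult",
    "run_psa",
    "PsaResult",
    "ceac",
    "probability_cost_effective",
    "default_wtp_grid",
]

BASELINE_LABEL = "none"


def default_wtp_grid(upper: float = 106_470.0, step: float = 500.0) -> np.ndarray:
    """Willingness-to-pay grid, 0 to twice the 3x-GDP threshold in 500-USD steps."""
    return np.arange(0.0, upper + step / 2, step)


@dataclass
class OneWayResult:
    parameter: str
    table: pd.DataFrame
    ranking_changed: bool


def _evaluate(
    params: ParameterSet,
    strategies: Sequence[ScreeningStrategy],
    cohort_size: float,
    discount_rate: Optional[float] = None,
    init_mode: str = "aged",
) -> dict[str, StrategyOutcome]:
    model = TransitionModel(params)
    inits: dict[int, object] = {}
    out = {}
    for s in strategies:
        if init_mode == "aged":
            if s.entry_age not in inits:
                inits[s.entry_age] = aged_distribution(params, s.entry_age, model=model)
            init = inits[s.entry_age]
        else:
            init = None
        out[s.label] = run_cohort(s, params, init=init, cohort_size=cohort_size,
                                  discount_rate=discount_rate, model=model)
    return out


def one_way_sweep(
    parameter: str,
    values: Sequence[float],
    params: ParameterSet,
    strategies: Sequence[ScreeningStrategy],
    baseline: ScreeningStrategy,
    cohort_size: float = 100_000,
    init_mode: str = "aged",
) -> OneWayResult:
    """Re-run the model at each value of one parameter, others at base case.

    For an age-banded parameter the values are multiplicative factors
    applied to every band (the bands keep their age profile).  The result
    notes whether the strategies' QALY ranking changed anywhere in the
    sweep relative to the base case.
    """
    if parameter not in params:
        raise KeyError(f"unknown parameter {parameter!r}")
    banded = True
    try:
        params.value(parameter)
        banded = False
    except KeyError:
        pass

    base_outcomes = _evaluate(params, [baseline, *strategies], cohort_size, init_mode=init_mode)
    base_rank = tuple(sorted((s.label for s in strategies),
                             key=lambda l: base_outcomes[l].qalys))

    rows = []
    ranking_changed = False
    for v in values:
        trial = (
            params.with_scaled_bands(parameter, v) if banded
            else params.with_value(parameter, v)
        )
        discount = trial["discount_rate"] if parameter == "discount_rate" else None
        outcomes = _evaluate(trial, [baseline, *strategies], cohort_size, discount, init_mode=init_mode)
        base = outcomes[baseline.label]
        rank = tuple(sorted((s.label for s in strategies), key=lambda l: outcomes[l].qalys))
        if rank != base_rank:
            ranking_changed = True
        for s in strategies:
            o = outcomes[s.label]
            dq, dc = o.qalys - base.qalys, o.cost - base.cost
            rows.append(
                {
                    "parameter": parameter,
                    "value": v,
                    "strategy": s.label,
                    "qalys": o.qalys,
                    "cost": o.cost,
                    "inc_qaly": dq,
                    "inc_cost": dc,
                    "icer_vs_baseline": dc / dq if dq > 0 else np.nan,
                    "crc_deaths": o.crc_deaths,
                    "deaths_averted": base.crc_deaths - o.crc_deaths,
                }
            )
    return OneWayResult(parameter=parameter, table=pd.DataFrame(rows),
                        ranking_changed=ranking_changed)


@dataclass
class PsaResult:
    """Joint-uncertainty evaluation of a strategy set.

    ``samples`` is long-format (draw, strategy, qalys, cost); ``summary``
    carries per-strategy means and 95 % uncertainty intervals (2.5/97.5
    percentiles), including the per-draw ICER versus the baseline.
    """

    seed: int
    n_draws: int
    baseline_label: str
    samples: pd.DataFrame
    summary: pd.DataFrame

    def wide(self, column: str) -> pd.DataFrame:
        return self.samples.pivot(index="draw", columns="strategy", values=column)


def run_psa(
    n_draws: int,
    seed: int,
    params: ParameterSet,
    strategies: Sequence[ScreeningStrategy],
    baseline: ScreeningStrategy,
    cohort_size: float = 100_000,
    init_mode: str = "aged",
) -> PsaResult:
    """Monte-Carlo PSA: one joint parameter draw and grid evaluation per draw.

    Per-draw random substreams are spawned deterministically from the master
    seed, so results do not depend on evaluation order or draw count.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_draws)
    records = []
    for draw, child in enumerate(children):
        drawn = params.sample(np.random.default_rng(child))
        outcomes = _evaluate(drawn, [baseline, *strategies], cohort_size,
                             discount_rate=drawn["discount_rate"], init_mode=init_mode)
        for label, o in outcomes.items():
            records.append({"draw": draw, "strategy": label, "qalys": o.qalys, "cost": o.cost})
    samples = pd.DataFrame(records)

    base = samples[samples.strategy == baseline.label].set_index("draw")
    rows = []
    for label, g in samples.groupby("strategy", sort=False):
        g = g.set_index("draw")
        dq = g.qalys - base.qalys
        dc = g.cost - base.cost
        with np.errstate(divide="ignore", invalid="ignore"):
            icer = np.where(dq > 0, dc / dq, np.nan)
        rows.append(
            {
                "strategy": label,
                "qalys_mean": g.qalys.mean(),
                "qalys_lo": g.qalys.quantile(0.025),
                "qalys_hi": g.qalys.quantile(0.975),
                "cost_mean": g.cost.mean(),
                "cost_lo": g.cost.quantile(0.025),
                "cost_hi": g.cost.quantile(0.975),
                "icer_mean": np.nanmean(icer) if label != baseline.label else np.nan,
                "icer_lo": np.nanpercentile(icer, 2.5) if label != baseline.label else np.nan,
                "icer_hi": np.nanpercentile(icer, 97.5) if label != baseline.label else np.nan,
            }
        )
    return PsaResult(
        seed=seed,
        n_draws=n_draws,
        baseline_label=baseline.label,
        samples=samples,
        summary=pd.DataFrame(rows),
    )


def ceac(
    samples: pd.DataFrame,
    wtp_grid: Sequence[float],
    baseline_label: str = BASELINE_LABEL,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA samples.

    At each willingness-to-pay value, a strategy is cost-effective versus
    the baseline when its net monetary benefit gain ``wtp * dQALY - dCost``
    is non-negative, and optimal when it has the highest net monetary
    benefit among all strategies (baseline included; ties broken toward
    lower cost).  Probabilities are fractions of draws; the per-wtp optimal
    probabilities sum to one.
    """
    if samples.empty:
        raise ValueError("empty PSA sample set")
    qalys = samples.pivot(index="draw", columns="strategy", values="qalys")
    costs = samples.pivot(index="draw", columns="strategy", values="cost")
    if baseline_label not in qalys.columns:
        raise ValueError(f"baseline {baseline_label!r} missing from samples")
    labels = list(qalys.columns)
    # deterministic tie-break: cheaper strategy wins equal NMB
    order = np.argsort([costs[l].mean() for l in labels], kind="stable")
    q = qalys.to_numpy()[:, order]
    c = costs.to_numpy()[:, order]
    ordered = [labels[i] for i in order]
    dq = qalys.sub(qalys[baseline_label], axis=0)
    dc = costs.sub(costs[baseline_label], axis=0)

    rows = []
    for wtp in wtp_grid:
        nmb = wtp * q - c
        best = np.argmax(nmb, axis=1)  # first (cheapest) argmax wins ties
        for j, label in enumerate(ordered):
            rows.append(
                {
                    "wtp": float(wtp),
                    "strategy": label,
                    "p_cost_effective": float((wtp * dq[label] - dc[label] >= 0).mean()),
                    "p_optimal": float((best == j).mean()),
                }
            )
    return pd.DataFrame(rows)


def probability_cost_effective(
    samples: pd.DataFrame, strategy_label: str, wtp: float,
    baseline_label: str = BASELINE_LABEL,
) -> float:
    """Fraction of PSA draws in which a strategy is cost-effective vs baseline."""
    curve = ceac(samples, [wtp], baseline_label=baseline_label)
    row = curve[curve.strategy == strategy_label]
    if row.empty:
        raise KeyError(f"strategy {strategy_label!r} not in samples")
    return float(row.p_cost_effective.iloc[0])
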