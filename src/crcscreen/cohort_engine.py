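"""Closed-cohort simulation of screening strategies.

A closed cohort (reported per 100 000 members) enters at a strategy's mean
entry age and is cycled annually until mean age 82.  Within each cycle the
event order is fixed: (1) a screening round if scheduled, (2) symptom
detection with its treatment-compliance split, (3) natural-history
progression and recurrence, (4) mortality — steps 2-4 are encoded in the
one-cycle transition structure of :mod:`crcscreen.natural_history`.
Utilities and the annual follow-up cost accrue on the half-cycle mean state
occupancy; event costs (screens, colonoscopies, diagnoses, treatments)
accrue at the cycle in which they occur.  All accruals in cycle *t* are
discounted by ``(1 + r) ** -t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .natural_history import (
    ALIVE,
    CLASS_STATES,
    CRC_CLASSES,
    LESION_CLASSES,
    MAX_AGE,
    N_STATES,
    TREATED,
    HealthState,
    TransitionModel,
    aged_distribution,
)
from .parameters import ParameterSet

__all__ = [
    "ScreeningStrategy",
    "CycleLedger",
    "StrategyOutcome",
    "apply_screening_round",
    "run_cohort",
    "deaths_averted",
    "DeathsAverted",
    "run_strategy_grid",
    "FREQUENCY_INTERVALS",
    "ENTRY_AGES",
]

S = HealthState

#: screening frequency label -> interval in years (None = single round / none)
FREQUENCY_INTERVALS: Mapping[str, Optional[int]] = {
    "none": None,
    "once": None,
    "every_10y": 10,
    "every_5y": 5,
    "every_3y": 3,
    "every_2y": 2,
    "annual": 1,
}

#: mean entry ages of the seven modelled initiation bands (40-44 ... 70-74)
ENTRY_AGES = (42, 47, 52, 57, 62, 67, 72)

MASS_TOL = 1e-10
COHORT_SIZE = 100_000

# states eligible for a screening invitation: the undiagnosed population,
# treated adenomas under surveillance, diagnosed-untreated adenomas and
# undiagnosed CRC; diagnosed CRC is never re-screened
LESION_FREE_SCREENED = (S.NORMAL, S.NAA_T, S.AA_T)
_SCREEN_LESION_STATES: dict[HealthState, tuple[str, bool]] = {}
for _cls in LESION_CLASSES:
    _u, _t, _du = CLASS_STATES[_cls]
    _SCREEN_LESION_STATES[_u] = (_cls, False)
for _cls in ("naa", "aa"):
    _u, _t, _du = CLASS_STATES[_cls]
    _SCREEN_LESION_STATES[_du] = (_cls, True)


@dataclass(frozen=True)
class ScreeningStrategy:
    """Initiation age, frequency, stop age and adherence decay.

    ``frequency`` is one of ``none, once, every_10y, every_5y, every_3y,
    every_2y, annual``.  Rounds occur at cycle starts while the cohort's
    mean age is at most ``stop_age``; ``once`` screens only at entry.
    ``adherence_decay`` multiplies participation and colonoscopy compliance
    by ``decay ** round_index`` (1.0 = constant adherence).
    """

    entry_age: int
    frequency: str = "none"
    stop_age: int = 74
    adherence_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency not in FREQUENCY_INTERVALS:
            raise ValueError(f"unknown frequency {self.frequency!r}")
        if not 40 <= self.entry_age < MAX_AGE:
            raise ValueError(f"entry age {self.entry_age} outside [40, {MAX_AGE})")
        if self.frequency != "none" and self.entry_age > self.stop_age:
            raise ValueError("entry_age must not exceed stop_age")
        if not 0.0 < self.adherence_decay <= 1.0:
            raise ValueError("adherence_decay must lie in (0, 1]")

    @property
    def screens(self) -> bool:
        return self.frequency != "none"

    @property
    def label(self) -> str:
        return f"{self.frequency}@{self.entry_age}"

    @property
    def horizon(self) -> int:
        return MAX_AGE - self.entry_age

    def screening_cycles(self) -> list[int]:
        """Cycle indices at which a screening round is offered."""
        if not self.screens:
            return []
        if self.frequency == "once":
            return [0]
        step = FREQUENCY_INTERVALS[self.frequency]
        return [
            t for t in range(0, self.horizon, step) if self.entry_age + t <= self.stop_age
        ]


@dataclass
class CycleLedger:
    """Per-cycle accruals and event counts (unit-cohort scale)."""

    cycle: int
    age: int
    cost: float = 0.0
    cost_discounted: float = 0.0
    qaly: float = 0.0
    qaly_discounted: float = 0.0
    screens: float = 0.0
    screen_positives: float = 0.0
    colonoscopies: float = 0.0
    false_positive_colonoscopies: float = 0.0
    screen_detections: dict = field(default_factory=lambda: dict.fromkeys(LESION_CLASSES, 0.0))
    treatments: float = 0.0
    symptom_detections: float = 0.0
    crc_deaths: float = 0.0
    other_deaths: float = 0.0

    def flat(self) -> dict:
        out = {
            k: v for k, v in self.__dict__.items() if k != "screen_detections"
        }
        for cls, v in self.screen_detections.items():
            out[f"screen_det_{cls}"] = v
        return out


@dataclass
class StrategyOutcome:
    """Lifetime discounted totals and event counts per 100 000 cohort."""

    strategy: ScreeningStrategy
    qalys: float
    cost: float
    qalys_undiscounted: float
    cost_undiscounted: float
    crc_deaths: float
    other_deaths: float
    screens: float
    colonoscopies: float
    detections: dict
    ledgers: list = field(default_factory=list, repr=False)
    trace_states: np.ndarray = field(default=None, repr=False)

    @property
    def trace(self) -> pd.DataFrame:
        """Per-cycle trace: age, 21 state masses and ledger columns."""
        rows = []
        for led, states in zip(self.ledgers, self.trace_states):
            row = led.flat()
            for s in HealthState:
                row[s.name] = states[s]
            rows.append(row)
        return pd.DataFrame(rows)


def _check_distribution(dist: np.ndarray) -> None:
    if dist.shape != (N_STATES,):
        raise ValueError(f"distribution must have {N_STATES} entries")
    if (dist < -MASS_TOL).any():
        raise ValueError("negative state mass")
    if abs(dist.sum() - 1.0) > MASS_TOL:
        raise ValueError(f"state mass {dist.sum()} deviates from 1 beyond {MASS_TOL}")


def apply_screening_round(
    dist: np.ndarray,
    params: ParameterSet,
    round_index: int = 0,
    adherence_decay: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """One screening round: risk-stratified initial screen then colonoscopy.

    A participation fraction of every screening-eligible state takes the
    initial screen (questionnaire + FIT).  Lesion states screen positive
    with the initial-screen sensitivity, lesion-free states with one minus
    specificity.  Positives comply with colonoscopy at the colonoscopy
    compliance rate; colonoscopy true positives are diagnosed and split by
    treatment compliance into treated vs diagnosed-untreated, while
    false-positive colonoscopies (lesion-free participants) incur cost only
    — a fraction one minus colonoscopy specificity additionally incurs one
    follow-up cost.  Returns the post-round distribution and an event dict
    (screens, positives, colonoscopies, detections by class, treatments,
    costs), on unit-cohort scale.
    """
    _check_distribution(np.asarray(dist, dtype=float))
    orig = np.asarray(dist, dtype=float)
    dist = orig.copy()

    decay = adherence_decay ** round_index
    participation = params["participation_rate"] * decay
    compliance = params["colonoscopy_compliance"] * decay
    sens_adenoma = params["screen_sensitivity_adenoma"]
    sens_crc = params["screen_sensitivity_crc"]
    fp_rate = 1.0 - params["screen_specificity"]
    colo_spec = params["colonoscopy_specificity"]
    colo_sens = {
        "naa": params["colonoscopy_sensitivity_naa"],
        "aa": params["colonoscopy_sensitivity_aa"],
        **{c: params["colonoscopy_sensitivity_crc"] for c in CRC_CLASSES},
    }
    treat_compliance = {c: params[f"treatment_compliance_{c}"] for c in LESION_CLASSES}
    treat_cost = {c: params[f"cost_treatment_{c}"] for c in LESION_CLASSES}

    events = {
        "screens": 0.0,
        "screen_positives": 0.0,
        "colonoscopies": 0.0,
        "false_positive_colonoscopies": 0.0,
        "screen_detections": dict.fromkeys(LESION_CLASSES, 0.0),
        "treatments": 0.0,
        "cost": 0.0,
    }

    # every screened mass is read from the pre-round distribution so that
    # people moved by this round are not screened twice
    # lesion-free participants: false-positive pathway, cost only
    for s in LESION_FREE_SCREENED:
        screened = orig[s] * participation
        events["screens"] += screened
        positives = screened * fp_rate
        events["screen_positives"] += positives
        colos = positives * compliance
        events["colonoscopies"] += colos
        events["false_positive_colonoscopies"] += colos
        events["cost"] += colos * (1.0 - colo_spec) * params["cost_followup"]

    # lesion-bearing participants: detection pathway
    for s, (cls, already_diagnosed) in _SCREEN_LESION_STATES.items():
        screened = orig[s] * participation
        events["screens"] += screened
        sens = sens_crc if cls in CRC_CLASSES else sens_adenoma
        positives = screened * sens
        events["screen_positives"] += positives
        colos = positives * compliance
        events["colonoscopies"] += colos
        confirmed = colos * colo_sens[cls]
        events["screen_detections"][cls] += confirmed
        treated = confirmed * treat_compliance[cls]
        events["treatments"] += treated
        events["cost"] += treated * treat_cost[cls]
        u, t, du = CLASS_STATES[cls]
        dist[s] -= treated
        dist[t] += treated
        if not already_diagnosed:
            declined = confirmed - treated
            dist[s] -= declined
            dist[du] += declined

    events["cost"] += events["screens"] * params["cost_initial_screen"]
    events["cost"] += events["colonoscopies"] * params["cost_colonoscopy"]

    _check_distribution(dist)
    return dist, events


def _utility_vector(age: int, params: ParameterSet) -> np.ndarray:
    """Per-state utility weights at a given age.

    Normal epithelium, non-advanced adenomas (all compartments) and treated
    advanced adenomas carry the age-dependent general-population utility;
    untreated advanced adenomas the AA utility; diagnosed CRC the stage
    utilities.  Undiagnosed preclinical CRC is asymptomatic and carries the
    general-population utility.  Death states accrue nothing.
    """
    u = np.zeros(N_STATES)
    general = params.value("utility_general", age)
    for s in (S.NORMAL, S.NAA_U, S.NAA_T, S.NAA_DU, S.AA_T,
              S.CRC1_U, S.CRC2_U, S.CRC3_U, S.CRC4_U):
        u[s] = general
    u[S.AA_U] = u[S.AA_DU] = params["utility_aa"]
    for i, cls in enumerate(CRC_CLASSES, start=1):
        stage_u = params[f"utility_crc{i}"]
        _, t, du = CLASS_STATES[cls]
        u[t] = stage_u
        u[du] = stage_u
    return u


def run_cohort(
    strategy: ScreeningStrategy,
    params: ParameterSet,
    init: Optional[np.ndarray] = None,
    cohort_size: float = COHORT_SIZE,
    discount_rate: Optional[float] = None,
    accrual: str = "half",
    model: Optional[TransitionModel] = None,
) -> StrategyOutcome:
    """Run the closed cohort from entry age to mean age 82.

    *init* defaults to an entirely lesion-free cohort; an age-specific
    initial state distribution may be supplied instead.  *accrual* selects
    how state-occupancy quantities (utilities, follow-up cost) are counted:
    ``half`` (default, half-cycle correction), ``start`` or ``end``.
    The one-time program preparation cost is charged at entry for any
    strategy that screens.  Totals are reported per *cohort_size* members.
    """
    if accrual not in ("half", "start", "end"):
        raise ValueError("accrual must be one of 'half', 'start', 'end'")
    horizon = strategy.horizon
    if horizon <= 0:
        raise ValueError("strategy horizon must be positive")
    r = params["discount_rate"] if discount_rate is None else float(discount_rate)
    model = model or TransitionModel(params)

    if init is None:
        dist = np.zeros(N_STATES)
        dist[S.NORMAL] = 1.0
    else:
        dist = np.asarray(init, dtype=float).copy()
        _check_distribution(dist)

    treated_idx = list(TREATED)
    screen_cycles = set(strategy.screening_cycles())
    ledgers: list[CycleLedger] = []
    trace = np.empty((horizon, N_STATES))
    crc_deaths_total = 0.0
    other_deaths_total = 0.0
    detections_total = dict.fromkeys(LESION_CLASSES, 0.0)

    for t in range(horizon):
        age = strategy.entry_age + t
        df = (1.0 + r) ** (-t)
        led = CycleLedger(cycle=t, age=age)

        if t == 0 and strategy.screens:
            led.cost += params["cost_preparation"] / cohort_size  # unit-mass scale

        round_index = None
        if t in screen_cycles:
            round_index = sorted(screen_cycles).index(t)
            dist, ev = apply_screening_round(
                dist, params, round_index=round_index, adherence_decay=strategy.adherence_decay
            )
            led.screens = ev["screens"]
            led.screen_positives = ev["screen_positives"]
            led.colonoscopies = ev["colonoscopies"]
            led.false_positive_colonoscopies = ev["false_positive_colonoscopies"]
            led.screen_detections = ev["screen_detections"]
            led.treatments += ev["treatments"]
            led.cost += ev["cost"]

        trace[t] = dist
        structure = model.structure(age)

        # symptom-detection events and their costs (diagnosis + treatment)
        sym_flow = float(dist @ structure.symptom_diagnosis)
        led.symptom_detections = sym_flow
        led.cost += sym_flow * params["cost_diagnosis"]
        for cls in LESION_CLASSES:
            entry_flow = float(dist @ structure.treatment_entry[cls])
            led.treatments += entry_flow
            led.cost += entry_flow * params[f"cost_treatment_{cls}"]
        led.crc_deaths = float(dist @ structure.crc_death)
        led.other_deaths = float(dist @ structure.other_death)

        nxt = dist @ structure.matrix
        if accrual == "half":
            occupancy = 0.5 * (dist + nxt)
        elif accrual == "start":
            occupancy = dist
        else:
            occupancy = nxt

        led.qaly = float(occupancy @ _utility_vector(age, params))
        led.cost += float(occupancy[treated_idx].sum()) * params["cost_followup"]

        led.qaly_discounted = led.qaly * df
        led.cost_discounted = led.cost * df

        crc_deaths_total += led.crc_deaths
        other_deaths_total += led.other_deaths
        for cls in LESION_CLASSES:
            detections_total[cls] += led.screen_detections.get(cls, 0.0)
        ledgers.append(led)
        dist = nxt
        _check_distribution(dist)

    scale = float(cohort_size)
    return StrategyOutcome(
        strategy=strategy,
        qalys=sum(l.qaly_discounted for l in ledgers) * scale,
        cost=sum(l.cost_discounted for l in ledgers) * scale,
        qalys_undiscounted=sum(l.qaly for l in ledgers) * scale,
        cost_undiscounted=sum(l.cost for l in ledgers) * scale,
        crc_deaths=crc_deaths_total * scale,
        other_deaths=other_deaths_total * scale,
        screens=sum(l.screens for l in ledgers) * scale,
        colonoscopies=sum(l.colonoscopies for l in ledgers) * scale,
        detections={c: v * scale for c, v in detections_total.items()},
        ledgers=ledgers,
        trace_states=trace,
    )


@dataclass(frozen=True)
class DeathsAverted:
    """CRC deaths averted by a strategy and colonoscopies per death averted."""

    deaths_averted: float
    colonoscopies_per_death_averted: Optional[float]

    @property
    def defined(self) -> bool:
        return self.colonoscopies_per_death_averted is not None


def deaths_averted(baseline: StrategyOutcome, strategy: StrategyOutcome) -> DeathsAverted:
    """Baseline lifetime CRC deaths minus the strategy's, per cohort.

    The colonoscopies-per-death-averted ratio is undefined (None) when no
    deaths are averted.
    """
    if baseline.strategy.entry_age != strategy.strategy.entry_age:
        raise ValueError("outcomes must share the same entry age")
    averted = baseline.crc_deaths - strategy.crc_deaths
    ratio = strategy.colonoscopies / averted if averted > 0 else None
    return DeathsAverted(deaths_averted=averted, colonoscopies_per_death_averted=ratio)


def run_strategy_grid(
    params: ParameterSet,
    entry_ages: Sequence[int] = ENTRY_AGES,
    frequencies: Sequence[str] = ("once", "every_10y", "every_5y", "every_3y", "every_2y", "annual"),
    stop_age: int = 74,
    adherence_decay: float = 1.0,
    cohort_size: float = COHORT_SIZE,
    discount_rate: Optional[float] = None,
    init_mode: str = "aged",
) -> dict[int, dict[str, StrategyOutcome]]:
    """All (entry age, frequency) outcomes plus the no-screening baseline.

    Returns ``{entry_age: {frequency: StrategyOutcome}}`` with the baseline
    under key ``"none"``.  ``init_mode="aged"`` (default) starts each cohort
    with the age-appropriate prevalent-lesion mix from
    :func:`crcscreen.natural_history.aged_distribution`; ``"normal"`` starts
    every cohort entirely lesion-free.  One transition-model cache is shared
    by all runs.
    """
    if init_mode not in ("aged", "normal"):
        raise ValueError("init_mode must be 'aged' or 'normal'")
    model = TransitionModel(params)
    grid: dict[int, dict[str, StrategyOutcome]] = {}
    for entry in entry_ages:
        init = aged_distribution(params, entry, model=model) if init_mode == "aged" else None
        per_age: dict[str, StrategyOutcome] = {}
        for freq in ("none", *frequencies):
            strat = ScreeningStrategy(
                entry_age=entry, frequency=freq, stop_age=stop_age,
                adherence_decay=adherence_decay,
            )
            per_age[freq] = run_cohort(
                strat, params, init=init, cohort_size=cohort_size,
                discount_rate=discount_rate, model=model,
            )
        grid[entry] = per_age
    return grid
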