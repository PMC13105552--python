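"""Natural history of colorectal neoplasia as a 21-state annual-cycle process.

The state space follows the adenoma-carcinoma sequence: normal epithelium
may develop a non-advanced adenoma (NAA), progress to an advanced adenoma
(AA) and then to preclinical colorectal cancer (CRC) stages I-IV.  Each
lesion class exists in three diagnostic compartments: undiagnosed (``_U``),
diagnosed and treated / under surveillance (``_T``), and diagnosed but
declining treatment (``_DU``).  Two absorbing death states close the model.

Per-cycle event structure (all transitions conditioned on surviving
background mortality, which is applied first):

* undiagnosed lesions may be symptom-detected and split by treatment
  compliance into treated vs diagnosed-untreated;
* undetected and diagnosed-untreated lesions progress irreversibly along
  NAA -> AA -> CRC I -> II -> III -> IV;
* treated lesions may recur, returning to the corresponding undiagnosed
  state (the lesion must be re-detected);
* every CRC state — preclinical, treated or diagnosed-untreated — faces
  the stage-specific annual CRC mortality converted from 5-year survival,
  so the gain from detection comes from intercepting stage progression
  rather than from moving a death clock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .parameters import AgeBand, ParameterSet

__all__ = [
    "HealthState",
    "N_STATES",
    "LESION_CLASSES",
    "annual_mortality_from_survival",
    "build_transition_matrix",
    "TransitionModel",
    "lesion_prevalence",
    "calibrate_transitions",
    "CalibrationResult",
    "goodness_of_fit",
    "GoodnessOfFit",
]

MIN_AGE, MAX_AGE = 40, 82


class HealthState(enum.IntEnum):
    NORMAL = 0
    NAA_U = 1
    AA_U = 2
    CRC1_U = 3
    CRC2_U = 4
    CRC3_U = 5
    CRC4_U = 6
    NAA_T = 7
    AA_T = 8
    CRC1_T = 9
    CRC2_T = 10
    CRC3_T = 11
    CRC4_T = 12
    NAA_DU = 13
    AA_DU = 14
    CRC1_DU = 15
    CRC2_DU = 16
    CRC3_DU = 17
    CRC4_DU = 18
    DEATH_CRC = 19
    DEATH_OTHER = 20


N_STATES = len(HealthState)
assert N_STATES == 21

LESION_CLASSES = ("naa", "aa", "crc1", "crc2", "crc3", "crc4")

S = HealthState
UNDIAGNOSED = (S.NAA_U, S.AA_U, S.CRC1_U, S.CRC2_U, S.CRC3_U, S.CRC4_U)
TREATED = (S.NAA_T, S.AA_T, S.CRC1_T, S.CRC2_T, S.CRC3_T, S.CRC4_T)
DECLINED = (S.NAA_DU, S.AA_DU, S.CRC1_DU, S.CRC2_DU, S.CRC3_DU, S.CRC4_DU)
ALIVE = tuple(s for s in S if s not in (S.DEATH_CRC, S.DEATH_OTHER))
DEAD = (S.DEATH_CRC, S.DEATH_OTHER)

#: lesion class -> (undiagnosed, treated, declined) state triple
CLASS_STATES: Mapping[str, tuple] = {
    cls: (UNDIAGNOSED[i], TREATED[i], DECLINED[i]) for i, cls in enumerate(LESION_CLASSES)
}

CRC_CLASSES = LESION_CLASSES[2:]


def annual_mortality_from_survival(five_year_survival: float) -> float:
    """Annual CRC death probability implied by a 5-year survival rate.

    Assumes a constant annual hazard, so ``1 - s ** (1/5)``.
    """
    s = float(five_year_survival)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"5-year survival {s} outside [0, 1]")
    return 1.0 - s ** 0.2


@dataclass(frozen=True)
class CycleStructure:
    """One-cycle transition matrix plus event-probability vectors.

    ``symptom_diagnosis[s]`` is the probability that unit mass in state *s*
    is symptom-detected this cycle (diagnosis cost attaches to it);
    ``treatment_entry[cls][s]`` the probability of entering the treated
    compartment of lesion class *cls* via the symptom pathway;
    ``crc_death`` / ``other_death`` the per-state death-flow probabilities.
    """

    matrix: np.ndarray
    symptom_diagnosis: np.ndarray
    treatment_entry: Mapping[str, np.ndarray]
    crc_death: np.ndarray
    other_death: np.ndarray


def _cycle_structure(age: int, params: ParameterSet) -> CycleStructure:
    if not MIN_AGE <= int(age) <= MAX_AGE:
        raise ValueError(f"age {age} outside model range [{MIN_AGE}, {MAX_AGE}]")
    age = int(age)
    p = params

    p_bg = p.value("background_mortality", age)
    q = 1.0 - p_bg  # survive background mortality this cycle

    onset = p.value("p_normal_to_naa", age)
    p_na = p.value("p_naa_to_aa", age)
    p_ac = p.value("p_aa_to_crc1", age)
    stage_prog = {
        "crc1": p["p_crc1_to_crc2"],
        "crc2": p["p_crc2_to_crc3"],
        "crc3": p["p_crc3_to_crc4"],
        "crc4": 0.0,
    }
    sym = {cls: p[f"symptom_rate_{cls}"] for cls in LESION_CLASSES}
    tc = {cls: p[f"treatment_compliance_{cls}"] for cls in LESION_CLASSES}
    rec = {cls: p[f"recurrence_{cls}"] for cls in LESION_CLASSES}
    crc_mort = {cls: annual_mortality_from_survival(p[f"survival5_{cls}"]) for cls in CRC_CLASSES}
    lesion_prog = {"naa": p_na, "aa": p_ac, **stage_prog}
    next_u = {
        S.NAA_U: S.AA_U, S.AA_U: S.CRC1_U, S.CRC1_U: S.CRC2_U,
        S.CRC2_U: S.CRC3_U, S.CRC3_U: S.CRC4_U, S.CRC4_U: None,
    }
    next_du = {
        S.NAA_DU: S.AA_DU, S.AA_DU: S.CRC1_DU, S.CRC1_DU: S.CRC2_DU,
        S.CRC2_DU: S.CRC3_DU, S.CRC3_DU: S.CRC4_DU, S.CRC4_DU: None,
    }

    M = np.zeros((N_STATES, N_STATES))
    sym_vec = np.zeros(N_STATES)
    entry = {cls: np.zeros(N_STATES) for cls in LESION_CLASSES}
    crc_death_vec = np.zeros(N_STATES)
    other_death_vec = np.zeros(N_STATES)

    for s in ALIVE:
        M[s, S.DEATH_OTHER] += p_bg
        other_death_vec[s] = p_bg

    # normal epithelium: adenoma onset
    M[S.NORMAL, S.NAA_U] += q * onset
    M[S.NORMAL, S.NORMAL] += q * (1.0 - onset)

    # undiagnosed lesions: CRC mortality (cancer states), then symptom
    # detection, then progression of the rest
    for cls in LESION_CLASSES:
        u, t, du = CLASS_STATES[cls]
        alive_frac = q
        if cls in CRC_CLASSES:
            M[u, S.DEATH_CRC] += q * crc_mort[cls]
            crc_death_vec[u] = q * crc_mort[cls]
            alive_frac = q * (1.0 - crc_mort[cls])
        detected = alive_frac * sym[cls]
        M[u, t] += detected * tc[cls]
        M[u, du] += detected * (1.0 - tc[cls])
        sym_vec[u] = detected
        entry[cls][u] += detected * tc[cls]
        undetected = alive_frac * (1.0 - sym[cls])
        prog = lesion_prog[cls]
        nxt = next_u[u]
        if nxt is not None:
            M[u, nxt] += undetected * prog
            M[u, u] += undetected * (1.0 - prog)
        else:
            M[u, u] += undetected

    # treated lesions: recurrence back to undiagnosed; diagnosed CRC also
    # faces stage-specific CRC mortality
    for cls in LESION_CLASSES:
        u, t, du = CLASS_STATES[cls]
        alive_frac = q
        if cls in CRC_CLASSES:
            M[t, S.DEATH_CRC] += q * crc_mort[cls]
            crc_death_vec[t] = q * crc_mort[cls]
            alive_frac = q * (1.0 - crc_mort[cls])
        M[t, u] += alive_frac * rec[cls]
        M[t, t] += alive_frac * (1.0 - rec[cls])

    # diagnosed-untreated: may become symptomatic and accept the re-offered
    # treatment (no new diagnosis — the lesion is already known); otherwise
    # natural-history progression with the same probabilities as undiagnosed;
    # CRC mortality applies
    for cls in LESION_CLASSES:
        u, t, du = CLASS_STATES[cls]
        alive_frac = q
        if cls in CRC_CLASSES:
            M[du, S.DEATH_CRC] += q * crc_mort[cls]
            crc_death_vec[du] = q * crc_mort[cls]
            alive_frac = q * (1.0 - crc_mort[cls])
        symptomatic = alive_frac * sym[cls]
        accepted = symptomatic * tc[cls]
        M[du, t] += accepted
        M[du, du] += symptomatic * (1.0 - tc[cls])
        entry[cls][du] += accepted
        remaining = alive_frac * (1.0 - sym[cls])
        prog = lesion_prog[cls]
        nxt = next_du[du]
        if nxt is not None:
            M[du, nxt] += remaining * prog
            M[du, du] += remaining * (1.0 - prog)
        else:
            M[du, du] += remaining

    for d in DEAD:
        M[d, d] = 1.0

    row_sums = M.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        raise ValueError(f"transition matrix rows do not sum to 1 at age {age}: {row_sums}")
    if (M < -1e-15).any() or (M > 1 + 1e-15).any():
        raise ValueError(f"transition probability outside [0, 1] at age {age}")

    return CycleStructure(
        matrix=M,
        symptom_diagnosis=sym_vec,
        treatment_entry=entry,
        crc_death=crc_death_vec,
        other_death=other_death_vec,
    )


def build_transition_matrix(age: int, params: ParameterSet) -> np.ndarray:
    """Row-stochastic 21x21 one-cycle matrix for the no-screening process."""
    return _cycle_structure(age, params).matrix


class TransitionModel:
    """Per-age cycle structures for one :class:`ParameterSet`, cached."""

    def __init__(self, params: ParameterSet):
        self.params = params
        self._cache: dict[int, CycleStructure] = {}

    def structure(self, age: int) -> CycleStructure:
        age = int(age)
        if age not in self._cache:
            self._cache[age] = _cycle_structure(age, self.params)
        return self._cache[age]

    def matrix(self, age: int) -> np.ndarray:
        return self.structure(age).matrix


# ---------------------------------------------------------------------------
# prevalence under no screening (used by calibration and synthetic data)
# ---------------------------------------------------------------------------

_CLASS_GROUPS = {
    "naa": (S.NAA_U, S.NAA_DU),
    "aa": (S.AA_U, S.AA_DU),
    "crc1": (S.CRC1_U, S.CRC1_T, S.CRC1_DU),
    "crc2": (S.CRC2_U, S.CRC2_T, S.CRC2_DU),
    "crc3": (S.CRC3_U, S.CRC3_T, S.CRC3_DU),
    "crc4": (S.CRC4_U, S.CRC4_T, S.CRC4_DU),
}


def lesion_prevalence(
    params: ParameterSet,
    age_bands: Sequence[AgeBand],
    start_age: int = MIN_AGE,
    by_stage: bool = False,
    model: Optional[TransitionModel] = None,
) -> pd.DataFrame:
    """Lesion prevalence by age band under the no-screening process.

    Runs a cohort that is entirely lesion-free at *start_age* through annual
    cycles and reports, for each band, the mean over its ages of the
    proportion of the alive cohort carrying each lesion class.  Adenoma
    prevalence counts current carriers (undiagnosed plus diagnosed-untreated;
    a treated adenoma has been removed), CRC prevalence counts all alive CRC
    states.  Columns: age_low, age_high, state_class, rate.
    """
    model = model or TransitionModel(params)
    top = max(b.upper for b in age_bands)
    dist = np.zeros(N_STATES)
    dist[S.NORMAL] = 1.0
    per_age: dict[int, np.ndarray] = {int(start_age): dist.copy()}
    for age in range(int(start_age), min(top, MAX_AGE)):
        dist = dist @ model.matrix(age)
        per_age[age + 1] = dist.copy()

    classes = LESION_CLASSES if by_stage else ("naa", "aa", "crc")
    rows = []
    for band in age_bands:
        ages = [a for a in range(band.lower, band.upper + 1) if a in per_age]
        if not ages:
            raise ValueError(f"band {band.label} outside the simulated age range")
        for cls in classes:
            states = (
                _CLASS_GROUPS[cls]
                if cls != "crc"
                else tuple(s for c in CRC_CLASSES for s in _CLASS_GROUPS[c])
            )
            vals = []
            for a in ages:
                d = per_age[a]
                alive = d[list(ALIVE)].sum()
                vals.append(d[list(states)].sum() / alive if alive > 0 else 0.0)
            rows.append(
                {
                    "age_low": band.lower,
                    "age_high": band.upper,
                    "state_class": cls,
                    "rate": float(np.mean(vals)),
                }
            )
    return pd.DataFrame(rows)


def aged_distribution(
    params: ParameterSet,
    entry_age: int,
    start_age: int = MIN_AGE,
    model: Optional[TransitionModel] = None,
) -> np.ndarray:
    """Initial state distribution of a cohort entering at *entry_age*.

    Ages a lesion-free cohort from *start_age* under the no-screening
    process and renormalizes over the survivors, so the entering cohort
    carries the age-appropriate mix of prevalent adenomas and preclinical
    cancer instead of being entirely lesion-free.
    """
    if not MIN_AGE <= int(entry_age) <= MAX_AGE:
        raise ValueError(f"entry age {entry_age} outside [{MIN_AGE}, {MAX_AGE}]")
    model = model or TransitionModel(params)
    dist = np.zeros(N_STATES)
    dist[S.NORMAL] = 1.0
    for age in range(int(start_age), int(entry_age)):
        dist = dist @ model.matrix(age)
    dist[S.DEATH_CRC] = 0.0
    dist[S.DEATH_OTHER] = 0.0
    return dist / dist.sum()


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_CALIBRATED_FAMILIES = ("p_normal_to_naa", "p_naa_to_aa", "p_aa_to_crc1")


@dataclass
class CalibrationResult:
    params: ParameterSet
    objective: float
    start_objective: float
    success: bool
    message: str
    free_keys: list = field(default_factory=list)


def calibrate_transitions(
    targets: pd.DataFrame,
    params: ParameterSet,
    bounds: Optional[Mapping[tuple, tuple]] = None,
    seed: int = 0,
    start_age: int = MIN_AGE,
) -> CalibrationResult:
    """Fit onset/progression probabilities to age-banded prevalence targets.

    *targets* must provide columns age_low, age_high, state_class
    (naa / aa / crc) and rate (a proportion), covering at least three age
    bands.  Only the calibration-sourced families (normal->NAA, NAA->AA,
    AA->CRC I) whose band overlaps the target age range are optimized, via
    bounded least squares from the current (base-case) starting point;
    all literature-sourced parameters are held fixed.  Bounds default to
    each parameter's 95 % UI.  The procedure is deterministic for a fixed
    starting point; *seed* is accepted for API uniformity.
    """
    req = {"age_low", "age_high", "state_class", "rate"}
    if not req.issubset(targets.columns):
        raise ValueError(f"targets must provide columns {sorted(req)}")
    if not targets["rate"].between(0.0, 1.0).all():
        raise ValueError("target prevalence outside [0, 1]")
    bands = sorted({(int(r.age_low), int(r.age_high)) for r in targets.itertuples()})
    if len(bands) < 3:
        raise ValueError("calibration requires targets for at least three age bands")
    lo_age, hi_age = bands[0][0], bands[-1][1]
    target_bands = [AgeBand(lo, hi) for lo, hi in bands]

    free_keys = []
    x0, lower, upper = [], [], []
    for family in _CALIBRATED_FAMILIES:
        for band, value in params.band_items(family):
            if band.lower > hi_age or band.upper < lo_age:
                continue
            key = (family, (band.lower, band.upper))
            spec = params.spec(family, band.lower)
            b = (bounds or {}).get(key, (spec.ui_low, spec.ui_high))
            free_keys.append(key)
            x0.append(np.clip(value, b[0], b[1]))
            lower.append(b[0])
            upper.append(b[1])

    tgt = targets.sort_values(["age_low", "state_class"]).reset_index(drop=True)

    def residuals(x: np.ndarray) -> np.ndarray:
        trial = params.with_values(dict(zip(free_keys, x)))
        prev = lesion_prevalence(trial, target_bands, start_age=start_age)
        merged = tgt.merge(prev, on=["age_low", "age_high", "state_class"], suffixes=("_t", "_m"))
        if len(merged) != len(tgt):
            raise ValueError("targets contain state classes the model does not report")
        return (merged["rate_m"] - merged["rate_t"]).to_numpy()

    start_obj = float(np.sum(residuals(np.array(x0)) ** 2))
    sol = optimize.least_squares(
        residuals, np.array(x0), bounds=(np.array(lower), np.array(upper)), method="trf"
    )
    fitted = params.with_values(dict(zip(free_keys, sol.x)))
    return CalibrationResult(
        params=fitted,
        objective=float(2.0 * sol.cost),
        start_objective=start_obj,
        success=bool(sol.success),
        message=str(sol.message),
        free_keys=free_keys,
    )


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoodnessOfFit:
    r_squared: float
    rmse: float


def goodness_of_fit(model_curve: Sequence[float], reference_curve: Sequence[float]) -> GoodnessOfFit:
    """RMSE and R-squared of a model curve against an aligned reference.

    ``rmse = sqrt(mean((model - reference)^2))``; R-squared is
    ``1 - SS_res / SS_tot`` with the total sum of squares taken about the
    reference mean.  A constant reference (zero SS_tot) is an error.
    """
    m = np.asarray(model_curve, dtype=float)
    r = np.asarray(reference_curve, dtype=float)
    if m.shape != r.shape:
        raise ValueError(f"curve length mismatch: {m.shape} vs {r.shape}")
    if m.size < 2:
        raise ValueError("goodness of fit requires at least 2 points")
    ss_res = float(np.sum((m - r) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference curve is constant; R-squared undefined")
    return GoodnessOfFit(r_squared=1.0 - ss_res / ss_tot, rmse=float(np.sqrt(ss_res / m.size)))
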