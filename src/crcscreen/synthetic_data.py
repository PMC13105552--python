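"""Synthetic stand-ins for inputs the study did not deposit.

Three generators emulate, with the statistical structure the analysis
assumes, the data products other modules consume: the age-specific initial
distribution of CRC-related health states among screenees, registry-style
age-specific CRC incidence and mortality curves used for external
validation, and the aggregate screening-cascade counts of a large program.
Every generator is a pure function of (seed, configuration) and returns the
generating parameters alongside its output so recovery-style tests can
close the loop.  These are synthetic fixtures, never the study's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .natural_history import (
    ALIVE,
    CRC_CLASSES,
    MAX_AGE,
    MIN_AGE,
    N_STATES,
    S,
    TransitionModel,
    lesion_prevalence,
)
from .parameters import AgeBand, ParameterSet, default_parameters
from .program_yield import ProgramCounts

__all__ = [
    "SyntheticScenario",
    "default_age_bands",
    "synth_initial_distribution",
    "synth_registry_curves",
    "synth_program_counts",
]


def default_age_bands() -> list[AgeBand]:
    """Five-year bands spanning the model's age range, 40-44 ... 80-82."""
    bands = [AgeBand(lo, lo + 4) for lo in range(40, 80, 5)]
    bands.append(AgeBand(80, 82))
    return bands


@dataclass
class SyntheticScenario:
    """A reproducible synthetic-data configuration.

    Stores the seed, the age grid and the generating parameter set so that
    parameter-recovery tests can compare estimates against the truth.
    """

    seed: int
    params: ParameterSet = field(default_factory=default_parameters)
    age_bands: list = field(default_factory=default_age_bands)
    noise: float = 0.0


def synth_initial_distribution(
    seed: int,
    age_bands: Optional[Sequence[AgeBand]] = None,
    params: Optional[ParameterSet] = None,
    noise: float = 0.0,
) -> pd.DataFrame:
    """Age-banded prevalence of NAA, AA and CRC stages I-IV at screening entry.

    Generated by running the no-screening natural history from age 40 under
    the given (stored) parameters, optionally perturbed by multiplicative
    log-normal noise.  A perturbed table is reshaped to the structure an
    entry-screening table exhibits: non-decreasing prevalence with age band
    within each class and decreasing prevalence with lesion severity
    (NAA >= AA >= total CRC) in every band.  With ``noise=0`` the output is
    exactly the model's own prevalence, unreshaped — note that under the
    packaged base case the natural-history AA stock overtakes NAA beyond the
    mid-60s (the printed NAA-to-AA progression rates are large relative to
    AA outflow), so the severity ordering there comes from the reshaping,
    not the raw process.  Columns: age_low, age_high, state_class, rate.
    """
    params = params or default_parameters()
    bands = list(age_bands) if age_bands is not None else default_age_bands()
    prev = lesion_prevalence(params, bands, by_stage=True)
    wide = prev.pivot_table(index=["age_low", "age_high"], columns="state_class",
                            values="rate", sort=False)
    rng = np.random.default_rng(seed)
    if noise > 0:
        factors = rng.lognormal(mean=0.0, sigma=noise, size=wide.shape)
        wide = wide * factors
        # impose the structural guarantees on the perturbed table
        wide = wide.apply(lambda col: np.maximum.accumulate(col.to_numpy()), axis=0)
        naa = wide["naa"].to_numpy()
        aa = np.minimum(wide["aa"].to_numpy(), naa)
        wide["aa"] = aa
        crc_cols = list(CRC_CLASSES)
        crc_total = wide[crc_cols].sum(axis=1).to_numpy()
        excess = crc_total > aa
        if excess.any():
            scale = np.where(excess, aa / np.maximum(crc_total, 1e-300), 1.0)
            wide[crc_cols] = wide[crc_cols].mul(scale, axis=0)
    out = wide.reset_index().melt(
        id_vars=["age_low", "age_high"], var_name="state_class", value_name="rate"
    )
    return out.sort_values(["age_low", "state_class"]).reset_index(drop=True)


def synth_registry_curves(
    seed: int,
    params: Optional[ParameterSet] = None,
    noise_sd: float = 15.0,
    start_age: int = MIN_AGE,
) -> pd.DataFrame:
    """Registry-style age-specific CRC incidence and mortality per 100 000.

    The noise-free curves are the model's own clinically diagnosed CRC rate
    (symptom-detected cases per alive person-year) and CRC death rate under
    no screening, from a lesion-free cohort at *start_age*.  Gaussian noise
    of standard deviation *noise_sd* (per 100 000) is added, rates are
    clipped at zero and mortality is capped at incidence at every age — a
    structural property of registry data the generator preserves.
    Columns: age, incidence, mortality, incidence_true, mortality_true.
    """
    params = params or default_parameters()
    model = TransitionModel(params)
    dist = np.zeros(N_STATES)
    dist[S.NORMAL] = 1.0
    rows = []
    for age in range(int(start_age), MAX_AGE):
        st = model.structure(age)
        alive = dist[list(ALIVE)].sum()
        crc_u = [S.CRC1_U, S.CRC2_U, S.CRC3_U, S.CRC4_U]
        diagnosed = float(dist[crc_u] @ st.symptom_diagnosis[crc_u])
        deaths = float(dist @ st.crc_death)
        rows.append(
            {
                "age": age,
                "incidence_true": 1e5 * diagnosed / alive,
                "mortality_true": 1e5 * deaths / alive,
            }
        )
        dist = dist @ st.matrix
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    inc = df["incidence_true"].to_numpy()
    mort = df["mortality_true"].to_numpy()
    if noise_sd > 0:
        inc = inc + rng.normal(0.0, noise_sd, size=inc.shape)
        mort = mort + rng.normal(0.0, noise_sd, size=mort.shape)
    inc = np.clip(inc, 0.0, None)
    mort = np.clip(mort, 0.0, inc)
    df["incidence"] = inc
    df["mortality"] = mort
    return df[["age", "incidence", "mortality", "incidence_true", "mortality_true"]]


def synth_program_counts(
    seed: int,
    n_invitees: int,
    params: Optional[ParameterSet] = None,
    participation: Optional[float] = None,
    positivity: Optional[float] = None,
    compliance: Optional[float] = None,
    detection: Optional[Mapping[str, float]] = None,
    prep_cost: bool = True,
) -> ProgramCounts:
    """Binomial draw of a screening-cascade count table.

    Cascade probabilities default to the base-case parameter set:
    participation and colonoscopy compliance directly; screen positivity
    from the lesion mix of the unscreened 50-74 population combined with
    the initial-screen sensitivity and one minus specificity; per-lesion
    detection probabilities (conditional on colonoscopy) from the lesion
    mix among positives and the colonoscopy sensitivities.  Any probability
    may be overridden.  Expected counts equal the closed-form products of
    the stage probabilities with *n_invitees*.
    """
    if n_invitees < 1:
        raise ValueError("n_invitees must be >= 1")
    params = params or default_parameters()
    if participation is None:
        participation = params["participation_rate"]
    if compliance is None:
        compliance = params["colonoscopy_compliance"]

    if positivity is None or detection is None:
        prev = lesion_prevalence(params, [AgeBand(50, 74)])
        mix = prev.set_index("state_class")["rate"]
        sens = {
            "naa": params["screen_sensitivity_adenoma"],
            "aa": params["screen_sensitivity_adenoma"],
            "crc": params["screen_sensitivity_crc"],
        }
        colo_sens = {
            "naa": params["colonoscopy_sensitivity_naa"],
            "aa": params["colonoscopy_sensitivity_aa"],
            "crc": params["colonoscopy_sensitivity_crc"],
        }
        lesion_free = 1.0 - float(mix.sum())
        true_pos = {c: float(mix[c]) * sens[c] for c in ("naa", "aa", "crc")}
        p_pos = sum(true_pos.values()) + lesion_free * (1.0 - params["screen_specificity"])
        if positivity is None:
            positivity = p_pos
        if detection is None:
            detection = {c: true_pos[c] / p_pos * colo_sens[c] for c in ("naa", "aa", "crc")}

    rng = np.random.default_rng(seed)
    completers = int(rng.binomial(n_invitees, participation))
    positives = int(rng.binomial(completers, positivity))
    colonoscopies = int(rng.binomial(positives, compliance))
    detected = {c: int(rng.binomial(colonoscopies, detection[c])) for c in ("naa", "aa", "crc")}

    cost = (
        completers * params["cost_initial_screen"]
        + colonoscopies * params["cost_colonoscopy"]
        + (params["cost_preparation"] if prep_cost else 0.0)
    )
    return ProgramCounts(
        invitees=n_invitees,
        completers=completers,
        screen_positives=positives,
        colonoscopies=colonoscopies,
        detected_naa=detected["naa"],
        detected_aa=detected["aa"],
        detected_crc=detected["crc"],
        total_cost_usd=cost,
    )
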