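"""Screening-cascade yield and resource metrics from aggregate counts.

Implements the published resource formulas exactly as stated: yields per
10 000 participants/colonoscopies are products of cascade rates, the
colonoscopies-to-detect-one-lesion quotient uses a ceiling, monetary and
rate quotients round half-up.  Cells of the published report that are not
arithmetically consistent with its own inputs are surfaced in a
discrepancy report, never silently matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .util import round_half_up, round_half_up_int

__all__ = [
    "ProgramCounts",
    "CascadeRates",
    "YieldReport",
    "cascade_rates",
    "yield_per_10k_participants",
    "yield_per_10k_colonoscopies",
    "colonoscopies_per_lesion",
    "cost_per_lesion",
    "nns_per_death_averted",
    "build_report",
    "pccsp_counts",
    "published_metrics",
]

LESIONS = ("naa", "aa", "crc")


@dataclass(frozen=True)
class ProgramCounts:
    """Aggregate counts along the screening cascade.

    ``detected_an`` (advanced neoplasms) is always advanced adenomas plus
    CRC.  ``crc_deaths_averted`` is optional because it comes from the
    model, not the cascade itself.
    """

    invitees: int
    completers: int
    screen_positives: int
    colonoscopies: int
    detected_naa: int
    detected_aa: int
    detected_crc: int
    total_cost_usd: Optional[float] = None
    crc_deaths_averted: Optional[int] = None

    def __post_init__(self) -> None:
        chain = (
            ("completers", self.completers, "invitees", self.invitees),
            ("screen_positives", self.screen_positives, "completers", self.completers),
            ("colonoscopies", self.colonoscopies, "screen_positives", self.screen_positives),
        )
        for name, val, upper_name, upper in chain:
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
            if val > upper:
                raise ValueError(f"{name} ({val}) exceeds {upper_name} ({upper})")
        for lesion in LESIONS:
            det = getattr(self, f"detected_{lesion}")
            if det < 0 or det > self.colonoscopies:
                raise ValueError(f"detected_{lesion} outside [0, colonoscopies]")

    @property
    def detected_an(self) -> int:
        return self.detected_aa + self.detected_crc

    def detections(self, lesion: str) -> int:
        if lesion == "an":
            return self.detected_an
        return getattr(self, f"detected_{lesion}")


@dataclass(frozen=True)
class CascadeRates:
    """Cascade ratios as percentages, rounded to two decimals."""

    participation_pct: float
    positivity_pct: float
    compliance_pct: float
    detection_pct: Mapping[str, float]


def _pct(numerator: float, denominator: float, what: str) -> float:
    if denominator == 0:
        raise ZeroDivisionError(f"zero denominator computing {what}")
    return round_half_up(100.0 * numerator / denominator, 2)


def cascade_rates(counts: ProgramCounts) -> CascadeRates:
    """Participation, positivity, colonoscopy compliance and detection rates."""
    return CascadeRates(
        participation_pct=_pct(counts.completers, counts.invitees, "participation"),
        positivity_pct=_pct(counts.screen_positives, counts.completers, "positivity"),
        compliance_pct=_pct(counts.colonoscopies, counts.screen_positives, "compliance"),
        detection_pct={
            lesion: _pct(counts.detections(lesion), counts.colonoscopies, f"detection {lesion}")
            for lesion in (*LESIONS, "an")
        },
    )


def yield_per_10k_participants(
    participation: float, positivity: float, compliance: float, detection_rate: float
) -> int:
    """10 000 x participation x positivity x colonoscopy compliance x
    detection rate, rounded half-up to an integer."""
    return round_half_up_int(10_000 * participation * positivity * compliance * detection_rate)


def yield_per_10k_colonoscopies(compliance: float, detection_rate: float) -> int:
    """10 000 x colonoscopy compliance x detection rate, rounded half-up."""
    return round_half_up_int(10_000 * compliance * detection_rate)


def colonoscopies_per_lesion(colonoscopies: int, detections: int) -> int:
    """Ceiling quotient; undefined (error) when nothing was detected."""
    if detections <= 0:
        raise ZeroDivisionError("colonoscopies per lesion undefined with zero detections")
    return math.ceil(colonoscopies / detections)


def cost_per_lesion(total_cost: float, detections: int) -> int:
    """Total screening cost per detected lesion, rounded half-up to a dollar."""
    if detections <= 0:
        raise ZeroDivisionError("cost per lesion undefined with zero detections")
    return round_half_up_int(total_cost / detections)


def nns_per_death_averted(
    screeners: int, colonoscopies: int, deaths_averted: int
) -> tuple[int, int]:
    """Number needed to screen (initially, clinically) per CRC death averted."""
    if deaths_averted <= 0:
        raise ZeroDivisionError("NNS undefined with zero deaths averted")
    return (
        round_half_up_int(screeners / deaths_averted),
        round_half_up_int(colonoscopies / deaths_averted),
    )


@dataclass
class YieldReport:
    """Computed resource metrics plus discrepancies vs a published report."""

    rates: CascadeRates
    table: pd.DataFrame
    discrepancies: pd.DataFrame


def build_report(
    counts: ProgramCounts,
    detection_rates: Optional[Mapping[str, float]] = None,
    published: Optional[pd.DataFrame] = None,
) -> YieldReport:
    """Compute every resource metric from the cascade counts.

    *detection_rates* (proportions per lesion, incl. ``an``) override the
    count-derived detection rates inside the yield formulas — the published
    program report quotes detection rates with a different denominator than
    raw colonoscopies, so reproducing it requires its own printed rates.
    When *published* (columns metric, lesion, value) is given, each computed
    cell is compared against it and mismatches land in ``discrepancies``.
    """
    rates = cascade_rates(counts)
    # the published footnote formulas operate on the report's rounded rates
    # (two-decimal percents), so the same precision is used here
    part = rates.participation_pct / 100.0
    pos = rates.positivity_pct / 100.0
    comp = rates.compliance_pct / 100.0
    det = {
        lesion: (
            detection_rates[lesion]
            if detection_rates is not None and lesion in detection_rates
            else rates.detection_pct[lesion] / 100.0
        )
        for lesion in (*LESIONS, "an")
    }
    if detection_rates is not None and "an" not in detection_rates:
        det["an"] = det["aa"] + det["crc"]

    rows = []
    for lesion in (*LESIONS, "an"):
        n_det = counts.detections(lesion)
        rows.append({"metric": "detections", "lesion": lesion, "value": n_det})
        rows.append(
            {
                "metric": "yield_per_10k_participants",
                "lesion": lesion,
                "value": yield_per_10k_participants(part, pos, comp, det[lesion]),
            }
        )
        rows.append(
            {
                "metric": "yield_per_10k_colonoscopies",
                "lesion": lesion,
                "value": yield_per_10k_colonoscopies(comp, det[lesion]),
            }
        )
        if n_det > 0:
            rows.append(
                {
                    "metric": "colonoscopies_per_lesion",
                    "lesion": lesion,
                    "value": colonoscopies_per_lesion(counts.colonoscopies, n_det),
                }
            )
            rows.append(
                {
                    "metric": "invitees_per_lesion",
                    "lesion": lesion,
                    "value": math.ceil(counts.invitees / n_det),
                }
            )
            if counts.total_cost_usd is not None:
                rows.append(
                    {
                        "metric": "cost_per_lesion_usd",
                        "lesion": lesion,
                        "value": cost_per_lesion(counts.total_cost_usd, n_det),
                    }
                )
    if counts.crc_deaths_averted:
        nns_i, nns_c = nns_per_death_averted(
            counts.completers, counts.colonoscopies, counts.crc_deaths_averted
        )
        rows.append({"metric": "crc_deaths_averted", "lesion": "crc", "value": counts.crc_deaths_averted})
        rows.append({"metric": "nns_initial_per_death_averted", "lesion": "crc", "value": nns_i})
        rows.append({"metric": "nns_clinical_per_death_averted", "lesion": "crc", "value": nns_c})
    table = pd.DataFrame(rows)

    if published is not None:
        merged = table.merge(
            published.rename(columns={"value": "published"}), on=["metric", "lesion"], how="inner"
        )
        discrepancies = merged[merged["value"] != merged["published"]].reset_index(drop=True)
    else:
        discrepancies = pd.DataFrame(columns=["metric", "lesion", "value", "published"])
    return YieldReport(rates=rates, table=table, discrepancies=discrepancies)


def pccsp_counts() -> ProgramCounts:
    """The packaged province-wide program cascade counts (2020-2024)."""
    ref = resources.files("crcscreen.data").joinpath("pccsp_counts.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path).set_index("metric")["value"]
    return ProgramCounts(
        invitees=int(df["invitees"]),
        completers=int(df["completers"]),
        screen_positives=int(df["screen_positives"]),
        colonoscopies=int(df["colonoscopies"]),
        detected_naa=int(df["detected_naa"]),
        detected_aa=int(df["detected_aa"]),
        detected_crc=int(df["detected_crc"]),
        total_cost_usd=float(df["total_screening_cost_usd"]),
        crc_deaths_averted=int(df["crc_deaths_averted"]),
    )


def published_metrics() -> pd.DataFrame:
    """Published program-report cells (metric, lesion, value)."""
    ref = resources.files("crcscreen.data").joinpath("pccsp_published_metrics.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
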