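"""Model parameters: loading, validation, and uncertainty distributions.

Every quantity the cohort model consumes — screening performance, costs,
natural-history transition probabilities, utilities, survival, background
mortality and the discount rate — is represented as a :class:`ParameterSpec`
(base-case value, 95 % uncertainty interval, distribution family, optional
age band) collected into a :class:`ParameterSet`.  The packaged default table
reproduces the published base case of the province-wide risk-stratified
screening program evaluation; probabilistic sensitivity analysis draws joint
parameter samples from the per-parameter distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "AgeBand",
    "ParameterSpec",
    "ParameterSet",
    "build_distribution",
    "load_parameter_table",
    "default_parameters",
    "sample_parameter_draw",
]

DISTRIBUTION_FAMILIES = ("triangular", "gamma", "beta", "uniform", "fixed")

#: The 95 % uncertainty interval is read as mean +/- 1.96 sd, so its width
#: spans 3.92 standard deviations (used for method-of-moments gamma/beta).
UI_SD_SPAN = 3.92

_BOUNDED_UNITS = ("probability", "utility")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed integer age interval [lower, upper] in years."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"AgeBand lower {self.lower} > upper {self.upper}")

    def __contains__(self, age: object) -> bool:
        return isinstance(age, (int, np.integer)) and self.lower <= int(age) <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: base case, uncertainty interval and family."""

    name: str
    base: float
    ui_low: float
    ui_high: float
    distribution: str
    age_band: Optional[AgeBand] = None
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTION_FAMILIES:
            raise ValueError(
                f"{self.name}: unknown distribution {self.distribution!r}; "
                f"expected one of {DISTRIBUTION_FAMILIES}"
            )
        if not (self.ui_low <= self.base <= self.ui_high):
            raise ValueError(
                f"{self.name}: base {self.base} outside UI [{self.ui_low}, {self.ui_high}]"
            )
        if self.units in _BOUNDED_UNITS and not (0.0 <= self.ui_low and self.ui_high <= 1.0):
            raise ValueError(f"{self.name}: {self.units} values must lie in [0, 1]")
        if self.units == "usd" and self.ui_low < 0:
            raise ValueError(f"{self.name}: costs must be non-negative")

    @property
    def key(self) -> tuple:
        band = (self.age_band.lower, self.age_band.upper) if self.age_band else None
        return (self.name, band)


class _FixedDistribution:
    """Degenerate distribution returning the base value on every draw."""

    def __init__(self, value: float):
        self._value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self._value
        return np.full(size, self._value)

    def mean(self) -> float:
        return self._value

    def std(self) -> float:
        return 0.0


def build_distribution(spec: ParameterSpec):
    """Return a sampleable distribution for *spec*.

    Conventions: triangular uses (min=ui_low, mode=base, max=ui_high);
    uniform uses (ui_low, ui_high); gamma and beta are parameterized by
    method of moments with mean = base and sd = UI width / 3.92; ``fixed``
    (and any degenerate interval) returns the base value always.
    """
    lo, hi, base = spec.ui_low, spec.ui_high, spec.base
    if spec.distribution == "fixed" or hi == lo:
        return _FixedDistribution(base)
    if spec.distribution == "triangular":
        return stats.triang((base - lo) / (hi - lo), loc=lo, scale=hi - lo)
    if spec.distribution == "uniform":
        return stats.uniform(loc=lo, scale=hi - lo)
    sd = (hi - lo) / UI_SD_SPAN
    if spec.distribution == "gamma":
        if base <= 0:
            raise ValueError(f"{spec.name}: gamma requires base > 0")
        shape = (base / sd) ** 2
        return stats.gamma(shape, scale=sd**2 / base)
    if spec.distribution == "beta":
        if not (0.0 < base < 1.0):
            raise ValueError(f"{spec.name}: beta requires base in (0, 1)")
        var = sd**2
        if var >= base * (1.0 - base):
            raise ValueError(f"{spec.name}: beta variance {var:.4g} too large for mean {base}")
        nu = base * (1.0 - base) / var - 1.0
        return stats.beta(base * nu, (1.0 - base) * nu)
    raise AssertionError("unreachable")


#: Mandatory parameters: name -> number of age bands (None = scalar).
MANDATORY_PARAMETERS: Mapping[str, Optional[int]] = {
    "cost_preparation": None,
    "cost_initial_screen": None,
    "cost_colonoscopy": None,
    "cost_treatment_naa": None,
    "cost_treatment_aa": None,
    "cost_treatment_crc1": None,
    "cost_treatment_crc2": None,
    "cost_treatment_crc3": None,
    "cost_treatment_crc4": None,
    "cost_diagnosis": None,
    "cost_followup": None,
    "participation_rate": None,
    "screen_sensitivity_adenoma": None,
    "screen_sensitivity_crc": None,
    "screen_specificity": None,
    "colonoscopy_compliance": None,
    "colonoscopy_sensitivity_naa": None,
    "colonoscopy_sensitivity_aa": None,
    "colonoscopy_sensitivity_crc": None,
    "colonoscopy_specificity": None,
    "p_normal_to_naa": 8,
    "p_naa_to_aa": 8,
    "p_aa_to_crc1": 8,
    "p_crc1_to_crc2": None,
    "p_crc2_to_crc3": None,
    "p_crc3_to_crc4": None,
    "symptom_rate_naa": None,
    "symptom_rate_aa": None,
    "symptom_rate_crc1": None,
    "symptom_rate_crc2": None,
    "symptom_rate_crc3": None,
    "symptom_rate_crc4": None,
    "treatment_compliance_naa": None,
    "treatment_compliance_aa": None,
    "treatment_compliance_crc1": None,
    "treatment_compliance_crc2": None,
    "treatment_compliance_crc3": None,
    "treatment_compliance_crc4": None,
    "recurrence_naa": None,
    "recurrence_aa": None,
    "recurrence_crc1": None,
    "recurrence_crc2": None,
    "recurrence_crc3": None,
    "recurrence_crc4": None,
    "utility_general": 4,
    "utility_aa": None,
    "utility_crc1": None,
    "utility_crc2": None,
    "utility_crc3": None,
    "utility_crc4": None,
    "survival5_crc1": None,
    "survival5_crc2": None,
    "survival5_crc3": None,
    "survival5_crc4": None,
    "background_mortality": 9,
    "discount_rate": None,
}


class ParameterSet:
    """Complete mapping from parameter name (+ age band) to value.

    Holds both the :class:`ParameterSpec` metadata (for sampling and bounds)
    and the current values, which default to each spec's base case.  Values
    of age-banded parameters are looked up with :meth:`value` given an age.
    """

    def __init__(self, specs: Iterable[ParameterSpec], values: Optional[Mapping[tuple, float]] = None):
        self._specs: dict[tuple, ParameterSpec] = {}
        for spec in specs:
            if spec.key in self._specs:
                raise ValueError(f"duplicate parameter {spec.key}")
            self._specs[spec.key] = spec
        self._values: dict[tuple, float] = {k: s.base for k, s in self._specs.items()}
        if values is not None:
            for k, v in values.items():
                if k not in self._specs:
                    raise KeyError(f"unknown parameter key {k}")
                self._values[k] = float(v)
        self._banded: dict[str, list[tuple]] = {}
        for key, spec in self._specs.items():
            if spec.age_band is not None:
                self._banded.setdefault(spec.name, []).append(key)
        for name in self._banded:
            self._banded[name].sort(key=lambda k: k[1])

    # -- access ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return (name, None) in self._specs or name in self._banded

    @property
    def names(self) -> list[str]:
        seen: dict[str, None] = {}
        for name, _ in self._specs:
            seen.setdefault(name)
        return list(seen)

    def spec(self, name: str, age: Optional[int] = None) -> ParameterSpec:
        return self._specs[self._resolve(name, age)]

    def value(self, name: str, age: Optional[int] = None) -> float:
        return self._values[self._resolve(name, age)]

    def __getitem__(self, name: str) -> float:
        return self.value(name)

    def band_items(self, name: str) -> list[tuple[AgeBand, float]]:
        """(band, value) pairs of an age-banded parameter, ascending age."""
        if name not in self._banded:
            raise KeyError(f"{name} is not age-banded")
        out = []
        for key in self._banded[name]:
            spec = self._specs[key]
            out.append((spec.age_band, self._values[key]))
        return out

    def _resolve(self, name: str, age: Optional[int]) -> tuple:
        if name in self._banded:
            if age is None:
                raise KeyError(f"{name} is age-banded; an age is required")
            for key in self._banded[name]:
                if int(age) in self._specs[key].age_band:
                    return key
            # ages beyond the last band use the last band (open-ended top)
            last = self._banded[name][-1]
            if int(age) > self._specs[last].age_band.upper:
                return last
            raise KeyError(f"no {name} band covers age {age}")
        if (name, None) not in self._specs:
            raise KeyError(f"unknown parameter {name!r}")
        return (name, None)

    # -- mutation (returns new sets; ParameterSet is value-like) ---------

    def with_values(self, updates: Mapping[tuple, float]) -> "ParameterSet":
        merged = dict(self._values)
        for k, v in updates.items():
            if k not in self._specs:
                raise KeyError(f"unknown parameter key {k}")
            merged[k] = float(v)
        return ParameterSet(self._specs.values(), merged)

    def with_value(self, name: str, value: float, age: Optional[int] = None) -> "ParameterSet":
        return self.with_values({self._resolve(name, age): value})

    def with_scaled_bands(self, name: str, factor: float) -> "ParameterSet":
        """Multiply every band of an age-banded parameter by *factor*."""
        updates = {}
        for key in self._banded[name]:
            updates[key] = self._values[key] * factor
        return self.with_values(updates)

    # -- validation ------------------------------------------------------

    def validate_complete(self) -> None:
        """Check every mandatory parameter is present with the right shape."""
        missing = []
        for name, n_bands in MANDATORY_PARAMETERS.items():
            if n_bands is None:
                if (name, None) not in self._specs:
                    missing.append(name)
            else:
                have = len(self._banded.get(name, []))
                if have != n_bands:
                    missing.append(f"{name} ({have}/{n_bands} bands)")
        if missing:
            raise ValueError(f"parameter table incomplete, missing: {', '.join(missing)}")
        for name in ("p_normal_to_naa", "p_naa_to_aa", "p_aa_to_crc1"):
            self._check_partition(name, 40, 82)
        self._check_partition("background_mortality", 40, 82)
        self._check_partition("utility_general", 40, 82)

    def _check_partition(self, name: str, lo: int, hi: int) -> None:
        bands = [self._specs[k].age_band for k in self._banded[name]]
        cursor = lo
        for band in bands:
            if band.lower > cursor:
                raise ValueError(f"{name}: gap in age coverage at {cursor}")
            cursor = max(cursor, band.upper + 1)
        if cursor <= hi:
            raise ValueError(f"{name}: bands end at {cursor - 1}, before {hi}")

    # -- sampling --------------------------------------------------------

    def sample(self, seed: Union[int, np.random.Generator, np.random.SeedSequence]) -> "ParameterSet":
        """One joint, independent draw of every non-fixed parameter."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws: dict[tuple, float] = {}
        for key in sorted(self._specs, key=lambda k: (k[0], k[1] or (-1, -1))):
            spec = self._specs[key]
            draws[key] = float(build_distribution(spec).rvs(random_state=rng))
        return ParameterSet(self._specs.values(), draws)

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, spec in self._specs.items():
            band = spec.age_band
            rows.append(
                {
                    "name": spec.name,
                    "age_low": band.lower if band else None,
                    "age_high": band.upper if band else None,
                    "base": self._values[key],
                    "ui_low": spec.ui_low,
                    "ui_high": spec.ui_high,
                    "distribution": spec.distribution,
                    "units": spec.units,
                    "source": spec.source,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path, IO[str]]) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._specs == other._specs and self._values == other._values


def _frame_to_set(df: pd.DataFrame) -> ParameterSet:
    required = {"name", "base", "ui_low", "ui_high", "distribution"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter table must provide columns {sorted(required)}")
    specs = []
    for _, row in df.iterrows():
        band = None
        if "age_low" in df.columns and pd.notna(row.get("age_low")):
            band = AgeBand(int(row["age_low"]), int(row["age_high"]))
        specs.append(
            ParameterSpec(
                name=str(row["name"]),
                base=float(row["base"]),
                ui_low=float(row["ui_low"]),
                ui_high=float(row["ui_high"]),
                distribution=str(row["distribution"]),
                age_band=band,
                units=str(row.get("units", "") or ""),
                source=str(row.get("source", "") or ""),
            )
        )
    params = ParameterSet(specs)
    params.validate_complete()
    return params


def load_parameter_table(source: Union[str, Path, IO[str]]) -> ParameterSet:
    """Load a parameter table from delimited text (CSV) or YAML.

    The table must provide one row per parameter (and per age band for
    banded parameters) with columns name, age_low, age_high, base, ui_low,
    ui_high, distribution, units, source.  A missing mandatory parameter,
    a base outside its UI, or an unknown distribution name is an error.
    """
    if isinstance(source, (str, Path)) and str(source).endswith((".yaml", ".yml")):
        with open(source) as fh:
            payload = yaml.safe_load(fh)
        df = pd.DataFrame(payload["parameters"] if isinstance(payload, dict) else payload)
    else:
        df = pd.read_csv(source)
    return _frame_to_set(df)


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter table."""
    ref = resources.files("crcscreen.data").joinpath("parameters.csv")
    with resources.as_file(ref) as path:
        return load_parameter_table(path)


def sample_parameter_draw(params: ParameterSet, seed) -> ParameterSet:
    """One reproducible joint draw of all parameters (PSA building block)."""
    return params.sample(seed)
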