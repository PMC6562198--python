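"""Domain types shared by all pipeline stages.

The package models ward admissions in which vital-sign observation sets
(the seven NEWS inputs) arrive every few hours and laboratory results
(seven routine blood analytes) arrive roughly daily and asynchronously.
Band/weight definitions for both component scores live in an external
config file (see :func:`load_scoring_table`), never in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Optional

import numpy as np
import yaml

#: The seven blood analytes used by LDT-EWS, with their reporting units.
ANALYTES = ("albumin", "creatinine", "haemoglobin", "potassium", "sodium", "urea", "wcc")

ANALYTE_UNITS = {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "haemoglobin": "g/L",
    "potassium": "mmol/L",
    "sodium": "mmol/L",
    "urea": "mmol/L",
    "wcc": "1e9 cells/L",
}

#: Numeric NEWS components (supplemental oxygen and consciousness are categorical).
NEWS_NUMERIC_COMPONENTS = (
    "respiratory_rate",
    "spo2",
    "temperature",
    "systolic_bp",
    "heart_rate",
)

AVPU_LEVELS = ("A", "V", "P", "U")

#: Carry-forward horizon: lab results older than this are treated as absent.
DEFAULT_HORIZON_HOURS = 120.0


class ValidationError(ValueError):
    """Raised when an input record or parameter violates its contract."""


@dataclass(frozen=True)
class Admission:
    """One completed hospital admission."""

    admission_id: str
    age: int
    sex: str  # "male" | "female"
    admit_time: datetime
    discharge_time: datetime
    admission_method: str  # "emergency" | "elective"
    specialty: str
    death_in_hospital: bool = False
    death_time: Optional[datetime] = None
    icu_admission_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.discharge_time < self.admit_time:
            raise ValidationError("discharge_time before admit_time")
        if self.death_in_hospital != (self.death_time is not None):
            raise ValidationError("death_in_hospital inconsistent with death_time")
        from datetime import timedelta

        lo = self.admit_time - timedelta(days=1)
        for name, t in (("death_time", self.death_time), ("icu_admission_time", self.icu_admission_time)):
            if t is not None and not (lo <= t <= self.discharge_time):
                raise ValidationError(f"{name} outside [admit - 1 day, discharge]")

    @property
    def first_event_time(self) -> Optional[datetime]:
        """Earliest of death and unanticipated ICU admission, if any."""
        events = [t for t in (self.death_time, self.icu_admission_time) if t is not None]
        return min(events) if events else None


@dataclass(frozen=True)
class VitalSignSet:
    """One timestamped set of the seven NEWS inputs.

    Neurological status is recorded either on the AVPU scale or as a GCS
    value in 3..15; at least one must be present.
    """

    admission_id: str
    obs_time: datetime
    heart_rate: float
    systolic_bp: float
    respiratory_rate: float
    temperature: float
    spo2: float
    supplemental_oxygen: bool
    avpu: Optional[str] = None
    gcs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.avpu is None and self.gcs is None:
            raise ValidationError("one of avpu/gcs is required")
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            raise ValidationError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        if self.gcs is not None and not 3 <= int(self.gcs) <= 15:
            raise ValidationError(f"gcs must be in [3, 15], got {self.gcs}")


@dataclass(frozen=True)
class LabResult:
    """One analyte measurement, timestamped at receipt by the laboratory."""

    admission_id: str
    received_time: datetime
    analyte: str
    value: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if not self.value > 0:
            raise ValidationError(f"{self.analyte} value must be > 0, got {self.value}")


@dataclass(frozen=True)
class LabSlot:
    """A carried-forward analyte value and its age at the observation time."""

    value: float
    age_hours: float


@dataclass(frozen=True)
class LinkedObservation:
    """A vitals set joined to the most recent value of each analyte.

    ``slots`` holds only analytes with a usable (within-horizon) result.
    ``time_since_labs`` is the minimum slot age, or the horizon when all
    slots are absent — the freshness of the *newest* piece of laboratory
    evidence, which drives the decay weight.
    """

    vitals: VitalSignSet
    slots: dict[str, LabSlot] = field(default_factory=dict)
    horizon_hours: float = DEFAULT_HORIZON_HOURS

    def __post_init__(self) -> None:
        for name, slot in self.slots.items():
            if name not in ANALYTES:
                raise ValidationError(f"unknown analyte slot {name!r}")
            if slot.age_hours > self.horizon_hours:
                raise ValidationError(
                    f"{name} slot age {slot.age_hours} h exceeds horizon {self.horizon_hours} h"
                )

    @property
    def time_since_labs(self) -> float:
        if not self.slots:
            return self.horizon_hours
        return min(slot.age_hours for slot in self.slots.values())


@dataclass(frozen=True)
class ScoredObservation:
    """Aggregate scores, decay weight and combined risk index at one time."""

    admission_id: str
    obs_time: datetime
    news_aggregate: int
    ldtews_aggregate: int
    time_since_labs: float
    omega: float
    risk_index: float
    outcome_primary_24h: bool = False
    outcome_death_24h: bool = False
    outcome_icu_24h: bool = False


# ---------------------------------------------------------------------------
# Scoring tables


@dataclass(frozen=True)
class Band:
    lower: float  # inclusive
    upper: float  # exclusive
    weight: int


class BandScale:
    """An ordered, gap-free set of half-open bands tiling the real line."""

    def __init__(self, name: str, bands: list[Band]):
        self.name = name
        self.bands = bands
        # interior edges for vectorized lookup
        self._edges = np.array([b.lower for b in bands[1:]], dtype=float)
        self._weights = np.array([b.weight for b in bands], dtype=np.int64)

    def weight(self, value: float) -> int:
        return int(self._weights[int(np.searchsorted(self._edges, value, side="right"))])

    def weights(self, values: np.ndarray) -> np.ndarray:
        """Vectorized band lookup."""
        return self._weights[np.searchsorted(self._edges, values, side="right")]

    @property
    def max_weight(self) -> int:
        return int(self._weights.max())

    def violations(self) -> list[str]:
        out = []
        if not self.bands:
            return [f"{self.name}: no bands"]
        if not math.isinf(self.bands[0].lower):
            out.append(f"{self.name}: first band does not start at -inf (gap below)")
        if not math.isinf(self.bands[-1].upper):
            out.append(f"{self.name}: last band does not end at +inf (gap above)")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lower < a.upper:
                out.append(f"{self.name}: overlap at {b.lower}")
            elif b.lower > a.upper:
                out.append(f"{self.name}: gap between {a.upper} and {b.lower}")
        for b in self.bands:
            if b.upper <= b.lower:
                out.append(f"{self.name}: empty band [{b.lower}, {b.upper})")
            if not float(b.weight).is_integer() or b.weight < 0:
                out.append(f"{self.name}: non-integer or negative weight {b.weight}")
        return out


@dataclass
class ScoringTable:
    """Externalized band/weight definitions for NEWS and LDT-EWS.

    ``ldtews_scales`` maps each analyte either to a single :class:`BandScale`
    or to a ``{"male": BandScale, "female": BandScale}`` dict where the chart
    distinguishes the sexes.
    """

    news_scales: dict[str, BandScale]
    supplemental_oxygen_weight: int
    consciousness_weights: dict[str, int]
    news_max: int
    ldtews_scales: dict[str, object]
    ldtews_max: int
    gcs_to_avpu_ranges: list[tuple[int, int, str]]

    def ldtews_scale(self, analyte: str, sex: Optional[str] = None) -> BandScale:
        scale = self.ldtews_scales[analyte]
        if isinstance(scale, dict):
            if sex not in ("male", "female"):
                raise ValidationError(f"{analyte} cut-offs are sex-specific; sex required")
            return scale[sex]
        return scale


def _parse_bands(name: str, raw: list) -> BandScale:
    return BandScale(name, [Band(float(lo), float(hi), int(w)) for lo, hi, w in raw])


def load_scoring_table(path: Optional[str] = None) -> ScoringTable:
    """Load a scoring table from YAML; the packaged default when *path* is None."""
    if path is None:
        text = resources.files("ewsfusion").joinpath("data/scoring_table.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    news = raw["news"]
    news_scales = {
        name: _parse_bands(f"news.{name}", spec["bands"])
        for name, spec in news["components"].items()
    }
    ldt = raw["ldtews"]
    ldtews_scales: dict[str, object] = {}
    for name, spec in ldt["analytes"].items():
        if "bands" in spec:
            ldtews_scales[name] = _parse_bands(f"ldtews.{name}", spec["bands"])
        else:
            ldtews_scales[name] = {
                sex: _parse_bands(f"ldtews.{name}.{sex}", spec[sex]["bands"])
                for sex in ("male", "female")
            }
    return ScoringTable(
        news_scales=news_scales,
        supplemental_oxygen_weight=int(news["supplemental_oxygen_weight"]),
        consciousness_weights={k: int(v) for k, v in news["consciousness_weights"].items()},
        news_max=int(news["max_aggregate"]),
        ldtews_scales=ldtews_scales,
        ldtews_max=int(ldt["max_aggregate"]),
        gcs_to_avpu_ranges=[(int(lo), int(hi), str(lvl)) for lo, hi, lvl in raw["gcs_to_avpu"]],
    )


def validate_tables(table: ScoringTable) -> list[str]:
    """Check band tiling and attainable maxima; returns violations (empty = valid)."""
    out: list[str] = []

    for name in NEWS_NUMERIC_COMPONENTS:
        if name not in table.news_scales:
            out.append(f"missing variable: news.{name}")
    for name, scale in table.news_scales.items():
        out.extend(scale.violations())

    if table.supplemental_oxygen_weight is None:
        out.append("missing variable: news.supplemental_oxygen")
    missing_avpu = [lvl for lvl in AVPU_LEVELS if lvl not in table.consciousness_weights]
    if missing_avpu:
        out.append(f"news.consciousness missing levels {missing_avpu}")

    for name in ANALYTES:
        if name not in table.ldtews_scales:
            out.append(f"missing variable: ldtews.{name}")
    for name, scale in table.ldtews_scales.items():
        scales = scale.values() if isinstance(scale, dict) else [scale]
        for s in scales:
            out.extend(s.violations())

    covered = set()
    for lo, hi, lvl in table.gcs_to_avpu_ranges:
        if lvl not in AVPU_LEVELS:
            out.append(f"gcs_to_avpu: unknown level {lvl!r}")
        covered.update(range(lo, hi + 1))
    if covered != set(range(3, 16)):
        out.append("gcs_to_avpu does not cover 3..15 exactly once")

    if not out:
        news_attainable = (
            sum(s.max_weight for s in table.news_scales.values())
            + table.supplemental_oxygen_weight
            + max(table.consciousness_weights.values())
        )
        if news_attainable != table.news_max:
            out.append(
                f"news attainable maximum {news_attainable} != declared {table.news_max}"
            )
        for sex in ("male", "female"):
            ldt_attainable = sum(
                table.ldtews_scale(a, sex).max_weight for a in table.ldtews_scales
            )
            if ldt_attainable != table.ldtews_max:
                out.append(
                    f"ldtews attainable maximum ({sex}) {ldt_attainable}"
                    f" != declared {table.ldtews_max}"
                )
    return out
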