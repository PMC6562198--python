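"""Cohort construction: inclusion/exclusion criteria and outcome labelling.

The study population is adult (>= 16 y) emergency admissions to a set of
qualifying medical specialties with at least one complete vital-sign set.
Two exclusions mirror common ward-study practice: (a) same-day alive
discharges (discharged before the first midnight after admission), and
(b) admissions with no observations in the 24 h before the earliest of ICU
admission, discharge or death — a proxy for end-of-life pathways on which
monitoring was deliberately withdrawn.

The primary outcome of an observation set is the *first* of in-hospital
death or unanticipated ICU admission within the following 24 h; the two
events are also labelled separately as secondary outcomes.  The window is
half-open, ``(obs_time, obs_time + 24 h]``.  Observations recorded at or
after the first event are dropped from evaluation (the patient is no
longer at risk on a ward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .core_model import Admission


@dataclass(frozen=True)
class CohortConfig:
    min_age: int = 16
    qualifying_specialties: tuple[str, ...] = ("GEN_MED",)
    outcome_horizon_hours: float = 24.0
    end_of_life_lookback_hours: float = 24.0


@dataclass
class AuditCounts:
    """Flow-diagram bookkeeping; exclusions use first-failing-criterion attribution."""

    input_n: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    retained_n: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_n)]
        rows += [(f"excluded: {k}", v) for k, v in self.excluded.items()]
        rows.append(("retained", self.retained_n))
        return pd.DataFrame(rows, columns=["step", "n"])


def apply_inclusion(
    admissions: pd.DataFrame, vitals: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> tuple[pd.DataFrame, AuditCounts]:
    """Keep adult emergency admissions to qualifying specialties with >= 1 vitals set."""
    audit = AuditCounts(input_n=len(admissions))
    has_vitals = set(vitals["admission_id"].unique())

    criteria = [
        ("age", admissions["age"] >= config.min_age),
        ("admission method", admissions["admission_method"] == "emergency"),
        ("specialty", admissions["specialty"].isin(config.qualifying_specialties)),
        ("no complete vitals set", admissions["admission_id"].isin(has_vitals)),
    ]
    keep = pd.Series(True, index=admissions.index)
    for name, ok in criteria:
        failed = keep & ~ok
        if failed.any():
            audit.excluded[name] = int(failed.sum())
        keep &= ok
    retained = admissions[keep].reset_index(drop=True)
    audit.retained_n = len(retained)
    return retained, audit


def apply_exclusions(
    admissions: pd.DataFrame, vitals: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> tuple[pd.DataFrame, AuditCounts]:
    """Drop same-day alive discharges and end-of-life-proxy admissions."""
    audit = AuditCounts(input_n=len(admissions))

    alive = ~admissions["death_in_hospital"].astype(bool)
    first_midnight = admissions["admit_time"].dt.normalize() + pd.Timedelta(days=1)
    same_day = alive & (admissions["discharge_time"] < first_midnight)

    # earliest of ICU admission, discharge, death per admission
    ref = admissions[["discharge_time", "death_time", "icu_admission_time"]].min(axis=1)
    lookback = pd.Timedelta(hours=config.end_of_life_lookback_hours)
    v = vitals.merge(
        admissions[["admission_id"]].assign(ref=ref.to_numpy()), on="admission_id", how="inner"
    )
    recent = v[(v["obs_time"] >= v["ref"] - lookback) & (v["obs_time"] <= v["ref"])]
    has_recent = admissions["admission_id"].isin(recent["admission_id"].unique())

    keep = pd.Series(True, index=admissions.index)
    for name, fail in [
        ("same-day alive discharge", same_day),
        ("no observations near end of stay", ~has_recent),
    ]:
        failed = keep & fail
        if failed.any():
            audit.excluded[name] = int(failed.sum())
        keep &= ~fail
    retained = admissions[keep].reset_index(drop=True)
    audit.retained_n = len(retained)
    return retained, audit


def label_outcomes(
    obs_time: datetime, admission: Admission, config: CohortConfig = CohortConfig()
) -> tuple[bool, bool, bool]:
    """(primary, death_24h, icu_24h) labels for one observation time.

    Raises if the observation falls at or after the first event — such
    observations are excluded from evaluation upstream.
    """
    horizon = timedelta(hours=config.outcome_horizon_hours)
    first = admission.first_event_time
    if first is not None and obs_time >= first:
        raise ValueError("observation at or after the first event is not evaluable")

    def _within(t: datetime | None) -> bool:
        return t is not None and obs_time < t <= obs_time + horizon

    primary = _within(first)
    return primary, _within(admission.death_time), _within(admission.icu_admission_time)


def label_observation_table(
    scored: pd.DataFrame, admissions: pd.DataFrame, config: CohortConfig = CohortConfig()
) -> pd.DataFrame:
    """Vectorized labelling; drops rows at or after the admission's first event."""
    adm = admissions.set_index("admission_id")
    first_event = adm[["death_time", "icu_admission_time"]].min(axis=1)
    out = scored.merge(
        pd.DataFrame(
            {
                "first_event": first_event,
                "death_time": adm["death_time"],
                "icu_time": adm["icu_admission_time"],
            }
        ),
        left_on="admission_id",
        right_index=True,
        how="left",
    )
    evaluable = out["first_event"].isna() | (out["obs_time"] < out["first_event"])
    out = out[evaluable].copy()

    horizon = pd.Timedelta(hours=config.outcome_horizon_hours)

    def _within(event: pd.Series) -> np.ndarray:
        return (
            event.notna() & (out["obs_time"] < event) & (event <= out["obs_time"] + horizon)
        ).to_numpy()

    out["outcome_primary_24h"] = _within(out["first_event"])
    out["outcome_death_24h"] = _within(out["death_time"])
    out["outcome_icu_24h"] = _within(out["icu_time"])
    return out.drop(columns=["first_event", "death_time", "icu_time"]).reset_index(drop=True)
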