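"""Join vital-sign sets to the most recent value of each laboratory analyte.

Laboratory work arrives asynchronously and much less often than ward
observations, so each analyte's latest result is carried forward to later
observation times, up to an ageing horizon (default 120 h) beyond which it
is treated as absent.  ``time_since_labs`` — the age of the *newest* linked
result — feeds the decay weight of the combined risk index.

Rules:

* only labs received between the calendar day before admission and the day
  of discharge belong to an admission;
* a lab received strictly after the observation time is never used (no
  look-ahead); receipt exactly at the observation time counts, with age 0;
* analytes past the horizon are absent both for scoring and for the
  ``time_since_labs`` minimum.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import pandas as pd

from .core_model import (
    ANALYTES,
    DEFAULT_HORIZON_HOURS,
    Admission,
    LabResult,
    LabSlot,
    LinkedObservation,
    VitalSignSet,
)

_HOUR = timedelta(hours=1)


def attach_labs_to_admission(admission: Admission, labs: list[LabResult]) -> list[LabResult]:
    """Retain labs received from the day before admission to the day of discharge.

    The day-prior extension covers patients admitted through the emergency
    department overnight, whose admission bloods may be timestamped before
    the formal admission time.
    """
    day = timedelta(days=1)
    window_start = _midnight(admission.admit_time) - day
    window_end = _midnight(admission.discharge_time) + day  # exclusive
    return [r for r in labs if window_start <= r.received_time < window_end]


def _midnight(t: datetime) -> datetime:
    return t.replace(hour=0, minute=0, second=0, microsecond=0)


def carry_forward(
    obs_time: datetime,
    labs: list[LabResult],
    horizon_hours: float = DEFAULT_HORIZON_HOURS,
    vitals: VitalSignSet | None = None,
) -> LinkedObservation:
    """Link one observation time to the latest within-horizon value per analyte."""
    if horizon_hours <= 0:
        raise ValueError("horizon must be positive")
    slots: dict[str, LabSlot] = {}
    best: dict[str, tuple] = {}
    for lab in labs:
        if lab.received_time > obs_time:
            continue
        age = (obs_time - lab.received_time) / _HOUR
        if age > horizon_hours:
            continue
        # most recent wins; exact receipt-time ties break to the higher value
        key = (lab.received_time, lab.value)
        if lab.analyte not in best or key > best[lab.analyte]:
            best[lab.analyte] = key
            slots[lab.analyte] = LabSlot(value=lab.value, age_hours=age)
    if vitals is None:
        vitals = _placeholder_vitals(obs_time)
    return LinkedObservation(vitals=vitals, slots=slots, horizon_hours=horizon_hours)


def _placeholder_vitals(obs_time: datetime) -> VitalSignSet:
    # carry_forward can be used on bare timestamps (e.g. in tests); the
    # placeholder has every component in a zero-weight band.
    return VitalSignSet(
        admission_id="",
        obs_time=obs_time,
        heart_rate=70.0,
        systolic_bp=120.0,
        respiratory_rate=16.0,
        temperature=36.8,
        spo2=98.0,
        supplemental_oxygen=False,
        avpu="A",
    )


def time_since_labs(linked: LinkedObservation) -> float:
    """Hours since the newest linked result; the horizon when none is linked."""
    return linked.time_since_labs


# ---------------------------------------------------------------------------
# Vectorized linkage over whole tables (pipeline path)


def link_observations(
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    admissions: pd.DataFrame,
    horizon_hours: float = DEFAULT_HORIZON_HOURS,
) -> pd.DataFrame:
    """Produce the wide linked-observation table for a whole cohort.

    One row per vitals set, with ``<analyte>_value`` / ``<analyte>_age_h``
    columns (NaN where absent), ``time_since_labs``, and the admission's
    ``sex`` merged in.  Row-for-row equivalent to
    :func:`attach_labs_to_admission` + :func:`carry_forward`.
    """
    out = vitals.sort_values(["obs_time", "admission_id"], kind="stable").reset_index(drop=True)

    adm = admissions.set_index("admission_id")
    adm_window = pd.DataFrame(
        {
            "window_start": adm["admit_time"].dt.normalize() - pd.Timedelta(days=1),
            "window_end": adm["discharge_time"].dt.normalize() + pd.Timedelta(days=1),
        }
    )
    labs = labs.merge(adm_window, left_on="admission_id", right_index=True, how="inner")
    labs = labs[
        (labs["received_time"] >= labs["window_start"])
        & (labs["received_time"] < labs["window_end"])
    ]

    tol = pd.Timedelta(hours=horizon_hours)
    for analyte in ANALYTES:
        sub = (
            labs.loc[labs["analyte"] == analyte, ["admission_id", "received_time", "value"]]
            .sort_values(["received_time", "value"], kind="stable")  # ties -> higher value last
        )
        merged = pd.merge_asof(
            out[["admission_id", "obs_time"]],
            sub,
            left_on="obs_time",
            right_on="received_time",
            by="admission_id",
            direction="backward",
            tolerance=tol,
        )
        out[f"{analyte}_value"] = merged["value"].to_numpy()
        age = (out["obs_time"] - merged["received_time"]).dt.total_seconds() / 3600.0
        out[f"{analyte}_age_h"] = age.to_numpy()

    ages = out[[f"{a}_age_h" for a in ANALYTES]]
    out["time_since_labs"] = ages.min(axis=1).fillna(horizon_hours).to_numpy()
    out = out.merge(adm[["sex"]], left_on="admission_id", right_index=True, how="left")
    return out.sort_values(["admission_id", "obs_time"], kind="stable").reset_index(drop=True)
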