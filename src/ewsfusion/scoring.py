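"""Table-driven computation of the aggregate NEWS and LDT-EWS scores.

All cut-offs come from a :class:`~ewsfusion.core_model.ScoringTable`; this
module only performs band lookups and sums.  Absent laboratory analytes
score zero (the missing-variable rule), so an observation with no usable
labs has LDT-EWS 0.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core_model import (
    ANALYTES,
    NEWS_NUMERIC_COMPONENTS,
    LinkedObservation,
    ScoringTable,
    ValidationError,
    VitalSignSet,
)


def convert_gcs_to_avpu(gcs: int, table: ScoringTable) -> str:
    """Map a Glasgow Coma Scale value (3..15) onto the AVPU scale.

    Default mapping: 15 -> A, 13-14 -> V, 9-12 -> P, 3-8 -> U; the ranges
    are config data alongside the scoring bands.
    """
    gcs = int(gcs)
    if not 3 <= gcs <= 15:
        raise ValidationError(f"gcs must be in [3, 15], got {gcs}")
    for lo, hi, level in table.gcs_to_avpu_ranges:
        if lo <= gcs <= hi:
            return level
    raise ValidationError(f"gcs_to_avpu ranges do not cover {gcs}")


def score_news_component(component: str, value, table: ScoringTable) -> int:
    """Weight of a single NEWS component.

    *value* is a number for the banded components, a bool for
    ``supplemental_oxygen``, and an AVPU letter for ``consciousness``.
    """
    if component in NEWS_NUMERIC_COMPONENTS:
        v = float(value)
        if component == "temperature":
            v = round(v, 1)  # scored at 0.1 degC resolution
        return table.news_scales[component].weight(v)
    if component == "supplemental_oxygen":
        return table.supplemental_oxygen_weight if value else 0
    if component == "consciousness":
        try:
            return table.consciousness_weights[value]
        except KeyError:
            raise ValidationError(f"unknown consciousness level {value!r}") from None
    raise ValidationError(f"unknown NEWS component {component!r}")


def _avpu_of(vitals: VitalSignSet, table: ScoringTable) -> str:
    if vitals.avpu is not None:
        return vitals.avpu
    return convert_gcs_to_avpu(vitals.gcs, table)


def aggregate_news(vitals: VitalSignSet, table: ScoringTable) -> int:
    """Sum of the seven NEWS component weights (0..20)."""
    total = 0
    for comp in NEWS_NUMERIC_COMPONENTS:
        total += score_news_component(comp, getattr(vitals, comp), table)
    total += score_news_component("supplemental_oxygen", vitals.supplemental_oxygen, table)
    total += score_news_component("consciousness", _avpu_of(vitals, table), table)
    return total


def score_ldtews_component(
    analyte: str,
    value: Optional[float],
    sex: Optional[str],
    table: ScoringTable,
) -> int:
    """Weight of one LDT-EWS analyte; 0 when the value is absent."""
    if analyte not in ANALYTES:
        raise ValidationError(f"unknown analyte {analyte!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0
    return table.ldtews_scale(analyte, sex).weight(float(value))


def aggregate_ldtews(linked: LinkedObservation, sex: str, table: ScoringTable) -> int:
    """Sum of the seven LDT-EWS analyte weights (0..15); 0 when all absent."""
    total = 0
    for analyte in ANALYTES:
        slot = linked.slots.get(analyte)
        total += score_ldtews_component(analyte, None if slot is None else slot.value, sex, table)
    return total


# ---------------------------------------------------------------------------
# Vectorized scoring over a linked-observation table (pipeline path)


def score_table(linked: pd.DataFrame, table: ScoringTable) -> pd.DataFrame:
    """Append ``news`` and ``ldtews`` aggregate columns to a linked table.

    Expects the wide layout produced by :func:`ewsfusion.linkage.link_observations`:
    the seven vitals columns, ``sex``, and ``<analyte>_value`` columns (NaN =
    absent).  The per-row result is identical to calling :func:`aggregate_news`
    / :func:`aggregate_ldtews` on the corresponding domain objects.
    """
    out = linked.copy()
    news = np.zeros(len(out), dtype=np.int64)
    for comp in NEWS_NUMERIC_COMPONENTS:
        values = out[comp].to_numpy(dtype=float)
        if comp == "temperature":
            values = np.round(values, 1)
        news += table.news_scales[comp].weights(values)
    news += np.where(
        out["supplemental_oxygen"].to_numpy(dtype=bool), table.supplemental_oxygen_weight, 0
    )
    avpu = out["avpu"].copy()
    if "gcs" in out.columns:
        needs = avpu.isna() & out["gcs"].notna()
        if needs.any():
            avpu.loc[needs] = [
                convert_gcs_to_avpu(g, table) for g in out.loc[needs, "gcs"].astype(int)
            ]
    news += avpu.map(table.consciousness_weights).to_numpy(dtype=np.int64)
    out["news"] = news

    ldt = np.zeros(len(out), dtype=np.int64)
    is_male = out["sex"].to_numpy() == "male"
    for analyte in ANALYTES:
        values = out[f"{analyte}_value"].to_numpy(dtype=float)
        present = ~np.isnan(values)
        scale = table.ldtews_scales[analyte]
        w = np.zeros(len(out), dtype=np.int64)
        if isinstance(scale, dict):
            for sex, mask in (("male", is_male), ("female", ~is_male)):
                sel = present & mask
                if sel.any():
                    w[sel] = scale[sex].weights(values[sel])
        elif present.any():
            w[present] = scale.weights(values[present])
        ldt += w
    out["ldtews"] = ldt
    return out
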