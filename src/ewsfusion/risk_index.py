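"""The combined LDTEWS:NEWS risk index.

The index blends the two normalised aggregate scores with a weight that
decays linearly with the age of the newest laboratory evidence:

    omega      = beta * (1 - TimeSinceLabs / 120)
    risk index = omega * (LDTEWS / 15) + (1 - omega) * (NEWS / 20)

``TimeSinceLabs`` is capped at the 120 h carry-forward horizon, so once all
laboratory results have aged out the index reduces exactly to NEWS / 20.
``beta`` bounds the laboratory share of the index: with the reference
coefficient 0.26 the LDT-EWS term contributes between 0% and 26% and the
NEWS term between 74% and 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import DEFAULT_HORIZON_HOURS, ValidationError

#: Decay coefficient obtained on the original development cohort of
#: emergency medical admissions; the package default.
DEVELOPMENT_BETA = 0.26

#: Normalising maxima of the two aggregate scores.
NEWS_MAX = 20
LDTEWS_MAX = 15


@dataclass(frozen=True)
class DecayParameters:
    """Linear-decay weighting: slope coefficient and ageing horizon."""

    beta: float = DEVELOPMENT_BETA
    horizon_hours: float = DEFAULT_HORIZON_HOURS

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValidationError(f"beta must be in (0, 1), got {self.beta}")
        if not self.horizon_hours > 0:
            raise ValidationError("horizon must be positive")


def decay_weight(time_since_labs, params: DecayParameters = DecayParameters()):
    """omega = beta * (1 - min(t, horizon) / horizon); accepts scalars or arrays."""
    t = np.asarray(time_since_labs, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time_since_labs must be non-negative")
    omega = params.beta * (1.0 - np.minimum(t, params.horizon_hours) / params.horizon_hours)
    return float(omega) if np.ndim(time_since_labs) == 0 else omega


def compute_risk_index(news_aggregate, ldtews_aggregate, omega):
    """omega * ldtews/15 + (1 - omega) * news/20, in [0, 1]."""
    news = np.asarray(news_aggregate, dtype=float)
    ldt = np.asarray(ldtews_aggregate, dtype=float)
    w = np.asarray(omega, dtype=float)
    if np.any((news < 0) | (news > NEWS_MAX)):
        raise ValidationError(f"news aggregate outside [0, {NEWS_MAX}]")
    if np.any((ldt < 0) | (ldt > LDTEWS_MAX)):
        raise ValidationError(f"ldtews aggregate outside [0, {LDTEWS_MAX}]")
    if np.any((w < 0) | (w > 1)):
        raise ValidationError("omega outside [0, 1]")
    value = w * (ldt / LDTEWS_MAX) + (1.0 - w) * (news / NEWS_MAX)
    return float(value) if np.ndim(value) == 0 else value


def fixed_weight_index(news_aggregate, ldtews_aggregate, beta: float = DEVELOPMENT_BETA):
    """The no-decay comparator: the index with omega fixed at beta."""
    return compute_risk_index(news_aggregate, ldtews_aggregate, beta)
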