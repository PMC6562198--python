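"""Seeded generator of synthetic emergency-admission cohorts.

Emulates the structure of ward EHR extracts: admissions to a medical
specialty (median age ~73, ~49% male, right-skewed length of stay with
median ~3.7 days), vital-sign sets every few hours, laboratory panels
roughly daily (often received before the formal admission time for
patients admitted overnight through the emergency department), and
death / unanticipated-ICU events at rates near 4.8% and 1.1% of
admissions.

A latent per-admission severity random walk drives both the vital signs
and the analyte values, so derangement is correlated across channels and
over time.  Event hazard is tied to the current risk score: in the default
mode to the normalised NEWS alone; in *planted-beta* mode to the combined
risk index computed with a chosen decay coefficient ``beta*`` through the
package's own linkage, scoring and decay code — which is what makes
parameter-recovery experiments on the fitted beta meaningful.

Each admission consumes its own pseudo-random substream (spawned from the
cohort seed by admission index), so enlarging a cohort leaves earlier
admissions bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_model import ANALYTES, load_scoring_table
from .linkage import link_observations
from .risk_index import decay_weight, DecayParameters
from .scoring import score_table

_MIN = "min"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic cohort; defaults emulate an
    emergency medical admissions case mix."""

    n_admissions: int = 500
    seed: int = 0
    start_date: str = "2024-01-01"

    # demographics
    male_fraction: float = 0.49
    age_beta_a: float = 5.0       # age = 16 + 84 * Beta(a, b): median ~= 73
    age_beta_b: float = 2.0
    under_age_fraction: float = 0.02   # minors, excluded by the cohort filter
    elective_fraction: float = 0.06
    other_specialty_fraction: float = 0.04
    specialty: str = "GEN_MED"

    # stay and sampling cadence
    los_log_mean_hours: float = math.log(3.7 * 24.0)
    los_log_sd: float = 0.66
    vitals_log_median_hours: float = math.log(6.0)
    vitals_log_sd: float = 0.45
    lab_day0_p: float = 0.95
    lab_daily_p: float = 0.80      # day-1 probability, declining geometrically
    lab_daily_decay: float = 0.90
    analyte_missing_p: float = 0.08
    no_labs_fraction: float = 0.04
    gcs_recorded_fraction: float = 0.30
    withdrawn_monitoring_fraction: float = 0.03

    # latent severity process
    severity_step_sd: float = 0.13     # per sqrt(6 h)
    lab_severity_offset_sd: float = 0.25
    lab_severity_noise_sd: float = 0.08

    # events: P(event within 24 h | observation) = expit(intercept + slope * risk);
    # intercepts are calibrated per hazard mode (the NEWS-only and blended
    # risk drivers have different upper tails) so that ~4.8% of admissions
    # die in hospital and ~1.1% have an unanticipated ICU admission
    event_slope: float = 10.0
    event_intercept: Optional[float] = None   # resolved per mode when None
    default_mode_intercept: float = -9.3
    planted_mode_intercept: float = -8.8
    death_fraction_given_event: float = 0.81

    # planted-beta mode: hazard driven by the combined index at this beta
    planted_beta: Optional[float] = None
    horizon_hours: float = 120.0


@dataclass
class SyntheticCohort:
    admissions: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame  # per-observation latent severity / hazard record


def _reflect01(x: np.ndarray) -> np.ndarray:
    x = np.mod(x, 2.0)
    return np.where(x > 1.0, 2.0 - x, x)


def _floor_minute(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor(_MIN)


def _gen_admission_raw(i: int, cfg: GeneratorConfig) -> dict:
    """Demographics, vitals and labs for one admission (no events yet)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
    aid = f"A{i:06d}"

    sex = "male" if rng.random() < cfg.male_fraction else "female"
    if rng.random() < cfg.under_age_fraction:
        age = int(rng.integers(1, 16))
    else:
        age = int(round(16 + 84 * rng.beta(cfg.age_beta_a, cfg.age_beta_b)))
    u = rng.random()
    if u < cfg.elective_fraction:
        method = "elective"
        specialty = cfg.specialty
    elif u < cfg.elective_fraction + cfg.other_specialty_fraction:
        method = "emergency"
        specialty = "SURG"
    else:
        method = "emergency"
        specialty = cfg.specialty

    start = pd.Timestamp(cfg.start_date)
    admit = _floor_minute(start + pd.Timedelta(hours=float(rng.uniform(0, 365 * 24))))
    los_h = float(np.clip(rng.lognormal(cfg.los_log_mean_hours, cfg.los_log_sd) / 24.0, 0.25, 60) * 24)

    # observation times
    t = float(rng.uniform(0.2, 1.0))
    obs_offsets = [t]
    while len(obs_offsets) < 240:
        t += float(np.clip(rng.lognormal(cfg.vitals_log_median_hours, cfg.vitals_log_sd), 0.75, 14.0))
        if t >= los_h:
            break
        obs_offsets.append(t)
    offsets = np.array(obs_offsets)
    los_h = max(los_h, offsets[-1] + 0.5)
    n_obs = offsets.size

    # monitoring occasionally withdrawn near the end of a long stay
    if n_obs > 6 and los_h > 48 and rng.random() < cfg.withdrawn_monitoring_fraction:
        keep = offsets < los_h - 30.0
        if keep.sum() >= 1:
            offsets = offsets[keep]
            n_obs = offsets.size

    # latent severity walk; the squared/power transforms below keep mild
    # severity inside zero-weight bands while high severity reaches the
    # worst bands, giving a realistic right-skewed score distribution
    sev = np.empty(n_obs)
    sev[0] = rng.uniform(0.02, 0.45)
    steps = rng.normal(0.0, 1.0, n_obs - 1)
    for k in range(1, n_obs):
        dt = offsets[k] - offsets[k - 1]
        sev[k] = _reflect01(np.array([sev[k - 1] + steps[k - 1] * cfg.severity_step_sd * math.sqrt(dt / 6.0)]))[0]

    # vitals from severity
    hr = np.clip(np.round(72 + 55 * sev**1.8 + rng.normal(0, 6, n_obs)), 25, 220)
    rr = np.clip(np.round(14 + 17 * sev**2 + rng.normal(0, 1.5, n_obs)), 4, 60)
    sbp = np.clip(np.round(128 - 55 * sev**1.8 + rng.normal(0, 9, n_obs)), 50, 250)
    febrile = rng.random() < 0.7
    temp_shift = 2.9 * sev**2 if febrile else -2.5 * sev**2
    temp = np.clip(np.round(36.6 + temp_shift + rng.normal(0, 0.25, n_obs), 1), 33.0, 41.5)
    spo2 = np.clip(np.round(98 - 9 * sev**1.8 + rng.normal(0, 1.2, n_obs)), 70, 100)
    oxy = rng.random(n_obs) < np.clip(0.02 + 0.8 * sev**3, 0, 0.9)

    p_non_alert = np.clip(1.8 * (sev - 0.65), 0.0, 0.9)
    non_alert = rng.random(n_obs) < p_non_alert
    level_draw = rng.random(n_obs)
    avpu = np.where(non_alert, np.where(level_draw < 0.55, "V", np.where(level_draw < 0.85, "P", "U")), "A")
    as_gcs = rng.random(n_obs) < cfg.gcs_recorded_fraction
    gcs_map = {"A": (15, 15), "V": (13, 14), "P": (9, 12), "U": (3, 8)}
    gcs = np.full(n_obs, np.nan)
    for k in np.flatnonzero(as_gcs):
        lo, hi = gcs_map[str(avpu[k])]
        gcs[k] = rng.integers(lo, hi + 1)
    avpu_col = np.where(as_gcs, None, avpu)

    obs_times = [_floor_minute(admit + pd.Timedelta(hours=h)) for h in offsets]
    vitals_rows = {
        "admission_id": [aid] * n_obs,
        "obs_time": obs_times,
        "heart_rate": hr,
        "systolic_bp": sbp,
        "respiratory_rate": rr,
        "temperature": temp,
        "spo2": spo2,
        "supplemental_oxygen": oxy,
        "avpu": avpu_col,
        "gcs": gcs,
    }

    # laboratory draws
    labs_rows: list[tuple] = []
    if rng.random() >= cfg.no_labs_fraction:
        draw_offsets = []
        if rng.random() < cfg.lab_day0_p:
            draw_offsets.append(float(rng.uniform(-8.0, 4.0)))  # admission bloods
        day = 1
        while day * 24.0 < los_h:
            if rng.random() < cfg.lab_daily_p * cfg.lab_daily_decay ** (day - 1):
                draw_offsets.append(day * 24.0 + float(rng.uniform(6.0, 11.0)) - admit.hour)
            day += 1
        lab_offset = rng.normal(0.0, cfg.lab_severity_offset_sd)
        k_dir = 1.0 if rng.random() < 0.6 else -1.0
        w_high = rng.random() < 0.85
        cre_base = 72.0 if sex == "male" else 58.0
        hb_base = 147.0 if sex == "male" else 132.0
        for off in draw_offsets:
            s_t = float(np.interp(off, offsets, sev))
            sl = float(np.clip(0.85 * s_t + lab_offset + rng.normal(0, cfg.lab_severity_noise_sd), 0.0, 1.0))
            values = {
                "albumin": max(8.0, 42 - 28 * sl**1.5 + rng.normal(0, 2.5)),
                "creatinine": max(20.0, cre_base + 330 * sl**2 + rng.normal(0, 9)),
                "haemoglobin": max(40.0, hb_base - 58 * sl**1.5 + rng.normal(0, 7)),
                "potassium": float(np.clip(4.1 + k_dir * 2.4 * sl**1.6 + rng.normal(0, 0.22), 1.5, 9.0)),
                "sodium": float(np.clip(139 - 16 * sl**1.5 + rng.normal(0, 2.4), 110, 165)),
                "urea": max(0.5, 4.5 + 26 * sl**1.8 + rng.normal(0, 1.2)),
                "wcc": max(0.2, 8 + 17 * sl**1.6 + rng.normal(0, 1.6)) if w_high
                else max(0.2, 8 - 6.5 * sl + rng.normal(0, 1.0)),
            }
            received = _floor_minute(admit + pd.Timedelta(hours=off))
            for analyte in ANALYTES:
                if rng.random() >= cfg.analyte_missing_p:
                    labs_rows.append((aid, received, analyte, round(values[analyte], 1)))

    return {
        "admission_id": aid,
        "index": i,
        "age": age,
        "sex": sex,
        "method": method,
        "specialty": specialty,
        "admit": admit,
        "planned_los_h": los_h,
        "vitals": vitals_rows,
        "labs": labs_rows,
        "severity": sev,
        "obs_offsets": offsets,
    }


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate admissions, vitals and labs tables (deterministic under seed)."""
    raw = [_gen_admission_raw(i, cfg) for i in range(cfg.n_admissions)]

    vitals = pd.concat([pd.DataFrame(r["vitals"]) for r in raw], ignore_index=True)
    lab_tuples = [t for r in raw for t in r["labs"]]
    labs = pd.DataFrame(lab_tuples, columns=["admission_id", "received_time", "analyte", "value"])

    planned = pd.DataFrame(
        {
            "admission_id": [r["admission_id"] for r in raw],
            "age": [r["age"] for r in raw],
            "sex": [r["sex"] for r in raw],
            "admit_time": [r["admit"] for r in raw],
            "discharge_time": [
                _floor_minute(r["admit"] + pd.Timedelta(hours=r["planned_los_h"])) for r in raw
            ],
            "admission_method": [r["method"] for r in raw],
            "specialty": [r["specialty"] for r in raw],
        }
    )

    # risk at each observation, via the package's own linkage/scoring path
    table = load_scoring_table()
    linked = link_observations(vitals, labs, planned, horizon_hours=cfg.horizon_hours)
    scored = score_table(linked, table)
    if cfg.planted_beta is not None:
        params = DecayParameters(beta=cfg.planted_beta, horizon_hours=cfg.horizon_hours)
        omega = decay_weight(scored["time_since_labs"].to_numpy(), params)
        risk = omega * (scored["ldtews"].to_numpy() / 15.0) + (1 - omega) * (
            scored["news"].to_numpy() / 20.0
        )
    else:
        risk = scored["news"].to_numpy() / 20.0
    scored = scored.assign(risk=risk)
    if cfg.event_intercept is not None:
        intercept = cfg.event_intercept
    elif cfg.planted_beta is not None:
        intercept = cfg.planted_mode_intercept
    else:
        intercept = cfg.default_mode_intercept
    by_adm = {aid: g for aid, g in scored.groupby("admission_id", sort=False)}

    adm_rows = []
    keep_vitals = []
    keep_labs = []
    truth_rows = []
    for r in raw:
        aid = r["admission_id"]
        g = by_adm[aid].sort_values("obs_time")
        obs_times = g["obs_time"].to_numpy()
        risks = g["risk"].to_numpy()
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(r["index"], 1)))

        planned_dis = planned.loc[planned["admission_id"] == aid, "discharge_time"].iloc[0]
        p24 = expit(intercept + cfg.event_slope * risks)
        event_time = None
        event_at = None
        draws = rng.random(risks.size)
        gaps = np.diff(np.append(obs_times, np.datetime64(planned_dis)))
        for k in range(risks.size):
            dt_h = min(float(gaps[k] / np.timedelta64(1, "h")), 24.0)
            if dt_h <= 0:
                continue
            if draws[k] < p24[k] * dt_h / 24.0:
                event_time = _floor_minute(
                    pd.Timestamp(obs_times[k]) + pd.Timedelta(hours=float(rng.uniform(0.1, max(0.2, dt_h))))
                )
                event_at = k
                break

        death_time = pd.NaT
        icu_time = pd.NaT
        if event_time is not None:
            if rng.random() < cfg.death_fraction_given_event:
                death_time = event_time
                discharge = event_time
            else:
                icu_time = event_time
                discharge = _floor_minute(
                    event_time + pd.Timedelta(hours=float(rng.exponential(72.0)) + 6.0)
                )
        else:
            discharge = planned_dis

        adm_rows.append(
            (
                aid,
                r["age"],
                r["sex"],
                r["admit"],
                discharge,
                r["method"],
                r["specialty"],
                death_time is not pd.NaT and not pd.isna(death_time),
                death_time,
                icu_time,
            )
        )

        cutoff = event_time if event_time is not None else discharge
        vmask = g["obs_time"] < cutoff
        keep_vitals.append(set(zip(g.loc[vmask, "admission_id"], g.loc[vmask, "obs_time"])))
        truth_rows.append(
            pd.DataFrame(
                {
                    "admission_id": aid,
                    "obs_time": g["obs_time"].to_numpy(),
                    "severity": r["severity"][: len(g)],
                    "risk": risks,
                    "p_event_24h": p24,
                    "event_interval": [event_at == k for k in range(len(g))],
                }
            )
        )
        keep_labs.append((aid, cutoff))

    admissions = pd.DataFrame(
        adm_rows,
        columns=[
            "admission_id",
            "age",
            "sex",
            "admit_time",
            "discharge_time",
            "admission_method",
            "specialty",
            "death_in_hospital",
            "death_time",
            "icu_admission_time",
        ],
    )

    keep_pairs = set().union(*keep_vitals) if keep_vitals else set()
    vkey = list(zip(vitals["admission_id"], vitals["obs_time"]))
    vitals = vitals[[k in keep_pairs for k in vkey]].reset_index(drop=True)

    cutoff_map = dict(keep_labs)
    if len(labs):
        labs = labs[
            [t <= cutoff_map[a] for a, t in zip(labs["admission_id"], labs["received_time"])]
        ].reset_index(drop=True)

    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame()
    return SyntheticCohort(admissions=admissions, vitals=vitals, labs=labs, truth=truth)


def generate_planted_beta_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Cohort whose event hazard follows the combined index at ``cfg.planted_beta``."""
    if cfg.planted_beta is None or not 0 < cfg.planted_beta < 1:
        raise ValueError("planted_beta must be set in (0, 1)")
    return generate_cohort(cfg)
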