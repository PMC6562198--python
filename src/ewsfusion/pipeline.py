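"""End-to-end pipeline: cohort -> link -> score -> (fit) -> evaluate.

A :class:`RunConfig` names the three input tables and the stage options;
:func:`run_pipeline` executes the stages, writes every intermediate table
to the output directory, and records a machine-readable manifest (seed,
config hash, library versions) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .cohort import CohortConfig, apply_exclusions, apply_inclusion, label_observation_table
from .core_model import load_scoring_table
from .evaluation import c_statistic, c_statistic_ci, matched_specificity_threshold
from .fitting import FitConfig, fit_beta
from .io import read_tables
from .linkage import link_observations
from .risk_index import DEVELOPMENT_BETA, DecayParameters, decay_weight, fixed_weight_index
from .scoring import score_table


@dataclass
class RunConfig:
    admissions_path: str
    vitals_path: str
    labs_path: str
    output_dir: str
    scoring_table_path: Optional[str] = None
    seed: int = 0
    beta: float = DEVELOPMENT_BETA
    fit_beta_first: bool = False
    horizon_hours: float = 120.0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def content_hash(self) -> str:
        # hash the analytic configuration only, not where outputs land
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def score_observations(
    linked: pd.DataFrame, table, params: DecayParameters
) -> pd.DataFrame:
    """Aggregate scores, decay weight, risk index and the fixed-weight comparator."""
    scored = score_table(linked, table)
    omega = decay_weight(scored["time_since_labs"].to_numpy(), params)
    scored["omega"] = omega
    scored["risk_index"] = omega * (scored["ldtews"] / 15.0) + (1 - omega) * (
        scored["news"] / 20.0
    )
    scored["fixed_variant_index"] = fixed_weight_index(
        scored["news"].to_numpy(), scored["ldtews"].to_numpy(), params.beta
    )
    return scored


def _evaluate_scores(labelled: pd.DataFrame) -> pd.DataFrame:
    rows = []
    scores = {
        "news": labelled["news"] / 20.0,
        "ldtews": labelled["ldtews"] / 15.0,
        "fixed_variant_index": labelled["fixed_variant_index"],
        "risk_index": labelled["risk_index"],
    }
    outcomes = {
        "primary": labelled["outcome_primary_24h"],
        "death": labelled["outcome_death_24h"],
        "icu": labelled["outcome_icu_24h"],
    }
    for outcome_name, y in outcomes.items():
        if y.all() or not y.any():
            continue  # outcome absent in this cohort
        for score_name, s in scores.items():
            auc = c_statistic(s, y)
            lo, hi = c_statistic_ci(s, y)
            rows.append((outcome_name, score_name, auc, lo, hi, int(y.sum())))
    return pd.DataFrame(
        rows, columns=["outcome", "score", "auroc", "ci_low", "ci_high", "n_events"]
    )


def _threshold_comparison(labelled: pd.DataFrame, triggers=(5, 7)) -> pd.DataFrame:
    """Index thresholds matching the specificity of standard NEWS triggers."""
    y = labelled["outcome_primary_24h"]
    rows = []
    for trig in triggers:
        res = matched_specificity_threshold(
            labelled["news"], trig, labelled["risk_index"], y
        )
        for name, rep in (("news", res.reference), ("risk_index", res.target)):
            rows.append(
                (
                    trig, name, rep.threshold, rep.sensitivity, rep.specificity,
                    rep.ppv, rep.npv, rep.n_flagged, res.specificity_attained,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "news_trigger", "score", "threshold", "sensitivity", "specificity",
            "ppv", "npv", "n_flagged", "specificity_attained",
        ],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the output bundle as a dict of frames/paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    admissions, vitals, labs, report = read_tables(
        config.admissions_path, config.vitals_path, config.labs_path
    )
    table = load_scoring_table(config.scoring_table_path)

    included, inc_audit = apply_inclusion(admissions, vitals, config.cohort)
    retained, exc_audit = apply_exclusions(included, vitals, config.cohort)
    flow = pd.concat(
        [
            inc_audit.as_frame().assign(stage="inclusion"),
            exc_audit.as_frame().assign(stage="exclusion"),
        ],
        ignore_index=True,
    )

    cohort_vitals = vitals[vitals["admission_id"].isin(retained["admission_id"])]
    linked = link_observations(cohort_vitals, labs, retained, config.horizon_hours)

    beta = config.beta
    fit_curve = None
    if config.fit_beta_first:
        prelim = score_table(linked, table)
        labelled_prelim = label_observation_table(prelim, retained, config.cohort)
        result = fit_beta(labelled_prelim, FitConfig(seed=config.seed))
        beta = result.beta_hat
        fit_curve = result.curve()

    params = DecayParameters(beta=beta, horizon_hours=config.horizon_hours)
    scored = score_observations(linked, table, params)
    labelled = label_observation_table(scored, retained, config.cohort)
    evaluation = _evaluate_scores(labelled)
    y = labelled["outcome_primary_24h"]
    thresholds = _threshold_comparison(labelled) if y.any() and not y.all() else None

    flow.to_csv(outdir / "flow_counts.csv", index=False)
    keep = [
        "admission_id", "obs_time", "news", "ldtews", "time_since_labs", "omega",
        "risk_index", "fixed_variant_index", "outcome_primary_24h",
        "outcome_death_24h", "outcome_icu_24h",
    ]
    labelled[keep].to_csv(outdir / "scored_observations.csv", index=False)
    evaluation.to_csv(outdir / "evaluation.csv", index=False)
    if thresholds is not None:
        thresholds.to_csv(outdir / "threshold_reports.csv", index=False)
    if fit_curve is not None:
        fit_curve.to_csv(outdir / "beta_curve.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "beta": beta,
        "config_hash": config.content_hash(),
        "n_admissions_input": len(admissions),
        "n_admissions_retained": len(retained),
        "n_observations": len(labelled),
        "rejected_vitals_rows": report.n_rejected,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "flow": flow,
        "labelled": labelled,
        "evaluation": evaluation,
        "thresholds": thresholds,
        "beta": beta,
        "fit_curve": fit_curve,
        "manifest": manifest,
    }
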