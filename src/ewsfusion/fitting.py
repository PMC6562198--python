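"""Grid-search estimation of the decay coefficient beta.

beta is the single fitted quantity of the combined index.  The data are
split at random into folds at the *admission* level (all observations of
an admission share a fold, preventing within-admission leakage); for every
candidate beta on the grid the risk index is evaluated on each fold and
its AUROC against the primary outcome recorded; the fitted beta is the one
with the maximal mean AUROC across folds (ties break to the smallest
beta).  With no per-fold training step this is a cross-validation-style
averaging that smooths the AUROC objective over resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))


@dataclass(frozen=True)
class FitConfig:
    grid: tuple[float, ...] = field(default_factory=_default_grid)
    n_folds: int = 10
    seed: int = 0
    fold_unit: str = "admission"

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(g <= 0) or np.any(g >= 1) or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing within (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.fold_unit != "admission":
            raise ValueError("only admission-level folds are supported")


def make_folds(admission_ids, config: FitConfig) -> pd.Series:
    """Seeded near-equal-size random partition of admissions into folds.

    Returns a Series mapping admission id -> fold index; fold sizes differ
    by at most one.
    """
    ids = pd.unique(pd.Series(admission_ids))
    if len(ids) < config.n_folds:
        raise ValueError(f"need at least {config.n_folds} admissions, got {len(ids)}")
    rng = np.random.default_rng(config.seed)
    order = np.array(sorted(ids, key=str))  # canonical order: independent of input order
    rng.shuffle(order)
    folds = np.arange(len(order)) % config.n_folds
    return pd.Series(folds, index=order, name="fold")


def _fold_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class FitResult:
    beta_hat: float
    grid: np.ndarray
    mean_auc: np.ndarray          # one entry per grid value
    fold_auc: np.ndarray          # shape (n_folds, len(grid))

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.grid, "mean_auc": self.mean_auc})


def fit_beta(observations: pd.DataFrame, config: FitConfig = FitConfig()) -> FitResult:
    """Fit beta on a labelled scored-observation table.

    Requires columns ``admission_id``, ``news``, ``ldtews``,
    ``time_since_labs`` and ``outcome_primary_24h``.  Every fold must
    contain both outcome classes.
    """
    df = observations
    folds = make_folds(df["admission_id"], config)
    fold_of_row = df["admission_id"].map(folds).to_numpy()

    news_n = df["news"].to_numpy(dtype=float) / 20.0
    ldt_n = df["ldtews"].to_numpy(dtype=float) / 15.0
    t = np.clip(df["time_since_labs"].to_numpy(dtype=float), 0.0, 120.0)
    # risk index at beta: news_n + beta * decay * (ldt_n - news_n)
    delta = (1.0 - t / 120.0) * (ldt_n - news_n)
    labels = df["outcome_primary_24h"].to_numpy(dtype=bool)

    grid = np.asarray(config.grid, dtype=float)
    fold_auc = np.empty((config.n_folds, grid.size))
    for f in range(config.n_folds):
        sel = fold_of_row == f
        y = labels[sel]
        if y.all() or not y.any():
            raise ValueError(
                f"fold {f} contains a single outcome class; AUROC is undefined -- "
                "use more data or fewer folds"
            )
        base, d = news_n[sel], delta[sel]
        for j, beta in enumerate(grid):
            fold_auc[f, j] = _fold_auc(base + beta * d, y)

    mean_auc = fold_auc.mean(axis=0)
    beta_hat = float(grid[int(np.argmax(mean_auc))])  # argmax ties -> smallest beta
    return FitResult(beta_hat=beta_hat, grid=grid, mean_auc=mean_auc, fold_auc=fold_auc)
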