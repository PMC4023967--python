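"""Cross-validated grid experiment over input groupings, hidden sizes and goals.

The study design: 56 subjects, a 4-fold rotation (42 train / 14 test per
fold, every subject tested exactly once), and a factorial grid of six input
groupings (the five clinical functional domains plus `all`) x four hidden
sizes (5, 10, 20, 30) x three normalized-MSE goals (0.1, 0.01, 0.001) --
72 network configurations.  Each configuration trains one network per fold,
predicts its held-out subjects in real-world units, and is scored by Pearson
correlation and mean absolute error per balance outcome.

Normalization is fitted inside each fold on the training rows only; test
rows never touch normalizer fitting (audited via the normalizer's fit-count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DOMAINS, FEATURE_NAMES, OUTCOME_NAMES
from .errors import ConfigurationError
from .network import NetworkConfig, predict, train_lm

__all__ = [
    "GROUPINGS",
    "STUDY_HIDDEN_SIZES",
    "STUDY_ERROR_GOALS",
    "FoldPlan",
    "make_folds",
    "select_inputs",
    "pearson_r",
    "run_config",
    "run_grid",
    "summarize",
]

#: the six input groupings: five functional domains plus their union
GROUPINGS: dict[str, tuple[str, ...]] = {
    **DOMAINS,
    "all": FEATURE_NAMES,
}

STUDY_HIDDEN_SIZES: tuple[int, ...] = (5, 10, 20, 30)
STUDY_ERROR_GOALS: tuple[float, ...] = (0.1, 0.01, 0.001)


@dataclass
class FoldPlan:
    """Disjoint test sets (by positional row index) covering every subject."""

    test_sets: list  # list of np.ndarray of row indices
    n_subjects: int
    seed: int
    independent_draws: bool = False

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.test_sets[fold].tolist())
        return np.array([i for i in range(self.n_subjects) if i not in test])


def make_folds(n_subjects: int, k: int = 4, test_size: int = 14,
               seed: int = 0, independent_draws: bool = False) -> FoldPlan:
    """Seeded rotation: k disjoint test sets of ``test_size`` subjects.

    With ``independent_draws`` each fold is a fresh random train/test split
    (subjects may then be tested more than once or never); the default is a
    partition, so that testing covers all subjects exactly once.
    """
    rng = np.random.default_rng(seed)
    if independent_draws:
        sets = [
            rng.permutation(n_subjects)[:test_size].copy() for _ in range(k)
        ]
        return FoldPlan(sets, n_subjects, seed, True)
    if n_subjects != k * test_size:
        raise ConfigurationError(
            f"{n_subjects} subjects cannot rotate through {k} folds of {test_size}"
        )
    perm = rng.permutation(n_subjects)
    sets = [np.sort(perm[i * test_size:(i + 1) * test_size]) for i in range(k)]
    return FoldPlan(sets, n_subjects, seed, False)


def select_inputs(grouping: str, cohort: pd.DataFrame) -> np.ndarray:
    """Feature matrix for a grouping, columns in canonical order."""
    if grouping not in GROUPINGS:
        raise ConfigurationError(
            f"unknown grouping '{grouping}'; valid: {sorted(GROUPINGS)}"
        )
    return cohort.loc[:, list(GROUPINGS[grouping])].to_numpy(dtype=float)


def pearson_r(y_true, y_pred):
    """Pearson product-moment correlation; None when undefined.

    Returns ``(r, reason)``; ``reason`` names the constant vector when the
    correlation is undefined instead of silently yielding NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 3:
        raise ConfigurationError("need at least 3 samples for a correlation")
    if np.ptp(y_true) == 0.0:
        return None, "y_true is constant"
    if np.ptp(y_pred) == 0.0:
        return None, "y_pred is constant"
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return r, None


def run_config(
    cohort: pd.DataFrame,
    grouping: str,
    n_hidden: int,
    error_goal: float,
    folds: FoldPlan,
    seed: int = 0,
    max_epochs: int = 500,
) -> pd.DataFrame:
    """Train/test one network configuration across all folds.

    Returns one row per fold x outcome with Pearson R, MAE in real units,
    epochs used and the stop reason.  A fold whose training fails is flagged
    and the remaining folds still run.
    """
    X_all = select_inputs(grouping, cohort)
    Y_all = cohort.loc[:, list(OUTCOME_NAMES)].to_numpy(dtype=float)
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(folds.test_sets))
    rows = []
    for fold, test_idx in enumerate(folds.test_sets):
        train_idx = folds.train_indices(fold)
        cfg = NetworkConfig(
            n_inputs=X_all.shape[1], n_hidden=n_hidden, n_outputs=len(OUTCOME_NAMES),
            error_goal=error_goal, max_epochs=max_epochs,
            seed=int(fold_seeds[fold] % (2**31)),
        )
        try:
            model, trace = train_lm(
                cfg, X_all[train_idx], Y_all[train_idx],
                x_columns=list(GROUPINGS[grouping]), y_columns=list(OUTCOME_NAMES),
            )
        except Exception as err:  # noqa: BLE001 - fold failure must not kill the run
            for o, name in enumerate(OUTCOME_NAMES):
                rows.append(_fold_row(grouping, n_hidden, error_goal, fold, name,
                                      None, np.nan, 0, f"error: {err}", None))
            continue
        assert model.x_norm.n_fit == len(train_idx), "normalizer saw non-train rows"
        pred = predict(model, X_all[test_idx])
        for o, name in enumerate(OUTCOME_NAMES):
            r, reason = pearson_r(Y_all[test_idx, o], pred[:, o])
            mae = float(np.mean(np.abs(pred[:, o] - Y_all[test_idx, o])))
            rows.append(_fold_row(grouping, n_hidden, error_goal, fold, name,
                                  r, mae, trace.epochs_used, trace.stop_reason,
                                  reason))
    return pd.DataFrame(rows)


def _fold_row(grouping, n_hidden, error_goal, fold, outcome, r, mae,
              epochs, stop_reason, r_undefined_reason):
    return {
        "grouping": grouping, "n_hidden": n_hidden, "error_goal": error_goal,
        "fold": fold, "outcome": outcome, "pearson_r": r, "mae": mae,
        "epochs_used": epochs, "stop_reason": stop_reason,
        "r_undefined_reason": r_undefined_reason,
    }


def run_grid(
    cohort: pd.DataFrame,
    folds: FoldPlan,
    groupings=None,
    hidden_sizes: tuple[int, ...] = STUDY_HIDDEN_SIZES,
    error_goals: tuple[float, ...] = STUDY_ERROR_GOALS,
    seed: int = 0,
    max_epochs: int = 500,
) -> pd.DataFrame:
    """Full factorial grid (default 6 x 4 x 3 = 72 configurations).

    One master seed expands deterministically into per-configuration seeds;
    per-configuration failures are recorded, never raised.
    """
    groupings = list(GROUPINGS) if groupings is None else list(groupings)
    for g in groupings:
        if g not in GROUPINGS:
            raise ConfigurationError(f"unknown grouping '{g}'")
    configs = [
        (g, h, e) for g in groupings for h in hidden_sizes for e in error_goals
    ]
    config_seeds = np.random.SeedSequence(seed).generate_state(len(configs))
    frames = []
    for (g, h, e), cseed in zip(configs, config_seeds):
        frames.append(
            run_config(cohort, g, h, e, folds, seed=int(cseed % (2**31)),
                       max_epochs=max_epochs)
        )
    return pd.concat(frames, ignore_index=True)


def _aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of R and MAE across folds for every configuration x outcome."""
    def agg(group):
        r = group["pearson_r"].dropna()
        return pd.Series({
            "mean_r": r.mean() if len(r) else np.nan,
            "sd_r": r.std(ddof=1) if len(r) > 1 else np.nan,
            "n_folds_defined": len(r),
            "n_r_undefined": group["pearson_r"].isna().sum(),
            "mean_mae": group["mae"].mean(),
            "mean_epochs": group["epochs_used"].mean(),
        })
    return (
        results.groupby(["grouping", "n_hidden", "error_goal", "outcome"])
        .apply(agg, include_groups=False)
        .reset_index()
    )


def summarize(results: pd.DataFrame, importance: pd.DataFrame | None = None):
    """Summary tables of a completed grid.

    Returns a dict with:

    * ``aggregates`` - mean (SD) fold R / MAE per configuration x outcome;
    * ``best_by_grouping`` - per grouping, the (hidden, goal) combination
      maximizing the mean R averaged over the three outcomes, with its
      per-outcome mean (SD) R;
    * ``epochs_by_hidden`` - median/mean epochs to stop, and how often the
      epoch cap was hit, per hidden size and error goal;
    * ``importance`` - pass-through of an input-importance table, if given.
    """
    if results.empty:
        raise ConfigurationError("empty grid results")
    aggregates = _aggregate(results)

    score = (
        aggregates.groupby(["grouping", "n_hidden", "error_goal"])["mean_r"]
        .mean()
        .reset_index(name="mean_r_over_outcomes")
    )
    best_rows = []
    for grouping, block in score.groupby("grouping"):
        top = block.loc[block["mean_r_over_outcomes"].idxmax()]
        sel = aggregates[
            (aggregates["grouping"] == grouping)
            & (aggregates["n_hidden"] == top["n_hidden"])
            & (aggregates["error_goal"] == top["error_goal"])
        ]
        row = {
            "grouping": grouping,
            "n_hidden": int(top["n_hidden"]),
            "error_goal": float(top["error_goal"]),
            "mean_r_over_outcomes": float(top["mean_r_over_outcomes"]),
        }
        for _, s in sel.iterrows():
            row[f"r_{s['outcome']}"] = s["mean_r"]
            row[f"sd_r_{s['outcome']}"] = s["sd_r"]
            row[f"mae_{s['outcome']}"] = s["mean_mae"]
        best_rows.append(row)
    best = pd.DataFrame(best_rows).sort_values(
        "mean_r_over_outcomes", ascending=False, ignore_index=True
    )

    per_fold = results.drop_duplicates(
        subset=["grouping", "n_hidden", "error_goal", "fold"]
    )
    epochs = (
        per_fold.groupby(["n_hidden", "error_goal"])
        .agg(
            median_epochs=("epochs_used", "median"),
            mean_epochs=("epochs_used", "mean"),
            frac_hit_cap=("stop_reason", lambda s: float((s == "max_epochs").mean())),
        )
        .reset_index()
    )
    out = {"aggregates": aggregates, "best_by_grouping": best,
           "epochs_by_hidden": epochs}
    if importance is not None:
        out["importance"] = importance
    return out
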