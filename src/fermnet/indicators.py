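"""Random-forest indicator-metabolite selection.

A random-forest classifier discriminates sample groups from metabolite
concentrations.  Feature importance is permutation-based mean decrease in
accuracy.  The rfcv-style cross-validation curve refits the forest at each
size k of a halving feature grid, re-ranking features *within each training
fold* (by the fold forest's impurity importance, which avoids selection
bias), and records the 10-fold CV error.  The selected feature-set size is
the smallest k whose mean CV error is within one fold-standard-deviation of
the global minimum (the 1-SE "stabilization" rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .tables_io import MetaboliteTable, SampleMetadata, TableError


@dataclass
class IndicatorResult:
    oob_accuracy: float
    cv_accuracy: float
    importance: pd.Series          # mean decrease in accuracy, descending
    cv_curve: pd.DataFrame         # k, mean_error, sd_error
    selected_k: int
    selected: list                 # top selected_k metabolites by importance
    n_trees: int
    seed: int


def _halving_grid(n_features: int) -> list[int]:
    grid = []
    k = n_features
    while k >= 1:
        grid.append(k)
        if k == 1:
            break
        k = max(1, k // 2)
    return grid


def indicator_select(met: MetaboliteTable, meta: SampleMetadata,
                     group_factor: str | None = None, n_trees: int = 500,
                     seed: int = 0, n_folds: int = 10,
                     n_repeats: int = 10,
                     plateau_tolerance_sd: float = 1.0) -> IndicatorResult:
    """Rank metabolites by RF importance and pick the stabilizing subset.

    ``plateau_tolerance_sd`` scales the 1-SE rule (0 selects the strict
    argmin of the CV error curve).
    """
    meta.require_samples(met.sample_ids)
    col = group_factor or meta.group_col
    y = meta.frame.loc[met.sample_ids, col].astype(str).to_numpy()
    # canonical (sorted) feature order: tree tie-breaks depend on column
    # order, so sorting makes the ranking invariant to input feature order
    features = sorted(met.metabolite_ids)
    X = met.concentrations.loc[features].T.to_numpy(dtype=float)
    n_samples = len(y)
    if n_samples < 10:
        raise TableError("need at least 10 samples")
    if len(set(y)) < 2:
        raise TableError("need at least two group levels")
    min_class = pd.Series(y).value_counts().min()
    if n_folds > min_class:
        warnings.warn(f"reducing folds from {n_folds} to {min_class}")
        n_folds = int(min_class)

    rng = np.random.default_rng(seed)
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=int(rng.integers(2 ** 31)))
    rf.fit(X, y)
    perm = permutation_importance(
        rf, X, y, n_repeats=n_repeats, scoring="accuracy",
        random_state=int(rng.integers(2 ** 31)))
    importance = pd.Series(perm.importances_mean, index=features)
    importance = importance.sort_values(ascending=False, kind="stable")

    grid = _halving_grid(len(features))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    fold_err = np.zeros((n_folds, len(grid)))
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        fold_seed = int(rng.integers(2 ** 31))
        ranker = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=fold_seed)
        ranker.fit(X[tr], y[tr])
        order = np.argsort(-ranker.feature_importances_, kind="stable")
        for gi, k in enumerate(grid):
            cols = order[:k]
            clf = RandomForestClassifier(n_estimators=n_trees,
                                         random_state=fold_seed)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            fold_err[fi, gi] = 1.0 - clf.score(X[np.ix_(te, cols)], y[te])
    mean_err = fold_err.mean(axis=0)
    sd_err = fold_err.std(axis=0, ddof=1)
    se_err = sd_err / np.sqrt(n_folds)
    cv_curve = pd.DataFrame({"k": grid, "mean_error": mean_err,
                             "sd_error": sd_err, "se_error": se_err})

    # canonical 1-SE rule: smallest model within one standard error of the
    # minimum of the CV curve
    i_min = int(np.argmin(mean_err))
    threshold = mean_err[i_min] + plateau_tolerance_sd * se_err[i_min]
    eligible = [(k, e) for k, e in zip(grid, mean_err) if e <= threshold + 1e-12]
    selected_k = min(k for k, _ in eligible)
    cv_accuracy = 1.0 - mean_err[0]  # k = all features

    return IndicatorResult(
        oob_accuracy=float(rf.oob_score_),
        cv_accuracy=float(cv_accuracy),
        importance=importance,
        cv_curve=cv_curve,
        selected_k=int(selected_k),
        selected=importance.index[:selected_k].tolist(),
        n_trees=n_trees,
        seed=seed,
    )
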