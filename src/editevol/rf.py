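"""Random-forest models of editing changes from cis-regulatory features.

Editing presence/absence and editing-level variation between a pair of
species are modelled from the anchor-species editing level, the change
in motif score, and the changes in the 8 dsRNA structural features
(other species minus anchor).  Forests are bagged decision trees with
per-split feature subsampling (mtry), matching the classic
randomForest semantics; accuracy is estimated out-of-bag (OOB), and
feature importance is the OOB permutation importance: the mean
accuracy drop (classification) or MSE increase (regression) across
trees after permuting a feature, divided by its standard deviation
over trees.  The explained variance of a regression forest is
R^2 = 1 - MSE_oob / Var(outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .structure import FEATURE_NAMES

__all__ = [
    "PREDICTOR_COLUMNS",
    "ImportanceReport",
    "assemble_features",
    "fit_presence_model",
    "fit_level_model",
    "compare_models",
    "delta_r2_interval",
]

PREDICTOR_COLUMNS = ["anchor_level", "delta_motif_score"] + [
    f"delta_{name}" for name in FEATURE_NAMES
]


@dataclass
class ImportanceReport:
    kind: str                       # "classification" | "regression"
    score: float                    # OOB accuracy or OOB R^2
    importance: dict[str, float]    # per-feature z-scaled permutation importance
    n_rows: int
    features: list[str] = field(default_factory=list)
    row_index: tuple = ()


def assemble_features(pairs: pd.DataFrame, mode: str,
                      strict_missing: bool = False) -> pd.DataFrame:
    """Build the model matrix from per-site cross-species annotations.

    ``pairs`` carries one row per candidate site with columns:
    site_id, pair_class, anchor_level, other_level, motif_anchor,
    motif_other, ecs_pass_anchor, ecs_pass_other (booleans), and the 8
    structural features per species as ``<name>_anchor`` /
    ``<name>_other`` (NaN when no folded candidate exists at all).

    mode="presence_absence" keeps sites whose ECS passes the stem
    filters in the anchor species (the other species' ECS may or may
    not survive -- that is the phenomenon under study);
    mode="presence_presence" keeps sites passing in at least one
    species.  A species without a passing ECS contributes the features
    of its best folded-but-failing candidate; if it has no candidate at
    all, paired counts and stem length are 0 and free energy 0 -- or,
    with ``strict_missing``, the row is excluded.
    """
    if mode == "presence_absence":
        # anchor-present sites whose other-species status is defined
        # either way: the model predicts presence vs absence there
        eligible = pairs[pairs["ecs_pass_anchor"].astype(bool)]
        eligible = eligible[eligible["pair_class"].isin(
            ["presence_absence", "presence_presence"])]
    elif mode == "presence_presence":
        ok = pairs["ecs_pass_anchor"].astype(bool) | pairs["ecs_pass_other"].astype(bool)
        eligible = pairs[ok]
        eligible = eligible[eligible["pair_class"] == "presence_presence"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for row in eligible.itertuples(index=False):
        rec = {"site_id": row.site_id,
               "anchor_level": row.anchor_level,
               "other_level": row.other_level,
               "delta_motif_score": row.motif_other - row.motif_anchor}
        missing = False
        for name in FEATURE_NAMES:
            a = getattr(row, f"{name}_anchor")
            b = getattr(row, f"{name}_other")
            if np.isnan(a) or np.isnan(b):
                if strict_missing:
                    missing = True
                    break
                a = 0.0 if np.isnan(a) else a
                b = 0.0 if np.isnan(b) else b
            rec[f"delta_{name}"] = b - a
        if missing:
            continue
        rows.append(rec)
    if not rows:
        raise ValueError("no eligible site pairs for this mode")
    return pd.DataFrame(rows)


def _oob_masks(bag, n: int) -> list[np.ndarray]:
    masks = []
    for in_bag in bag.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[in_bag] = False
        masks.append(mask)
    return masks


def _fit_bagged(X: np.ndarray, y: np.ndarray, classification: bool,
                ntree: int, mtry: int, seed):
    if classification:
        base = DecisionTreeClassifier(max_features=mtry)
        bag = BaggingClassifier(estimator=base, n_estimators=ntree,
                                bootstrap=True, random_state=seed, n_jobs=1)
    else:
        base = DecisionTreeRegressor(max_features=mtry)
        bag = BaggingRegressor(estimator=base, n_estimators=ntree,
                               bootstrap=True, random_state=seed, n_jobs=1)
    bag.fit(X, y)
    return bag


def _oob_score_and_importance(bag, X, y, classification, feature_names, rng,
                              compute_importance: bool = True):
    n, p = X.shape
    masks = _oob_masks(bag, n)
    # aggregated OOB prediction
    if classification:
        classes = bag.classes_
        votes = np.zeros((n, classes.size))
        for tree, mask in zip(bag.estimators_, masks):
            if mask.any():
                pred = tree.predict(X[mask])
                for ci, c in enumerate(classes):
                    votes[mask, ci] += pred == c
        covered = votes.sum(axis=1) > 0
        oob_pred = classes[np.argmax(votes, axis=1)]
        score = float((oob_pred[covered] == y[covered]).mean())
    else:
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, mask in zip(bag.estimators_, masks):
            if mask.any():
                sums[mask] += tree.predict(X[mask])
                counts[mask] += 1
        covered = counts > 0
        oob_pred = sums[covered] / counts[covered]
        mse = float(np.mean((oob_pred - y[covered]) ** 2))
        var = float(np.var(y[covered]))
        score = 1.0 - mse / var if var > 0 else float("nan")

    if not compute_importance:
        return score, {}

    # per-tree permutation importance
    drops = np.zeros((len(bag.estimators_), p))
    for t, (tree, mask) in enumerate(zip(bag.estimators_, masks)):
        if not mask.any():
            continue
        Xo, yo = X[mask], y[mask]
        base_pred = tree.predict(Xo)
        if classification:
            base_err = np.mean(base_pred != yo)
        else:
            base_err = np.mean((base_pred - yo) ** 2)
        for f in range(p):
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(Xo.shape[0]), f]
            pred = tree.predict(Xp)
            if classification:
                err = np.mean(pred != yo)
            else:
                err = np.mean((pred - yo) ** 2)
            drops[t, f] = err - base_err
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    importance = dict(zip(feature_names, z))
    return score, importance


def fit_presence_model(rows: pd.DataFrame, ntree: int = 1000, mtry: int = 3,
                       presence_level: float = 0.10,
                       absence_level: float = 0.015,
                       seed: int = 0) -> ImportanceReport:
    """Classify whether the other species is edited from feature changes.

    The outcome is edited (>= 10%) vs unedited (<= 1.5%) in the other
    species; intermediate rows are excluded.  Requires both classes.
    """
    edited = rows["other_level"] >= presence_level
    unedited = rows["other_level"] <= absence_level
    use = rows[edited | unedited]
    y = (use["other_level"] >= presence_level).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("presence model needs both outcome classes")
    X = use[PREDICTOR_COLUMNS].to_numpy(dtype=float)
    bag = _fit_bagged(X, y, True, ntree, mtry, seed)
    rng = np.random.default_rng(seed)
    score, imp = _oob_score_and_importance(bag, X, y, True, PREDICTOR_COLUMNS, rng)
    return ImportanceReport("classification", score, imp, len(use),
                            PREDICTOR_COLUMNS, tuple(use.index))


def fit_level_model(rows: pd.DataFrame, with_cis_features: bool = True,
                    ntree: int = 1000, mtry: int = 3,
                    seed: int = 0, compute_importance: bool = True) -> ImportanceReport:
    """Predict the other species' editing level.

    The full model uses all predictors (mtry features per split); the
    reduced model uses the anchor level alone (mtry = 1) and measures
    how much variation the anchor level explains by itself.
    """
    y = rows["other_level"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("zero outcome variance; R^2 undefined")
    if with_cis_features:
        features = PREDICTOR_COLUMNS
    else:
        features = ["anchor_level"]
        mtry = 1
    X = rows[features].to_numpy(dtype=float)
    bag = _fit_bagged(X, y, False, ntree, min(mtry, len(features)), seed)
    rng = np.random.default_rng(seed)
    score, imp = _oob_score_and_importance(bag, X, y, False, features, rng,
                                           compute_importance)
    return ImportanceReport("regression", score, imp, len(rows), list(features),
                            tuple(rows.index))


def compare_models(full: ImportanceReport, reduced: ImportanceReport) -> float:
    """Delta R^2 between a full and a reduced model fit on the same rows."""
    if full.row_index != reduced.row_index:
        raise ValueError("models were fit on different row sets")
    return full.score - reduced.score


def delta_r2_interval(rows: pd.DataFrame, n_refits: int = 20, ntree: int = 1000,
                      mtry: int = 3, seed: int = 0):
    """Seed-resampling interval for the full-vs-reduced delta R^2.

    Refits both models ``n_refits`` times with different forest seeds
    and returns (mean delta, (min, max), per-seed deltas).
    """
    ss = np.random.SeedSequence(seed)
    deltas = []
    for child in ss.spawn(n_refits):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        full = fit_level_model(rows, True, ntree, mtry, seed=s,
                               compute_importance=False)
        reduced = fit_level_model(rows, False, ntree, mtry, seed=s,
                                  compute_importance=False)
        deltas.append(compare_models(full, reduced))
    deltas = np.array(deltas)
    return float(deltas.mean()), (float(deltas.min()), float(deltas.max())), deltas
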