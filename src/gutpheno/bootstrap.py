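"""Bootstrap forest engine: repeated half-split rounds with importance recording.

Each round splits the disease-vs-control subset in stratified halves, fits a
random forest (Gini criterion) on the training half of one candidate block
(taxa, quantitative, qualitative, or all three integrated), records the
unnormalized mean-decrease-Gini importance and the mean absolute SHAP value
of every feature, the ten most important features, and the test-half
ROC/AUC.  Across ``n_rounds`` rounds the engine accumulates how often each
feature entered the top ten — the importance-frequency matrix from which
final model variables are chosen.

Qualitative variables are one-hot encoded for fitting; their importances
(Gini and SHAP alike) are summed back to the parent variable so frequency
counting happens at the variable level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .preselect import CandidateSet, split_phenotype_columns
from .shapley import forest_shap

__all__ = [
    "ForestConfig",
    "SplitPlan",
    "RoundResult",
    "FittedForest",
    "half_split",
    "build_design",
    "fit_forest",
    "gini_importance",
    "shap_importance",
    "gini_shap_correlation",
    "top_k",
    "run_bootstrap_rounds",
]

BLOCKS = ("taxa", "quantitative", "qualitative", "integrated")


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest and resampling configuration.

    ``cv_repeats`` x ``cv_folds`` repeated stratified cross-validation on the
    training half is used solely to pick mtry (max_features) from a small
    grid around sqrt(p); it never touches the test half.  ``compute_shap``
    can be switched off when only Gini importances are needed.
    """

    n_trees: int = 100
    cv_repeats: int = 20
    cv_folds: int = 5
    threshold: float = 0.5
    tune_mtry: bool = True
    compute_shap: bool = True

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class SplitPlan:
    """One stratified half-split: per-class halves, extras go to training."""

    round_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


def half_split(labels: pd.Series, seed: int, round_index: int = 0) -> SplitPlan:
    """Random per-class half split (ceil half to training on odd counts)."""
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        ids = np.asarray(labels.index[labels == cls])
        if ids.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(ids)
        n_train = (ids.size + 1) // 2
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return SplitPlan(round_index=round_index, train_ids=tuple(train),
                     test_ids=tuple(test), seed=seed)


@dataclass
class DesignMatrix:
    """Model matrix with one-hot bookkeeping.

    ``column_parent`` maps every model-matrix column to the variable it
    represents (identity for numeric columns, parent name for one-hot
    levels).
    """

    X: pd.DataFrame
    column_parent: dict[str, str]
    features: list[str]  # variable-level feature names, ordered


def build_design(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    features_taxa: list[str],
    features_quant: list[str],
    features_qual: list[str],
) -> DesignMatrix:
    """Assemble the model matrix: taxa as relative abundances, one-hot categoricals."""
    parts: list[pd.DataFrame] = []
    column_parent: dict[str, str] = {}
    if features_taxa:
        totals = counts.sum(axis=1).replace(0, 1)
        rel = counts[features_taxa].div(totals, axis=0)
        parts.append(rel)
        column_parent.update({t: t for t in features_taxa})
    if features_quant:
        q = phenotypes[features_quant].astype(float)
        parts.append(q)
        column_parent.update({c: c for c in features_quant})
    for col in features_qual:
        onehot = pd.get_dummies(phenotypes[col], prefix=col, prefix_sep="=",
                                dtype=float)
        parts.append(onehot)
        column_parent.update({c: col for c in onehot.columns})
    if not parts:
        raise ValueError("no features supplied")
    X = pd.concat(parts, axis=1)
    features = list(features_taxa) + list(features_quant) + list(features_qual)
    return DesignMatrix(X=X, column_parent=column_parent, features=features)


def _impute(train: pd.DataFrame, other: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute from the training half only (one-hot columns included)."""
    med = train.median(axis=0)
    return train.fillna(med), other.fillna(med)


@dataclass
class FittedForest:
    """A fitted forest plus the design bookkeeping needed for importances."""

    model: RandomForestClassifier
    design: DesignMatrix
    mtry: int
    classes_: np.ndarray = field(init=False)

    def __post_init__(self):
        self.classes_ = self.model.classes_

    def predict_case_probability(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(X.to_numpy(dtype=float))[:, 1]


def _mtry_grid(p: int) -> list[int]:
    root = max(1, round(np.sqrt(p)))
    grid = sorted({max(1, root // 2), root, min(p, 2 * root)})
    return grid


def fit_forest(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    design: DesignMatrix,
    config: ForestConfig,
    seed: int,
) -> FittedForest:
    """Fit a Gini random forest, tuning mtry by repeated stratified CV.

    ``y_train`` must be 0/1 with the case class coded 1.
    """
    y = np.asarray(y_train)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    p = X_train.shape[1]
    grid = _mtry_grid(p)
    Xa = X_train.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = grid[len(grid) // 2]
    if config.tune_mtry and len(grid) > 1:
        min_class = int(np.bincount(y).min())
        folds = min(config.cv_folds, min_class)
        if folds >= 2:
            cv = RepeatedStratifiedKFold(
                n_splits=folds, n_repeats=config.cv_repeats,
                random_state=int(rng.integers(2**31)),
            )
            scores = {m: [] for m in grid}
            split_list = list(cv.split(Xa, y))
            for m in grid:
                for tr, va in split_list:
                    if np.unique(y[tr]).size < 2:
                        continue
                    rf = RandomForestClassifier(
                        n_estimators=config.n_trees, criterion="gini",
                        max_features=m,
                        random_state=int(rng.integers(2**31)),
                    ).fit(Xa[tr], y[tr])
                    prob = rf.predict_proba(Xa[va])[:, 1]
                    if np.unique(y[va]).size == 2:
                        scores[m].append(roc_auc_score(y[va], prob))
            means = {m: (np.mean(s) if s else -np.inf) for m, s in scores.items()}
            best = max(grid, key=lambda m: (means[m], -m))
    model = RandomForestClassifier(
        n_estimators=config.n_trees, criterion="gini", max_features=best,
        random_state=int(rng.integers(2**31)),
    ).fit(Xa, y)
    return FittedForest(model=model, design=design, mtry=best)


def _aggregate_to_parent(values: pd.Series, design: DesignMatrix) -> pd.Series:
    out = {f: 0.0 for f in design.features}
    for col, v in values.items():
        out[design.column_parent[col]] += float(v)
    return pd.Series(out, name=values.name)


def gini_importance(fitted: FittedForest) -> pd.Series:
    """Unnormalized mean decrease in Gini impurity per variable.

    Per tree, each internal node contributes its cover-weighted impurity
    decrease to the split feature; tree totals are averaged over the forest
    and one-hot columns summed back to their parent variable.
    """
    cols = list(fitted.design.X.columns)
    acc = np.zeros(len(cols))
    for est in fitted.model.estimators_:
        acc += est.tree_.compute_feature_importances(normalize=False)
    per_column = pd.Series(acc / len(fitted.model.estimators_), index=cols,
                           name="gini")
    return _aggregate_to_parent(per_column, fitted.design)


def shap_importance(fitted: FittedForest, X: pd.DataFrame) -> pd.Series:
    """Mean absolute SHAP value per variable over the given samples."""
    phi, _ = forest_shap(fitted.model, X.to_numpy(dtype=float))
    per_column = pd.Series(np.abs(phi).mean(axis=0), index=list(X.columns),
                           name="mean_abs_shap")
    return _aggregate_to_parent(per_column, fitted.design)


def top_k(importances: pd.Series, k: int = 10) -> list[str]:
    """The k largest-importance feature names; ties broken by ascending name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


@dataclass
class RoundResult:
    """Everything recorded for one bootstrap round of one block."""

    round_index: int
    block: str
    gini: pd.Series
    shap: pd.Series | None
    top10: list[str]
    auc: float  # percent
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    test_scores: pd.Series
    mtry: int


def _round_metrics(scores: np.ndarray, y: np.ndarray, threshold: float):
    from .evaluate import auc as auc_fn, confusion_metrics

    a = auc_fn(scores, y)
    cm = confusion_metrics(scores, y, threshold=threshold)
    return a, cm


def run_bootstrap_rounds(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: pd.Series,
    candidates: CandidateSet,
    block: str,
    control: str = "CT",
    n_rounds: int = 50,
    config: ForestConfig = ForestConfig(),
    seed: int = 0,
) -> tuple[list[RoundResult], pd.Series]:
    """Run the bootstrap rounds for one disease and candidate block.

    Returns the per-round results and the importance-frequency Series
    (variable -> number of rounds in which it entered the top ten).
    Deterministic given (data, candidates, config, seed).
    """
    if block not in BLOCKS:
        raise ValueError(f"block must be one of {BLOCKS}")
    taxa = candidates.taxa if block in ("taxa", "integrated") else []
    quant = candidates.quantitative if block in ("quantitative", "integrated") else []
    qual = candidates.qualitative if block in ("qualitative", "integrated") else []
    if not (taxa or quant or qual):
        raise ValueError(
            f"candidate block {block!r} is empty for disease "
            f"{candidates.disease!r}; rerun preselection or choose another block"
        )
    disease = candidates.disease
    subset = labels[labels.isin([control, disease])]
    design = build_design(counts.loc[subset.index], phenotypes.loc[subset.index],
                          taxa, quant, qual)
    y_all = (subset == disease).astype(int)

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_rounds) % (2**31)
    results: list[RoundResult] = []
    freq = pd.Series(0, index=design.features, dtype=int, name=disease)
    for r in range(n_rounds):
        plan = half_split(subset, seed=int(child_seeds[2 * r]), round_index=r)
        X_train = design.X.loc[list(plan.train_ids)]
        X_test = design.X.loc[list(plan.test_ids)]
        X_train, X_test = _impute(X_train, X_test)
        y_train = y_all.loc[list(plan.train_ids)].to_numpy()
        y_test = y_all.loc[list(plan.test_ids)].to_numpy()
        fitted = fit_forest(X_train, y_train, design, config,
                            seed=int(child_seeds[2 * r + 1]))
        gini = gini_importance(fitted)
        shap = shap_importance(fitted, X_test) if config.compute_shap else None
        top = top_k(gini, 10)
        scores = fitted.predict_case_probability(X_test)
        a, cm = _round_metrics(scores, y_test, config.threshold)
        freq.loc[top] += 1
        results.append(
            RoundResult(
                round_index=r, block=block, gini=gini, shap=shap, top10=top,
                auc=a, sensitivity=cm["sensitivity"],
                specificity=cm["specificity"], precision=cm["precision"],
                recall=cm["recall"],
                test_scores=pd.Series(scores, index=list(plan.test_ids)),
                mtry=fitted.mtry,
            )
        )
    return results, freq


def gini_shap_correlation(rounds: list[RoundResult]) -> dict[str, object]:
    """Pearson correlation of Gini vs mean-|SHAP| trajectories across rounds.

    Returns ``{"same": Series feature -> rho, "null": ndarray}`` where the
    null holds correlations of mismatched feature pairs (feature i's Gini
    against feature j's SHAP, i != j).  Zero-variance trajectories yield NaN.
    """
    if len(rounds) < 3:
        raise ValueError("need at least 3 rounds to correlate trajectories")
    if any(r.shap is None for r in rounds):
        raise ValueError("rounds lack SHAP values; rerun with compute_shap=True")
    features = list(rounds[0].gini.index)
    g = np.array([[r.gini[f] for r in rounds] for f in features])
    s = np.array([[r.shap[f] for r in rounds] for f in features])

    def rho(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    same = pd.Series({f: rho(g[i], s[i]) for i, f in enumerate(features)},
                     name="rho")
    null = np.array([
        rho(g[i], s[j])
        for i in range(len(features))
        for j in range(len(features))
        if i != j
    ])
    return {"same": same, "null": null[~np.isnan(null)] if null.size else null}
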