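"""Final variable selection, consensus models, and ROC/AUC reporting.

A variable survives to the final model when it entered the bootstrap top ten
in at least ``threshold`` of the rounds (default 25 of 50) for at least one
disease.  The consensus model refits a forest on the final variables across
seeded half-split resamples; each sample's consensus score is its mean
predicted case-probability over the resamples in which it sat in the test
half, so every score is out-of-sample.  AUCs are reported on the percent
scale and banded qualitatively (weak / regular / good / excellent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bootstrap import ForestConfig, build_design, fit_forest, half_split, _impute
from .preselect import CandidateSet

__all__ = [
    "FinalVariableSet",
    "ModelPerformance",
    "select_final_variables",
    "consensus_fit_predict",
    "roc_curve",
    "auc",
    "confusion_metrics",
    "discrimination_band",
    "build_comparison_report",
    "evaluate_scores",
]

BANDS = ((0.0, 60.0, "weak"), (60.0, 70.0, "regular"),
         (70.0, 80.0, "good"), (80.0, 100.0 + 1e-12, "excellent"))


@dataclass
class FinalVariableSet:
    """Variables passing the frequency rule, with per-disease counts and blocks."""

    variables: list[str]
    counts: pd.DataFrame  # feature x disease frequency matrix (selected rows)
    blocks: dict[str, str]  # variable -> taxa | quantitative | qualitative
    threshold: int

    def for_disease(self, disease: str) -> list[str]:
        return list(self.variables)

    def split_blocks(self) -> tuple[list[str], list[str], list[str]]:
        taxa = [v for v in self.variables if self.blocks.get(v) == "taxa"]
        quant = [v for v in self.variables if self.blocks.get(v) == "quantitative"]
        qual = [v for v in self.variables if self.blocks.get(v) == "qualitative"]
        return taxa, quant, qual


def select_final_variables(
    freq: pd.DataFrame,
    blocks: dict[str, str],
    threshold: int = 25,
    n_rounds: int = 50,
) -> FinalVariableSet:
    """Keep every feature whose top-ten count reaches ``threshold`` for any disease.

    The rule is inclusive: a count exactly equal to the threshold selects the
    feature ("at least half").
    """
    if threshold > n_rounds:
        raise ValueError("threshold cannot exceed the number of rounds")
    if (freq.to_numpy() > n_rounds).any() or (freq.to_numpy() < 0).any():
        raise ValueError("frequency counts must lie in [0, n_rounds]")
    keep = freq.max(axis=1) >= threshold
    selected = sorted(freq.index[keep])
    return FinalVariableSet(
        variables=selected,
        counts=freq.loc[selected].copy(),
        blocks={v: blocks[v] for v in selected},
        threshold=threshold,
    )


def consensus_fit_predict(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: pd.Series,
    variables: FinalVariableSet | CandidateSet,
    disease: str,
    control: str = "CT",
    n_resamples: int = 50,
    config: ForestConfig = ForestConfig(),
    seed: int = 0,
    max_extra: int = 20,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Consensus out-of-sample case scores for one disease-vs-control contrast.

    Fits a forest per half-split resample on the final variables; a sample's
    score is the mean predicted case-probability over resamples where it was
    held out.  If any sample is never held out after ``n_resamples`` draws,
    additional resamples are drawn (up to ``max_extra``).  Returns
    (scores, 0/1 labels, consensus mean Gini importance).
    """
    if isinstance(variables, FinalVariableSet):
        taxa, quant, qual = variables.split_blocks()
    else:
        taxa, quant, qual = (list(variables.taxa), list(variables.quantitative),
                             list(variables.qualitative))
    if not (taxa or quant or qual):
        raise ValueError(f"no final variables for disease {disease!r}")
    subset = labels[labels.isin([control, disease])]
    design = build_design(counts.loc[subset.index], phenotypes.loc[subset.index],
                          taxa, quant, qual)
    y_all = (subset == disease).astype(int)

    score_sum = pd.Series(0.0, index=subset.index)
    score_n = pd.Series(0, index=subset.index)
    gini_acc = pd.Series(0.0, index=design.features)
    seeds = np.random.SeedSequence(seed).generate_state(
        2 * (n_resamples + max_extra)) % (2**31)

    def one_resample(r: int) -> None:
        nonlocal gini_acc
        plan = half_split(subset, seed=int(seeds[2 * r]), round_index=r)
        X_train = design.X.loc[list(plan.train_ids)]
        X_test = design.X.loc[list(plan.test_ids)]
        X_train, X_test = _impute(X_train, X_test)
        fitted = fit_forest(X_train, y_all.loc[list(plan.train_ids)].to_numpy(),
                            design, config, seed=int(seeds[2 * r + 1]))
        from .bootstrap import gini_importance

        gini_acc = gini_acc + gini_importance(fitted)
        prob = fitted.predict_case_probability(X_test)
        score_sum.loc[list(plan.test_ids)] += prob
        score_n.loc[list(plan.test_ids)] += 1

    done = 0
    for r in range(n_resamples):
        one_resample(r)
        done += 1
    extra = 0
    while (score_n == 0).any() and extra < max_extra:
        one_resample(n_resamples + extra)
        extra += 1
        done += 1
    if (score_n == 0).any():
        missing = list(score_n.index[score_n == 0])
        raise RuntimeError(f"samples never held out: {missing}")
    scores = score_sum / score_n
    scores.name = "consensus_score"
    return scores, y_all, gini_acc / done


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr, thresholds) from a descending threshold sweep."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, thr


def auc(scores, labels) -> float:
    """Trapezoidal AUC of the ROC curve, on the percent scale [0, 100]."""
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr) * 100.0)


def concordance_auc(scores, labels) -> float:
    """Pairwise-concordance AUC (ties count half), percent scale.

    Independent of the trapezoid route; the two agree to numerical precision.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (pos.size * neg.size) * 100.0)


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity/specificity/precision/recall at a probability threshold.

    Ratios with a zero denominator are reported as NaN, not zero.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = ratio(tp, tp + fn)
    return {
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "recall": sens,
    }


def discrimination_band(auc_percent: float) -> str:
    """Qualitative discrimination label for an AUC on the percent scale.

    [0, 60) weak; [60, 70) regular; [70, 80) good; [80, 100] excellent.
    """
    if not 0 <= auc_percent <= 100:
        raise ValueError("AUC percent must lie in [0, 100]")
    for lo, hi, name in BANDS:
        if lo <= auc_percent < hi:
            return name
    return "excellent"


@dataclass
class ModelPerformance:
    """ROC points plus summary metrics for one model."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float  # percent
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    band: str = field(init=False)

    def __post_init__(self):
        self.band = discrimination_band(self.auc)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "band": self.band,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "roc": {"fpr": self.fpr.tolist(), "tpr": self.tpr.tolist()},
        }


def evaluate_scores(scores, labels, threshold: float = 0.5) -> ModelPerformance:
    fpr, tpr, thr = roc_curve(scores, labels)
    cm = confusion_metrics(scores, labels, threshold=threshold)
    return ModelPerformance(fpr=fpr, tpr=tpr, thresholds=thr,
                            auc=auc(scores, labels), **cm)


BLOCK_TAGS = {"taxa": "bt", "quantitative": "ni", "qualitative": "cc"}


def build_comparison_report(
    isolated: dict[str, ModelPerformance],
    integrated: dict[str, ModelPerformance],
    top_variables: dict[str, list[tuple[str, str]]],
) -> dict:
    """Per-disease comparison of isolated-taxa vs integrated model performance.

    ``top_variables`` maps disease -> ordered (variable, block) pairs for the
    integrated model (by consensus mean Gini), truncated to ten.  The report
    serializes losslessly to JSON.
    """
    if set(isolated) != set(integrated):
        raise ValueError(
            "isolated and integrated results must cover the same diseases: "
            f"{sorted(set(isolated) ^ set(integrated))} mismatch"
        )
    rows = {}
    for disease in sorted(isolated):
        top = [
            {"variable": v, "block": b, "tag": BLOCK_TAGS.get(b, b)}
            for v, b in top_variables.get(disease, [])[:10]
        ]
        rows[disease] = {
            "isolated_auc": isolated[disease].auc,
            "isolated_band": isolated[disease].band,
            "integrated_auc": integrated[disease].auc,
            "integrated_band": integrated[disease].band,
            "top_variables": top,
        }
    return {"diseases": rows}


def report_to_table(report: dict) -> pd.DataFrame:
    rows = []
    for disease, r in report["diseases"].items():
        rows.append({
            "disease": disease,
            "isolated_auc": r["isolated_auc"],
            "isolated_band": r["isolated_band"],
            "integrated_auc": r["integrated_auc"],
            "integrated_band": r["integrated_band"],
            "top_variables": "; ".join(
                f"{i + 1} {v['variable']} ({v['tag']})"
                for i, v in enumerate(r["top_variables"])
            ),
        })
    return pd.DataFrame(rows).set_index("disease")


def report_round_trip(report: dict) -> dict:
    return json.loads(json.dumps(report))
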