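"""Subtype–stage association and subtype/stage prediction.

Covers the downstream epidemiological checks: a chi-square test of the
stage distribution across subtypes, leave-one-out random-forest prediction
of subtype (AUROC) and stage (accuracy), top-k feature selection by
impurity importance, the alternative-classifier benchmark, and the
alpha-diversity comparison between subtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core_io import ClinicalTable, OmicsMatrix
from .subtyping import SubtypeAssignment

logger = logging.getLogger(__name__)

MODEL_SPECS = ("random_forest", "knn", "svm", "logistic")

FEATURE_SETS = (
    "micro_all",
    "micro_top20",
    "expr_all",
    "expr_top20",
    "both_all",
    "both_top40",
)


@dataclass
class PredictionReport:
    """Out-of-fold (leave-one-out) prediction summary."""

    feature_set: str
    metric: str  # "AUROC" or "accuracy"
    value: float
    scores: np.ndarray  # per-sample out-of-fold scores / predicted labels
    majority_share: float = float("nan")
    extra: dict = field(default_factory=dict)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, (OmicsMatrix,)) or hasattr(features, "values"):
        return np.asarray(features.values, dtype=float)
    return np.asarray(features, dtype=float)


def stage_chi_square(
    assignment: SubtypeAssignment, clinical: ClinicalTable
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square test of the subtype × stage contingency table.

    Samples with stage NA are excluded.  Returns (statistic, p, table); a
    warning is logged when any expected count is below 5.
    """
    if assignment.sample_ids != clinical.sample_ids:
        raise ValueError("assignment and clinical table must be sample-aligned")
    stage = np.asarray(clinical.stage)
    labels = np.asarray(assignment.labels)
    known = stage != "NA"
    stage, labels = stage[known], labels[known]
    if len(set(stage)) < 2:
        raise ValueError("all staged samples share one stage; test undefined")
    table = pd.crosstab(
        pd.Series(labels, name="subtype"), pd.Series(stage, name="stage")
    )
    statistic, p, _, expected = stats.chi2_contingency(
        table.to_numpy(), correction=False
    )
    if (expected < 5).any():
        logger.warning(
            "stage_chi_square: %d expected cell count(s) below 5",
            int((expected < 5).sum()),
        )
    return float(statistic), float(p), table


def _make_model(model_spec: str, seed: int, n_estimators: int):
    if model_spec == "random_forest":
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(seed),
            n_jobs=1,
        )
    if model_spec == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if model_spec == "svm":
        return SVC(kernel="rbf", random_state=int(seed))
    if model_spec == "logistic":
        return LogisticRegression(max_iter=2000, random_state=int(seed))
    raise ValueError(f"unknown model_spec {model_spec!r}; choose from {MODEL_SPECS}")


def _oof_scores(
    X: np.ndarray, y: np.ndarray, model_spec: str, seed: int, n_estimators: int
) -> np.ndarray:
    """Leave-one-out out-of-fold continuous scores for the positive class."""
    n = len(y)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = _make_model(model_spec, seed, n_estimators)
        model.fit(X[mask], y[mask])
        if hasattr(model, "predict_proba"):
            prob = model.predict_proba(X[i : i + 1])
            pos = list(model.classes_).index(1)
            scores[i] = prob[0, pos]
        else:
            scores[i] = float(model.decision_function(X[i : i + 1])[0])
        mask[i] = True
    return scores


def loo_predict(
    features,
    labels: Sequence[int],
    model_spec: str = "random_forest",
    seed: int = 0,
    n_estimators: int = 500,
    feature_set: str = "both_all",
) -> PredictionReport:
    """Leave-one-out AUROC for a binary label.

    Each sample is scored by a model trained on the other n−1 samples; the
    AUROC is computed strictly from those held-out scores.  Deterministic
    given the seed.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(y) != X.shape[0]:
        raise ValueError("labels must match feature rows")
    if len(y) < 10:
        raise ValueError("need at least 10 samples for leave-one-out")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    scores = _oof_scores(X, y, model_spec, seed, n_estimators)
    auroc = float(roc_auc_score(y, scores))
    return PredictionReport(
        feature_set=feature_set,
        metric="AUROC",
        value=auroc,
        scores=scores,
        majority_share=float(counts.max() / counts.sum()),
        extra={"model": model_spec},
    )


def top_k_features(
    features,
    labels: Sequence[int],
    k: int = 20,
    seed: int = 0,
    n_estimators: int = 500,
    feature_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Rank features by random-forest impurity importance; return the top k.

    The forest is fit once on the full data; ranking ties keep the original
    column order (stable sort), so identical calls are identical.
    """
    X = _as_matrix(features)
    if feature_ids is None:
        feature_ids = list(getattr(features, "feature_ids"))
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds n_features={X.shape[1]}")
    y = np.asarray(labels, dtype=int)
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, y)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return [feature_ids[j] for j in order[:k]]


def stage_prediction(
    features,
    stages: Sequence[str],
    mode: str = "all_stages",
    seed: int = 0,
    n_estimators: int = 500,
    min_stage14_fraction: float = 0.3,
    min_samples: int = 10,
    feature_set: str = "both_top40",
) -> PredictionReport:
    """Leave-one-out random-forest stage prediction (accuracy).

    ``all_stages`` predicts the full multi-class stage; ``stage1_vs_4``
    restricts to stages I and IV and is only allowed when those stages make
    up at least ``min_stage14_fraction`` of the staged samples.  Cohorts
    smaller than ``min_samples`` (after restriction) are refused.  The
    majority-class share is reported alongside so that accuracy inflated by
    class imbalance is visible.
    """
    X = _as_matrix(features)
    stage = np.asarray([str(s) for s in stages])
    known = stage != "NA"
    X, stage = X[known], stage[known]
    if mode == "stage1_vs_4":
        frac = float(np.isin(stage, ["I", "IV"]).mean())
        if frac < min_stage14_fraction:
            raise ValueError(
                f"stage I+IV proportion {frac:.3f} below the "
                f"{min_stage14_fraction:.0%} eligibility threshold"
            )
        keep = np.isin(stage, ["I", "IV"])
        X, stage = X[keep], stage[keep]
    elif mode != "all_stages":
        raise ValueError(f"unknown mode {mode!r}")
    if len(set(stage)) < 2:
        raise ValueError("need at least two stages present")
    n = len(stage)
    if n < min_samples:
        raise ValueError(f"cohort too small: {n} staged samples < {min_samples}")
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(seed),
            n_jobs=1,
        )
        rf.fit(X[mask], stage[mask])
        preds[i] = rf.predict(X[i : i + 1])[0]
        mask[i] = True
    accuracy = float(np.mean(preds == stage))
    _, counts = np.unique(stage, return_counts=True)
    return PredictionReport(
        feature_set=feature_set,
        metric="accuracy",
        value=accuracy,
        scores=preds,
        majority_share=float(counts.max() / counts.sum()),
        extra={"mode": mode, "n_used": n},
    )


def shannon_diversity(microbiome: OmicsMatrix) -> np.ndarray:
    """Per-sample Shannon index H = −Σ pᵢ ln pᵢ on relative abundances."""
    if microbiome.state != "normalized":
        raise ValueError("shannon_diversity expects normalized proportions")
    P = microbiome.values
    if (P < 0).any():
        raise ValueError("negative proportions")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


def compare_diversity(
    assignment: SubtypeAssignment, diversity: np.ndarray
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of alpha diversity across subtypes.

    For two subtypes this is the Mann-Whitney U test (asymptotic, no
    continuity correction, so identical groups give p = 1 exactly); for more
    than two groups the Kruskal-Wallis test is used and the H statistic is
    returned in place of U.
    """
    diversity = np.asarray(diversity, dtype=float)
    if len(diversity) != len(assignment.sample_ids):
        raise ValueError("diversity must match assignment samples")
    groups = [
        diversity[idx] for _, idx in sorted(assignment.groups().items())
    ]
    if len(groups) == 2:
        if np.ptp(np.concatenate(groups)) == 0:
            return float(len(groups[0]) * len(groups[1]) / 2.0), 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                groups[0],
                groups[1],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=False,
            )
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def subtype_prediction_reports(
    expr: OmicsMatrix,
    micro: OmicsMatrix,
    assignment: SubtypeAssignment,
    seed: int = 0,
    k: int = 20,
    n_estimators: int = 500,
) -> dict[str, PredictionReport]:
    """The six feature-set reports for binary subtype prediction.

    The ``both_top40`` set is the union of the per-omic top-20 lists; a
    binary label requires K = 2 (the first subtype vs the rest is refused to
    keep the metric interpretable).
    """
    if assignment.K != 2:
        raise ValueError("subtype prediction reports require K = 2")
    y = (np.asarray(assignment.labels) == "ASD-2").astype(int)

    def run(X, fid, name):
        return loo_predict(
            X, y, "random_forest", seed=seed, n_estimators=n_estimators,
            feature_set=name,
        )

    reports: dict[str, PredictionReport] = {}
    e, m = expr.values, micro.values
    reports["expr_all"] = run(e, expr.feature_ids, "expr_all")
    reports["micro_all"] = run(m, micro.feature_ids, "micro_all")
    top_e = top_k_features(
        e, y, k=k, seed=seed, n_estimators=n_estimators, feature_ids=expr.feature_ids
    )
    top_m = top_k_features(
        m, y, k=k, seed=seed, n_estimators=n_estimators, feature_ids=micro.feature_ids
    )
    e_pos = {f: j for j, f in enumerate(expr.feature_ids)}
    m_pos = {f: j for j, f in enumerate(micro.feature_ids)}
    reports["expr_top20"] = run(e[:, [e_pos[f] for f in top_e]], top_e, "expr_top20")
    reports["micro_top20"] = run(m[:, [m_pos[f] for f in top_m]], top_m, "micro_top20")
    reports["both_all"] = run(
        np.hstack([e, m]), list(expr.feature_ids) + list(micro.feature_ids), "both_all"
    )
    both40 = np.hstack(
        [e[:, [e_pos[f] for f in top_e]], m[:, [m_pos[f] for f in top_m]]]
    )
    reports["both_top40"] = run(both40, top_e + top_m, "both_top40")
    for name in ("expr_top20", "micro_top20", "both_top40"):
        reports[name].extra["features"] = {
            "expr_top20": top_e,
            "micro_top20": top_m,
            "both_top40": top_e + top_m,
        }[name]
    return reports
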