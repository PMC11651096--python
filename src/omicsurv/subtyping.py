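"""Survival subtyping: Cox screening of latent features, GMM clustering with
silhouette-guided choice of K, prognosis-ordered labels, and survival
evaluation (Kaplan-Meier curves, log-rank test, concordance index).

The subtyping logic mirrors the intended analysis: every pooled latent
feature is tested univariately against survival (Wald p < alpha keeps it);
the selected features are clustered with Gaussian mixtures for K = 2..5 and
the K with the highest silhouette wins; clusters are then renamed so that
ASD-1 always denotes the best-prognosis subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index, restricted_mean_survival_time
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from ._cox import univariate_cox
from .ae_ensemble import LatentMatrix
from .core_io import OmicsMatrix, SurvivalTable

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 3, 4, 5)

FLAG_OK = "ok"
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_NOT_CONVERGED = "not_converged"
FLAG_BOUNDARY = "boundary"


@dataclass
class ScreenResult:
    """Univariate Cox screen over latent features."""

    feature_ids: list[str]
    coefficient: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray
    flag: list[str]
    omic_of_origin: list[str]
    alpha: float

    @property
    def selected_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "omic": self.omic_of_origin,
                "coefficient": self.coefficient,
                "p_value": self.p_value,
                "selected": self.selected,
                "flag": self.flag,
            }
        )


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels, named ASD-1 … ASD-K.

    After :func:`order_labels_by_prognosis`, ASD-1 is the subtype with the
    best prognosis (largest median Kaplan-Meier survival).
    """

    sample_ids: list[str]
    labels: list[str]
    K: int
    silhouette: float
    gmm_params: dict = field(default_factory=dict)
    candidate_scores: dict = field(default_factory=dict)
    prognosis_ordered: bool = False

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must cover every sample")

    def numeric_labels(self) -> np.ndarray:
        return np.array([int(l.split("-")[1]) for l in self.labels])

    def groups(self) -> dict[str, np.ndarray]:
        lab = np.asarray(self.labels)
        return {g: np.flatnonzero(lab == g) for g in sorted(set(self.labels))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": self.labels,
                "K": self.K,
                "silhouette": self.silhouette,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


@dataclass
class SubtypeEvaluation:
    """Log-rank p, Harrell's C, and per-subtype Kaplan-Meier curves."""

    logrank_p: float
    c_index: float
    km_curves: dict  # label -> DataFrame(time, survival, at_risk)

    def curves_frame(self) -> pd.DataFrame:
        parts = []
        for label, df in self.km_curves.items():
            part = df.copy()
            part.insert(0, "subtype", label)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def _check_alignment(features, survival: SurvivalTable) -> None:
    if list(features.sample_ids) != list(survival.sample_ids):
        raise ValueError("features and survival table must be sample-aligned")


def cox_screen(
    latent: LatentMatrix, survival: SurvivalTable, alpha: float = 0.05
) -> ScreenResult:
    """Univariate Cox proportional-hazards screen of every latent feature.

    A feature is selected when its two-sided Wald p-value is below ``alpha``.
    Zero-variance and non-convergent fits are flagged and never selected; an
    empty selection is reported, not fatal.
    """
    _check_alignment(latent, survival)
    if latent.n_samples < 10:
        raise ValueError("need at least 10 samples for Cox screening")
    n_events = int(survival.event.sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox screening impossible")
    if n_events < 3:
        raise ValueError(f"need at least 3 events, got {n_events}")

    res = univariate_cox(latent.values, survival.time, survival.event)
    usable = res.converged | res.at_boundary
    flags = []
    for j in range(latent.n_features):
        if res.zero_variance[j]:
            flags.append(FLAG_ZERO_VARIANCE)
        elif res.at_boundary[j]:
            flags.append(FLAG_BOUNDARY)
        elif not res.converged[j]:
            flags.append(FLAG_NOT_CONVERGED)
        else:
            flags.append(FLAG_OK)
    with np.errstate(invalid="ignore"):
        selected = usable & np.isfinite(res.p_value) & (res.p_value < alpha)
    logger.info(
        "cox_screen: %d/%d features selected at alpha=%g",
        int(selected.sum()),
        latent.n_features,
        alpha,
    )
    return ScreenResult(
        feature_ids=list(latent.feature_ids),
        coefficient=res.coef,
        p_value=res.p_value,
        selected=selected,
        flag=flags,
        omic_of_origin=[latent.omic_of(f) for f in latent.feature_ids],
        alpha=alpha,
    )


def select_k_and_cluster(
    features: LatentMatrix,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
) -> SubtypeAssignment:
    """Gaussian-mixture clustering over candidate K; highest silhouette wins.

    Silhouette is computed with Euclidean distance on the same selected-
    feature matrix that is clustered.  Ties prefer the smaller K.  GMMs use
    full covariances, 10 initializations and a small diagonal regularizer
    for stability at modest sample sizes.
    """
    if features.n_features < 2:
        raise ValueError(
            "no survival-related features: need >= 2 selected features to cluster"
        )
    if features.n_samples <= 5:
        raise ValueError("need more than 5 samples to cluster")
    X = features.values
    best: Optional[tuple[int, float, np.ndarray, GaussianMixture]] = None
    candidate_scores: dict[int, float] = {}
    for K in k_range:
        gmm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            n_init=10,
            max_iter=200,
            reg_covar=1e-6,
            random_state=int(seed),
        )
        labels = gmm.fit_predict(X)
        if len(set(labels)) < 2:
            score = -1.0  # degenerate fit collapsed to one component
        else:
            score = float(silhouette_score(X, labels, metric="euclidean"))
        candidate_scores[int(K)] = score
        if best is None or score > best[1] + 1e-12:
            best = (int(K), score, labels, gmm)
    assert best is not None
    K, score, labels, gmm = best
    return SubtypeAssignment(
        sample_ids=list(features.sample_ids),
        labels=[f"ASD-{l + 1}" for l in labels],
        K=K,
        silhouette=score,
        gmm_params={
            "means": gmm.means_,
            "covariances": gmm.covariances_,
            "weights": gmm.weights_,
        },
        candidate_scores=candidate_scores,
    )


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate under right-censoring.

    Returns a step-function table (time, survival, at_risk) including t=0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    at_risk = at_risk.ffill().fillna(len(times))
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(float),
            "survival": surv.to_numpy(float),
            "at_risk": at_risk.to_numpy(int),
        }
    )


def _group_prognosis_stats(
    times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """(median KM survival, restricted mean survival) for one group."""
    kmf = KaplanMeierFitter().fit(times, events)
    median = float(kmf.median_survival_time_)
    horizon = float(times.max())
    rmst = float(restricted_mean_survival_time(kmf, t=horizon))
    return median, rmst


def order_labels_by_prognosis(
    assignment: SubtypeAssignment, survival: SurvivalTable
) -> SubtypeAssignment:
    """Rename clusters so median KM survival decreases from ASD-1 to ASD-K.

    Ties on the median (including both medians undefined/infinite) are broken
    by restricted-mean survival, then by cluster size (larger first).  The
    operation is idempotent and independent of the incoming label names.
    """
    _check_alignment(assignment, survival)
    keys = []
    for label, idx in assignment.groups().items():
        median, rmst = _group_prognosis_stats(
            survival.time[idx], survival.event[idx]
        )
        keys.append((label, median, rmst, idx.size))
    # best prognosis first: largest median, then largest RMST, then size
    keys.sort(key=lambda k: (-k[1], -k[2], -k[3]))
    mapping = {old: f"ASD-{rank + 1}" for rank, (old, *_) in enumerate(keys)}
    return SubtypeAssignment(
        sample_ids=list(assignment.sample_ids),
        labels=[mapping[l] for l in assignment.labels],
        K=assignment.K,
        silhouette=assignment.silhouette,
        gmm_params=assignment.gmm_params,
        candidate_scores=assignment.candidate_scores,
        prognosis_ordered=True,
    )


def evaluate_subtypes(
    assignment: SubtypeAssignment, survival: SurvivalTable
) -> SubtypeEvaluation:
    """Multivariate log-rank test across subtypes plus Harrell's C.

    The concordance index is computed from a Cox model with the subtype
    label (dummy-encoded) as the only covariate; its linear predictor is the
    risk score.  Kaplan-Meier curves are returned per subtype.
    """
    _check_alignment(assignment, survival)
    groups = assignment.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty subtype groups")
    labels = np.asarray(assignment.labels)
    lr = multivariate_logrank_test(survival.time, labels, survival.event)
    logrank_p = float(lr.p_value)

    dummies = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
    df = dummies.copy()
    df["time"] = survival.time
    df["event"] = survival.event
    if dummies.shape[1] == 0:
        raise ValueError("single subtype; cannot evaluate")
    cph = CoxPHFitter(penalizer=1e-4)
    cph.fit(df, duration_col="time", event_col="event")
    risk = cph.predict_log_partial_hazard(df).to_numpy(float)
    c_index = float(
        concordance_index(survival.time, -risk, survival.event)
    )
    curves = {
        label: km_estimate(survival.time[idx], survival.event[idx])
        for label, idx in groups.items()
    }
    return SubtypeEvaluation(
        logrank_p=logrank_p, c_index=c_index, km_curves=curves
    )


def direct_cox_baseline(
    features: Union[LatentMatrix, OmicsMatrix],
    survival: SurvivalTable,
    penalizer: float = 0.1,
    seed: int = 0,
) -> tuple[SubtypeAssignment, SubtypeEvaluation]:
    """Baseline without clustering: ridge Cox on the features, then a median
    split of the linear predictor into high/low-risk halves (always K=2).

    When n_features >= n_samples the features are first reduced to their top
    principal components (at most 100, fewer if n is small) so the ridge fit
    is well-posed.
    """
    _check_alignment(features, survival)
    X = np.asarray(features.values, dtype=float)
    n, p = X.shape
    if p >= n:
        n_comp = min(100, n - 2, p)
        X = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
        p = n_comp
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("degenerate fit: all features constant")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df["time"] = survival.time
    df["event"] = survival.event
    cph = CoxPHFitter(penalizer=penalizer, l1_ratio=0.0)
    cph.fit(df, duration_col="time", event_col="event")
    lp = cph.predict_log_partial_hazard(df).to_numpy(float)
    if np.allclose(lp, lp[0]):
        raise ValueError("degenerate fit: constant linear predictor")
    median = np.median(lp)
    high = lp > median
    if high.sum() == 0 or (~high).sum() == 0:
        # ties at the median: split by rank instead
        order = np.argsort(lp, kind="stable")
        high = np.zeros(n, dtype=bool)
        high[order[n // 2 :]] = True
    labels = ["ASD-2" if h else "ASD-1" for h in high]
    assignment = SubtypeAssignment(
        sample_ids=list(features.sample_ids),
        labels=labels,
        K=2,
        silhouette=float("nan"),
        candidate_scores={},
    )
    assignment = order_labels_by_prognosis(assignment, survival)
    evaluation = evaluate_subtypes(assignment, survival)
    return assignment, evaluation


def subtype_pipeline(
    latent: LatentMatrix,
    survival: SurvivalTable,
    alpha: float = 0.05,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
) -> tuple[ScreenResult, SubtypeAssignment, SubtypeEvaluation]:
    """Screen → cluster → order → evaluate, the core subtyping chain."""
    screen = cox_screen(latent, survival, alpha=alpha)
    selected = screen.selected_ids
    per_omic = pd.Series([latent.omic_of(f) for f in selected]).value_counts()
    for omic in set(screen.omic_of_origin):
        if omic not in per_omic.index:
            logger.warning(
                "no survival-related features selected from %s; proceeding "
                "with the remaining omic(s)",
                omic,
            )
    if len(selected) < 2:
        raise ValueError(
            "no survival-related features were extracted; cannot cluster"
        )
    assignment = select_k_and_cluster(
        latent.select(selected), k_range=k_range, seed=seed
    )
    assignment = order_labels_by_prognosis(assignment, survival)
    evaluation = evaluate_subtypes(assignment, survival)
    return screen, assignment, evaluation
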