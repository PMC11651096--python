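"""Apply a pretrained ensemble bundle to an external cohort.

The transferable knowledge is the trained encoders (plus the z-scoring
parameters their inputs expect).  A new cohort is normalized internally
(rank transform / proportions are cohort-relative by construction), scaled
with the *bundle's* scaler on the feature intersection, encoded with the
pretrained models, and then Cox screening and clustering are re-run on the
new cohort's own survival data.  Features the new cohort lacks are filled
with 0 — the scaled training mean — and the filled fraction is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ae_ensemble import encode_ensemble, hstack_latents
from .association import PredictionReport, loo_predict
from .autoencoder import TrainingConfig
from .core_io import SCALED, Cohort, EnsembleBundle, OmicsMatrix
from .preprocess import normalize
from .subtyping import (
    DEFAULT_K_RANGE,
    SubtypeAssignment,
    SubtypeEvaluation,
    subtype_pipeline,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureAlignment:
    """Scaled matrices in the bundle's feature space + fill bookkeeping."""

    scaled: dict  # omic -> OmicsMatrix (bundle feature order)
    filled_fraction: dict  # omic -> float
    missing_features: dict  # omic -> list[str]


def align_features(
    bundle: EnsembleBundle,
    cohort: Cohort,
    min_overlap: float = 0.5,
) -> FeatureAlignment:
    """Project a cohort onto the bundle's feature vocabulary.

    Each omic is normalized on the cohort itself, z-scored with the bundle's
    training parameters on the shared features, reordered to the bundle
    vocabulary, and zero-filled (the scaled training mean) where the cohort
    lacks a feature.  Errors out when the overlap drops below
    ``min_overlap`` of the bundle features.
    """
    scaled: dict[str, OmicsMatrix] = {}
    filled: dict[str, float] = {}
    missing_all: dict[str, list] = {}
    for omic, matrix in cohort.omics().items():
        params = bundle.scalers[omic]
        norm = normalize(matrix)
        pos = {f: j for j, f in enumerate(norm.feature_ids)}
        present = [f for f in params.feature_ids if f in pos]
        overlap = len(present) / len(params.feature_ids)
        if overlap < min_overlap:
            raise ValueError(
                f"{omic}: only {overlap:.1%} of bundle features present "
                f"(minimum {min_overlap:.0%})"
            )
        values = np.zeros((norm.n_samples, len(params.feature_ids)))
        safe_sd = np.where(params.constant_mask, 1.0, params.sd)
        for k, f in enumerate(params.feature_ids):
            j = pos.get(f)
            if j is None:
                continue  # stays 0 = scaled training mean
            if params.constant_mask[k]:
                values[:, k] = 0.0
            else:
                values[:, k] = (norm.values[:, j] - params.mean[k]) / safe_sd[k]
        missing = [f for f in params.feature_ids if f not in pos]
        filled[omic] = len(missing) / len(params.feature_ids)
        missing_all[omic] = missing
        if missing:
            logger.info(
                "align_features: %s: %.1f%% of bundle features zero-filled",
                omic,
                100 * filled[omic],
            )
        scaled[omic] = OmicsMatrix(
            list(norm.sample_ids),
            list(params.feature_ids),
            values,
            omic,
            state=SCALED,
        )
    return FeatureAlignment(
        scaled=scaled, filled_fraction=filled, missing_features=missing_all
    )


def transfer_subtyping(
    bundle: EnsembleBundle,
    cohort: Cohort,
    seed: int = 0,
    fine_tune_epochs: int = 0,
    alpha: float = 0.05,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    config: Optional[TrainingConfig] = None,
    min_overlap: float = 0.5,
) -> tuple[SubtypeAssignment, SubtypeEvaluation]:
    """Subtype an external cohort with pretrained encoders.

    With ``fine_tune_epochs = 0`` (default) the bundle weights are used
    bit-unchanged; otherwise each model is copied and trained further on the
    new cohort for at most that many epochs (same early-stopping rule).
    Screening and clustering always use the new cohort's survival data, so a
    cohort identical to the training cohort reproduces the native pipeline.
    """
    alignment = align_features(bundle, cohort, min_overlap=min_overlap)
    latents = []
    for omic, matrix in alignment.scaled.items():
        models = bundle.models[omic]
        if fine_tune_epochs > 0:
            cfg = config or TrainingConfig()
            ft_cfg = TrainingConfig(
                learning_rate=cfg.learning_rate,
                max_epochs=fine_tune_epochs,
                patience=cfg.patience,
                batch_size=cfg.batch_size,
                validation_fraction=cfg.validation_fraction,
            )
            # warm-start from the pretrained weights on a model copy; the
            # bundle itself is never mutated
            models = [
                _fine_tune(model.copy(), matrix.values, ft_cfg)
                for model in models
            ]
        latents.append(encode_ensemble(models, matrix))
    pooled = hstack_latents(latents)
    screen, assignment, evaluation = subtype_pipeline(
        pooled, cohort.survival, alpha=alpha, k_range=k_range, seed=seed
    )
    if not screen.selected.any():
        raise ValueError("no features passed screening on the new cohort")
    return assignment, evaluation


def _fine_tune(model, X: np.ndarray, cfg: TrainingConfig):
    """Continue training a copied model on new data with early stopping."""
    from .autoencoder import _eval_loss, _forward_backward

    rng = np.random.default_rng(model.seed + 1_000_003)
    n = X.shape[0]
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    Xval, Xtr = X[perm[:n_val]], X[perm[n_val:]]
    w = model.weights
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(val) for k, val in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    batch = min(cfg.batch_size, len(Xtr))
    best_val = _eval_loss(w, Xval)
    best_w = {k: a.copy() for k, a in w.items()}
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), batch):
            idx = order[start : start + batch]
            loss, g = _forward_backward(w, Xtr[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            t += 1
            for k in w:
                m[k] = beta1 * m[k] + (1 - beta1) * g[k]
                v[k] = beta2 * v[k] + (1 - beta2) * g[k] ** 2
                w[k] -= cfg.learning_rate * (m[k] / (1 - beta1**t)) / (
                    np.sqrt(v[k] / (1 - beta2**t)) + eps
                )
        val = _eval_loss(w, Xval)
        model.training_history.append((loss, val))
        if val < best_val - 1e-12:
            best_val, stale = val, 0
            best_w = {k: a.copy() for k, a in w.items()}
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.weights = best_w
    return model


def transfer_classify(
    feature_list: Sequence[str],
    expr: OmicsMatrix,
    micro: OmicsMatrix,
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 500,
    max_missing: float = 0.5,
) -> PredictionReport:
    """Leave-one-out AUROC on a new cohort using a pretrained feature list
    (e.g. the union of the per-omic top-20 importance lists).

    Features absent from the new cohort are zero-filled and counted in the
    report; more than ``max_missing`` missing is an error.
    """
    pools = {**{f: ("expr", j) for j, f in enumerate(expr.feature_ids)},
             **{f: ("micro", j) for j, f in enumerate(micro.feature_ids)}}
    n = expr.n_samples
    if micro.n_samples != n:
        raise ValueError("matrices must be sample-aligned")
    X = np.zeros((n, len(feature_list)))
    missing = []
    for k, f in enumerate(feature_list):
        src = pools.get(f)
        if src is None:
            missing.append(f)
        elif src[0] == "expr":
            X[:, k] = expr.values[:, src[1]]
        else:
            X[:, k] = micro.values[:, src[1]]
    if len(missing) / len(feature_list) > max_missing:
        raise ValueError(
            f"{len(missing)}/{len(feature_list)} pretrained features missing"
        )
    report = loo_predict(
        X, labels, "random_forest", seed=seed, n_estimators=n_estimators,
        feature_set="both_top40",
    )
    report.extra["n_resolved"] = len(feature_list) - len(missing)
    report.extra["n_missing"] = len(missing)
    report.extra["missing_features"] = missing
    return report
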