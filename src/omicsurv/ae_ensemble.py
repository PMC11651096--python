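"""Autoencoder ensembles per omic layer, pooled latent features, the PCA
baseline, and the ensemble-size consistency sweep.

A single 100-unit bottleneck trained once is a noisy feature extractor; the
pipeline therefore trains ``ensemble_size`` independently seeded autoencoders
per omic and pools their bottleneck activations, giving ensemble_size × 100
latent features per omic layer.  Downstream Cox screening then decides which
of those pooled features carry survival signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .autoencoder import LATENT_DIM, AEModel, TrainingConfig, train_autoencoder
from .core_io import SCALED, Cohort, EnsembleBundle, OmicsMatrix
from .preprocess import ScalingParams, preprocess_matrix

logger = logging.getLogger(__name__)


@dataclass
class LatentMatrix:
    """Samples × latent-features matrix pooled over models and omics.

    Latent feature IDs encode their provenance as ``{omic}|m{model}|z{unit}``
    (or ``{omic}|pc{j}`` for the PCA baseline), so the omic of origin of any
    screened feature can always be recovered.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("latent matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("latent matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def omic_of(self, feature_id: str) -> str:
        return feature_id.split("|", 1)[0]

    def select(self, feature_ids: Sequence[str]) -> "LatentMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [pos[f] for f in feature_ids]
        return LatentMatrix(
            list(self.sample_ids), list(feature_ids), self.values[:, cols]
        )


def hstack_latents(parts: Sequence[LatentMatrix]) -> LatentMatrix:
    ref = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != ref:
            raise ValueError("latent matrices must share sample order")
    return LatentMatrix(
        list(ref),
        [f for p in parts for f in p.feature_ids],
        np.hstack([p.values for p in parts]),
    )


def encode(model: AEModel, matrix: OmicsMatrix) -> LatentMatrix:
    """Deterministic bottleneck activations for one model (dropout off)."""
    if matrix.state != SCALED:
        raise ValueError("encode expects a scaled matrix")
    z = model.encode(matrix.values)
    ids = [
        f"{matrix.omic_kind}|m{model.seed}|z{j:03d}" for j in range(z.shape[1])
    ]
    return LatentMatrix(list(matrix.sample_ids), ids, z)


def encode_ensemble(
    models: Sequence[AEModel], matrix: OmicsMatrix
) -> LatentMatrix:
    """Pool bottlenecks over an ensemble: model index becomes part of the ID."""
    if matrix.state != SCALED:
        raise ValueError("encode_ensemble expects a scaled matrix")
    blocks = []
    ids = []
    for i, model in enumerate(models):
        blocks.append(model.encode(matrix.values))
        ids.extend(
            f"{matrix.omic_kind}|m{i:02d}|z{j:03d}" for j in range(LATENT_DIM)
        )
    return LatentMatrix(list(matrix.sample_ids), ids, np.hstack(blocks))


def train_ensemble(
    scaled: dict[str, OmicsMatrix],
    scalers: dict[str, ScalingParams],
    ensemble_size: int = 30,
    base_seed: int = 0,
    config: Optional[TrainingConfig] = None,
    cancer_label: str = "",
) -> tuple[EnsembleBundle, dict[str, LatentMatrix]]:
    """Train ``ensemble_size`` autoencoders per omic with seeds
    ``base_seed … base_seed+ensemble_size−1`` and return the bundle plus the
    pooled latent matrix per omic (ensemble_size × 100 columns each)."""
    seeds = [int(base_seed) + i for i in range(ensemble_size)]
    models: dict[str, list[AEModel]] = {}
    latents: dict[str, LatentMatrix] = {}
    for omic, matrix in scaled.items():
        if matrix.state != SCALED:
            raise ValueError(f"{omic}: train_ensemble expects scaled matrices")
        omic_models = []
        for i, seed in enumerate(seeds):
            try:
                omic_models.append(
                    train_autoencoder(matrix.values, seed=seed, config=config)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"training model {i} for omic {omic!r} failed: {exc}"
                ) from exc
        models[omic] = omic_models
        latents[omic] = encode_ensemble(omic_models, matrix)
        logger.info(
            "trained %d autoencoders for %s (pooled latent width %d)",
            ensemble_size,
            omic,
            latents[omic].n_features,
        )
    bundle = EnsembleBundle(
        models=models,
        scalers=scalers,
        ensemble_size=ensemble_size,
        latent_dim=LATENT_DIM,
        seeds=seeds,
        cancer_label=cancer_label,
    )
    return bundle, latents


def pca_transform(matrix: OmicsMatrix, n_components: int = 100) -> LatentMatrix:
    """Baseline extractor: replace the autoencoder with PCA scores.

    Components are ordered by decreasing explained variance.
    """
    if matrix.state != SCALED:
        raise ValueError("pca_transform expects a scaled matrix")
    limit = min(matrix.n_samples, matrix.n_features)
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={limit}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    ids = [f"{matrix.omic_kind}|pc{j:03d}" for j in range(n_components)]
    return LatentMatrix(list(matrix.sample_ids), ids, scores)


def consistency_sweep(
    cohort: Cohort,
    sizes: Sequence[int] = (5, 10, 15, 20, 25, 30, 35, 40),
    repeats: int = 3,
    seed: int = 0,
    config: Optional[TrainingConfig] = None,
    k_range: Sequence[int] = (2, 3, 4, 5),
) -> list[dict]:
    """Clustering-consistency experiment over ensemble sizes.

    For each candidate size the full subtyping pipeline is run ``repeats``
    times with distinct base seeds; consistency is the mean pairwise adjusted
    Rand index between the resulting labelings.  Larger ensembles are
    expected to stabilize the clustering.
    """
    from .subtyping import cox_screen, select_k_and_cluster

    if repeats < 2:
        raise ValueError("repeats must be at least 2")
    scaled = {}
    scalers = {}
    for omic, mat in cohort.omics().items():
        scaled[omic], scalers[omic] = preprocess_matrix(mat)
    rows = []
    for size in sizes:
        labelings = []
        for r in range(repeats):
            base = int(seed) + 10_000 * r + 100 * int(size)
            _, latents = train_ensemble(
                scaled, scalers, ensemble_size=size, base_seed=base, config=config
            )
            pooled = hstack_latents(list(latents.values()))
            screen = cox_screen(pooled, cohort.survival)
            selected = [
                f for f, s in zip(screen.feature_ids, screen.selected) if s
            ]
            if len(selected) < 2:
                logger.warning(
                    "sweep size=%d repeat=%d: %d features selected; skipping",
                    size,
                    r,
                    len(selected),
                )
                continue
            assignment = select_k_and_cluster(
                pooled.select(selected), k_range=k_range, seed=base
            )
            labelings.append(np.asarray(assignment.numeric_labels()))
        agreements = [
            adjusted_rand_score(a, b)
            for i, a in enumerate(labelings)
            for b in labelings[i + 1 :]
        ]
        rows.append(
            {
                "ensemble_size": int(size),
                "n_labelings": len(labelings),
                "mean_pairwise_ari": float(np.mean(agreements)) if agreements else float("nan"),
            }
        )
    return rows
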