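"""Omic-specific normalization and per-feature standardization.

Expression values are rank-based inverse-normal transformed per gene across
samples: ranks (average over ties) are mapped through the standard normal
quantile function Φ⁻¹((r − 0.5)/n), damping extreme values while preserving
each gene's sample ordering.  Microbiome counts become per-sample relative
abundances.  Both layers are then z-scored per feature so that every feature
enters the autoencoder on a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    MICROBIOME,
    NORMALIZED,
    RAW,
    SCALED,
    TRANSCRIPTOME,
    OmicsMatrix,
)


@dataclass
class ScalingParams:
    """Per-feature mean/sd fitted on a training cohort (population sd).

    ``constant_mask`` flags features with zero variance; those are mapped to
    all-zero columns instead of being dropped so that feature indices stay
    aligned with a trained encoder's input layer.
    """

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    constant_mask: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.constant_mask = np.asarray(self.constant_mask, dtype=bool)
        n = len(self.feature_ids)
        if not (self.mean.shape == self.sd.shape == self.constant_mask.shape == (n,)):
            raise ValueError("scaler parameter vectors must share feature_ids length")
        if (self.sd < 0).any():
            raise ValueError("sd must be non-negative")
        if ((self.sd == 0) != self.constant_mask).any():
            raise ValueError("constant_mask must flag exactly the sd == 0 features")


def rank_normal_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Rank-based inverse normal transform of a raw transcriptome matrix.

    Each gene column is replaced by Φ⁻¹((rᵢ − 0.5)/n) where rᵢ is sample i's
    average rank within that gene.  Requires at least 3 samples.
    """
    if matrix.omic_kind != TRANSCRIPTOME:
        raise ValueError("rank_normal_transform applies to transcriptome matrices")
    if matrix.state != RAW:
        raise ValueError("input must be in raw state")
    n = matrix.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    ranks = stats.rankdata(matrix.values, axis=0, method="average")
    transformed = stats.norm.ppf((ranks - 0.5) / n)
    return OmicsMatrix(
        list(matrix.sample_ids),
        list(matrix.feature_ids),
        transformed,
        TRANSCRIPTOME,
        state=NORMALIZED,
    )


def relative_abundance(matrix: OmicsMatrix) -> OmicsMatrix:
    """Convert raw microbiome counts to per-sample proportions (rows sum to 1)."""
    if matrix.omic_kind != MICROBIOME:
        raise ValueError("relative_abundance applies to microbiome matrices")
    if matrix.state != RAW:
        raise ValueError("input must be in raw state")
    if (matrix.values < 0).any():
        raise ValueError("negative counts in microbiome matrix")
    totals = matrix.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"zero-sum microbiome sample(s): {[matrix.sample_ids[i] for i in zero[:5]]}"
        )
    return OmicsMatrix(
        list(matrix.sample_ids),
        list(matrix.feature_ids),
        matrix.values / totals[:, None],
        MICROBIOME,
        state=NORMALIZED,
    )


def normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Dispatch to the omic-appropriate normalization."""
    if matrix.omic_kind == TRANSCRIPTOME:
        return rank_normal_transform(matrix)
    return relative_abundance(matrix)


def fit_scaler(matrix: OmicsMatrix) -> ScalingParams:
    """Fit per-feature mean/sd (population convention, divide by n)."""
    if matrix.state != NORMALIZED:
        raise ValueError("fit_scaler expects a normalized matrix")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)  # ddof=0
    constant = sd < 1e-12
    sd = np.where(constant, 0.0, sd)
    return ScalingParams(list(matrix.feature_ids), mean, sd, constant)


def apply_scaler(matrix: OmicsMatrix, params: ScalingParams) -> OmicsMatrix:
    """Z-score ``matrix`` with previously fitted parameters.

    Columns are reordered to ``params.feature_ids``; features the scaler does
    not know are dropped, and features it expects but the matrix lacks raise
    an error listing them.  Constant features map to all-zero columns.
    """
    if matrix.state != NORMALIZED:
        raise ValueError("apply_scaler expects a normalized matrix")
    pos = {f: j for j, f in enumerate(matrix.feature_ids)}
    missing = [f for f in params.feature_ids if f not in pos]
    if missing:
        raise ValueError(
            f"{len(missing)} scaler features missing from matrix, e.g. {missing[:5]}"
        )
    cols = [pos[f] for f in params.feature_ids]
    vals = matrix.values[:, cols]
    safe_sd = np.where(params.constant_mask, 1.0, params.sd)
    scaled = (vals - params.mean) / safe_sd
    scaled[:, params.constant_mask] = 0.0
    return OmicsMatrix(
        list(matrix.sample_ids),
        list(params.feature_ids),
        scaled,
        matrix.omic_kind,
        state=SCALED,
    )


def preprocess_matrix(matrix: OmicsMatrix) -> tuple[OmicsMatrix, ScalingParams]:
    """Normalize then fit-and-apply the scaler; returns (scaled, params)."""
    norm = normalize(matrix)
    params = fit_scaler(norm)
    return apply_scaler(norm, params), params
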