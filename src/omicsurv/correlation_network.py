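"""Microbe–host-gene Pearson correlation edges and network export.

All gene × taxon pairs are correlated in memory-bounded blocks; pairs whose
coefficient clears the threshold (|r| by default) become network edges.
Pearson r is invariant to per-feature affine rescaling, so normalized
(pre-z-scoring) matrices give the same edges as scaled ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationEdge:
    gene_id: str
    taxon_id: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (z, keep_mask) excluding zero variance."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > 1e-12
    z = np.zeros_like(values)
    z[:, keep] = (values[:, keep] - mean[keep]) / sd[keep]
    return z, keep


def pearson_pairs(
    expr: OmicsMatrix,
    micro: OmicsMatrix,
    threshold: float = 0.9,
    mode: str = "absolute",
    block_size: int = 512,
) -> list[CorrelationEdge]:
    """All-pairs gene × taxon Pearson correlations above a threshold.

    ``mode="absolute"`` emits edges with |r| > threshold; ``"signed"``
    requires r > threshold.  Zero-variance features are excluded with a
    warning and never form edges.  The result is independent of
    ``block_size`` and sorted by |r| descending (ties by IDs).
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    if expr.sample_ids != micro.sample_ids:
        raise ValueError("matrices must be sample-aligned")
    n = expr.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples for correlation analysis")

    ez, ekeep = _standardize(expr.values)
    mz, mkeep = _standardize(micro.values)
    for name, keep, ids in (
        ("gene", ekeep, expr.feature_ids),
        ("taxon", mkeep, micro.feature_ids),
    ):
        dropped = int((~keep).sum())
        if dropped:
            logger.warning(
                "pearson_pairs: excluded %d zero-variance %s feature(s), e.g. %s",
                dropped,
                name,
                [ids[j] for j in np.flatnonzero(~keep)[:3]],
            )

    edges: list[CorrelationEdge] = []
    gene_idx = np.flatnonzero(ekeep)
    taxon_idx = np.flatnonzero(mkeep)
    mzk = mz[:, taxon_idx]
    for start in range(0, gene_idx.size, block_size):
        block = gene_idx[start : start + block_size]
        R = ez[:, block].T @ mzk / n
        np.clip(R, -1.0, 1.0, out=R)
        if mode == "absolute":
            hits = np.argwhere(np.abs(R) > threshold)
        else:
            hits = np.argwhere(R > threshold)
        for bi, tj in hits:
            edges.append(
                CorrelationEdge(
                    gene_id=expr.feature_ids[block[bi]],
                    taxon_id=micro.feature_ids[taxon_idx[tj]],
                    r=float(R[bi, tj]),
                    n=n,
                )
            )
    edges.sort(key=lambda e: (-abs(e.r), e.gene_id, e.taxon_id))
    return edges


def edges_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.gene_id, e.taxon_id, e.r, e.n) for e in edges],
        columns=["gene", "taxon", "r", "n"],
    )


def write_network(edges: list[CorrelationEdge], path, sif_path=None) -> None:
    """Write edges as a TSV (gene, taxon, r, n), |r| descending; optionally
    also as a SIF file (``gene corr taxon``) for network tools."""
    path = Path(path)
    edges_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.10g")
    if sif_path is not None:
        lines = [f"{e.gene_id}\tcorr\t{e.taxon_id}" for e in edges]
        Path(sif_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_network(path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        CorrelationEdge(str(g), str(t), float(r), int(n))
        for g, t, r, n in df.itertuples(index=False)
    ]
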