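"""Domain containers, table readers, cohort alignment, and model-bundle persistence.

Tables are delimited text (TSV by default, CSV by extension), samples in rows
and features in columns, with the first column holding sample IDs.  Clinical
missing values are written as ``NA``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSCRIPTOME = "transcriptome"
MICROBIOME = "microbiome"
OMIC_KINDS = (TRANSCRIPTOME, MICROBIOME)

RAW = "raw"
NORMALIZED = "normalized"
SCALED = "scaled"

STAGES = ("I", "II", "III", "IV", "NA")

BUNDLE_SCHEMA_VERSION = 1


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """Samples × features matrix for a single omic layer.

    Parameters
    ----------
    sample_ids, feature_ids
        Ordered, duplicate-free identifier lists.
    values
        Real matrix of shape ``(n_samples, n_features)``.
    omic_kind
        ``"transcriptome"`` or ``"microbiome"``.
    state
        Processing state: ``"raw"``, ``"normalized"`` or ``"scaled"``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    omic_kind: str
    state: str = RAW

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.omic_kind not in OMIC_KINDS:
            raise ValueError(f"unknown omic_kind {self.omic_kind!r}")
        if self.state not in (RAW, NORMALIZED, SCALED):
            raise ValueError(f"unknown state {self.state!r}")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.feature_ids)} features"
            )
        if self.state != RAW and not np.isfinite(self.values).all():
            raise ValueError("non-finite values in a processed matrix")
        if self.omic_kind == MICROBIOME and self.state == RAW:
            finite = self.values[np.isfinite(self.values)]
            if (finite < 0).any():
                raise ValueError("microbiome raw values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise KeyError(f"samples not present: {missing[:5]}")
        return OmicsMatrix(
            list(sample_ids), list(self.feature_ids), self.values[pos], self.omic_kind, self.state
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1 = death observed)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event length must match sample_ids")
        if not (self.time > 0).all():
            raise ValueError("survival times must be strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            raise KeyError("samples not present in survival table")
        return SurvivalTable(list(sample_ids), self.time[pos], self.event[pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=self.sample_ids
        )


@dataclass
class ClinicalTable:
    """Per-sample AJCC stage (I–IV or NA) and age (NaN where unknown)."""

    sample_ids: list[str]
    stage: list[str]
    age: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.stage = [str(s) for s in self.stage]
        bad = sorted(set(self.stage) - set(STAGES))
        if bad:
            raise ValueError(f"stage values outside {STAGES}: {bad}")
        if len(self.stage) != len(self.sample_ids):
            raise ValueError("stage length must match sample_ids")
        if self.age is None:
            self.age = np.full(len(self.sample_ids), np.nan)
        self.age = np.asarray(self.age, dtype=float)
        if self.age.shape != (len(self.sample_ids),):
            raise ValueError("age length must match sample_ids")
        finite_age = self.age[np.isfinite(self.age)]
        if (finite_age < 0).any():
            raise ValueError("age must be non-negative")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            raise KeyError("samples not present in clinical table")
        return ClinicalTable(
            list(sample_ids), [self.stage[p] for p in pos], self.age[pos]
        )


@dataclass
class Cohort:
    """Paired transcriptome + microbiome matrices with survival (and optional
    clinical) tables sharing one identically ordered sample list."""

    transcriptome: OmicsMatrix
    microbiome: OmicsMatrix
    survival: SurvivalTable
    clinical: Optional[ClinicalTable] = None
    cancer_label: str = ""
    dropped_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.survival.sample_ids
        for name, comp in (
            ("transcriptome", self.transcriptome),
            ("microbiome", self.microbiome),
        ):
            if comp.sample_ids != ref:
                raise ValueError(f"{name} sample order differs from survival table")
        if self.clinical is not None and self.clinical.sample_ids != ref:
            raise ValueError("clinical sample order differs from survival table")

    @property
    def sample_ids(self) -> list[str]:
        return self.survival.sample_ids

    @property
    def n_samples(self) -> int:
        return self.survival.n_samples

    def omics(self) -> dict[str, OmicsMatrix]:
        return {TRANSCRIPTOME: self.transcriptome, MICROBIOME: self.microbiome}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_omics_table(
    path, omic_kind: str, *, transpose: bool = False
) -> OmicsMatrix:
    """Read a delimited text table into a raw :class:`OmicsMatrix`.

    First column holds sample IDs and the header row feature IDs; pass
    ``transpose=True`` for feature-major files.  Raises on duplicate IDs and
    on non-numeric cells, naming the offending coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate feature ID: {dup!r} in {path}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at sample {df.index[i]!r}, "
                        f"feature {col!r}: {cell!r}"
                    ) from None
        raise
    return OmicsMatrix(
        list(df.index), list(df.columns), values, omic_kind, state=RAW
    )


def write_omics_table(matrix: OmicsMatrix, path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_survival_table(path) -> SurvivalTable:
    """Read sample_id / time / event columns from a delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "event" not in cols:
        raise ValueError(f"survival table {path} must have 'time' and 'event' columns")
    return SurvivalTable(
        list(df.index.astype(str)),
        df[cols["time"]].to_numpy(float),
        df[cols["event"]].to_numpy(),
    )


def write_survival_table(table: SurvivalTable, path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_clinical_table(path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "stage" not in cols:
        raise ValueError(f"clinical table {path} must have a 'stage' column")
    stage = [s if s else "NA" for s in df[cols["stage"]]]
    if "age" in cols:
        age = pd.to_numeric(df[cols["age"]].replace("NA", np.nan), errors="coerce").to_numpy()
    else:
        age = None
    return ClinicalTable(list(df.index.astype(str)), stage, age)


def write_clinical_table(table: ClinicalTable, path) -> None:
    path = Path(path)
    age = ["NA" if not np.isfinite(a) else f"{a:g}" for a in table.age]
    pd.DataFrame(
        {"stage": table.stage, "age": age}, index=table.sample_ids
    ).to_csv(path, sep=_sep_for(path), index_label="sample_id")


def align_cohort(
    transcriptome: OmicsMatrix,
    microbiome: OmicsMatrix,
    survival: SurvivalTable,
    clinical: Optional[ClinicalTable] = None,
    cancer_label: str = "",
) -> Cohort:
    """Intersect sample IDs across all inputs and return a lexicographically
    ordered :class:`Cohort`; dropped IDs are logged and recorded.

    Raises ``ValueError`` when the intersection is empty.
    """
    parts: dict[str, Sequence[str]] = {
        TRANSCRIPTOME: transcriptome.sample_ids,
        MICROBIOME: microbiome.sample_ids,
        "survival": survival.sample_ids,
    }
    if clinical is not None:
        parts["clinical"] = clinical.sample_ids
    shared = set(parts[TRANSCRIPTOME])
    for ids in parts.values():
        shared &= set(ids)
    if not shared:
        raise ValueError("no samples shared across all inputs")
    order = sorted(shared)
    dropped = {name: sorted(set(ids) - shared) for name, ids in parts.items()}
    for name, ids in dropped.items():
        if ids:
            logger.info("align_cohort: dropped %d samples from %s", len(ids), name)
    return Cohort(
        transcriptome=transcriptome.subset_samples(order),
        microbiome=microbiome.subset_samples(order),
        survival=survival.subset_samples(order),
        clinical=None if clinical is None else clinical.subset_samples(order),
        cancer_label=cancer_label,
        dropped_ids=dropped,
    )


@dataclass
class EnsembleBundle:
    """Trained autoencoder ensemble plus the preprocessing parameters needed
    to apply it to a new cohort — the persistable model."""

    models: dict  # omic -> list[AEModel]
    scalers: dict  # omic -> ScalingParams
    ensemble_size: int
    latent_dim: int
    seeds: list[int]
    cancer_label: str = ""

    def __post_init__(self) -> None:
        for omic, mods in self.models.items():
            if len(mods) != self.ensemble_size:
                raise ValueError(
                    f"{omic}: {len(mods)} models stored but ensemble_size={self.ensemble_size}"
                )
        for omic, sc in self.scalers.items():
            if len(sc.feature_ids) != len(sc.mean):
                raise ValueError(f"{omic}: scaler feature/parameter length mismatch")

    def feature_ids(self, omic: str) -> list[str]:
        return list(self.scalers[omic].feature_ids)


def save_bundle(bundle: EnsembleBundle, path) -> None:
    """Persist a bundle as a directory: JSON metadata + one ``.npz`` archive
    of weight arrays per model plus one per scaler (no pickled objects)."""
    from .preprocess import ScalingParams  # noqa: F401  (type documented here)

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "ensemble_size": bundle.ensemble_size,
        "latent_dim": bundle.latent_dim,
        "seeds": list(map(int, bundle.seeds)),
        "cancer_label": bundle.cancer_label,
        "omics": {
            omic: {
                "n_features": len(bundle.scalers[omic].feature_ids),
                "n_models": len(models),
            }
            for omic, models in bundle.models.items()
        },
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for omic, models in bundle.models.items():
        sc = bundle.scalers[omic]
        np.savez(
            path / f"{omic}_scaler.npz",
            feature_ids=np.asarray(sc.feature_ids, dtype="U"),
            mean=sc.mean,
            sd=sc.sd,
            constant_mask=sc.constant_mask,
        )
        for i, model in enumerate(models):
            arrays = model.state_arrays()
            np.savez(
                path / f"{omic}_model{i:03d}.npz",
                seed=np.asarray(model.seed),
                stopped_epoch=np.asarray(model.stopped_epoch),
                history=np.asarray(model.training_history, dtype=float),
                **arrays,
            )


def load_bundle(path) -> EnsembleBundle:
    """Load a bundle saved by :func:`save_bundle`; round-trips encode output
    bit-identically.  Raises on missing/corrupt metadata or model-count
    mismatches."""
    from .autoencoder import AEModel
    from .preprocess import ScalingParams

    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise ValueError(f"no metadata.json under {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt bundle metadata: {exc}") from exc
    if meta.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported bundle schema version {meta.get('schema_version')!r}"
        )
    models: dict[str, list] = {}
    scalers: dict[str, ScalingParams] = {}
    for omic, info in meta["omics"].items():
        with np.load(path / f"{omic}_scaler.npz") as z:
            scalers[omic] = ScalingParams(
                feature_ids=[str(f) for f in z["feature_ids"]],
                mean=z["mean"],
                sd=z["sd"],
                constant_mask=z["constant_mask"].astype(bool),
            )
        stored = sorted(path.glob(f"{omic}_model*.npz"))
        if len(stored) != info["n_models"]:
            raise ValueError(
                f"{omic}: metadata promises {info['n_models']} models, found {len(stored)}"
            )
        models[omic] = [AEModel.from_npz(p) for p in stored]
    return EnsembleBundle(
        models=models,
        scalers=scalers,
        ensemble_size=int(meta["ensemble_size"]),
        latent_dim=int(meta["latent_dim"]),
        seeds=[int(s) for s in meta["seeds"]],
        cancer_label=meta.get("cancer_label", ""),
    )
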