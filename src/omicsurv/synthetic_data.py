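"""Synthetic paired-omics survival cohorts with known ground truth.

The generator emulates the structure the pipeline assumes: K latent survival
subtypes that (i) shift a subset of informative genes, (ii) tilt the
microbial composition on a subset of informative taxa, and (iii) scale the
hazard of an exponential survival time, with independent uniform censoring
calibrated to a target censoring fraction; clinical stage is drawn from a
subtype-tilted multinomial; and a set of planted (gene, taxon) pairs share a
latent factor tuned to a target population Pearson correlation.  Everything
flows from one seed, so datasets are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .core_io import (
    MICROBIOME,
    TRANSCRIPTOME,
    ClinicalTable,
    Cohort,
    OmicsMatrix,
    SurvivalTable,
    write_clinical_table,
    write_omics_table,
    write_survival_table,
)

# Stage composition used when subtype exerts no pull (roughly the early-stage
# skew of registry cohorts).
_BASE_STAGE_P = np.array([0.30, 0.30, 0.25, 0.15])
_STAGE_NAMES = ("I", "II", "III", "IV")


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults are the documented standard test cohort."""

    n_samples: int = 200
    n_genes: int = 500
    n_taxa: int = 150
    K_true: int = 2
    n_informative_genes: int = 50
    n_informative_taxa: int = 20
    effect_size_genes: float = 1.5   # mean shift per subtype step, in sd units
    taxa_shift: float = 1.0          # log-composition shift per subtype step
    hazard_ratio: float = 3.0        # between adjacent subtypes
    baseline_hazard: float = 1e-3    # per day for the best-prognosis subtype
    censoring_rate: float = 0.3
    stage_association: float = 0.7   # 0 = independent, 1 = deterministic
    n_corr_pairs: int = 10
    target_r: float = 0.95
    seed: int = 42
    # nuisance structure
    mean_library_size: float = 5e4
    library_size_sigma: float = 0.3  # lognormal sd of sequencing depth
    taxa_noise_sigma: float = 0.3    # per-sample log-abundance noise

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_taxa, self.K_true) <= 0:
            raise ValueError("counts must be positive")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        if self.n_informative_taxa > self.n_taxa:
            raise ValueError("n_informative_taxa exceeds n_taxa")
        if self.n_corr_pairs > min(
            self.n_genes - self.n_informative_genes,
            self.n_taxa - self.n_informative_taxa,
        ):
            raise ValueError("not enough non-informative features for planted pairs")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not (0 <= self.stage_association <= 1):
            raise ValueError("stage_association must lie in [0, 1]")
        if not (-1 < self.target_r < 1):
            raise ValueError("target_r must lie in (−1, 1)")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class SyntheticDataset:
    cohort: Cohort
    truth_labels: np.ndarray          # subtype index per sample, 0-based
    truth_gene_ids: list[str]
    truth_taxon_ids: list[str]
    truth_pairs: list[tuple[str, str]]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _calibrate_censoring(
    hazards: np.ndarray, weights: np.ndarray, rate: float
) -> float:
    """Upper bound u of the Uniform(0, u) censoring time such that the
    marginal censoring probability equals ``rate``.

    For T ~ Exp(h) and C ~ U(0, u): P(C < T) = (1 − e^{−hu}) / (hu), which
    decreases from 1 (u→0) to 0 (u→∞), so a root always exists in (0, 1).
    """
    if rate == 0:
        return np.inf

    def prob(u: float) -> float:
        x = hazards * u
        return float(np.sum(weights * np.where(x < 1e-12, 1.0, (1 - np.exp(-x)) / x)))

    lo, hi = 1e-9, 1.0
    while prob(hi) > rate:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("censoring calibration failed to bracket")
    return float(optimize.brentq(lambda u: prob(u) - rate, lo, hi, xtol=1e-12))


def _pair_factor_correlation(cfg: SyntheticConfig) -> float:
    """Latent-factor correlation needed so the *observed* gene–proportion
    correlation lands near ``target_r``.

    Two attenuation sources sit between the shared factor and the observed
    relative abundance: the exp() link (corr(x, e^{sx}) = s/√(e^{s²}−1)) and
    multinomial counting noise at finite depth.  Both are estimated
    analytically and divided out, capped below 0.999.
    """
    s = _PAIR_FACTOR_LOADING
    lognorm_att = s / np.sqrt(np.expm1(s**2))
    expected_count = _PAIR_MEAN_SHARE * cfg.mean_library_size
    count_cv = 1.0 / np.sqrt(max(expected_count, 1.0))
    count_att = s / np.sqrt(s**2 + count_cv**2)
    needed = cfg.target_r / (lognorm_att * count_att)
    return float(np.clip(needed, -0.999, 0.999))


_PAIR_FACTOR_LOADING = 0.25  # log-share loading of the shared factor
_PAIR_MEAN_SHARE = 0.02      # mean relative abundance of each planted taxon


def generate_cohort(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one paired-omics cohort with planted structure (deterministic)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, G, T, K = cfg.n_samples, cfg.n_genes, cfg.n_taxa, cfg.K_true

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"gene_{j:04d}" for j in range(G)]
    taxon_ids = [f"taxon_{j:04d}" for j in range(T)]

    z = rng.integers(0, K, size=n)

    # --- transcriptome ---------------------------------------------------
    expr = rng.standard_normal((n, G))
    info_genes = np.arange(cfg.n_informative_genes)
    expr[:, info_genes] += cfg.effect_size_genes * z[:, None]

    # --- planted correlated pairs (disjoint from informative features) ---
    pair_genes = np.arange(G - cfg.n_corr_pairs, G)
    pair_taxa = np.arange(T - cfg.n_corr_pairs, T)
    r0 = _pair_factor_correlation(cfg)
    factors = rng.standard_normal((n, cfg.n_corr_pairs))
    expr[:, pair_genes] = factors
    taxon_signal = r0 * factors + np.sqrt(1 - r0**2) * rng.standard_normal(
        (n, cfg.n_corr_pairs)
    )

    # --- microbiome -------------------------------------------------------
    base_log = rng.normal(0.0, 1.0, size=T)
    info_taxa = np.arange(cfg.n_informative_taxa)
    logits = np.tile(base_log, (n, 1))
    logits += rng.normal(0.0, cfg.taxa_noise_sigma, size=(n, T))
    logits[:, info_taxa] += cfg.taxa_shift * z[:, None]
    # planted-pair taxa get their relative abundance directly: a lognormal
    # share in the shared factor.  Routing them through the softmax would
    # couple them to every other taxon's noise via the normalizer and make
    # the target correlation unreachable.
    s = _PAIR_FACTOR_LOADING
    pair_share = _PAIR_MEAN_SHARE * np.exp(s * taxon_signal - s**2 / 2)
    pair_total = pair_share.sum(axis=1)
    if (pair_total >= 0.9).any():
        raise ValueError("planted-pair taxa would dominate the composition")
    rest = np.ones(T, dtype=bool)
    rest[pair_taxa] = False
    probs = np.zeros((n, T))
    w = np.exp(logits[:, rest] - logits[:, rest].max(axis=1, keepdims=True))
    probs[:, rest] = w / w.sum(axis=1, keepdims=True) * (1 - pair_total)[:, None]
    probs[:, pair_taxa] = pair_share
    depths = np.maximum(
        rng.lognormal(
            np.log(cfg.mean_library_size) - cfg.library_size_sigma**2 / 2,
            cfg.library_size_sigma,
            size=n,
        ).round().astype(int),
        100,
    )
    counts = np.empty((n, T), dtype=float)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    # --- survival ---------------------------------------------------------
    hazards = cfg.baseline_hazard * cfg.hazard_ratio ** z.astype(float)
    latent_t = rng.exponential(1.0 / hazards)
    group_w = np.bincount(z, minlength=K) / n
    group_h = cfg.baseline_hazard * cfg.hazard_ratio ** np.arange(K, dtype=float)
    u = _calibrate_censoring(group_h, group_w, cfg.censoring_rate)
    if np.isinf(u):
        time = latent_t
        event = np.ones(n, dtype=int)
    else:
        cens = rng.uniform(0.0, u, size=n)
        event = (latent_t <= cens).astype(int)
        time = np.minimum(latent_t, cens)
    time = np.maximum(time, 1e-6)

    # --- stage ------------------------------------------------------------
    # subtype k is pulled toward stage index min(k * 3 // max(K-1, 1), 3)
    stage = np.empty(n, dtype=object)
    targets = np.minimum(
        (np.arange(K) * 3) // max(K - 1, 1), 3
    )
    tilted = rng.random(n) < cfg.stage_association
    base_draw = rng.choice(4, size=n, p=_BASE_STAGE_P)
    for i in range(n):
        idx = targets[z[i]] if tilted[i] else base_draw[i]
        stage[i] = _STAGE_NAMES[idx]
    age = rng.normal(62.0, 11.0, size=n).clip(18.0, 95.0).round(1)

    cohort = Cohort(
        transcriptome=OmicsMatrix(sample_ids, gene_ids, expr, TRANSCRIPTOME),
        microbiome=OmicsMatrix(sample_ids, taxon_ids, counts, MICROBIOME),
        survival=SurvivalTable(sample_ids, time, event),
        clinical=ClinicalTable(sample_ids, list(stage), age),
        cancer_label="synthetic",
    )
    return SyntheticDataset(
        cohort=cohort,
        truth_labels=z,
        truth_gene_ids=[gene_ids[j] for j in info_genes],
        truth_taxon_ids=[taxon_ids[j] for j in info_taxa],
        truth_pairs=[
            (gene_ids[g], taxon_ids[t]) for g, t in zip(pair_genes, pair_taxa)
        ],
        config=cfg,
    )


def default_fixture(seed: int = 42) -> SyntheticDataset:
    """The documented standard test cohort: n=200, 500 genes (50 informative,
    shift 1.5 sd), 150 taxa (20 informative), K=2, hazard ratio 3, 30%
    censoring, 10 planted pairs at r=0.95, stage association 0.7."""
    return generate_cohort(SyntheticConfig(seed=seed))


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A structure-free cohort: no omic effects, flat hazard."""
    cfg = SyntheticConfig(
        effect_size_genes=0.0,
        taxa_shift=0.0,
        hazard_ratio=1.0,
        stage_association=0.0,
        n_corr_pairs=0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write the four standard TSV tables plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_omics_table(dataset.cohort.transcriptome, out / "expression.tsv")
    write_omics_table(dataset.cohort.microbiome, out / "microbiome.tsv")
    write_survival_table(dataset.cohort.survival, out / "survival.tsv")
    write_clinical_table(dataset.cohort.clinical, out / "clinical.tsv")
    truth = {
        "labels": {
            s: int(l)
            for s, l in zip(dataset.cohort.sample_ids, dataset.truth_labels)
        },
        "informative_genes": dataset.truth_gene_ids,
        "informative_taxa": dataset.truth_taxon_ids,
        "correlated_pairs": dataset.truth_pairs,
        "config": asdict(dataset.config),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
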