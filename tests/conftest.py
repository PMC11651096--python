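import numpy as np
import pytest

from omicsurv import (
    PipelineConfig,
    TrainingConfig,
    default_fixture,
    run_pipeline,
)
from omicsurv.ae_ensemble import LatentMatrix
from omicsurv.core_io import SurvivalTable
from omicsurv.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def fixture_dataset():
    """The documented standard synthetic cohort (n=200, K=2, HR=3)."""
    return default_fixture(42)


@pytest.fixture(scope="session")
def small_dataset():
    """A light cohort for tests that train autoencoders repeatedly."""
    return generate_cohort(
        SyntheticConfig(
            n_samples=80,
            n_genes=60,
            n_taxa=40,
            n_informative_genes=15,
            n_informative_taxa=8,
            effect_size_genes=2.5,
            taxa_shift=1.5,
            n_corr_pairs=3,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def fast_training():
    return TrainingConfig(max_epochs=60)


@pytest.fixture(scope="session")
def fixture_pipeline_result(fixture_dataset):
    """One full pipeline run on the standard cohort, shared across tests."""
    cfg = PipelineConfig(
        ensemble_size=5,
        seed=0,
        run_associations=False,
        run_network=False,
    )
    return run_pipeline(fixture_dataset.cohort, cfg)


def make_survival(n, seed=0, censor=0.3, scale=500.0):
    rng = np.random.default_rng(seed)
    t = rng.exponential(scale, n).clip(1e-3)
    e = (rng.random(n) > censor).astype(int)
    ids = [f"S{i:04d}" for i in range(n)]
    return SurvivalTable(ids, t, e)


def make_latent(values, omic="transcriptome"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return LatentMatrix(
        [f"S{i:04d}" for i in range(n)],
        [f"{omic}|f{j:04d}" for j in range(p)],
        values,
    )
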