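import numpy as np
import pytest

from popconn.config import TrainConfig
from popconn.synthetic import CohortSpec, generate_cohort
from popconn.training import cross_validate, prepare_data


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 subjects, 3 sites, two small atlases; cheap enough for every test."""
    spec = CohortSpec(
        n_subjects=24, n_sites=3, atlas_sizes=(6, 8), n_timepoints=40,
        effect_pairs=((0, (1, 4)), (1, (2, 6))), effect_size=1.0, seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_config():
    cfg = TrainConfig(
        epochs=8, n_folds=3, patience=8, early_stop_start=6,
        embed_dim=8, proj_dim=8, learning_rate=1e-3,
    )
    cfg.taa.hidden = 8
    cfg.gcn.hidden = 8
    return cfg


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort, tiny_config):
    return prepare_data(tiny_cohort, tiny_config)


@pytest.fixture(scope="session")
def single_atlas_cv():
    """Small trained single-atlas cross-validation shared by the
    explainability tests: 40 subjects, one 6-ROI atlas, planted pair (1, 4)."""
    spec = CohortSpec(
        n_subjects=40, n_sites=2, atlas_sizes=(6,), n_timepoints=80,
        effect_pairs=((0, (1, 4)),), effect_size=2.0, seed=9,
    )
    cfg = TrainConfig(
        epochs=15, n_folds=3, patience=15, early_stop_start=12,
        embed_dim=8, proj_dim=8, learning_rate=1e-3, seed=9,
    )
    cfg.taa.hidden = 8
    cfg.gcn.hidden = 8
    bundle = prepare_data(generate_cohort(spec), cfg)
    cv = cross_validate(bundle, cfg)
    return cv, bundle


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
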