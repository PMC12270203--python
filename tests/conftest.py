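"""Shared fixtures: the synthetic study set and the desk-scale GAN run."""

from __future__ import annotations

import numpy as np
import pytest

import pepgan as pg

#: seeds of the frozen study fixture (training and held-out draws)
FIXTURE_SEED = 1
HELDOUT_SEED = 2


@pytest.fixture(scope="session")
def study_set() -> pg.PeptideDataset:
    """1,000-peptide synthetic fixture: 500 strong / 500 weak, enrichment 0.8."""
    return pg.generate_dataset(pg.SyntheticConfig(n_strong=500, n_weak=500, seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def held_out() -> pg.PeptideDataset:
    return pg.generate_dataset(pg.SyntheticConfig(n_strong=500, n_weak=500, seed=HELDOUT_SEED))


@pytest.fixture(scope="session")
def featurizer(study_set) -> pg.Featurizer:
    return pg.Featurizer.fit(study_set.subset(label="strong"))


@pytest.fixture(scope="session")
def desk_gan(study_set, held_out, featurizer):
    """Desk-scale adversarial run under the frozen study conditions."""
    cfg = pg.GANConfig.desk_scale(seed=0)
    state, trace = pg.train(
        pg.init_gan(cfg), study_set.subset(label="strong"), cfg,
        featurizer=featurizer, eval_set=held_out,
    )
    return state, trace


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
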