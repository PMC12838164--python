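"""Shared fixtures: small synthetic studies built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from confvar import synthetic as syn
from confvar.features import build_feature_matrix, standardize
from confvar.synthetic import GeneratorConfig, toy_motif


@pytest.fixture(scope="session")
def motif():
    return toy_motif()


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced study design: 6 variants x 1 depth x 2 seeds x 64 frames."""
    return GeneratorConfig(n_depths=1, n_seeds_per_depth=2,
                           n_frames_per_seed=64, rng_seed=0)


@pytest.fixture(scope="session")
def small_study(small_config, motif):
    """(conformers, targets, feature_matrix) for the reduced study."""
    conformers, targets = syn.generate_study(small_config)
    fm = build_feature_matrix(conformers, motif, syn.energy_table(targets),
                              small_config.labels())
    return conformers, targets, fm


@pytest.fixture(scope="session")
def small_fm(small_study):
    return small_study[2]


@pytest.fixture(scope="session")
def small_fm_std(small_fm):
    fm_std, scaler = standardize(small_fm)
    return fm_std, scaler


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
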