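"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

import gradlex as gx


@pytest.fixture(scope="session")
def tiny_cfg():
    return gx.SimConfig(
        n_words=400,
        n_sentences=20,
        n_parcels_per_hemi=30,
        n_subjects=5,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_lexicon(tiny_cfg):
    return gx.simulate_lexicon(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_embeddings(tiny_cfg, tiny_lexicon):
    return gx.simulate_embeddings(tiny_lexicon, tiny_cfg)


@pytest.fixture(scope="session")
def tiny_events(tiny_cfg, tiny_lexicon, tiny_embeddings):
    return gx.simulate_sentences(tiny_lexicon, tiny_embeddings, tiny_cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cfg, tiny_lexicon, tiny_embeddings, tiny_events):
    return gx.build_feature_table(tiny_events, tiny_lexicon, tiny_embeddings)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_cfg):
    return gx.simulate_atlas(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_sensitivities(tiny_cfg, tiny_atlas):
    return {
        p: gx.simulate_effect_profile(
            tiny_atlas,
            gx.TrueProfile(p, "linear", intercept=0.0, slope=0.5, noise_sd=0.1),
            tiny_cfg,
        )
        for p in gx.PARAMETERS
    }


@pytest.fixture(scope="session")
def tiny_trials(tiny_cfg, tiny_features, tiny_sensitivities):
    return gx.simulate_meg_trials(tiny_features, tiny_sensitivities, tiny_cfg)


@pytest.fixture(scope="session")
def tiny_maps(tiny_trials, tiny_features):
    return gx.fit_mass_lmm(tiny_trials, tiny_features)


@pytest.fixture(scope="session")
def tiny_spins(tiny_atlas):
    return gx.generate_spins(tiny_atlas, n_perm=99, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260401)
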