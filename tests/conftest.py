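"""Shared fixtures: a down-scaled synthetic cohort used across test modules.

The small cohort (8 slices, 80 volumes, 3 subjects) keeps the full model
structure — four segments, all confound families, physiological logs — at a
fraction of the full acquisition size, so orchestration tests stay fast.
"""

import numpy as np
import pytest

import cordconn as cc


SMALL_KW = dict(nz=8, segment_boundaries=(0, 2, 4, 6, 8), n_volumes=80,
                n_subjects=3, seed=123)


@pytest.fixture(scope="session")
def small_config():
    return cc.SimConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return cc.make_atlas(small_config)


@pytest.fixture(scope="session")
def prob_masks(small_atlas):
    return cc.build_prob_horn_masks(small_atlas.gm)


@pytest.fixture(scope="session")
def cog_masks(prob_masks):
    return cc.build_cog_horn_masks(prob_masks)


@pytest.fixture(scope="session")
def one_subject(small_config, small_atlas):
    """(Fmri4D, PhysioRecording, GroundTruth) for a single small subject."""
    return cc.simulate_subject(small_atlas, small_config, seed=7)


@pytest.fixture(scope="session")
def small_assets(small_config, small_atlas, prob_masks, cog_masks):
    """Prepared pipeline assets for the three-small-subject cohort."""
    assets = []
    for i, seed in enumerate(cc.synthetic.subject_seeds(small_config)):
        fmri, physio, _ = cc.simulate_subject(small_atlas, small_config,
                                              seed=seed)
        assets.append(cc.prepare_subject(
            fmri, physio, small_atlas, prob_masks, cog_masks,
            task_times=small_config.task_times(), subject=f"sub-{i + 1:02d}"))
    return assets


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
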