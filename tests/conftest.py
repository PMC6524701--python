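"""Shared fixtures: a tiny corpus for unit tests, the full default study
cohort (7 subjects, 9 tasks, 10 x 10 s trials) for end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from earauth import (
    GeneratorConfig,
    ProtocolConfig,
    build_features,
    make_study_corpus,
    make_study_profiles,
    montage,
    run_full_grid,
    synthesize_corpus,
)

MASTER_SEED = 1


@pytest.fixture(scope="session")
def small_setup():
    """3 subjects x 9 tasks x 4 trials: fast, enough structure for units."""
    protocol = ProtocolConfig(n_trials=4)
    profiles = make_study_profiles(3, seed=7)
    corpus = synthesize_corpus(profiles, protocol=protocol, seed=7)
    return profiles, corpus


@pytest.fixture(scope="session")
def small_corpus(small_setup):
    return small_setup[1]


@pytest.fixture(scope="session")
def small_fm(small_corpus):
    return build_features(small_corpus, montage("left3"))


@pytest.fixture(scope="session")
def study():
    """The full default study conditions under one master seed."""
    profiles, corpus = make_study_corpus(7, seed=MASTER_SEED)
    return profiles, corpus


@pytest.fixture(scope="session")
def study_fm(study):
    return build_features(study[1], montage("left3"))


@pytest.fixture(scope="session")
def study_grid(study):
    """Default-scheme left-ear evaluation grid for the study cohort."""
    return run_full_grid(
        study[1], montages=("left3",), schemes=("default",), seed=MASTER_SEED
    )
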