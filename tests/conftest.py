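"""Shared fixtures: small phantom cohorts and the trained desk-scale models.

The heavyweight parameter-recovery fixture (trained verifier + retriever on a
200-patient phantom) is session-scoped so the acceptance-style tests share
one training run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("no-db", database=None)
hypothesis_settings.load_profile("no-db")

from cxreid.cohort import patient_wise_split
from cxreid.pairs import MiningConfig, assemble_epoch_pairs, mine_positive_pairs
from cxreid.phantom import NuisanceRanges, PhantomConfig, generate_cohort
from cxreid.training import (ImageBank, desk_scale_config, score_pair_set,
                             train_retriever, train_verifier)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """30 patients at default nuisance — cheap input for unit tests."""
    out = tmp_path_factory.mktemp("phantom_small")
    cohort = generate_cohort(PhantomConfig(n_patients=30, canvas_side=64, seed=7), out)
    return cohort


@pytest.fixture(scope="session")
def recovery_setting(tmp_path_factory):
    """The parameter-recovery condition: 200 patients, 64 px, low nuisance."""
    out = tmp_path_factory.mktemp("phantom_recovery")
    cohort = generate_cohort(
        PhantomConfig(n_patients=200, canvas_side=64, seed=1,
                      nuisance=NuisanceRanges().scaled(0.5)), out)
    split = patient_wise_split(cohort, seed=1)
    return cohort, split


@pytest.fixture(scope="session")
def trained_verifier(recovery_setting):
    _, split = recovery_setting
    cfg = desk_scale_config(seed=1)
    positives = mine_positive_pairs(split.train)
    mining = MiningConfig("RNP", 2 * min(positives.size, 700), 1)
    model, history = train_verifier(split, mining, cfg)
    return model, history, cfg


@pytest.fixture(scope="session")
def trained_retriever(recovery_setting):
    _, split = recovery_setting
    cfg = desk_scale_config(seed=1)
    model, history = train_retriever(split, cfg)
    return model, history, cfg


@pytest.fixture(scope="session")
def test_split_bank(recovery_setting):
    _, split = recovery_setting
    return ImageBank(split.test, 64)


def balanced_test_pairs(cohort, n_half_cap=300, seed=99):
    positives = mine_positive_pairs(cohort)
    n = 2 * min(positives.size, n_half_cap)
    return assemble_epoch_pairs(positives, cohort,
                                MiningConfig("FTS", n, seed), 0)
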