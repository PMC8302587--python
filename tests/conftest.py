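"""Shared fixtures: one small simulated cohort with synthesized epochs.

Session-scoped so the expensive simulation/synthesis happens once; tests
must not mutate fixture objects in place.
"""

import numpy as np
import pandas as pd
import pytest

import prederr as pe
from prederr import behavior, erp, synth


@pytest.fixture(scope="session")
def cohort():
    """Six-participant Target Time cohort (default task/agent settings)."""
    return pe.simulate_cohort(6, seed=101)


@pytest.fixture(scope="session")
def features(cohort):
    return pe.pe_feature_table(cohort)


@pytest.fixture(scope="session")
def main_trials(cohort, features):
    """Non-training trials, row-aligned with the reset-index features."""
    return cohort.loc[~cohort["is_training"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def features_reset(features):
    return features.reset_index(drop=True)


@pytest.fixture(scope="session")
def small_layout():
    return synth.ChannelLayout.biosemi64().subset(("Fz", "FCz", "Pz"))


@pytest.fixture(scope="session")
def epochs(main_trials, features_reset, small_layout):
    """Raw synthesized epochs with the three default components."""
    return synth.synthesize_epochs(
        main_trials, features_reset, synth.default_component_set(),
        synth.NoiseSpec(), small_layout, seed=2024)


@pytest.fixture(scope="session")
def clean_epochs(epochs):
    return erp.preprocess_erp(epochs)


@pytest.fixture(scope="session")
def clean_features(clean_epochs, features_reset):
    """Features aligned to the RT-screened epochs."""
    keys = clean_epochs.events[["participant_id", "trial_index"]]
    return keys.merge(features_reset,
                      on=["participant_id", "trial_index"])
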