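import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import immunometh as im

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> im.SimulationConfig:
    return im.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def panel(default_config):
    return im.generate_reference_panel(default_config)


@pytest.fixture(scope="session")
def selected_pairs(panel, default_config):
    pairs, report = im.run_selection(
        panel.beta,
        panel.sample_types,
        panel.signature_a,
        panel.signature_b,
        panel.annotation,
        im.SelectionParams(seed=default_config.seed),
    )
    return pairs, report


@pytest.fixture(scope="session")
def cohort(default_config, panel):
    return im.generate_tumor_cohort(default_config, panel)


@pytest.fixture(scope="session")
def consensus(cohort, selected_pairs, default_config):
    pairs, _ = selected_pairs
    return im.consensus_cluster(
        cohort.beta.loc[pairs["probe_id"]],
        k=3,
        settings=im.ConsensusSettings(seed=default_config.seed),
    )


@pytest.fixture(scope="session")
def centroids(cohort, selected_pairs, consensus):
    pairs, _ = selected_pairs
    return im.build_centroids(cohort.beta, consensus.labels, pairs["probe_id"])


@pytest.fixture(scope="session")
def fresh_cohort(default_config, panel):
    """A second cohort drawn from the same generative model, new samples."""
    return im.generate_tumor_cohort(
        default_config, panel, seed=default_config.seed + 1, sample_prefix="Ext"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
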