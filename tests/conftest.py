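"""Shared fixtures.

The heavy end-to-end studies (replicated mechanism recovery, the large-n
noise calibration, the CV-leakage comparison) are session-scoped: they are
computed once and shared between the acceptance tests that assert different
facets of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from lncloc.experiments import (cohort_config, leakage_study,
                                mechanism_recovery_study, noise_mpv_check)
from lncloc.synthetic import (generate_context_tracks, generate_genome,
                              generate_interactions)

BASE_SEED = 2025


@pytest.fixture(scope="session")
def small_cohort():
    """A small four-mechanism cohort for module-level tests."""
    cfg = cohort_config(seed=BASE_SEED, n_pos=60)
    genome = generate_genome(cfg)
    tracks = generate_context_tracks(cfg, genome)
    imap = generate_interactions(cfg, genome, tracks)
    return cfg, genome, tracks, imap


@pytest.fixture(scope="session")
def recovery_study():
    """Ten replicated cohort runs of the planted-mechanism recovery study."""
    return mechanism_recovery_study(BASE_SEED, n_replicates=10)


@pytest.fixture(scope="session")
def noise_band():
    """Family MPVs of a pure-noise lncRNA at 4200 examples."""
    return noise_mpv_check(seed=BASE_SEED)


@pytest.fixture(scope="session")
def leakage_table():
    """Random-CV vs block-CV AUROCs across 12 seeds."""
    return leakage_study(BASE_SEED, n_seeds=12)


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)
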