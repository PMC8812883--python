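"""Shared fixtures: small deterministic synthetic cohorts."""

import numpy as np
import pytest

import daf_ecog as de
from daf_ecog.config import SynthConfig


@pytest.fixture(scope="session")
def two_archetype():
    return de.make_fixture("two-archetype-minimal")


@pytest.fixture(scope="session")
def flat_null():
    return de.make_fixture("flat-null")


@pytest.fixture(scope="session")
def planted_divergence():
    return de.make_fixture("planted-divergence")


@pytest.fixture(scope="session")
def word_cohort_full():
    """Full signal-path word cohort: one participant, 8 electrodes."""
    cfg = SynthConfig(n_participants=1, task="word", n_trials_per_delay=8,
                      n_electrodes_per_roi={"STG": 3, "vPreCG": 3},
                      noise_sd=0.0, duration_noise_sd=0.0, seed=21)
    trials, electrodes, recs = de.generate_cohort(cfg)
    return {"cfg": cfg, "trials": trials, "electrodes": electrodes,
            "rec": recs["P00"]}


@pytest.fixture(scope="session")
def word_hg_full(word_cohort_full):
    hg = de.compute_high_gamma(word_cohort_full["rec"],
                               word_cohort_full["trials"], "word")
    return {**word_cohort_full, "hg": hg}


def rng(*key):
    return np.random.default_rng(list(key))
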