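"""Shared fixtures: small synthetic subjects and an on-disk cohort."""

from __future__ import annotations

import numpy as np
import pytest

from arousaldyn.conditioning import make_arousal_signals
from arousaldyn.io import load_cohort, write_cohort
from arousaldyn.simulate import SimulationConfig, generate_subject, subject_seed


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small-but-complete simulation: 3 subjects, 600 TR, 60 parcels."""
    return SimulationConfig(n_subjects=3, T=600, R=60, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    """One generated subject: (cortex, subcortical, nuisance, truth)."""
    return generate_subject(small_cfg, subject_seed(small_cfg.seed, 0))


@pytest.fixture(scope="session")
def small_signals(small_subject):
    _, sub, nuis, _ = small_subject
    return make_arousal_signals(
        sub["lc"], sub["bnm"], [nuis["fourth_ventricle"], nuis["pons"]]
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 2-subject cohort written to disk in the manifest layout."""
    cfg = SimulationConfig(n_subjects=2, T=400, R=40, seed=7)
    out = tmp_path_factory.mktemp("cohort")
    manifest = write_cohort(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def cohort_store(cohort_dir):
    return load_cohort(cohort_dir)
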