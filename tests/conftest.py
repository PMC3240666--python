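"""Shared fixtures: small synthetic datasets with known structure."""

import logging

import numpy as np
import pandas as pd
import pytest

from hccstrat.simulate import SimulationConfig, SignatureBlock, \
    generate_cohort
from hccstrat.survival import make_outcome

logging.getLogger("hccstrat").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A 260-patient cohort with one tumor-tissue good-stratum block."""
    cfg = SimulationConfig(
        seed=42, n_patients=260, n_genes=400, n_snps=200, n_eqtl=10,
        n_csnp=4,
        signature_spec=[SignatureBlock("tumor", "good", 40, 1.2, 0.3)])
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n, event_frac=0.5, ids=None):
    """Continuous times (no ties) with a fixed expected event fraction."""
    time = rng.uniform(1.0, 100.0, n)
    event = rng.binomial(1, event_frac, n)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return make_outcome(time, event, ids=ids)


@pytest.fixture()
def outcome_noties(rng):
    return random_survival(rng, 40)
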