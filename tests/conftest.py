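from __future__ import annotations

import numpy as np
import pytest

from triptanpgx.cohort import Cohort, Individual, NON_USER, TABLET_ONLY, USER
from triptanpgx.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Deterministic 300-individual synthetic cohort with missingness."""
    return generate_cohort(default_config(300, seed=11))


@pytest.fixture(scope="session")
def clean_cohort() -> Cohort:
    """Synthetic cohort without missingness or tablet-only individuals."""
    return generate_cohort(default_config(
        400, seed=7, tablet_only_fraction=0.0, missing_rate={}))


def logistic_fixture(n: int, seed: int, k_covariates: int = 1):
    """Deterministic small regression dataset: dosage + covariates + outcome."""
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=n).astype(float)
    covs = rng.integers(0, 2, size=(n, k_covariates)).astype(float)
    eta = -0.4 + 0.6 * dosage + covs @ np.linspace(-0.8, 0.5, k_covariates)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(n), dosage, covs])
    # regenerate until both outcomes present (tiny n could degenerate)
    while y.min() == y.max():
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def hand_cohort() -> Cohort:
    """Six-person cohort with hand-checkable genotypes and answers."""
    g = {
        "rs1024905": ("C", "C"), "rs6724624": ("C", "C"),
        "rs5443": ("C", "T"), "5-HTTLPR": ("L_A", "S"),
        "rs2651899": ("C", "T"),
    }
    inds = [
        Individual("A1", "male", 45.0, USER, genotypes=dict(g),
                   answers={"attack_frequency": ["1-2", "3-5"]}),
        Individual("A2", "female", 50.0, NON_USER,
                   genotypes={**g, "rs5443": ("T", "T")}),
        Individual("A3", "male", 61.0, USER,
                   genotypes={**g, "rs1024905": None}),
        Individual("A4", "female", 38.0, TABLET_ONLY, genotypes=dict(g)),
        Individual("A5", "male", 55.0, NON_USER,
                   genotypes={**g, "rs5443": ("C", "C")}),
        Individual("A6", "female", 47.0, USER, genotypes=dict(g)),
    ]
    return Cohort(inds)
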