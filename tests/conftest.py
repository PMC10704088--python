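"""Shared fixtures: hemoglobin table and session-scoped Monte Carlo bases.

The bases are simulated once per session at reduced photon counts; every test
that needs one reuses it, keeping the whole suite inside a practical runtime
while still exercising the full pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from skindrs import chromophores, engine, forward


@pytest.fixture(scope="session")
def hb_table():
    return chromophores.compile_hemoglobin_table()


@pytest.fixture(scope="session")
def probe():
    return engine.ProbeGeometry()


@pytest.fixture(scope="session")
def fit_basis(probe):
    """Default-grid basis without path storage, for forward/inverse tests."""
    return engine.build_basis(
        t_epi_levels=list(engine.DEFAULT_T_EPI_LEVELS),
        mus_r_levels=list(engine.DEFAULT_MUS_R_LEVELS),
        probe=probe,
        n_photons=20_000,
        seed=42,
        store_paths=False,
    )


@pytest.fixture(scope="session")
def path_basis(probe):
    """Small path-stored basis for sampling-depth tests."""
    return engine.build_basis(
        t_epi_levels=[0.04, 0.09],
        mus_r_levels=[1.0, 2.2, 3.8],
        probe=probe,
        n_photons=40_000,
        seed=47,
        store_paths=True,
    )


@pytest.fixture(scope="session")
def median_params():
    """Cohort-median skin model parameters."""
    return forward.SkinModelParams.from_values(
        alpha=1.99, beta=0.82, gamma=0.31, t_epi=0.063, f_mel=0.05,
        beta_mel=4.3, f_blood_1=0.011, f_blood_2=0.0075, s=0.5,
    )
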