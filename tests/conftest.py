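"""Shared fixtures.

The heavy end-to-end recovery experiment (50 synthetic studies, each fitted
with both the density-linked and the constant-variance model) runs once per
session and feeds several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import dlspop as d


@pytest.fixture(scope="session")
def dls_preset():
    """(design, spec, params) of the published density-linked model."""
    return d.preset("dls_table2")


@pytest.fixture(scope="session")
def constant_preset():
    """(design, spec, params) of the published constant-variance model."""
    return d.preset("constant_table1")


@pytest.fixture(scope="session")
def skeleton_params():
    """Deterministic skeleton of the best-fitting first-order linear model."""
    _, spec, params = d.preset("deterministic_table1")
    return spec, params


@pytest.fixture(scope="session")
def small_study(dls_preset):
    """One seeded synthetic study at the field design size."""
    design, spec, params = dls_preset
    return d.generate_study(design, spec, params, seed=11)


@pytest.fixture(scope="session")
def dls_recovery_fits(dls_preset, constant_preset):
    """50 synthetic studies from the DLS model, each fitted with the DLS and
    the constant-variance specs.  Returns (dls_fits, constant_fits)."""
    design, spec, params = dls_preset
    _, spec_c, _ = constant_preset
    dls_fits, const_fits = [], []
    for rep in range(50):
        plots = d.generate_study(design, spec, params, seed=10_000 + rep)
        ds = d.build_lag_dataset(plots, max_lag=1)
        dls_fits.append(d.fit_ml(ds, spec, n_starts=3, seed=rep))
        const_fits.append(d.fit_ml(ds, spec_c, n_starts=3, seed=rep))
    return dls_fits, const_fits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
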