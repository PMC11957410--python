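"""Shared fixtures.

The expensive artifacts (the reference 128^3 ensemble spectra and the
trained surrogate with its 200-spectrum library) are session-scoped and
shared between the unit suites and the acceptance tests, so each is built
exactly once per run.
"""

import math

import numpy as np
import pytest

from leveledwaves.field import (WaveModelParams, WaveVectorDistribution,
                                build_plane_wave_field, waves_for)

D_REF = 40.0            # Angstroms; reference mean spacing
K0_REF = 2.0 * math.pi / D_REF


def make_params(sigma_k=0.05, gamma=128.0, alpha=0.0, n_waves=1000,
                grid_n=64, box_factor=8, seed=0, d=D_REF):
    dist = WaveVectorDistribution(k0=2.0 * math.pi / d, sigma_k=sigma_k,
                                  gamma=gamma)
    return WaveModelParams(dist=dist, alpha=alpha, n_waves=n_waves,
                           box_factor=box_factor, grid_n=grid_n, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """One well-aligned lamellar field on a 64^3 grid."""
    p = make_params(seed=7)
    return build_plane_wave_field(p, waves_for(p), dtype=np.complex64)


@pytest.fixture(scope="session")
def sponge_field():
    """A nearly isotropic (sponge-like) field on a 64^3 grid."""
    p = make_params(gamma=1.0, sigma_k=0.1, seed=8)
    return build_plane_wave_field(p, waves_for(p), dtype=np.complex64)


@pytest.fixture(scope="session")
def trained_surrogate():
    """Surrogate trained on the 200-spectrum 64^3 library (the desk-scale
    training study); shared by the surrogate, inversion and acceptance
    suites.

    The working model is a two-member seed ensemble (mean log-intensity),
    which suppresses the initialization-dependent part of the spline
    network's approximation error; the returned histories carry each
    member's validation curve.
    """
    from leveledwaves.kan import (SurrogateEnsemble, SurrogateModel,
                                  TrainingConfig, make_library, train)
    lib = make_library(n_samples=200, grid_n=64, n_real=4, seed=42)
    members = []
    histories = []
    for seed in (0, 1):
        model = SurrogateModel(seed=seed)
        model, history = train(model, lib,
                               TrainingConfig(epochs=2500, seed=seed))
        members.append(model)
        histories.append(history)
    return SurrogateEnsemble(members), lib, histories
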