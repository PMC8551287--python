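import numpy as np
import pytest

from ssikit import kernels, simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """3 cycles x 4 families x 20 DH lines, moderate heterogeneity."""
    gmap = simdata.default_map(120, 6)
    plan = simdata.overlapping_plan(
        n_cycles=3, founders_per_cycle=6, n_shared=2,
        families_per_cycle=4, dh_per_family=20, seed=11,
    )
    arch = simdata.sample_architecture(
        n_markers=120, n_qtl=40, n_cycles=3, rho_g=0.4, h2_true=0.5, seed=12
    )
    return simdata.simulate_population(plan, gmap, arch, seed=13)


@pytest.fixture(scope="session")
def small_grm(small_population):
    f = small_population.markers.presence_freq()
    mm = small_population.markers.select_markers((f > 0.02) & (f < 0.98))
    return kernels.additive_kernel(mm)


def random_psd_system(rng, n, lambda0=None):
    """Random PD system (C, g) mimicking a K_TS + lambda0*I problem."""
    p = max(2 * n, 10)
    X = rng.normal(size=(n, p))
    K = X @ X.T / p
    lam0 = lambda0 if lambda0 is not None else rng.uniform(0.3, 2.0)
    C = K + lam0 * np.eye(n)
    g = rng.normal(size=n)
    return C, g, lam0
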