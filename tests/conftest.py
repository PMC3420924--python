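import numpy as np
import pytest

import dimerfes as df


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def double_well_1d():
    """1D double well with exactly known Boltzmann statistics."""
    return df.ModelPotential.double_well(
        centers=(0.7, 1.3), depth=2.0, sigma=0.12, domain=(0.4, 1.6)
    )


@pytest.fixture(scope="session")
def toy_2d():
    """2D (r, θ) potential with two coupled wells and confining walls."""
    return df.ModelPotential.gaussian_wells(
        cv_names=("r", "theta"),
        heights=[-2.5, -1.2],
        centers=[[1.0, 0.5], [1.5, 0.9]],
        sigmas=[[0.10, 0.15], [0.12, 0.15]],
        domain=[[0.3, 0.0], [2.2, 1.4]],
        wall_lo=np.array([0.5, 0.1]),
        wall_hi=np.array([2.0, 1.3]),
        wall_kappa=np.array([1e4, 1e4]),
    )


def harmonic_window_samples(rng, k_pot, k_umb, x0, centers, n, temperature=300.0):
    """Exact Gaussian samples from harmonic potential + harmonic umbrellas."""
    kT = df.kt(temperature)
    windows = []
    for i, c in enumerate(centers):
        k_tot = k_pot + k_umb
        mean = (k_pot * x0 + k_umb * c) / k_tot
        sd = np.sqrt(kT / k_tot)
        r = rng.normal(mean, sd, n)
        ws = df.WeightedSamples(r=r, weights=np.ones(n), window_index=i)
        windows.append(
            (df.UmbrellaWindow(center=float(c), force_constant=k_umb, index=i),
             ws)
        )
    return windows
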