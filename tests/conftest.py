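import numpy as np
import pytest

import sitekit as sk


@pytest.fixture(scope="session")
def toy_layer():
    return sk.generate_toy_layer(73, 4.0, seed=1)


@pytest.fixture(scope="session")
def fibril_single(toy_layer):
    """One-layer model: the template itself, axis +z."""
    return sk.build_supercell(toy_layer, 1, rise=0.48, twist=0.973)


@pytest.fixture(scope="session")
def fibril_stack(toy_layer):
    """Ten-layer 2-fold screw stack with the tau-like twist."""
    return sk.build_supercell(toy_layer, 10, rise=0.48, twist=0.973)


@pytest.fixture(scope="session")
def double_well_oracle():
    """Canonical analytic double-well + umbrella windows for WHAM tests.

    Stiff springs (k well above the barrier curvature) keep every biased
    window density unimodal, and window centers span the closed domain so
    all bins are covered.
    """
    pot = sk.AnalyticPotential.double_well(
        barrier=3.0, half_separation=0.35, tilt=1.0, domain=(-0.44, 0.44)
    )
    centers = np.linspace(-0.44, 0.44, 25)
    windows = sk.generate_umbrella_windows(
        pot, centers, k_umb=600.0, n_samples=5000, seed=42
    )
    return pot, windows
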