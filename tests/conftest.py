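import numpy as np
import pytest

from foldhelix import (EnsembleSpec, HelixSpec, build_ideal_helix,
                       generate_ensemble)


@pytest.fixture(scope="session")
def ideal_base():
    """The reference 18-unit ideal helix (36 deg per unit, 3.5 Å rise)."""
    return build_ideal_helix(HelixSpec())


@pytest.fixture(scope="session")
def ideal_traj(ideal_base):
    """Single-frame trajectory of the ideal helix."""
    return generate_ensemble(ideal_base, EnsembleSpec(n_frames=1, seed=0))


@pytest.fixture(scope="session")
def small_ensemble(ideal_base):
    """A modest fluctuating ensemble with known elastic ground truth."""
    spec = EnsembleSpec(n_frames=400, sigma_twist=3.0, lp_bend=500.0,
                        sigma_rise=0.1, seed=42)
    return generate_ensemble(ideal_base, spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
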