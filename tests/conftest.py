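import numpy as np
import pytest

import vortexmelt as vm


@pytest.fixture(scope="session")
def small_params():
    """Cheap solver configuration used by several unit tests."""
    return vm.ModelParams(
        lambda_adv=0.0, alpha=-0.8, beta=0.01, L=20 * np.pi, N=32, dt=0.01
    )


@pytest.fixture(scope="session")
def tri_fixture():
    """Exactly commensurate (rectangular torus) triangular lattice."""
    return vm.triangular_lattice_points(L=20.0, a=1.0, seed=0, rectangular=True)


@pytest.fixture(scope="session")
def tri_fixture_square():
    """Triangular lattice on a square torus (slightly compressed rows)."""
    return vm.triangular_lattice_points(L=20.0, a=1.0, seed=0)
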