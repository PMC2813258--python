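import numpy as np
import pytest

from foveamap import ModelParams, VisualAreaMap


@pytest.fixture(scope="session")
def defaults() -> ModelParams:
    """Canonical parameter set (k=20, a=1.05, b=90, lam=0.4)."""
    return ModelParams()


@pytest.fixture(scope="session")
def conformal_wedge() -> VisualAreaMap:
    """Classical log-polar (conformal dipole) wedge model."""
    return VisualAreaMap(ModelParams(variant="dipole"), banded=False)


@pytest.fixture(scope="session")
def sheared_wedge() -> VisualAreaMap:
    """Meridionally isotropic (double-sech style) dipole wedge model."""
    return VisualAreaMap(ModelParams(variant="sheared_dipole"), banded=False)


@pytest.fixture(scope="session")
def banded_model() -> VisualAreaMap:
    """Full banded sheared-dipole model at canonical parameters."""
    return VisualAreaMap(ModelParams(variant="sheared_dipole"), banded=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
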