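import numpy as np
import pytest

from qprm import (AcquisitionConfig, ProbeModel, SpinSpecies, build_spectrum,
                  fit_decay, roi_aggregate)


@pytest.fixture
def probe():
    return ProbeModel()


@pytest.fixture
def cu():
    return SpinSpecies.hexaaqua_cu()


@pytest.fixture
def surface():
    return SpinSpecies.surface_bath()


@pytest.fixture
def small_acq():
    """Compact acquisition: 12 log-spaced tau points, default photon budget."""
    return AcquisitionConfig(tau_grid=np.geomspace(1e-6, 3e-3, 12), seed=0)


def fov_spectrum(sweep, provenance="FOV"):
    """FOV-summed decay fit per field -> rate spectrum (shared test helper)."""
    results = []
    for B0, stack in sweep:
        ny, nx = stack.shape
        curve = roi_aggregate(stack, (0, ny, 0, nx))
        results.append((B0, fit_decay(stack.tau, curve)))
    return build_spectrum(results, provenance=provenance)
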