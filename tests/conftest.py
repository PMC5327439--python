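import logging

import numpy as np
import pytest

from phasect import (
    AcquisitionGeometry,
    PhantomObject,
    RegularizationParams,
    build_phantom,
    retrieve_stack,
    simulate_scan,
)

# clamp/QC messages are expected in many tests; keep the output readable
logging.getLogger("phasect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def inverse_geometry() -> AcquisitionGeometry:
    """High-resolution inverse geometry (z1 >> z2), ~1 um effective pixel."""
    return AcquisitionGeometry(mode="inverse", z1=2000.0, z2=10.0, detector_pixel=1.0)


@pytest.fixture(scope="session")
def contact_geometry() -> AcquisitionGeometry:
    """Essentially zero propagation distance: pure attenuation imaging."""
    return AcquisitionGeometry(mode="parallel", z1=2000.0, z2=1e-9, detector_pixel=1.0)


@pytest.fixture(scope="session")
def three_cell_phantom(inverse_geometry):
    objs = [
        PhantomObject("cell", (20, 25, 35), (6, 6, 6), 2e-6, 4e-8),
        PhantomObject("cell", (44, 38, 20), (5, 8, 5), 2e-6, 4e-8),
        PhantomObject("cell", (32, 20, 44), (4, 4, 4), 2e-6, 4e-8),
    ]
    return build_phantom(
        "disk_stack", 64, objects=objs, voxel_size=inverse_geometry.effective_pixel
    )


@pytest.fixture(scope="session")
def clean_scan(three_cell_phantom, inverse_geometry):
    """Noise-free 100-angle near-field scan of the three-cell phantom."""
    return simulate_scan(three_cell_phantom, inverse_geometry, 100, noise=False, seed=1)


@pytest.fixture(scope="session")
def contrast_stack(clean_scan):
    from phasect.retrieval import matched_alpha

    alpha = matched_alpha(clean_scan.geometry, 50.0)
    stack, qc = retrieve_stack(clean_scan, RegularizationParams(alpha=alpha, gamma=1.0))
    return stack


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
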