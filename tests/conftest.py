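import numpy as np
import pytest

from hippomre.fields import ComplexModulusField
from hippomre.forward import (
    ForwardConfig,
    add_noise,
    restrict_field,
    solve_time_harmonic,
)
from hippomre.phantom import make_phantom, reference_phantom_spec


@pytest.fixture(scope="session")
def ref_phantom():
    """Reference two-region phantom on the 1.6 mm inversion grid."""
    spec = reference_phantom_spec(grid_shape=(40, 40), voxel_size_mm=1.6)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ref_measurement(ref_phantom):
    """Noisy measurements of the reference phantom from two drive faces.

    Data are simulated on a 2x finer grid (0.8 mm) and restricted to the
    inversion grid to avoid the inverse crime; 1% RMS Gaussian noise is
    added per experiment.
    """
    spec_fine = reference_phantom_spec(grid_shape=(79, 79), voxel_size_mm=0.8)
    props_fine, _ = make_phantom(spec_fine)
    experiments = [
        ForwardConfig(drive_axis=0, drive_side=0),
        ForwardConfig(drive_axis=1, drive_side=0),
    ]
    fields = []
    for i, exp in enumerate(experiments):
        f = restrict_field(solve_time_harmonic(props_fine, exp), 2)
        rms = float(np.sqrt(np.mean(np.abs(f.u) ** 2)))
        fields.append(add_noise(f, 0.01 * rms, seed=100 + i))
    return fields, experiments


@pytest.fixture()
def homogeneous_props():
    return ComplexModulusField(
        np.full((32, 32), 2000.0), np.full((32, 32), 700.0), 1.6
    )
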