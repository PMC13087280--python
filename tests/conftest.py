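import numpy as np
import pytest

from echogen.synthetic import (DatasetConfig, build_paired_dataset,
                               simulate_reference_frame, simulate_rf_frame)
from echogen.types import AcousticRegion, GridSpec, PhantomScene, PulseModel


@pytest.fixture(scope="session")
def pulse():
    return PulseModel()


@pytest.fixture(scope="session")
def desk_grid():
    return GridSpec(n_axial=512, n_lines=128, lateral_pitch_mm=0.3125)


@pytest.fixture(scope="session")
def wide_grid():
    """Homogeneous-recovery grid: >= 200 lines for spectral averaging."""
    return GridSpec(n_axial=512, n_lines=256, lateral_pitch_mm=0.3125)


@pytest.fixture(scope="session")
def reference_frame(pulse, wide_grid):
    return simulate_reference_frame(pulse, wide_grid, seed=7)


@pytest.fixture(scope="session")
def homogeneous_frame(pulse, wide_grid):
    """a_eff = 75 um, n = 10 / mm^2, alpha = 1 dB/MHz/cm."""
    bg = AcousticRegion(a_eff_um=75.0, density_per_mm2=10.0,
                        attenuation_db_mhz_cm=1.0)
    return simulate_rf_frame(PhantomScene(regions=(bg,), seed=3), pulse,
                             wide_grid)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 lesions per class x 4 planes on the desk grid."""
    return build_paired_dataset(DatasetConfig(n_lesions_per_class=2,
                                              n_planes=4), seed=11)
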