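import numpy as np
import pytest

from plaqueifem.materials import neo_hookean
from plaqueifem.phantom import annular_mesh
from plaqueifem.ultrasound import ImagingConfig, RFFrame, render_rf, seed_scatterers
from plaqueifem.phantom import CrossSectionPhantom, LABELS


@pytest.fixture(scope="session")
def fit_table():
    from plaqueifem.reporting import packaged_fit_table
    return packaged_fit_table()


@pytest.fixture(scope="session")
def imaging():
    return ImagingConfig()


@pytest.fixture(scope="session")
def block_phantom():
    """A plain rectangular slab of intima tissue for speckle experiments."""
    px = 0.02
    mask = np.full((150, 120), LABELS["intima"], dtype=np.uint8)
    return CrossSectionPhantom(label_mask=mask, pixel_size=px,
                               origin=(-1.2, -1.5), contours=None, seed=0)


@pytest.fixture(scope="session")
def speckle_frames(block_phantom, imaging):
    """Reference speckle frame + frames shifted axially by 5 and 0.3 samples,
    rendered from one scatterer realization (frames big enough for the
    default tracking windows)."""
    scat = seed_scatterers(block_phantom, 2500.0, seed=11)
    extent = (-1.2, 1.2, -1.5, 1.5)
    pitch_mm = imaging.axial_pitch_um * 1e-3

    def shifted(samples):
        shift = samples * pitch_mm
        return render_rf(scat, lambda p: np.tile([0.0, shift], (len(p), 1)),
                         imaging, extent, pressure_mmhg=20.0)

    ref = render_rf(scat, None, imaging, extent, pressure_mmhg=10.0)
    return {"ref": ref, "int5": shifted(5), "sub03": shifted(0.3)}


@pytest.fixture(scope="session")
def annulus_solution():
    """Neo-Hookean annulus inflated to 80/100/120 mmHg on a medium mesh."""
    from plaqueifem.fem import InflationProtocol, solve_inflation

    mesh = annular_mesh(1.5, 3.0, 12, 72)
    mat = neo_hookean(30.0)
    sol = solve_inflation(mesh, {"wall": mat},
                          InflationProtocol.from_mmhg((80.0, 100.0, 120.0)))
    return mesh, mat, sol
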