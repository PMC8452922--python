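"""Synthetic RF speckle frames of a deforming cross-section.

A scatterer field is seeded uniformly over the tissue components of a
phantom; each frame is the superposition of a separable point-spread
function centered at the (displaced) scatterer positions:

* axially, a Gaussian-windowed cosine at the two-way RF spatial frequency
  ``2 fc / c`` (a 40 MHz pulse in soft tissue oscillates every
  c / (2 fc) ~ 19.25 um of depth);
* laterally, a Gaussian beam profile.

The simulator works directly in space (the time axis and beamforming are
abstracted away); frames are deterministic given scatterers and displacement
field, and optional additive white noise exercises tracking robustness.
Default pitches (2.75 um axial, 27.5 um lateral) are chosen so that the
standard tracking window sizes map to integer sample counts.

Axial = image depth = the +y direction of phantom/mesh coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .phantom import CrossSectionPhantom, LABELS

__all__ = ["ImagingConfig", "RFFrame", "ScattererField", "seed_scatterers",
           "render_rf", "simulate_sequence", "save_rf_sequence", "load_rf_sequence"]

_TISSUE_LABELS = (LABELS["intima"], LABELS["wall"], LABELS["lipid"], LABELS["calcium"])


@dataclass(frozen=True)
class ImagingConfig:
    center_frequency_mhz: float = 40.0
    speed_of_sound_m_s: float = 1540.0
    axial_pitch_um: float = 2.75
    lateral_pitch_um: float = 27.5
    pulse_sigma_um: float = 12.0    # axial Gaussian envelope of the pulse
    beam_sigma_um: float = 60.0     # lateral Gaussian beam width
    noise_snr_db: float | None = None  # additive white noise; None = clean

    @property
    def rf_wavelength_um(self) -> float:
        """Two-way RF oscillation period along depth: c / (2 fc)."""
        return self.speed_of_sound_m_s / (2.0 * self.center_frequency_mhz)

    def __post_init__(self):
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ConfigurationError("pitches must be > 0")
        if self.axial_pitch_um > self.rf_wavelength_um / 2.0:
            raise ConfigurationError(
                f"axial pitch {self.axial_pitch_um} um undersamples the "
                f"{self.rf_wavelength_um:.2f} um RF wavelength (Nyquist)")


@dataclass
class RFFrame:
    samples: np.ndarray            # (n_axial, n_lateral) real RF
    axial_pitch_um: float
    lateral_pitch_um: float
    center_frequency_mhz: float
    pressure_mmhg: float
    origin_mm: tuple = (0.0, 0.0)  # (x, y) of sample (0, 0)

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ConfigurationError("RF samples must be finite")
        self.samples = s

    @property
    def shape(self):
        return self.samples.shape


@dataclass(frozen=True)
class ScattererField:
    positions_mm: np.ndarray       # (N, 2) reference (x, y)
    amplitudes: np.ndarray         # (N,) ~ N(0, 1)
    seed: int


def seed_scatterers(phantom: CrossSectionPhantom, density_per_mm2: float,
                    seed: int = 0) -> ScattererField:
    """Poisson-seed point scatterers uniformly over the tissue components.

    Candidates are drawn in the mask bounding box and thinned by label, so
    the kept count is Poisson with mean density x tissue area.
    """
    if density_per_mm2 < 0:
        raise ConfigurationError("density must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = phantom.label_mask.shape
    px = phantom.pixel_size
    box_area = (h * px) * (w * px)
    n = rng.poisson(density_per_mm2 * box_area) if density_per_mm2 > 0 else 0
    xy = rng.uniform(size=(n, 2)) * np.array([w * px, h * px]) + np.array(phantom.origin)
    cols = np.clip(((xy[:, 0] - phantom.origin[0]) / px).astype(int), 0, w - 1)
    rows = np.clip(((xy[:, 1] - phantom.origin[1]) / px).astype(int), 0, h - 1)
    keep = np.isin(phantom.label_mask[rows, cols], _TISSUE_LABELS)
    return ScattererField(positions_mm=xy[keep],
                          amplitudes=rng.standard_normal(int(keep.sum())),
                          seed=seed)


def render_rf(scatterers: ScattererField, displacement_mm, imaging: ImagingConfig,
              extent_mm, pressure_mmhg: float = 0.0,
              noise_rng: np.random.Generator | None = None) -> RFFrame:
    """Render one RF frame of the displaced scatterer field.

    ``displacement_mm`` is None (reference) or a callable mapping (N, 2)
    reference positions to (N, 2) displacements; scatterers whose
    displacement evaluates to NaN (outside the solved mesh) are dropped
    with a warning.  ``extent_mm`` is (xmin, xmax, ymin, ymax) of the image.
    """
    xmin, xmax, ymin, ymax = extent_mm
    dz = imaging.axial_pitch_um * 1e-3
    dx = imaging.lateral_pitch_um * 1e-3
    nz = int(np.round((ymax - ymin) / dz)) + 1
    nx = int(np.round((xmax - xmin) / dx)) + 1

    pos = scatterers.positions_mm
    amp = scatterers.amplitudes
    if displacement_mm is not None and len(pos):
        disp = np.asarray(displacement_mm(pos), dtype=float)
        bad = ~np.all(np.isfinite(disp), axis=1)
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} scatterers outside the "
                          "displacement field", stacklevel=2)
            pos, amp, disp = pos[~bad], amp[~bad], disp[~bad]
        pos = pos + disp

    frame = np.zeros((nz, nx))
    if len(pos):
        sz = imaging.pulse_sigma_um * 1e-3
        sx = imaging.beam_sigma_um * 1e-3
        wavelength = imaging.rf_wavelength_um * 1e-3
        hz = int(np.ceil(3.0 * sz / dz))
        hx = int(np.ceil(3.0 * sx / dx))
        iz = np.round((pos[:, 1] - ymin) / dz).astype(int)
        ix = np.round((pos[:, 0] - xmin) / dx).astype(int)
        inside = (iz >= -hz) & (iz < nz + hz) & (ix >= -hx) & (ix < nx + hx)
        pos, amp, iz, ix = pos[inside], amp[inside], iz[inside], ix[inside]
        # local patches, vectorized over scatterers in chunks
        oz = np.arange(-hz, hz + 1)
        ox = np.arange(-hx, hx + 1)
        for lo in range(0, len(pos), 4096):
            sl = slice(lo, lo + 4096)
            zi = iz[sl][:, None] + oz[None, :]                     # (n, 2hz+1)
            xi = ix[sl][:, None] + ox[None, :]
            zc = ymin + zi * dz - pos[sl, 1][:, None]              # depth offset
            xc = xmin + xi * dx - pos[sl, 0][:, None]
            ax = np.exp(-0.5 * (zc / sz) ** 2) * np.cos(2 * np.pi * zc / wavelength)
            lat = np.exp(-0.5 * (xc / sx) ** 2)
            patch = amp[sl][:, None, None] * ax[:, :, None] * lat[:, None, :]
            zok = (zi >= 0) & (zi < nz)
            xok = (xi >= 0) & (xi < nx)
            zi_c = np.clip(zi, 0, nz - 1)
            xi_c = np.clip(xi, 0, nx - 1)
            flat = (zi_c[:, :, None] * nx + xi_c[:, None, :]).ravel()
            vals = (patch * zok[:, :, None] * xok[:, None, :]).ravel()
            np.add.at(frame.ravel(), flat, vals)

    if imaging.noise_snr_db is not None:
        if noise_rng is None:
            noise_rng = np.random.default_rng(scatterers.seed + 1)
        power = float(np.mean(frame**2))
        sigma = np.sqrt(power * 10 ** (-imaging.noise_snr_db / 10.0))
        frame = frame + sigma * noise_rng.standard_normal(frame.shape)

    return RFFrame(samples=frame, axial_pitch_um=imaging.axial_pitch_um,
                   lateral_pitch_um=imaging.lateral_pitch_um,
                   center_frequency_mhz=imaging.center_frequency_mhz,
                   pressure_mmhg=pressure_mmhg, origin_mm=(xmin, ymin))


def simulate_sequence(phantom: CrossSectionPhantom, displacement_by_pressure: dict,
                      imaging: ImagingConfig, seed: int = 0,
                      density_per_mm2: float = 2000.0,
                      margin_mm: float = 1.0, reference_pressure_mmhg: float = 10.0
                      ) -> list:
    """Render one frame per pressure step with a shared scatterer field.

    ``displacement_by_pressure`` maps pressure (mmHg) to a displacement
    callable (or None for the reference); the reference frame is generated
    for ``reference_pressure_mmhg`` with zero displacement.  Frames are
    returned ordered by pressure.  ``margin_mm`` pads the image beyond the
    tissue bounding box so large tracking kernels stay inside the frame.
    """
    scat = seed_scatterers(phantom, density_per_mm2, seed)
    xmin, xmax, ymin, ymax = phantom.tissue_bbox()
    extent = (xmin - 0.3, xmax + 0.3, ymin - margin_mm, ymax + margin_mm)
    items = [(reference_pressure_mmhg, None)]
    items += sorted(displacement_by_pressure.items())
    frames = []
    for k, (p_mmhg, disp) in enumerate(items):
        rng = np.random.default_rng((seed + 7919 * k) % (2**31 - 1))
        frames.append(render_rf(scat, disp, imaging, extent, pressure_mmhg=p_mmhg,
                                noise_rng=rng))
    return frames


# ---------------------------------------------------------------------------
# container I/O (binary array container + JSON header, bit-exact round trip)

def save_rf_sequence(path: str, frames: list):
    header = [{"axial_pitch_um": f.axial_pitch_um,
               "lateral_pitch_um": f.lateral_pitch_um,
               "center_frequency_mhz": f.center_frequency_mhz,
               "pressure_mmhg": f.pressure_mmhg,
               "origin_mm": list(f.origin_mm)} for f in frames]
    arrays = {f"frame_{i:03d}": f.samples for i, f in enumerate(frames)}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_rf_sequence(path: str) -> list:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        return [RFFrame(samples=data[f"frame_{i:03d}"], **{
            "axial_pitch_um": h["axial_pitch_um"],
            "lateral_pitch_um": h["lateral_pitch_um"],
            "center_frequency_mhz": h["center_frequency_mhz"],
            "pressure_mmhg": h["pressure_mmhg"],
            "origin_mm": tuple(h["origin_mm"])}) for i, h in enumerate(header)]
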