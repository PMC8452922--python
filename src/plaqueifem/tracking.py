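"""Coarse-to-fine 2D block-matching displacement estimation from RF frames.

Three fixed iterations, each matching reference templates against search
kernels from the deformed frame by zero-mean normalized cross-correlation
(ZNCC):

1. demodulated (envelope) data, large templates/kernels on a coarse grid,
   followed by a 5x5 median filter;
2. demodulated data, smaller windows on the final fine grid, offsets seeded
   by iteration 1, followed by a 41x41 median filter;
3. raw RF data, smallest windows, offsets from iteration 2, and subsample
   peak localization by 2D cubic interpolation of the correlation surface;
   no post-filtering.

Window/grid sizes are specified in micrometers and converted to sample
counts from the frame pitches (centered windows need odd counts, so sizes
map to the nearest odd number of samples; grid spacings round half-up).
Displacements across consecutive pressure steps are accumulated by sampling
each step's field at the current displaced position (bilinear interpolation).
Grid points whose template leaves the frame, or whose trajectory leaves the
valid region during accumulation, are flagged invalid rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator
from scipy.signal import correlate, hilbert

from .errors import ConfigurationError
from .ultrasound import RFFrame

try:
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _direct_corr(search, t0):
        na = search.shape[0] - t0.shape[0] + 1
        nb = search.shape[1] - t0.shape[1] + 1
        out = np.empty((na, nb))
        for a in range(na):
            for b in range(nb):
                s = 0.0
                for i in range(t0.shape[0]):
                    for j in range(t0.shape[1]):
                        s += search[a + i, b + j] * t0[i, j]
                out[a, b] = s
        return out

except ImportError:   # pragma: no cover - numba is an optional accelerator
    _direct_corr = None

__all__ = ["IterationSettings", "TrackingSettings", "DisplacementField",
           "demodulate", "zncc_map", "track_pair", "accumulate"]


@dataclass(frozen=True)
class IterationSettings:
    use_demodulated: bool
    template_um: tuple      # (axial, lateral)
    kernel_um: tuple
    grid_um: tuple

    def __post_init__(self):
        if not (self.template_um[0] <= self.kernel_um[0]
                and self.template_um[1] <= self.kernel_um[1]):
            raise ConfigurationError("template must not exceed the search kernel")


@dataclass(frozen=True)
class TrackingSettings:
    """Per-iteration window settings; defaults are the standard three-pass
    coarse-to-fine configuration for ~40 MHz RF data."""

    iterations: tuple = (
        IterationSettings(True, (481.3, 412.5), (1684.4, 962.5), (481.3, 27.5)),
        IterationSettings(True, (240.6, 247.5), (360.9, 522.5), (27.1, 27.5)),
        IterationSettings(False, (120.3, 137.5), (144.4, 192.5), (27.1, 27.5)),
    )
    median_filter_sizes: tuple = ((5, 5), (41, 41))  # after iterations 1 and 2

    def __post_init__(self):
        if len(self.iterations) != 3:
            raise ConfigurationError("exactly 3 iterations are required")


@dataclass
class DisplacementField:
    axial_um: np.ndarray        # (A, L)
    lateral_um: np.ndarray
    correlation: np.ndarray     # peak ZNCC in [-1, 1]
    valid: np.ndarray           # bool
    grid_axial_um: np.ndarray   # (A,) positions along depth, relative to frame origin
    grid_lateral_um: np.ndarray
    origin_mm: tuple
    from_pressure_mmhg: float
    to_pressure_mmhg: float

    def positions_mm(self):
        """(A*L, 2) (x, y) positions of the grid points in phantom coords."""
        gy, gx = np.meshgrid(self.grid_axial_um, self.grid_lateral_um, indexing="ij")
        x = self.origin_mm[0] + gx * 1e-3
        y = self.origin_mm[1] + gy * 1e-3
        return np.column_stack([x.ravel(), y.ravel()])


def demodulate(frame: RFFrame) -> RFFrame:
    """Envelope frame: magnitude of the axial analytic signal."""
    env = np.abs(hilbert(frame.samples, axis=0))
    return RFFrame(samples=env, axial_pitch_um=frame.axial_pitch_um,
                   lateral_pitch_um=frame.lateral_pitch_um,
                   center_frequency_mhz=frame.center_frequency_mhz,
                   pressure_mmhg=frame.pressure_mmhg, origin_mm=frame.origin_mm)


def _nearest_odd(size_um: float, pitch_um: float) -> int:
    n = size_um / pitch_um
    lo = 2 * int(np.floor((n - 1) / 2)) + 1
    hi = lo + 2
    if lo < 1:
        return 1
    return lo if (n - lo) <= (hi - n) else hi


def _grid_step(size_um: float, pitch_um: float) -> int:
    return max(1, int(np.floor(size_um / pitch_um + 0.5)))


def _window_sums(img: np.ndarray, shape) -> np.ndarray:
    """Sliding-window sums via a padded integral image ('valid' placement)."""
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    a, b = shape
    return ii[a:, b:] - ii[:-a, b:] - ii[a:, :-b] + ii[:-a, :-b]


def zncc_map(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-mean normalized cross-correlation of a template over a search
    region ('valid' mode; output shape = search - template + 1)."""
    # ZNCC is invariant to a global offset of either input; removing the
    # search mean up front conditions the windowed variance computation
    search = search - search.mean()
    t0 = template - template.mean()
    tss = float(np.sum(t0 * t0))
    n_out = (search.shape[0] - t0.shape[0] + 1) * (search.shape[1] - t0.shape[1] + 1)
    if _direct_corr is not None and n_out * t0.size < 2_000_000:
        num = _direct_corr(search, t0)
    else:
        num = correlate(search, t0, mode="valid", method="auto")
    s1 = _window_sums(search, template.shape)
    s2 = _window_sums(search * search, template.shape)
    var = np.maximum(s2 - s1 * s1 / template.size, 0.0)
    denom = np.sqrt(var * tss)
    floor = 1e-12 * max(tss, 1.0)
    out = np.where(denom > floor, num / np.maximum(denom, floor), 0.0)
    return np.clip(out, -1.0, 1.0)


def _fill_nearest(fieldarr: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all() or not valid.any():
        return fieldarr
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return fieldarr[tuple(idx)]


def _spline_basis_5pt():
    """Coefficient tensors of the not-a-knot cubic spline through 5 points
    at x = -2..2, for the two central segments [-1, 0] and [0, 1].

    The spline is linear in the data, so feeding the identity basis through
    CubicSpline once yields matrices mapping the 5 sample values directly to
    the local polynomial coefficients (descending powers of x - x_left).
    """
    from scipy.interpolate import CubicSpline

    grid = np.arange(-2.0, 3.0)
    basis = np.empty((2, 4, 5))
    for k in range(5):
        e = np.zeros(5)
        e[k] = 1.0
        c = CubicSpline(grid, e).c            # (4, 4 segments)
        basis[0, :, k] = c[:, 1]              # segment [-1, 0]
        basis[1, :, k] = c[:, 2]              # segment [0, 1]
    return basis


_SPLINE_BASIS = _spline_basis_5pt()


def _cubic_1d_peak(profile: np.ndarray) -> float:
    """Peak in [-1, 1] of the cubic interpolant through 5 samples centered
    on the integer maximum (closed-form extrema of the two segments)."""
    best_v, best_d = profile[2], 0.0
    for seg, x0 in ((0, -1.0), (1, 0.0)):
        a, b, c, d = _SPLINE_BASIS[seg] @ profile   # a t^3 + b t^2 + c t + d
        cands = [0.0, 1.0]
        disc = b * b - 3.0 * a * c
        if disc >= 0.0 and abs(a) > 1e-300:
            r = np.sqrt(disc)
            cands += [(-b + r) / (3.0 * a), (-b - r) / (3.0 * a)]
        elif abs(b) > 1e-300:                        # quadratic segment
            cands.append(-c / (2.0 * b))
        for t in cands:
            if 0.0 <= t <= 1.0:
                v = ((a * t + b) * t + c) * t + d
                x = x0 + t
                if v > best_v + 1e-15 or (abs(v - best_v) <= 1e-15
                                          and abs(x) < abs(best_d)):
                    best_v, best_d = v, x
    return float(np.clip(best_d, -1.0, 1.0))


def _parabolic_1d_peak(m1: float, c0: float, p1: float) -> float:
    denom = m1 - 2.0 * c0 + p1
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (m1 - p1) / denom, -1.0, 1.0))


def _subsample_peak(ncc: np.ndarray, pi: int, pj: int):
    """Refine an integer correlation peak on a subsample scale.

    Uses a bicubic surface through the 5x5 neighborhood when the correlation
    map is large enough; with the standard window sizes the lateral extent of
    the map is often only 3 columns, in which case each axis is refined
    separately (5-point cubic axially, 3-point parabola laterally).
    Returns (di, dj) corrections in [-1, 1].
    """
    ni, nj = ncc.shape
    if 2 <= pi < ni - 2 and 2 <= pj < nj - 2:
        neigh = ncc[pi - 2: pi + 3, pj - 2: pj + 3]
        grid = np.arange(-2.0, 3.0)
        spl = RectBivariateSpline(grid, grid, neigh, kx=3, ky=3)
        fine = np.arange(-1.0, 1.0 + 1e-9, 0.02)
        vals = spl(fine, fine, grid=True)
        best = np.flatnonzero(vals >= vals.max() - 1e-12)
        ii, jj = np.unravel_index(best, vals.shape)
        k = int(np.argmin(fine[ii] ** 2 + fine[jj] ** 2))  # tie-break inward
        di, dj = fine[ii[k]], fine[jj[k]]
        for _ in range(2):
            gx = spl.ev(di, dj, dx=1)
            gy = spl.ev(di, dj, dy=1)
            hxx = spl.ev(di, dj, dx=2)
            hyy = spl.ev(di, dj, dy=2)
            hxy = spl.ev(di, dj, dx=1, dy=1)
            det = hxx * hyy - hxy * hxy
            if det <= 0 or hxx >= 0:
                break
            di = float(np.clip(di - (hyy * gx - hxy * gy) / det, -1.0, 1.0))
            dj = float(np.clip(dj - (hxx * gy - hxy * gx) / det, -1.0, 1.0))
        return float(di), float(dj)
    di = dj = 0.0
    if 2 <= pi < ni - 2:
        di = _cubic_1d_peak(ncc[pi - 2: pi + 3, pj])
    elif 1 <= pi < ni - 1:
        di = _parabolic_1d_peak(ncc[pi - 1, pj], ncc[pi, pj], ncc[pi + 1, pj])
    if 2 <= pj < nj - 2:
        dj = _cubic_1d_peak(ncc[pi, pj - 2: pj + 3])
    elif 1 <= pj < nj - 1:
        dj = _parabolic_1d_peak(ncc[pi, pj - 1], ncc[pi, pj], ncc[pi, pj + 1])
    return di, dj


def track_pair(reference: RFFrame, deformed: RFFrame,
               settings: TrackingSettings | None = None) -> DisplacementField:
    """Estimate the displacement field from a pair of RF frames."""
    settings = settings or TrackingSettings()
    if (reference.axial_pitch_um != deformed.axial_pitch_um
            or reference.lateral_pitch_um != deformed.lateral_pitch_um):
        raise ConfigurationError("frames must share sample pitches")
    dz, dx = reference.axial_pitch_um, reference.lateral_pitch_um
    nz, nx = reference.shape
    ref_env = demodulate(reference).samples
    def_env = demodulate(deformed).samples

    prev = None  # (grid_i, grid_j, off_ax, off_lat, valid) in samples
    result = None
    for it_num, it in enumerate(settings.iterations):
        img_r = ref_env if it.use_demodulated else reference.samples
        img_d = def_env if it.use_demodulated else deformed.samples
        ta = _nearest_odd(it.template_um[0], dz)
        tl = _nearest_odd(it.template_um[1], dx)
        ka = _nearest_odd(it.kernel_um[0], dz)
        kl = _nearest_odd(it.kernel_um[1], dx)
        sa = _grid_step(it.grid_um[0], dz)
        sl = _grid_step(it.grid_um[1], dx)
        hta, htl = ta // 2, tl // 2
        hka, hkl = ka // 2, kl // 2
        if 2 * hta + 1 > nz or 2 * htl + 1 > nx:
            raise ConfigurationError("frame smaller than the template window")
        gi = np.arange(hta, nz - hta, sa)
        gj = np.arange(htl, nx - htl, sl)

        if prev is None:
            off_ax = np.zeros((len(gi), len(gj)))
            off_lat = np.zeros((len(gi), len(gj)))
        else:
            pgi, pgj, pax, plat, pvalid = prev
            pax = _fill_nearest(pax, pvalid)
            plat = _fill_nearest(plat, pvalid)
            qi = np.clip(gi.astype(float), pgi[0], pgi[-1])
            qj = np.clip(gj.astype(float), pgj[0], pgj[-1])
            qq = np.stack(np.meshgrid(qi, qj, indexing="ij"), axis=-1)
            off_ax = RegularGridInterpolator((pgi, pgj), pax)(qq)
            off_lat = RegularGridInterpolator((pgi, pgj), plat)(qq)

        ax = np.zeros((len(gi), len(gj)))
        lat = np.zeros((len(gi), len(gj)))
        corr = np.zeros((len(gi), len(gj)))
        valid = np.ones((len(gi), len(gj)), dtype=bool)
        last = it_num == len(settings.iterations) - 1
        var_floor = (1e-9 * max(float(np.abs(img_r).max()), 1e-30)) ** 2

        for a, i in enumerate(gi):
            for b, j in enumerate(gj):
                ci = i + int(np.rint(off_ax[a, b]))
                cj = j + int(np.rint(off_lat[a, b]))
                lo_i, hi_i = max(ci - hka, 0), min(ci + hka + 1, nz)
                lo_j, hi_j = max(cj - hkl, 0), min(cj + hkl + 1, nx)
                if hi_i - lo_i < ta or hi_j - lo_j < tl:
                    valid[a, b] = False
                    continue
                tpl = img_r[i - hta: i + hta + 1, j - htl: j + htl + 1]
                # a featureless (echo-free) template carries no motion signal
                if np.var(tpl) <= var_floor:
                    valid[a, b] = False
                    continue
                ncc = zncc_map(img_d[lo_i:hi_i, lo_j:hi_j], tpl)
                pk = int(np.argmax(ncc))
                pi, pj = np.unravel_index(pk, ncc.shape)
                corr[a, b] = ncc[pi, pj]
                di = dj = 0.0
                # a peak at the Cauchy-Schwarz bound is a perfect match;
                # interpolating around it could only drift off spuriously
                if last and corr[a, b] < 1.0 - 1e-9:
                    di, dj = _subsample_peak(ncc, pi, pj)
                ax[a, b] = (lo_i + pi + hta + di) - i
                lat[a, b] = (lo_j + pj + htl + dj) - j

        if not last:
            size = settings.median_filter_sizes[it_num]
            ax = ndimage.median_filter(_fill_nearest(ax, valid), size=size,
                                       mode="reflect")
            lat = ndimage.median_filter(_fill_nearest(lat, valid), size=size,
                                        mode="reflect")
        prev = (gi, gj, ax, lat, valid)
        result = DisplacementField(
            axial_um=ax * dz, lateral_um=lat * dx, correlation=corr, valid=valid,
            grid_axial_um=gi * dz, grid_lateral_um=gj * dx,
            origin_mm=reference.origin_mm,
            from_pressure_mmhg=reference.pressure_mmhg,
            to_pressure_mmhg=deformed.pressure_mmhg)
    return result


def accumulate(fields: list) -> DisplacementField:
    """Chain displacement fields across consecutive pressure steps.

    Cumulative displacement at each reference grid point follows the material
    trajectory: each subsequent field is sampled at the current displaced
    position by bilinear interpolation.  Points whose trajectory leaves a
    field's valid region are flagged invalid.
    """
    if not fields:
        raise ConfigurationError("no fields to accumulate")
    for prv, nxt in zip(fields, fields[1:]):
        if abs(prv.to_pressure_mmhg - nxt.from_pressure_mmhg) > 1e-9:
            raise ConfigurationError(
                f"broken pressure chain: {prv.to_pressure_mmhg} -> "
                f"{nxt.from_pressure_mmhg}")
    base = fields[0]
    if len(fields) == 1:
        return base
    gy, gx = np.meshgrid(base.grid_axial_um, base.grid_lateral_um, indexing="ij")
    cum_ax = base.axial_um.copy()
    cum_lat = base.lateral_um.copy()
    valid = base.valid.copy()
    corr = base.correlation.copy()
    for f in fields[1:]:
        pts = np.stack([gy + cum_ax, gx + cum_lat], axis=-1)
        interp_kw = dict(method="linear", bounds_error=False, fill_value=np.nan)
        grid = (f.grid_axial_um, f.grid_lateral_um)
        ax_i = RegularGridInterpolator(grid, np.where(f.valid, f.axial_um, np.nan),
                                       **interp_kw)(pts)
        lat_i = RegularGridInterpolator(grid, np.where(f.valid, f.lateral_um, np.nan),
                                        **interp_kw)(pts)
        corr_i = RegularGridInterpolator(grid, np.where(f.valid, f.correlation,
                                                        np.nan), **interp_kw)(pts)
        ok = np.isfinite(ax_i) & np.isfinite(lat_i)
        valid &= ok
        cum_ax = np.where(ok, cum_ax + ax_i, cum_ax)
        cum_lat = np.where(ok, cum_lat + lat_i, cum_lat)
        corr = np.where(ok, np.minimum(corr, np.where(np.isfinite(corr_i),
                                                      corr_i, -1.0)), corr)
    return DisplacementField(axial_um=cum_ax, lateral_um=cum_lat, correlation=corr,
                             valid=valid, grid_axial_um=base.grid_axial_um,
                             grid_lateral_um=base.grid_lateral_um,
                             origin_mm=base.origin_mm,
                             from_pressure_mmhg=base.from_pressure_mmhg,
                             to_pressure_mmhg=fields[-1].to_pressure_mmhg)
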