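"""Synthetic multicomponent cross-section phantoms and their FE meshes.

A phantom stands in for a segmented, co-registered cross-section of an
atherosclerotic artery.  It is built from concentric-ish rings: an eccentric
circular lumen, a fibrous-intima ring, and an outer wall (media+adventitia)
ring, with optional lipid and calcium inclusions shaped as tapered polar
crescents inside the intima.  Default dimensions emulate diseased human
coronary morphology: intima ~2.6 mm^2 (fibrous part), wall ~4.6 mm^2 and a
lipid pool ~1.3 mm^2.

Components are encoded in an integer label mask (0 background/bath, 1 lumen,
2 fibrous intima, 3 wall, 4 lipid, 5 calcium) with pixel centers at
``origin + (index + 0.5) * pixel_size``, and as closed contour polygons in mm.

Meshing is structured-transfinite: rays are cast from the lumen centroid and
node rings are graded from the lumen contour to the intima outer contour and
on to the wall outer contour, producing a conforming quad mesh whose
lumen-boundary edges lie exactly on the lumen contour and whose intima/wall
interface is a node ring.  Inclusions are tagged element-wise by centroid
lookup.  The lumen itself is never meshed — it is the pressurized cavity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import imageio.v3 as iio
import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "InclusionSpec",
    "GeometrySpec",
    "CrossSectionPhantom",
    "MultiComponentMesh",
    "generate_phantom",
    "rasterize_contours",
    "extract_contours",
    "mesh_phantom",
    "annular_mesh",
    "save_mask",
    "load_mask",
    "write_mesh_vtk",
]

LABELS = {"background": 0, "lumen": 1, "intima": 2, "wall": 3, "lipid": 4, "calcium": 5}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class InclusionSpec:
    """A tapered polar crescent inside the intima ring.

    ``angle_deg`` is the circumferential center of the pool, ``span_rad`` the
    full angular support, and ``area_mm2`` the target area; the radial
    thickness profile is solved for the target area and follows the local
    ring thickness with a smooth (cosine-ramped trapezoid) taper.
    """

    area_mm2: float
    angle_deg: float = 180.0
    span_rad: float = 3.6
    margin_mm: float = 0.08  # clearance kept from lumen and intima outer


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the synthetic cross-section (all lengths in mm)."""

    lumen_radius: float = 0.7
    lumen_offset: tuple = (0.3, 0.0)  # eccentricity vector of the lumen center
    intima_outer_radius: float = 1.324
    wall_outer_radius: float = 1.795
    lipid: Optional[InclusionSpec] = InclusionSpec(area_mm2=1.33)
    calcium: Optional[InclusionSpec] = None
    boundary_wobble_mm: float = 0.02  # seeded harmonic perturbation amplitude
    n_contour_points: int = 720

    def __post_init__(self):
        if self.lumen_radius <= 0:
            raise GeometryError("lumen radius must be > 0")
        off = float(np.hypot(*self.lumen_offset))
        if self.lumen_radius + off >= self.intima_outer_radius:
            raise GeometryError("lumen (incl. offset) must lie inside the intima ring")
        if self.intima_outer_radius >= self.wall_outer_radius:
            raise GeometryError("intima outer radius must be < wall outer radius")

    @classmethod
    def concentric(cls, lumen_radius=0.7, intima_outer_radius=1.324,
                   wall_outer_radius=1.795):
        """Concentric annulus with no inclusions (degenerate test case)."""
        return cls(lumen_radius=lumen_radius, lumen_offset=(0.0, 0.0),
                   intima_outer_radius=intima_outer_radius,
                   wall_outer_radius=wall_outer_radius,
                   lipid=None, calcium=None, boundary_wobble_mm=0.0)


@dataclass
class CrossSectionPhantom:
    label_mask: np.ndarray          # (H, W) uint8, row = depth (y), col = lateral (x)
    pixel_size: float               # mm / pixel
    origin: tuple                   # (x0, y0) of the corner of pixel (0, 0), mm
    contours: Optional[dict]        # name -> (N, 2) closed polygon, mm
    seed: int = 0
    spec: Optional[GeometrySpec] = None

    def pixel_centers(self):
        h, w = self.label_mask.shape
        x = self.origin[0] + (np.arange(w) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(h) + 0.5) * self.pixel_size
        return x, y

    def component_area(self, name: str) -> float:
        """Area of a labeled component by pixel counting (mm^2)."""
        n = int(np.count_nonzero(self.label_mask == LABELS[name]))
        return n * self.pixel_size**2

    def tissue_bbox(self):
        """(xmin, xmax, ymin, ymax) of non-background pixels, mm."""
        rows, cols = np.nonzero(self.label_mask > 0)
        x, y = self.pixel_centers()
        return x[cols.min()], x[cols.max()], y[rows.min()], y[rows.max()]


# ---------------------------------------------------------------------------
# generation

def _wobble(theta, amplitude, rng):
    """Smooth zero-mean radial perturbation from harmonics 2..5."""
    out = np.zeros_like(theta)
    if amplitude <= 0:
        return out
    for k in range(2, 6):
        a = amplitude * rng.uniform(0.3, 1.0) / k
        phi = rng.uniform(0.0, _TWO_PI)
        out += a * np.cos(k * theta + phi)
    return out


def _lumen_distance(theta, spec: GeometrySpec):
    """Distance from the origin to the lumen circle along direction theta."""
    ox, oy = spec.lumen_offset
    b = ox * np.cos(theta) + oy * np.sin(theta)
    c = ox * ox + oy * oy - spec.lumen_radius**2
    return b + np.sqrt(np.maximum(b * b - c, 0.0))


def _trapezoid_taper(theta, center, span, ramp_frac=0.2):
    """Smooth trapezoid in angle: 1 on the plateau, cos^2 ramps, 0 outside."""
    d = np.angle(np.exp(1j * (theta - center)))  # wrapped to (-pi, pi]
    half = span / 2.0
    ramp = ramp_frac * span
    out = np.zeros_like(theta)
    inside = np.abs(d) <= half
    plateau = np.abs(d) <= half - ramp
    edge = inside & ~plateau
    out[plateau] = 1.0
    out[edge] = np.cos(0.5 * np.pi * (np.abs(d[edge]) - (half - ramp)) / ramp) ** 2
    return out


def _inclusion_polygon(spec: GeometrySpec, inc: InclusionSpec, theta, r_lumen, r_intima):
    """Build a crescent polygon hitting the target area inside the intima ring."""
    center = np.deg2rad(inc.angle_deg)
    w = _trapezoid_taper(theta, center, inc.span_rad)
    rin_avail = r_lumen + inc.margin_mm
    rout_avail = r_intima - inc.margin_mm
    rmid = 0.5 * (rin_avail + rout_avail)
    hw_avail = 0.5 * (rout_avail - rin_avail)
    if np.any(hw_avail <= 0):
        raise GeometryError("intima ring too thin for the requested inclusion")
    # area(fill) = fill * int 2 * rmid * w * hw_avail dtheta  (linear in fill)
    dtheta = _TWO_PI / len(theta)
    area_per_fill = float(np.sum(2.0 * rmid * w * hw_avail) * dtheta)
    fill = inc.area_mm2 / area_per_fill
    if fill > 0.9:
        raise GeometryError(
            f"inclusion of {inc.area_mm2} mm^2 does not fit in the intima ring "
            f"(would need fill factor {fill:.2f} > 0.9)"
        )
    hw = fill * w * hw_avail
    sel = np.nonzero(w > 1e-9)[0]
    # order the support contiguously around the crescent center
    d = np.angle(np.exp(1j * (theta[sel] - center)))
    sel = sel[np.argsort(d)]
    outer = np.column_stack([(rmid + hw)[sel] * np.cos(theta[sel]),
                             (rmid + hw)[sel] * np.sin(theta[sel])])
    inner = np.column_stack([(rmid - hw)[sel] * np.cos(theta[sel]),
                             (rmid - hw)[sel] * np.sin(theta[sel])])
    return np.vstack([outer, inner[::-1]])


def generate_phantom(spec: GeometrySpec | None = None, pixel_size: float = 0.025,
                     seed: int = 0, margin_mm: float = 0.2) -> CrossSectionPhantom:
    """Generate a labeled cross-section phantom (reproducible per seed)."""
    if spec is None:
        spec = GeometrySpec()
    if pixel_size <= 0:
        raise GeometryError("pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    theta = np.arange(spec.n_contour_points) * _TWO_PI / spec.n_contour_points

    r_int = spec.intima_outer_radius + _wobble(theta, spec.boundary_wobble_mm, rng)
    r_wall = spec.wall_outer_radius + _wobble(theta, spec.boundary_wobble_mm, rng)
    r_lum = _lumen_distance(theta, spec)
    if np.any(r_int <= r_lum) or np.any(r_wall <= r_int):
        raise GeometryError("contours intersect; reduce wobble or eccentricity")

    contours = {
        "lumen": np.column_stack([spec.lumen_offset[0] + spec.lumen_radius * np.cos(theta),
                                  spec.lumen_offset[1] + spec.lumen_radius * np.sin(theta)]),
        "intima_outer": np.column_stack([r_int * np.cos(theta), r_int * np.sin(theta)]),
        "wall_outer": np.column_stack([r_wall * np.cos(theta), r_wall * np.sin(theta)]),
    }
    if spec.lipid is not None:
        contours["lipid"] = _inclusion_polygon(spec, spec.lipid, theta, r_lum, r_int)
    if spec.calcium is not None:
        contours["calcium"] = _inclusion_polygon(spec, spec.calcium, theta, r_lum, r_int)
        if spec.lipid is not None:
            if Polygon(contours["calcium"]).intersects(Polygon(contours["lipid"])):
                raise GeometryError("lipid and calcium inclusions overlap")

    half = spec.wall_outer_radius + spec.boundary_wobble_mm * 2 + margin_mm
    n = int(np.ceil(2 * half / pixel_size))
    origin = (-n * pixel_size / 2.0, -n * pixel_size / 2.0)
    mask = _rasterize(contours, (n, n), pixel_size, origin)
    return CrossSectionPhantom(label_mask=mask, pixel_size=pixel_size, origin=origin,
                               contours=contours, seed=seed, spec=spec)


def _rasterize(contours: dict, shape, pixel_size, origin) -> np.ndarray:
    h, w = shape
    x = origin[0] + (np.arange(w) + 0.5) * pixel_size
    y = origin[1] + (np.arange(h) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)
    pts_x, pts_y = xx.ravel(), yy.ravel()
    mask = np.zeros(h * w, dtype=np.uint8)

    def paint(name, label):
        poly = Polygon(contours[name])
        inside = shapely.contains_xy(poly, pts_x, pts_y)
        mask[inside] = label

    paint("wall_outer", LABELS["wall"])
    paint("intima_outer", LABELS["intima"])
    if "lipid" in contours:
        paint("lipid", LABELS["lipid"])
    if "calcium" in contours:
        paint("calcium", LABELS["calcium"])
    paint("lumen", LABELS["lumen"])
    return mask.reshape(h, w)


def rasterize_contours(phantom: CrossSectionPhantom) -> np.ndarray:
    """Re-rasterize a phantom's contour polygons onto its pixel grid."""
    return _rasterize(phantom.contours, phantom.label_mask.shape,
                      phantom.pixel_size, phantom.origin)


def extract_contours(mask: np.ndarray, pixel_size: float, origin=(0.0, 0.0)) -> dict:
    """Recover component boundary polygons (mm) from a label mask.

    Uses marching squares on nested binary masks so that the reconstruction
    order (wall -> intima -> inclusions -> lumen) mirrors rasterization.
    """
    from skimage import measure

    def largest_contour(binary):
        cs = measure.find_contours(binary.astype(float), 0.5)
        if not cs:
            raise GeometryError("no contour found for a component")
        c = max(cs, key=len)
        # rows are y, cols are x; pixel centers at (i + 0.5) * px
        xy = np.column_stack([(c[:, 1] + 0.5) * pixel_size + origin[0],
                              (c[:, 0] + 0.5) * pixel_size + origin[1]])
        return xy

    out = {}
    out["wall_outer"] = largest_contour(mask >= 1)
    inner = np.isin(mask, [LABELS["lumen"], LABELS["intima"],
                           LABELS["lipid"], LABELS["calcium"]])
    out["intima_outer"] = largest_contour(inner)
    if np.any(mask == LABELS["lipid"]):
        out["lipid"] = largest_contour(mask == LABELS["lipid"])
    if np.any(mask == LABELS["calcium"]):
        out["calcium"] = largest_contour(mask == LABELS["calcium"])
    out["lumen"] = largest_contour(mask == LABELS["lumen"])
    return out


# ---------------------------------------------------------------------------
# meshing

@dataclass
class MultiComponentMesh:
    nodes: np.ndarray               # (N, 2) mm
    quads: np.ndarray               # (E, 4) node indices, CCW
    quad_tags: np.ndarray           # (E,) component name per element
    boundary_edges: dict            # {"lumen_boundary": (B, 2), "outer_boundary": ...}
    tris: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    tri_tags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    @property
    def n_nodes(self):
        return len(self.nodes)

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.quads]  # (E, 4, 2)
        # shoelace for quads
        x2 = np.roll(x, -1, axis=1)
        return 0.5 * np.abs(np.sum(x[:, :, 0] * x2[:, :, 1] - x2[:, :, 0] * x[:, :, 1], axis=1))

    def component_area(self, tag: str) -> float:
        return float(self.element_areas()[self.quad_tags == tag].sum())

    def median_element_size(self) -> float:
        return float(np.median(np.sqrt(self.element_areas())))

    def min_scaled_jacobian(self) -> float:
        """Worst corner Jacobian / ideal, a standard quad quality measure."""
        x = self.nodes[self.quads]
        worst = np.inf
        for k in range(4):
            a = x[:, (k + 1) % 4] - x[:, k]
            b = x[:, (k - 1) % 4] - x[:, k]
            cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
            denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            worst = min(worst, float(np.min(cross / denom)))
        return worst


def _ray_hits(polygon: np.ndarray, center, theta):
    """Entry/exit distances of rays from ``center`` through a polygon,
    (a, b) per angle or NaN where the ray misses."""
    from shapely.geometry import LineString
    poly = Polygon(polygon)
    reach = 2.0 * float(np.abs(polygon - center).max()) + 1.0
    a = np.full(len(theta), np.nan)
    b = np.full(len(theta), np.nan)
    for k, t in enumerate(theta):
        ray = LineString([center, (center[0] + reach * np.cos(t),
                                   center[1] + reach * np.sin(t))])
        hit = poly.exterior.intersection(ray)
        if hit.is_empty:
            continue
        pts = getattr(hit, "geoms", [hit])
        dists = sorted(np.hypot(p.x - center[0], p.y - center[1])
                       for p in pts if p.geom_type == "Point")
        if len(dists) >= 2:
            a[k], b[k] = dists[0], dists[-1]
    return a, b


def _snap_band_to_inclusion(band, theta, center, r_in, r_out, polygon):
    """Deform the intima node rings so two of them follow an inclusion's
    radial boundaries (blended away where the inclusion tapers thin)."""
    nr1 = band.shape[0] - 1
    a, b = _ray_hits(polygon, center, theta)
    hit = np.isfinite(a) & np.isfinite(b) & (b > a)
    if not hit.any():
        return band
    h_typ = float(np.mean((r_out - r_in))) / nr1
    frac_a = np.mean((a[hit] - r_in[hit]) / (r_out[hit] - r_in[hit]))
    frac_b = np.mean((b[hit] - r_in[hit]) / (r_out[hit] - r_in[hit]))
    k1 = int(np.clip(round(nr1 * frac_a), 1, nr1 - 2))
    k2 = int(np.clip(round(nr1 * frac_b), k1 + 1, nr1 - 1))
    # full snap only where the inclusion is at least one element thick
    w = np.zeros(len(theta))
    w[hit] = np.clip((b[hit] - a[hit]) / h_typ, 0.0, 1.0)
    s = np.arange(nr1 + 1, dtype=float)
    new = band.copy()
    for j in np.flatnonzero(w > 0):
        knots_s = [0.0, float(k1), float(k2), float(nr1)]
        knots_r = [r_in[j], a[j], b[j], r_out[j]]
        snapped = np.interp(s, knots_s, knots_r)
        new[:, j] = (1 - w[j]) * band[:, j] + w[j] * snapped
        if np.any(np.diff(new[:, j]) <= 0):      # keep rings strictly nested
            new[:, j] = band[:, j]
    return new


def _radial_function(polygon: np.ndarray, center: np.ndarray):
    """Periodic interpolator r(phi) of a star-shaped polygon about ``center``."""
    d = polygon - center
    phi = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(phi)
    phi, r = phi[order], r[order]
    if np.any(np.diff(phi) <= 0):
        keep = np.concatenate([[True], np.diff(phi) > 0])
        phi, r = phi[keep], r[keep]
    phi_ext = np.concatenate([phi - _TWO_PI, phi, phi + _TWO_PI])
    r_ext = np.tile(r, 3)

    def f(angles):
        return np.interp(np.angle(np.exp(1j * np.asarray(angles))), phi_ext, r_ext)

    return f


def mesh_phantom(phantom: CrossSectionPhantom, target_element_size: float = 0.035
                 ) -> MultiComponentMesh:
    """Conforming structured quad mesh of the tissue (lumen left unmeshed)."""
    if phantom.contours is None:
        raise GeometryError("phantom has no contours; run extract_contours first")
    h = float(target_element_size)
    if h <= 0:
        raise GeometryError("target element size must be > 0")
    lumen_poly = phantom.contours["lumen"]
    center = lumen_poly.mean(axis=0)
    r_lum = _radial_function(lumen_poly, center)
    r_int = _radial_function(phantom.contours["intima_outer"], center)
    r_wal = _radial_function(phantom.contours["wall_outer"], center)

    probe = np.linspace(0, _TWO_PI, 256, endpoint=False)
    t_int = r_int(probe) - r_lum(probe)
    t_wal = r_wal(probe) - r_int(probe)
    if np.any(t_int <= 0) or np.any(t_wal <= 0):
        raise GeometryError(
            "contours are not nested about the lumen centroid; "
            f"min intima thickness {t_int.min():.4f} mm, wall {t_wal.min():.4f} mm"
        )
    has_inclusion = any(phantom.contours.get(n) is not None
                        and n in phantom.contours for n in ("lipid", "calcium"))
    circumference = _TWO_PI * float(np.mean(r_int(probe)))
    ntheta = max(16, int(round(circumference / h)))
    nr1 = max(4 if has_inclusion else 2, int(round(float(np.mean(t_int)) / h)))
    nr2 = max(2, int(round(float(np.mean(t_wal)) / h)))

    theta = np.arange(ntheta) * _TWO_PI / ntheta
    rl, ri, rw = r_lum(theta), r_int(theta), r_wal(theta)
    s1 = np.linspace(0.0, 1.0, nr1 + 1)[:, None]
    band1 = rl + s1 * (ri - rl)                     # (nr1+1, ntheta)
    for name in ("lipid", "calcium"):
        if name in phantom.contours and phantom.contours[name] is not None:
            band1 = _snap_band_to_inclusion(band1, theta, center, rl, ri,
                                            phantom.contours[name])
    s2 = np.linspace(0.0, 1.0, nr2 + 1)[1:, None]
    radii = np.vstack([band1, ri + s2 * (rw - ri)])  # (nr+1, ntheta)
    nr = nr1 + nr2
    xs = center[0] + radii * np.cos(theta)
    ys = center[1] + radii * np.sin(theta)
    nodes = np.column_stack([xs.ravel(), ys.ravel()])  # ring-major

    def nid(i, j):
        return i * ntheta + (j % ntheta)

    i_idx, j_idx = np.meshgrid(np.arange(nr), np.arange(ntheta), indexing="ij")
    quads = np.stack([nid(i_idx, j_idx), nid(i_idx + 1, j_idx),
                      nid(i_idx + 1, j_idx + 1), nid(i_idx, j_idx + 1)],
                     axis=-1).reshape(-1, 4)
    band1 = (i_idx < nr1).ravel()
    tags = np.where(band1, "intima", "wall").astype(object)

    # tag inclusions by element centroid
    cent = nodes[quads].mean(axis=1)
    for name in ("lipid", "calcium"):
        if phantom.contours.get(name) is not None and name in phantom.contours:
            poly = Polygon(phantom.contours[name])
            inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
            tags[inside & band1] = name

    j = np.arange(ntheta)
    boundary = {
        "lumen_boundary": np.column_stack([nid(0, j), nid(0, j + 1)]),
        "outer_boundary": np.column_stack([nid(nr, j), nid(nr, j + 1)]),
    }
    mesh = MultiComponentMesh(nodes=nodes, quads=quads, quad_tags=np.asarray(tags),
                              boundary_edges=boundary)
    if mesh.min_scaled_jacobian() <= 0.05:
        raise GeometryError("degenerate elements produced; contour too irregular")
    return mesh


def annular_mesh(inner_radius: float, outer_radius: float, n_radial: int,
                 n_theta: int, tag: str = "wall") -> MultiComponentMesh:
    """Concentric annulus mesh (validation workhorse for the tube oracle)."""
    theta = np.arange(n_theta) * _TWO_PI / n_theta
    radii = np.linspace(inner_radius, outer_radius, n_radial + 1)[:, None]
    nodes = np.column_stack([(radii * np.cos(theta)).ravel(),
                             (radii * np.sin(theta)).ravel()])

    def nid(i, j):
        return i * n_theta + (j % n_theta)

    i_idx, j_idx = np.meshgrid(np.arange(n_radial), np.arange(n_theta), indexing="ij")
    quads = np.stack([nid(i_idx, j_idx), nid(i_idx + 1, j_idx),
                      nid(i_idx + 1, j_idx + 1), nid(i_idx, j_idx + 1)],
                     axis=-1).reshape(-1, 4)
    j = np.arange(n_theta)
    boundary = {
        "lumen_boundary": np.column_stack([nid(0, j), nid(0, j + 1)]),
        "outer_boundary": np.column_stack([nid(n_radial, j), nid(n_radial, j + 1)]),
    }
    return MultiComponentMesh(nodes=nodes, quads=quads,
                              quad_tags=np.full(len(quads), tag, dtype=object),
                              boundary_edges=boundary)


# ---------------------------------------------------------------------------
# I/O

def save_mask(phantom: CrossSectionPhantom, path: str):
    """Write the label mask as PNG plus a JSON sidecar with the geometry."""
    path = str(path)
    iio.imwrite(path, phantom.label_mask.astype(np.uint8))
    meta = {"pixel_size_mm": phantom.pixel_size, "origin_mm": list(phantom.origin),
            "labels": LABELS, "seed": phantom.seed}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_mask(path: str) -> CrossSectionPhantom:
    path = str(path)
    mask = np.asarray(iio.imread(path)).astype(np.uint8)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    phantom = CrossSectionPhantom(label_mask=mask, pixel_size=meta["pixel_size_mm"],
                                  origin=tuple(meta["origin_mm"]), contours=None,
                                  seed=meta.get("seed", 0))
    phantom.contours = extract_contours(mask, phantom.pixel_size, phantom.origin)
    return phantom


def write_mesh_vtk(mesh: MultiComponentMesh, path: str):
    """Legacy ASCII VTK export (quads with integer component tags)."""
    tag_ids = {t: i for i, t in enumerate(sorted(set(mesh.quad_tags)))}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nplaque-ifem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.9g} {y:.9g} 0\n")
        e = len(mesh.quads)
        fh.write(f"CELLS {e} {5 * e}\n")
        for q in mesh.quads:
            fh.write("4 " + " ".join(map(str, q)) + "\n")
        fh.write(f"CELL_TYPES {e}\n" + "9\n" * e)
        fh.write(f"CELL_DATA {e}\nSCALARS component int 1\nLOOKUP_TABLE default\n")
        for t in mesh.quad_tags:
            fh.write(f"{tag_ids[t]}\n")
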