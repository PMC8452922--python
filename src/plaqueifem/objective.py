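"""Grid-based comparison of tracked and FE axial displacements, and the
normalized mean square error (NMSE) cost.

A regular grid (default 100 um x 100 um cells) is laid over the cross
section.  Only cells in the mid band — lateral centers within +/- 25 % of
the total lateral tissue width around the lateral centroid — are kept (the
side regions have poor axial-displacement SNR), and a cell must contain a
minimum number of both FE nodes and valid tracking points.  Within each
selected cell both data sources are averaged, the per-cell means are
concatenated over cells (cell-major) and pressures (80/100/120 mmHg,
innermost), and the cost is

    NMSE = sum_i (yhat_i - y_i)^2 / sum_i (y_i - mean(y))^2,

with y the experimental (tracked) and yhat the computational (FE) axial
displacements.  Only axial displacements enter the cost; lateral values are
computed and stored upstream but never used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["ComparisonGrid", "build_grid", "average_in_cells", "nmse",
           "build_objective_vectors"]


@dataclass
class ComparisonGrid:
    x_edges: np.ndarray            # (nx+1,) mm
    y_edges: np.ndarray            # (ny+1,) mm
    selected: np.ndarray           # (k,) flat cell indices (row-major y, x)
    fe_cells: np.ndarray           # (n_fe,) flat cell index per FE node (-1 outside)
    track_cells: np.ndarray        # (n_track,) per tracking point
    fe_counts: np.ndarray          # (k,) FE nodes per selected cell
    track_counts: np.ndarray

    @property
    def n_cells(self):
        return len(self.selected)

    def cell_centers(self):
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        nx = len(cx)
        return np.array([(cx[c % nx], cy[c // nx]) for c in self.selected])

    def to_dataframe(self):
        """Audit table of the selected cells (centers and populations)."""
        import pandas as pd

        centers = self.cell_centers()
        return pd.DataFrame({"cell": self.selected,
                             "x_mm": centers[:, 0], "y_mm": centers[:, 1],
                             "n_fe_nodes": self.fe_counts,
                             "n_track_points": self.track_counts})


def _assign(points: np.ndarray, x_edges, y_edges) -> np.ndarray:
    """Flat cell index per point; -1 outside the grid."""
    ix = np.searchsorted(x_edges, points[:, 0], side="right") - 1
    iy = np.searchsorted(y_edges, points[:, 1], side="right") - 1
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    return np.where(ok, iy * nx + ix, -1)


def build_grid(fe_points: np.ndarray, track_points: np.ndarray,
               track_valid: np.ndarray, cell_size_um: float = 100.0,
               mid_band_fraction: float = 0.5, min_fe_points: int = 3,
               min_track_points: int = 3) -> ComparisonGrid:
    """Construct the comparison grid from co-registered point sets.

    ``fe_points`` are reference FE node positions (mm), ``track_points`` the
    tracking grid positions (mm) with their validity flags.  The lateral
    (x) width and centroid of the tissue are taken from the FE nodes.
    """
    if len(track_points) == 0 or not np.any(track_valid):
        raise ConfigurationError("empty tracking field")
    cell = cell_size_um * 1e-3
    x_lo, x_hi = fe_points[:, 0].min(), fe_points[:, 0].max()
    y_lo, y_hi = fe_points[:, 1].min(), fe_points[:, 1].max()
    x_edges = np.arange(x_lo, x_hi + cell, cell)
    y_edges = np.arange(y_lo, y_hi + cell, cell)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    if nx < 1 or ny < 1:
        raise ConfigurationError("tissue extent smaller than one grid cell")

    fe_cells = _assign(fe_points, x_edges, y_edges)
    tp = track_points.astype(float).copy()
    tp[~track_valid] = np.inf           # invalid points never land in a cell
    track_cells = _assign(tp, x_edges, y_edges)

    n_total = nx * ny
    fe_counts = np.bincount(fe_cells[fe_cells >= 0], minlength=n_total)
    tr_counts = np.bincount(track_cells[track_cells >= 0], minlength=n_total)

    width = x_hi - x_lo
    centroid = float(fe_points[:, 0].mean())
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    in_band = np.abs(cx - centroid) <= 0.5 * mid_band_fraction * width
    band_mask = np.tile(in_band, ny)

    selected = np.flatnonzero(band_mask & (fe_counts >= min_fe_points)
                              & (tr_counts >= min_track_points))
    if len(selected) == 0:
        raise ConfigurationError(
            "no grid cells survive the mid-band/population filters; "
            f"band cells={int(band_mask.sum())}, "
            f"max fe count={int(fe_counts.max())}, "
            f"max track count={int(tr_counts.max())}")
    return ComparisonGrid(x_edges=x_edges, y_edges=y_edges, selected=selected,
                          fe_cells=fe_cells, track_cells=track_cells,
                          fe_counts=fe_counts[selected],
                          track_counts=tr_counts[selected])


def average_in_cells(values: np.ndarray, cell_index: np.ndarray,
                     grid: ComparisonGrid, valid: np.ndarray | None = None
                     ) -> np.ndarray:
    """Arithmetic mean of valid point values per selected cell."""
    values = np.asarray(values, dtype=float).ravel()
    cells = cell_index.copy()
    if valid is not None:
        cells = np.where(valid.ravel(), cells, -1)
    n_total = (len(grid.x_edges) - 1) * (len(grid.y_edges) - 1)
    ok = cells >= 0
    sums = np.bincount(cells[ok], weights=values[ok], minlength=n_total)
    counts = np.bincount(cells[ok], minlength=n_total)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means[grid.selected]


def nmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalized mean square error (fraction; multiply by 100 for %)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ConfigurationError("y and yhat must be equal-length, non-empty")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom <= 0.0:
        raise ConfigurationError("constant experimental vector: NMSE undefined")
    return float(np.sum((yhat - y) ** 2) / denom)


def build_objective_vectors(grid: ComparisonGrid, tracked_by_pressure: dict,
                            fe_by_pressure: dict, pressures) -> tuple:
    """Assemble the paired (y, yhat) vectors.

    ``tracked_by_pressure[p]`` is (values, valid) at the tracking points,
    ``fe_by_pressure[p]`` values at the FE nodes; ordering is cell-major
    with the pressures innermost.  Cells that lose all valid tracking points
    at any pressure are dropped from both vectors (paired construction).
    """
    per_pressure = []
    for p in pressures:
        tvals, tvalid = tracked_by_pressure[p]
        ybar = average_in_cells(tvals, grid.track_cells, grid, valid=tvalid)
        fbar = average_in_cells(fe_by_pressure[p], grid.fe_cells, grid)
        per_pressure.append((ybar, fbar))
    keep = np.all([np.isfinite(a) & np.isfinite(b) for a, b in per_pressure], axis=0)
    y = np.concatenate([np.column_stack([a[keep] for a, _ in per_pressure])])
    yhat = np.concatenate([np.column_stack([b[keep] for _, b in per_pressure])])
    return y.ravel(), yhat.ravel()
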