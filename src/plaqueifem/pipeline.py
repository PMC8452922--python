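"""End-to-end inverse-FEM orchestration.

``run_ifem`` ties the stages together: for every parameter vector proposed
by the optimizer it assigns Yeoh materials to the fibrous intima and wall
(lipid/calcium stay fixed), solves the plane-strain inflation problem,
projects the nodal displacements onto the beam axis, averages both data
sources on the comparison grid and scores the NMSE against the tracked
(experimental) axial displacements.  After the search the final GP is
inverted for the uniqueness assessment.

``make_synthetic_case`` builds a complete case bundle from a phantom and a
known ground-truth material pair — either "noiseless" (the experimental
displacements are FE outputs themselves, so the global minimum is zero) or
through the RF simulation + speckle tracking loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from . import bayesopt, objective, tracking, ultrasound
from .errors import ConfigurationError
from .fem import (FESolution, InflationProtocol, SolverOptions,
                  axial_displacement_field, solve_inflation)
from .materials import MaterialModel, neo_hookean, yeoh
from .phantom import CrossSectionPhantom, MultiComponentMesh, mesh_phantom
from .units import mmhg_to_kpa

__all__ = ["CaseBundle", "IfemResult", "run_ifem", "make_synthetic_case",
           "BEAM_DIRECTION"]

#: Ultrasound beam axis in phantom coordinates: +y, i.e. increasing depth.
BEAM_DIRECTION = (0.0, 1.0)


@dataclass
class CaseBundle:
    """Everything the inverse analysis needs for one cross-section."""

    phantom: CrossSectionPhantom
    mesh: MultiComponentMesh
    tracked_by_pressure: dict       # mmHg -> (positions_mm, axial_mm, valid)
    protocol_mmhg: tuple = (80.0, 100.0, 120.0)
    fixed_materials: dict = field(default_factory=dict)  # lipid/calcium etc.
    space: bayesopt.SearchSpace = field(default_factory=bayesopt.default_search_space)
    solver_opts: SolverOptions = field(default_factory=SolverOptions)
    cell_size_um: float = 100.0
    min_fe_points: int = 3
    min_track_points: int = 3


@dataclass
class IfemResult:
    intima: MaterialModel
    wall: MaterialModel
    nmse: float
    record: bayesopt.OptimizationRecord
    uniqueness: bayesopt.UniquenessReport | None
    converged: bool


def _materials_from_vector(x, fixed: dict) -> dict:
    mats = dict(fixed)
    mats["intima"] = yeoh(x[0], x[1], x[2], name="intima")
    mats["wall"] = yeoh(x[3], x[4], x[5], name="wall")
    return mats


def _cost_function(case: CaseBundle):
    protocol = InflationProtocol.from_mmhg(case.protocol_mmhg)
    pressures = case.protocol_mmhg
    track_pts = np.vstack([case.tracked_by_pressure[p][0] for p in pressures[:1]])
    track_valid = case.tracked_by_pressure[pressures[0]][2]
    grid = objective.build_grid(case.mesh.nodes, track_pts, track_valid,
                                cell_size_um=case.cell_size_um,
                                min_fe_points=case.min_fe_points,
                                min_track_points=case.min_track_points)
    tracked = {p: (case.tracked_by_pressure[p][1], case.tracked_by_pressure[p][2])
               for p in pressures}

    def cost(x):
        mats = _materials_from_vector(x, case.fixed_materials)
        sol = solve_inflation(case.mesh, mats, protocol, case.solver_opts)
        fe = {p: axial_displacement_field(sol, BEAM_DIRECTION, mmhg_to_kpa(p))
              for p in pressures}
        y, yhat = objective.build_objective_vectors(grid, tracked, fe, pressures)
        return objective.nmse(y, yhat)

    return cost, grid


def run_ifem(case: CaseBundle, n_init: int = 50, budget: int = 400, seed: int = 0,
             uniqueness_samples: int = 400) -> IfemResult:
    """Full inverse analysis of one case bundle."""
    cost, _ = _cost_function(case)
    record = bayesopt.minimize(cost, case.space, n_init=n_init, budget=budget,
                               seed=seed)
    best = record.best_x
    uniq = None
    if len(record.x) >= max(2, n_init):
        try:
            sur = bayesopt.fit_gp(record)
            uniq = bayesopt.invert_gp(sur, record.best_y, case.space,
                                      n_samples=uniqueness_samples, seed=seed + 1,
                                      best_parameters=best)
        except ConfigurationError:
            uniq = None
    return IfemResult(intima=yeoh(*best[:3], name="intima"),
                      wall=yeoh(*best[3:], name="wall"),
                      nmse=record.best_y, record=record, uniqueness=uniq,
                      converged=record.termination != "budget" or budget > 1)


# ---------------------------------------------------------------------------
# synthetic case construction

def _fe_displacement_interpolators(mesh, sol: FESolution, pressures_mmhg):
    out = {}
    for p in pressures_mmhg:
        u = sol.displacement(mmhg_to_kpa(p))
        out[p] = LinearNDInterpolator(mesh.nodes, u)
    return out


def make_synthetic_case(phantom: CrossSectionPhantom,
                        true_intima: MaterialModel, true_wall: MaterialModel,
                        mode: str = "noiseless",
                        element_size_mm: float = 0.1,
                        protocol_mmhg=(80.0, 100.0, 120.0),
                        tracking_pressures_mmhg=(10, 15, 20, 25, 30, 40, 50,
                                                 60, 70, 80, 100, 120),
                        imaging: ultrasound.ImagingConfig | None = None,
                        seed: int = 0, scatterer_density: float = 2000.0,
                        space: bayesopt.SearchSpace | None = None) -> CaseBundle:
    """Build a case whose "experimental" data come from known constants.

    ``mode='noiseless'``: the tracked displacements are the ground-truth FE
    axial displacements sampled on a regular grid — the inverse problem's
    global minimum is exactly zero.  ``mode='tracked'``: RF frames of the
    deforming phantom are simulated at the intermediate pressure steps,
    speckle-tracked pair-wise and accumulated, so the experimental vector
    carries realistic estimation noise.
    """
    mesh = mesh_phantom(phantom, target_element_size=element_size_mm)
    fixed = {"lipid": neo_hookean(1.0, name="lipid"),
             "calcium": neo_hookean(1.0e6, name="calcium")}
    fixed = {k: v for k, v in fixed.items() if k in set(mesh.quad_tags)}
    mats = dict(fixed, intima=true_intima, wall=true_wall)

    tracked = {}
    if mode == "noiseless":
        protocol = InflationProtocol.from_mmhg(protocol_mmhg)
        sol = solve_inflation(mesh, mats, protocol)
        # the "experimental" displacements are the forward model's own nodal
        # outputs, so the ground truth attains exactly zero cost
        pts = mesh.nodes.copy()
        valid = np.ones(len(pts), dtype=bool)
        for p in protocol_mmhg:
            axial = sol.displacement(mmhg_to_kpa(p))[:, 1]
            tracked[p] = (pts, axial, valid)
    elif mode == "tracked":
        imaging = imaging or ultrasound.ImagingConfig()
        steps = tuple(tracking_pressures_mmhg)
        if steps[0] != 10:
            raise ConfigurationError("tracking sequence must start at the "
                                     "10 mmHg reference")
        protocol = InflationProtocol.from_mmhg(steps[1:])
        sol = solve_inflation(mesh, mats, protocol)
        interp = _fe_displacement_interpolators(mesh, sol, steps[1:])
        disp = {float(p): interp[p] for p in steps[1:]}
        frames = ultrasound.simulate_sequence(phantom, disp, imaging, seed=seed,
                                              density_per_mm2=scatterer_density)
        pair_fields = [tracking.track_pair(frames[k], frames[k + 1])
                       for k in range(len(frames) - 1)]
        for p in protocol_mmhg:
            upto = [f for f in pair_fields if f.to_pressure_mmhg <= p + 1e-9]
            acc = tracking.accumulate(upto)
            if abs(acc.to_pressure_mmhg - p) > 1e-9:
                raise ConfigurationError(
                    f"tracking sequence has no step ending at {p} mmHg")
            pts = acc.positions_mm()
            axial_mm = acc.axial_um.ravel() * 1e-3
            valid = acc.valid.ravel()
            # the co-registered morphology defines the measurement ROI:
            # points in the echo-free lumen/bath carry no displacement signal
            px = phantom.pixel_size
            cols = np.clip(((pts[:, 0] - phantom.origin[0]) / px).astype(int),
                           0, phantom.label_mask.shape[1] - 1)
            rows = np.clip(((pts[:, 1] - phantom.origin[1]) / px).astype(int),
                           0, phantom.label_mask.shape[0] - 1)
            valid = valid & np.isin(phantom.label_mask[rows, cols],
                                    (2, 3, 4, 5))
            tracked[p] = (pts, axial_mm, valid)
    else:
        raise ConfigurationError(f"unknown mode '{mode}'")

    # coarse recovery meshes carry ~1-2 nodes per 100 um cell (the analog of
    # ~10 nodes/cell on a production 0.035 mm mesh), so a single FE node
    # suffices for a cell average here
    return CaseBundle(phantom=phantom, mesh=mesh, tracked_by_pressure=tracked,
                      protocol_mmhg=tuple(protocol_mmhg), fixed_materials=fixed,
                      space=space or bayesopt.default_search_space(),
                      min_fe_points=1,
                      min_track_points=1 if mode == "noiseless" else 3)
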