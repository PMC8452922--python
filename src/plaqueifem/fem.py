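"""Forward model: quasi-static plane-strain inflation of a multicomponent
hyperelastic cross-section.

Formulation
-----------
Displacement/pressure mixed finite elements: bilinear quadrilaterals for the
displacement with a single (element-wise constant) hydrostatic pressure
unknown enforcing the incompressibility constraint ``det F = 1`` in the
element mean — the open-source analog of the commercial "hybrid" plane-strain
element.  The out-of-plane stretch is fixed at 1 and included in
``I1 = tr(F F^T) + 1``, so the first Piola-Kirchhoff stress is

    P = 2 W'(I1) F - p cof(F).

The intraluminal pressure acts as a follower load on the deformed lumen
boundary.  The outer (bath) boundary is traction free; the three in-plane
rigid-body modes are removed by Lagrange constraints on the mesh-average
translation and rotation.  Newton's method with adaptive load sub-stepping
and an analytic consistent tangent (including the follower-load term) is used
throughout; divergence is reported carrying the last converged pressure so a
surrounding optimizer can penalize rather than crash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, FESolverError
from .materials import MaterialKind, MaterialModel, check_yeoh_stability
from .phantom import MultiComponentMesh
from .units import mmhg_to_kpa

__all__ = ["InflationProtocol", "SolverOptions", "FESolution", "solve_inflation",
           "axial_displacement_field"]


@dataclass(frozen=True)
class InflationProtocol:
    """Target pressures in kPa, strictly increasing.

    ``reference_pressure_kpa`` is the (approximately 10 mmHg) imaging state
    at which the geometry was acquired.  By default the reference state is
    treated as stress-free and the listed pressures are applied in full;
    with ``SolverOptions.incremental`` the applied load is reduced by the
    reference pressure instead.
    """

    pressures_kpa: tuple
    reference_pressure_kpa: float = mmhg_to_kpa(10.0)

    def __post_init__(self):
        p = tuple(float(v) for v in self.pressures_kpa)
        if any(v < 0 for v in p) or any(b <= a for a, b in zip(p, p[1:])):
            raise ConfigurationError("pressures must be >= 0 and strictly increasing")
        object.__setattr__(self, "pressures_kpa", p)

    @classmethod
    def from_mmhg(cls, pressures_mmhg=(80.0, 100.0, 120.0), reference_mmhg=10.0):
        return cls(tuple(mmhg_to_kpa(p) for p in pressures_mmhg),
                   reference_pressure_kpa=mmhg_to_kpa(reference_mmhg))


@dataclass(frozen=True)
class SolverOptions:
    newton_tol: float = 1e-8        # relative residual
    max_newton_iterations: int = 15
    min_load_step_kpa: float = 1e-4
    incremental: bool = False       # apply P - P_ref instead of P
    formulation: str = "mixed"      # element-wise constant pressure (Q1/P0)

    def __post_init__(self):
        if self.formulation != "mixed":
            raise ConfigurationError("only the mixed u/p formulation is implemented")


@dataclass
class FESolution:
    mesh: MultiComponentMesh
    protocol: InflationProtocol
    displacements: dict             # pressure_kpa -> (N, 2) mm
    pressure_field: dict            # pressure_kpa -> (E,) kPa
    diagnostics: list = field(default_factory=list)

    def _lookup(self, pressure_kpa: float) -> float:
        for key in self.displacements:
            if abs(key - pressure_kpa) <= 1e-9 + 1e-9 * abs(key):
                return key
        raise KeyError(f"pressure {pressure_kpa} kPa not in solution "
                       f"(have {sorted(self.displacements)})")

    def displacement(self, pressure_kpa: float) -> np.ndarray:
        return self.displacements[self._lookup(pressure_kpa)]

    def to_dataframe(self):
        """Long-format table of nodal displacements per pressure (CSV-ready)."""
        import pandas as pd

        frames = []
        for p in sorted(self.displacements):
            u = self.displacements[p]
            frames.append(pd.DataFrame({
                "pressure_kpa": p, "node": np.arange(len(u)),
                "x_mm": self.mesh.nodes[:, 0], "y_mm": self.mesh.nodes[:, 1],
                "ux_mm": u[:, 0], "uy_mm": u[:, 1]}))
        return pd.concat(frames, ignore_index=True)

    def max_volumetric_strain(self, pressure_kpa: float) -> float:
        """max |mean(J) - 1| over elements (incompressibility check)."""
        u = self.displacement(pressure_kpa)
        asm = _Assembler(self.mesh, np.zeros(3), np.zeros(3), np.zeros(3))
        jbar = asm.element_mean_j(u)
        return float(np.max(np.abs(jbar - 1.0)))


def axial_displacement_field(solution: FESolution, beam_direction, pressure_kpa: float
                             ) -> np.ndarray:
    """Project nodal displacements onto the ultrasound beam direction.

    Positive values point along ``beam_direction`` (by convention away from
    the transducer, i.e. increasing image depth).
    """
    b = np.asarray(beam_direction, dtype=float)
    b = b / np.linalg.norm(b)
    return solution.displacement(pressure_kpa) @ b


# ---------------------------------------------------------------------------

_GAUSS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


def _shape_gradients(xi, eta):
    # bilinear quad, nodes at (-1,-1),(1,-1),(1,1),(-1,1)
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


class _Assembler:
    """Precomputed quadrature data and sparse index maps for one mesh."""

    def __init__(self, mesh: MultiComponentMesh, c1, c2, c3):
        if len(mesh.tris):
            raise ConfigurationError("triangle elements are not supported by the solver")
        self.mesh = mesh
        self.c1, self.c2, self.c3 = c1, c2, c3
        nodes, quads = mesh.nodes, mesh.quads
        self.nn, self.ne = len(nodes), len(quads)
        xe = nodes[quads]                                   # (E, 4, 2)
        grads, wdet = [], []
        for xi, eta in _GAUSS:
            dn = _shape_gradients(xi, eta)                  # (4, 2) reference
            jac = np.einsum("eak,aj->ekj", xe, dn)          # (E, 2, 2) dX/dxi
            det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
            inv = np.empty_like(jac)
            inv[:, 0, 0], inv[:, 1, 1] = jac[:, 1, 1], jac[:, 0, 0]
            inv[:, 0, 1], inv[:, 1, 0] = -jac[:, 0, 1], -jac[:, 1, 0]
            inv /= det[:, None, None]
            grads.append(np.einsum("aj,ejk->eak", dn, inv))  # physical dN/dX
            wdet.append(det)
        self.grad = np.stack(grads, axis=1)                 # (E, 4, 4nodes, 2) g-major
        self.wdet = np.stack(wdet, axis=1)                  # (E, 4)

        # dof layout: u interleaved (2*nn) | p (ne).  Rigid-body modes are
        # removed by pinning 3 dofs (a sparse gauge choice); solutions are
        # post-projected to the zero-average-translation/rotation gauge.
        self.ndof = 2 * self.nn + self.ne
        edof = (2 * quads[:, :, None] + np.arange(2)).reshape(self.ne, 8)
        self.edof = edof
        self.iuu = np.repeat(edof, 8, axis=1).ravel()
        self.juu = np.tile(edof, (1, 8)).ravel()
        pdof = 2 * self.nn + np.arange(self.ne)
        self.iup = np.repeat(edof, 1, axis=1).ravel()
        self.jup = np.repeat(pdof, 8)
        # gauge: clamp node n0 fully; block rotation about n0 at the node
        # farthest from it (the component most sensitive to rotation)
        n0 = 0
        d = nodes - nodes[n0]
        n1 = int(np.argmax(np.einsum("ni,ni->n", d, d)))
        comp = 0 if abs(d[n1, 1]) > abs(d[n1, 0]) else 1
        self.fixed_dofs = np.array([2 * n0, 2 * n0 + 1, 2 * n1 + comp])
        self._free_mask = np.ones(self.ndof, dtype=bool)
        self._free_mask[self.fixed_dofs] = False
        # lumen boundary edges for the follower load
        self.ledges = mesh.boundary_edges["lumen_boundary"]

    def project_rigid(self, u):
        """Remove the best-fit (linearized) rigid motion from a nodal field."""
        v = u.reshape(-1, 2).copy()
        v -= v.mean(axis=0)
        xy = self.mesh.nodes - self.mesh.nodes.mean(axis=0)
        omega = float(np.sum(xy[:, 0] * v[:, 1] - xy[:, 1] * v[:, 0])
                      / np.sum(xy * xy))
        v[:, 0] += omega * xy[:, 1]
        v[:, 1] -= omega * xy[:, 0]
        return v

    def kinematics(self, u):
        ue = u.reshape(-1, 2)[self.mesh.quads]              # (E, 4, 2)
        f = np.einsum("eai,egaj->egij", ue, self.grad)
        f[:, :, 0, 0] += 1.0
        f[:, :, 1, 1] += 1.0
        i1 = np.einsum("egij,egij->eg", f, f) + 1.0
        detf = f[:, :, 0, 0] * f[:, :, 1, 1] - f[:, :, 0, 1] * f[:, :, 1, 0]
        cof = np.empty_like(f)
        cof[:, :, 0, 0], cof[:, :, 1, 1] = f[:, :, 1, 1], f[:, :, 0, 0]
        cof[:, :, 0, 1], cof[:, :, 1, 0] = -f[:, :, 1, 0], -f[:, :, 0, 1]
        return f, i1, detf, cof

    def element_mean_j(self, u):
        _, _, detf, _ = self.kinematics(np.asarray(u).ravel())
        return np.einsum("eg,eg->e", detf, self.wdet) / self.wdet.sum(axis=1)

    def follower_load(self, u, pressure):
        """Consistent nodal force and tangent triplets for lumen pressure."""
        x = self.mesh.nodes + u.reshape(-1, 2)
        a, b = self.ledges[:, 0], self.ledges[:, 1]
        e = x[b] - x[a]                                     # (B, 2)
        fedge = 0.5 * pressure * np.column_stack([e[:, 1], -e[:, 0]])
        fvec = np.zeros(2 * self.nn)
        np.add.at(fvec, 2 * a, fedge[:, 0])
        np.add.at(fvec, 2 * a + 1, fedge[:, 1])
        np.add.at(fvec, 2 * b, fedge[:, 0])
        np.add.at(fvec, 2 * b + 1, fedge[:, 1])
        # d f_n / d x_a = -(P/2) S,  d f_n / d x_b = +(P/2) S,  S = [[0,1],[-1,0]]
        rows, cols, vals = [], [], []
        half = 0.5 * pressure
        for n in (a, b):
            for src, sgn in ((a, -half), (b, half)):
                rows += [2 * n, 2 * n + 1]
                cols += [2 * src + 1, 2 * src]
                vals += [np.full(len(n), sgn), np.full(len(n), -sgn)]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return fvec, (rows, cols, vals)

    def residual_and_tangent(self, u, p, pressure):
        f, i1, detf, cof = self.kinematics(u)
        x = i1 - 3.0
        wp = self.c1[:, None] + 2 * self.c2[:, None] * x + 3 * self.c3[:, None] * x * x
        wpp = 2 * self.c2[:, None] + 6 * self.c3[:, None] * x
        g, wd = self.grad, self.wdet

        pk = 2.0 * wp[..., None, None] * f - p[:, None, None, None] * cof
        r_ue = np.einsum("egij,egaj,eg->eai", pk, g, wd)
        r_pe = -np.einsum("eg,eg->e", detf - 1.0, wd)

        fg = np.einsum("egij,egaj->egai", f, g)             # (F gradNa)_i
        k1 = np.einsum("eg,egai,egbk,eg->eaibk", 4.0 * wpp, fg, fg, wd)
        d_ab = np.einsum("eg,egaj,egbj,eg->eab", 2.0 * wp, g, g, wd)
        k1[:, :, 0, :, 0] += d_ab
        k1[:, :, 1, :, 1] += d_ab
        xab = np.einsum("ega,egb,eg->eab", g[..., 0], g[..., 1], wd) \
            - np.einsum("ega,egb,eg->eab", g[..., 1], g[..., 0], wd)
        k1[:, :, 0, :, 1] -= p[:, None, None] * xab
        k1[:, :, 1, :, 0] += p[:, None, None] * xab
        k_up = -np.einsum("egij,egaj,eg->eai", cof, g, wd)  # (E, 4, 2)

        fext, (br, bc, bv) = self.follower_load(u, pressure)

        rows = np.concatenate([self.iuu, self.iup, self.jup, br])
        cols = np.concatenate([self.juu, self.jup, self.iup, bc])
        vals = np.concatenate([k1.reshape(-1), k_up.reshape(-1),
                               k_up.reshape(-1), -bv])
        # eliminate pinned dofs: drop their rows/cols, unit diagonal
        keep = self._free_mask[rows] & self._free_mask[cols]
        rows = np.concatenate([rows[keep], self.fixed_dofs])
        cols = np.concatenate([cols[keep], self.fixed_dofs])
        vals = np.concatenate([vals[keep], np.ones(len(self.fixed_dofs))])
        kmat = sp.coo_matrix((vals, (rows, cols)), shape=(self.ndof, self.ndof))

        res = np.zeros(self.ndof)
        np.add.at(res, self.edof.ravel(), r_ue.reshape(-1))
        res[2 * self.nn: 2 * self.nn + self.ne] = r_pe
        res[: 2 * self.nn] -= fext
        res[self.fixed_dofs] = 0.0
        return res, kmat.tocsr(), float(np.linalg.norm(fext))


def _material_arrays(mesh: MultiComponentMesh, materials: dict):
    c1 = np.empty(len(mesh.quads))
    c2 = np.zeros(len(mesh.quads))
    c3 = np.zeros(len(mesh.quads))
    for tag in np.unique(mesh.quad_tags):
        if tag not in materials:
            raise ConfigurationError(f"no material supplied for component '{tag}'")
        m: MaterialModel = materials[tag]
        sel = mesh.quad_tags == tag
        if m.kind is MaterialKind.YEOH:
            verdict = check_yeoh_stability(*m.constants)
            if not verdict.stable:
                warnings.warn(
                    f"Yeoh constants for '{tag}' violate the stability criteria "
                    f"({', '.join(verdict.violated_conditions)}); attempting anyway",
                    stacklevel=3)
            c1[sel], c2[sel], c3[sel] = m.constants
        else:
            c1[sel] = m.constants[0]
    return c1, c2, c3


def solve_inflation(mesh: MultiComponentMesh, materials: dict,
                    protocol: InflationProtocol,
                    solver_opts: SolverOptions | None = None) -> FESolution:
    """Solve the inflation problem at every protocol pressure.

    Returns nodal displacements (mm, relative to the reference configuration)
    and the element hydrostatic pressure field per target pressure.
    """
    opts = solver_opts or SolverOptions()
    c1, c2, c3 = _material_arrays(mesh, materials)
    asm = _Assembler(mesh, c1, c2, c3)

    u = np.zeros(2 * asm.nn)
    p = 2.0 * c1.copy()          # hydrostatic unknown of the stress-free state
    diagnostics = []
    sol = FESolution(mesh=mesh, protocol=protocol, displacements={},
                     pressure_field={}, diagnostics=diagnostics)

    offset = protocol.reference_pressure_kpa if opts.incremental else 0.0
    p_cur = 0.0
    for target in protocol.pressures_kpa:
        applied_target = max(target - offset, 0.0)
        step = applied_target - p_cur
        while p_cur < applied_target - 1e-12:
            trial = min(p_cur + step, applied_target)
            ok, iters, resnorm, (u_t, p_t) = _newton(asm, u, p, trial, opts)
            if ok:
                u, p = u_t, p_t
                p_cur = trial
                diagnostics.append({"pressure_kpa": trial, "iterations": iters,
                                    "residual": resnorm})
                step *= 1.5
            else:
                step *= 0.5
                if step < opts.min_load_step_kpa:
                    raise FESolverError(
                        f"Newton diverged near {trial:.3f} kPa",
                        last_converged_pressure_kpa=p_cur)
        sol.displacements[target] = asm.project_rigid(u)
        sol.pressure_field[target] = p.copy()
    return sol


def _newton(asm: _Assembler, u0, p0, pressure, opts: SolverOptions):
    u, p = u0.copy(), p0.copy()
    nn = asm.nn
    resnorm, prev = np.inf, np.inf
    grew = 0
    for it in range(opts.max_newton_iterations + 1):
        res, kmat, fext_norm = asm.residual_and_tangent(u, p, pressure)
        scale = max(fext_norm, 1.0)
        resnorm = np.linalg.norm(res) / scale
        if resnorm < opts.newton_tol:
            return True, it, resnorm, (u, p)
        grew = grew + 1 if resnorm > 2.0 * prev else 0
        if grew >= 2:                    # diverging: fail fast, halve the load
            return False, it, resnorm, (u, p)
        prev = min(prev, resnorm)
        try:
            delta = spla.spsolve(kmat.tocsc(), -res)
        except Exception:
            return False, it, resnorm, (u, p)
        if not np.all(np.isfinite(delta)):
            return False, it, resnorm, (u, p)
        u += delta[: 2 * nn]
        p += delta[2 * nn:]
        if np.max(np.abs(u)) > 100.0:    # runaway: treat as divergence
            return False, it, resnorm, (u, p)
    return False, opts.max_newton_iterations, resnorm, (u, p)
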