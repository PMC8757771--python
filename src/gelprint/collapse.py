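"""Transient plane-strain Kelvin–Voigt collapse of a printed scaffold.

A freshly printed soft-gel lattice creeps under its own weight.  The gel
(and, in embedded printing, the sacrificial support bath filling its
pores) is modelled as a Kelvin–Voigt solid: stress is the sum of a linear
elastic part and a viscous part proportional to the strain rate,

    sigma = C(E, nu) : eps + (eta0 / E) * C(E, nu) : eps_dot.

Scaling the viscous operator by the elastic one gives every subdomain a
single retardation time tau = eta0 / E, the same constant that governs
the one-dimensional Kelvin–Voigt creep law (sigma/E)(1 - exp(-E t/eta0));
under a constant load the full FE solution then relaxes exponentially to
the elastic equilibrium with that time constant.

Discretisation: linear (constant-strain) triangles, plane strain, gravity
as a consistent body load, implicit backward-Euler time stepping with the
constant system matrix factorised once.  Boundary conditions mirror the
printing situation: the bottom edge sits on the build plate (fixed), the
lateral edges are symmetry planes of the periodic lattice (zero normal
displacement), the top is free.

Small-strain linear kinematics are used throughout.  Collapse strains of
very soft gels can exceed the linear range; results beyond 20% strain are
flagged as indicative only (see ``CollapseSolution.beyond_linear_validity``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .mesh import GEL, SUPPORT, Mesh2D, ScaffoldUnitCell, build_unit_cell_mesh
from .rheology import KelvinVoigtMaterial

__all__ = [
    "CollapseSolution",
    "CollapseComparison",
    "solve_collapse",
    "compare_strategies",
    "analytic_kv_creep",
    "oedometric_modulus",
    "LINEAR_VALIDITY_STRAIN",
]

#: strains above this are outside small-strain validity and only indicative
LINEAR_VALIDITY_STRAIN = 0.20


def plane_strain_stiffness(E: float, nu: float) -> np.ndarray:
    """Plane-strain elastic matrix for [eps_xx, eps_yy, gamma_xy]."""
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return f * np.array(
        [
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ]
    )


def oedometric_modulus(E: float, nu: float) -> float:
    """Constrained (zero-lateral-strain, plane-strain) axial modulus.

    A laterally confined column compresses with this modulus; it reduces
    to E at nu = 0.
    """
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass
class CollapseSolution:
    """Transient solution with the monitored point A series.

    Point A is the upper outer corner node of the top strand; its final
    displacement magnitude divided by the initial structure height is the
    reported collapse strain.
    """

    times: np.ndarray  # (n_t,)
    displacements: np.ndarray  # (n_t, n_nodes, 2), zero at t = 0
    point_a: int
    height: float
    mesh: Mesh2D

    @property
    def point_a_series(self) -> np.ndarray:
        return np.linalg.norm(self.displacements[:, self.point_a, :], axis=1)

    @property
    def final_displacement(self) -> float:
        return float(self.point_a_series[-1])

    @property
    def final_strain(self) -> float:
        return self.final_displacement / self.height

    @property
    def beyond_linear_validity(self) -> bool:
        return self.final_strain > LINEAR_VALIDITY_STRAIN

    def series_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time": self.times, "point_a_displacement": self.point_a_series}
        ).to_csv(path, index=False)


def _assemble(mesh: Mesh2D, materials: dict[int, KelvinVoigtMaterial], gravity: float):
    """Stiffness K, damping B (= tau * K per subdomain) and gravity load F."""
    pts = mesh.points
    t = mesh.thickness
    n_dof = 2 * mesh.n_nodes

    rows, cols, k_vals, b_vals = [], [], [], []
    F = np.zeros(n_dof)
    C_by_label = {lab: plane_strain_stiffness(m.E, m.nu) for lab, m in materials.items()}
    tau_by_label = {lab: m.retardation_time for lab, m in materials.items()}

    for tri, lab in zip(mesh.triangles, mesh.labels):
        lab = int(lab)
        mat = materials[lab]
        p = pts[tri]
        x, y = p[:, 0], p[:, 1]
        area = 0.5 * (
            (x[1] - x[0]) * (y[2] - y[0]) - (y[1] - y[0]) * (x[2] - x[0])
        )
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / (2 * area)
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / (2 * area)
        Bm = np.zeros((3, 6))
        Bm[0, 0::2] = b
        Bm[1, 1::2] = c
        Bm[2, 0::2] = c
        Bm[2, 1::2] = b
        Ke = t * area * Bm.T @ C_by_label[lab] @ Bm
        dofs = np.empty(6, dtype=np.int64)
        dofs[0::2] = 2 * tri
        dofs[1::2] = 2 * tri + 1
        rr, cc = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        k_vals.append(Ke.ravel())
        b_vals.append((tau_by_label[lab] * Ke).ravel())
        # consistent body load: -rho g y, a third of the element weight per node
        F[dofs[1::2]] += -mat.rho * gravity * t * area / 3.0

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = coo_matrix((np.concatenate(k_vals), (rows, cols)), shape=(n_dof, n_dof)).tocsc()
    B = coo_matrix((np.concatenate(b_vals), (rows, cols)), shape=(n_dof, n_dof)).tocsc()
    return K, B, F


def _constrained_dofs(mesh: Mesh2D) -> np.ndarray:
    """Fixed bottom edge; zero normal displacement on the symmetry sides."""
    fixed = set()
    for nid in mesh.bottom_nodes():
        fixed.add(2 * nid)
        fixed.add(2 * nid + 1)
    for nid in np.concatenate([mesh.left_nodes(), mesh.right_nodes()]):
        fixed.add(2 * nid)
    return np.asarray(sorted(fixed), dtype=np.int64)


def _top_edge_load(mesh: Mesh2D, traction: float) -> np.ndarray:
    """Consistent nodal forces (vertical) for a uniform traction on the top edge."""
    F = np.zeros(2 * mesh.n_nodes)
    if traction == 0.0:
        return F
    ymax = mesh.points[:, 1].max()
    tol = mesh._tol()
    for a, b in mesh.boundary_edges():
        if mesh.points[a, 1] >= ymax - tol and mesh.points[b, 1] >= ymax - tol:
            length = abs(mesh.points[a, 0] - mesh.points[b, 0])
            f = traction * length * mesh.thickness / 2.0
            F[2 * a + 1] += f
            F[2 * b + 1] += f
    return F


def _monitor_point(mesh: Mesh2D) -> int:
    """Upper outer corner of the top strand: max y, then max x."""
    y = mesh.points[:, 1]
    tol = mesh._tol()
    top = np.nonzero(y >= y.max() - tol)[0]
    return int(top[np.argmax(mesh.points[top, 0])])


def solve_collapse(
    mesh: Mesh2D,
    gel: KelvinVoigtMaterial,
    support: KelvinVoigtMaterial | None = None,
    gravity: float = 9.81,
    t_end: float = 200.0,
    dt: float = 0.5,
    top_traction: float = 0.0,
) -> CollapseSolution:
    """Backward-Euler transient solve of the gravity-driven collapse.

    ``support`` must be given iff the mesh contains support-labelled
    elements.  ``top_traction`` (Pa, negative = downward) applies an extra
    uniform load on the top edge — used by the creep validation oracle.
    """
    has_support = bool(np.any(mesh.labels == SUPPORT))
    if has_support and support is None:
        raise ValueError("mesh has support elements but no support material was given")
    if not has_support and support is not None:
        raise ValueError("support material given but the mesh has no support elements")
    materials = {GEL: gel}
    if has_support:
        materials[SUPPORT] = support

    K, B, F = _assemble(mesh, materials, gravity)
    F = F + _top_edge_load(mesh, top_traction)

    fixed = _constrained_dofs(mesh)
    if fixed.size == 0:
        raise ValueError("no constrained degrees of freedom: the system is singular")
    n_dof = 2 * mesh.n_nodes
    free = np.setdiff1d(np.arange(n_dof), fixed)

    Kf = K[np.ix_(free, free)]
    Bf = B[np.ix_(free, free)]
    Ff = F[free]

    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    disp = np.zeros((n_steps + 1, mesh.n_nodes, 2))

    lhs = splu(csc_matrix(Kf + Bf / dt))
    u = np.zeros(free.size)
    for k in range(1, n_steps + 1):
        rhs = Ff + Bf.dot(u) / dt
        u = lhs.solve(rhs)
        full = np.zeros(n_dof)
        full[free] = u
        disp[k] = full.reshape(-1, 2)

    height = float(mesh.points[:, 1].max() - mesh.points[:, 1].min())
    return CollapseSolution(
        times=times,
        displacements=disp,
        point_a=_monitor_point(mesh),
        height=height,
        mesh=mesh,
    )


def analytic_kv_creep(E: float, eta: float, stress: float, t):
    """1-D Kelvin–Voigt creep strain (stress/E)(1 - exp(-E t / eta)).

    ``eta = 0`` degenerates to the instantaneous elastic response stress/E.
    Accepts scalar or array times.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if eta < 0:
        raise ValueError("eta must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    eq = stress / E
    if eta == 0.0:
        out = np.full_like(t_arr, eq, dtype=float)
    else:
        out = eq * (1.0 - np.exp(-E * t_arr / eta))
    return float(out) if np.isscalar(t) else out


@dataclass
class CollapseComparison:
    """Paired solutions of the two printing strategies on the same gel cell."""

    without_support: CollapseSolution
    with_support: CollapseSolution

    @property
    def strain_without(self) -> float:
        return self.without_support.final_strain

    @property
    def strain_with(self) -> float:
        return self.with_support.final_strain

    @property
    def improvement_ratio(self) -> float:
        """How many times smaller the final strain is with the support bath."""
        return self.strain_without / self.strain_with

    def summary(self) -> dict:
        return {
            "final_strain_without_support": self.strain_without,
            "final_strain_with_support": self.strain_with,
            "improvement_ratio": self.improvement_ratio,
            "beyond_linear_validity_without_support":
                self.without_support.beyond_linear_validity,
            "beyond_linear_validity_with_support":
                self.with_support.beyond_linear_validity,
        }


def compare_strategies(
    cell: ScaffoldUnitCell,
    gel: KelvinVoigtMaterial,
    support: KelvinVoigtMaterial,
    gravity: float = 9.81,
    t_end: float = 200.0,
    dt: float = 0.5,
    target_element_size: float | None = None,
) -> CollapseComparison:
    """Run the collapse model with and without the sacrificial bath."""
    mesh_plain = build_unit_cell_mesh(cell, with_support=False,
                                      target_element_size=target_element_size)
    mesh_bath = build_unit_cell_mesh(cell, with_support=True,
                                     target_element_size=target_element_size)
    sol_plain = solve_collapse(mesh_plain, gel, None, gravity, t_end, dt)
    sol_bath = solve_collapse(mesh_bath, gel, support, gravity, t_end, dt)
    return CollapseComparison(without_support=sol_plain, with_support=sol_bath)
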