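"""Quasi-static large-deformation membrane finite elements.

Three-node membrane elements in a total-Lagrangian setting: the Green–Lagrange
strain ``E = (FᵀF − I)/2`` of the mapping from the reference element plane into
3-D is paired with a St. Venant–Kirchhoff material reduced to plane stress,

    S = Ey/(1 − ν²) [ (1 − ν) E + ν tr(E) I ],

where ``S`` is the in-plane second Piola–Kirchhoff stress.  The law is linear
in ``E`` but fully objective under large rotations.  Pressure acts as a
follower load on the deformed faces; equal internal cell pressures cancel
exactly on shared lateral walls because those triangles carry both owners.

Units: µm, kPa; forces come out in nN (kPa·µm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .meshing import (
    TAG_ABLUMINAL,
    TAG_LUMINAL,
    MembraneMesh,
)


@dataclass
class MaterialParams:
    """Isotropic St. Venant membrane material.

    ``youngs_modulus`` defaults to 100 kPa, chosen so that two 0.1 µm
    membranes spanning a 2 µm-deep cell reproduce a 10 kPa effective
    cell-level modulus.  The Poisson ratio is not pinned down by the membrane
    idealization; 0.3 is the package default and is exposed for sweeps.
    """

    youngs_modulus: float = 100.0
    poisson_ratio: float = 0.3
    thickness: float = 0.1

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")

    @property
    def plane_stress_matrix(self) -> np.ndarray:
        """Voigt elasticity matrix for [E11, E22, 2E12]."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        f = E / (1.0 - nu * nu)
        return f * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - nu)]]
        )

    @property
    def mu(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))


def effective_cell_modulus(material: MaterialParams, depth: float = 2.0) -> float:
    """Cell-level Young's modulus implied by the membrane idealization.

    Two membranes of thickness ``t`` span a cell of depth ``d``, so the
    membrane cross-section is a fraction ``2t/d`` of the cell cross-section
    and the homogenized modulus is ``E * 2t / d`` — 10 kPa for the defaults
    (100 kPa, 0.1 µm, 2 µm).
    """
    return material.youngs_modulus * 2.0 * material.thickness / depth


@dataclass
class LoadCase:
    """Pressure loading of the monolayer, all in kPa.

    ``cell_pressure`` acts normal to the inside faces of every cell (and
    cancels on shared walls); ``lumen_pressure`` and ``abluminal_pressure``
    push on the luminal/abluminal surfaces from outside the monolayer.
    ``end_constraint`` is ``"pinned"`` (both end node rings fixed) or
    ``"one_end"`` (only the z=0 ring fixed).
    """

    cell_pressure: float = 0.015
    lumen_pressure: float = 0.0
    abluminal_pressure: float = 0.0
    end_constraint: str = "pinned"

    def __post_init__(self) -> None:
        for v in (self.cell_pressure, self.lumen_pressure, self.abluminal_pressure):
            if not np.isfinite(v):
                raise ValueError("pressures must be finite")
        if self.end_constraint not in ("pinned", "one_end"):
            raise ValueError(f"unknown end_constraint {self.end_constraint!r}")

    @classmethod
    def transmural(cls, dp: float, cell_pressure: float = 0.015, **kw):
        """Load case with interstitial pressure exceeding lumen pressure by
        ``dp`` (kPa), realized as the equivalent lumen suction −dp — the
        higher pressure is assigned to the inside (luminal) faces."""
        return cls(cell_pressure=cell_pressure, lumen_pressure=-dp, **kw)


@dataclass
class SolverOptions:
    """Options for the quasi-static equilibrium solve.

    Equilibrium is found by minimizing the total potential energy (elastic
    energy minus the pressure–volume work of the follower loads) with a
    truncated-Newton method (Newton-CG on diagonally scaled variables, using
    the analytic tangent for Hessian-vector products), optionally ramping the
    load in ``n_steps`` increments.  Energy minimization handles the
    post-buckling character of membrane bulging/lumen collapse, where
    load-controlled Newton continuation from the unstressed state stalls on
    near-inextensional soft modes.  ``tol_rel`` is on the max-norm of the
    residual (= energy gradient) relative to the max nodal external force.
    """

    n_steps: int = 1
    max_iterations: int = 400  # truncated-Newton outer iterations per step
    tol_rel: float = 1e-4
    tol_abs: float = 1e-9
    verbose: bool = False


@dataclass
class EquilibriumState:
    """Converged (or partially converged) nodal solution and element fields."""

    displacements: np.ndarray  # (N, 3) µm
    strain_voigt: np.ndarray  # (M, 3) [E11, E22, 2E12]
    stress_voigt: np.ndarray  # (M, 3) [S11, S22, S12] kPa
    stress_trace: np.ndarray  # (M,) kPa
    residual_norm: float
    converged: bool
    load_factor: float = 1.0
    load_history: list = field(default_factory=list)

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


# ---------------------------------------------------------------------------
# element kernels
# ---------------------------------------------------------------------------


def _skew(v: np.ndarray) -> np.ndarray:
    """Skew matrices for an (n,3) array of vectors."""
    z = np.zeros(len(v))
    return np.array(
        [
            [z, -v[:, 2], v[:, 1]],
            [v[:, 2], z, -v[:, 0]],
            [-v[:, 1], v[:, 0], z],
        ]
    ).transpose(2, 0, 1)


class MembraneAssembler:
    """Vectorized assembly of internal/external forces and tangents."""

    def __init__(self, mesh: MembraneMesh, material: MaterialParams):
        self.mesh = mesh
        self.material = material
        tri = mesh.triangles
        X = mesh.nodes
        d1 = X[tri[:, 1]] - X[tri[:, 0]]
        d2 = X[tri[:, 2]] - X[tri[:, 0]]
        nrm = np.cross(d1, d2)
        a2 = np.linalg.norm(nrm, axis=1)
        if np.any(a2 < 1e-12):
            bad = np.where(a2 < 1e-12)[0]
            raise ValueError(f"degenerate reference triangles: {bad[:10]}")
        self.area = 0.5 * a2
        l1 = np.linalg.norm(d1, axis=1)
        e1 = d1 / l1[:, None]
        e2 = np.cross(nrm / a2[:, None], e1)
        # reference plane metric [[l1, d2.e1], [0, d2.e2]]
        m01 = np.einsum("ij,ij->i", d2, e1)
        m11 = np.einsum("ij,ij->i", d2, e2)
        # analytic inverse of the upper-triangular 2x2
        Binv = np.zeros((len(tri), 2, 2))
        Binv[:, 0, 0] = 1.0 / l1
        Binv[:, 0, 1] = -m01 / (l1 * m11)
        Binv[:, 1, 1] = 1.0 / m11
        self.Binv = Binv
        self.Cmat = material.plane_stress_matrix

        # relative-dof expansion: d(3a+i) = u(node a+1, i) - u(node 0, i)
        T = np.zeros((6, 9))
        for a in range(2):
            for i in range(3):
                T[3 * a + i, 3 * (a + 1) + i] = 1.0
                T[3 * a + i, i] = -1.0
        self.T = T
        self.edofs = (3 * tri[:, [0, 0, 0, 1, 1, 1, 2, 2, 2]]) + np.tile(
            [0, 1, 2], 3
        )
        self.ndof = 3 * mesh.n_nodes

    # -- kinematics --------------------------------------------------------

    def _deformation(self, u: np.ndarray):
        tri = self.mesh.triangles
        x = self.mesh.nodes + u
        D = np.stack(
            [x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]]], axis=2
        )  # (M, 3, 2)
        F = np.einsum("eid,eda->eia", D, self.Binv)
        C = np.einsum("eia,eib->eab", F, F)
        Ev = np.stack(
            [
                0.5 * (C[:, 0, 0] - 1.0),
                0.5 * (C[:, 1, 1] - 1.0),
                C[:, 0, 1],
            ],
            axis=1,
        )  # Voigt [E11, E22, 2E12]
        Sv = Ev @ self.Cmat.T
        return F, Ev, Sv

    def strain_stress(self, u: np.ndarray):
        _, Ev, Sv = self._deformation(u)
        trace = Sv[:, 0] + Sv[:, 1]
        return Ev, Sv, trace

    def energy(self, u: np.ndarray) -> float:
        _, Ev, Sv = self._deformation(u)
        psi = 0.5 * np.einsum("ei,ei->e", Sv, Ev)
        return float(np.sum(self.area * self.material.thickness * psi))

    def energy_and_force(self, u: np.ndarray):
        """Stored energy and internal nodal forces in one kinematics pass."""
        F, Ev, Sv = self._deformation(u)
        At = self.area * self.material.thickness
        e = float(np.dot(At, 0.5 * np.einsum("ei,ei->e", Sv, Ev)))
        S = np.empty((len(Sv), 2, 2))
        S[:, 0, 0] = Sv[:, 0]
        S[:, 1, 1] = Sv[:, 1]
        S[:, 0, 1] = S[:, 1, 0] = Sv[:, 2]
        fD = At[:, None, None] * np.einsum("eia,eab,edb->eid", F, S, self.Binv)
        f = np.zeros((self.mesh.n_nodes, 3))
        tri = self.mesh.triangles
        np.add.at(f, tri[:, 1], fD[:, :, 0])
        np.add.at(f, tri[:, 2], fD[:, :, 1])
        np.add.at(f, tri[:, 0], -(fD[:, :, 0] + fD[:, :, 1]))
        return e, f

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        F, _, Sv = self._deformation(u)
        S = np.empty((len(Sv), 2, 2))
        S[:, 0, 0] = Sv[:, 0]
        S[:, 1, 1] = Sv[:, 1]
        S[:, 0, 1] = S[:, 1, 0] = Sv[:, 2]
        At = (self.area * self.material.thickness)[:, None, None]
        fD = At * np.einsum("eia,eab,edb->eid", F, S, self.Binv)  # (M,3,2)
        f = np.zeros((self.mesh.n_nodes, 3))
        tri = self.mesh.triangles
        np.add.at(f, tri[:, 1], fD[:, :, 0])
        np.add.at(f, tri[:, 2], fD[:, :, 1])
        np.add.at(f, tri[:, 0], -(fD[:, :, 0] + fD[:, :, 1]))
        return f

    def internal_force_and_stiffness(self, u: np.ndarray):
        F, _, Sv = self._deformation(u)
        M = len(Sv)
        S = np.empty((M, 2, 2))
        S[:, 0, 0] = Sv[:, 0]
        S[:, 1, 1] = Sv[:, 1]
        S[:, 0, 1] = S[:, 1, 0] = Sv[:, 2]
        At = self.area * self.material.thickness

        fD = At[:, None, None] * np.einsum(
            "eia,eab,edb->eid", F, S, self.Binv
        )
        f = np.zeros((self.mesh.n_nodes, 3))
        tri = self.mesh.triangles
        np.add.at(f, tri[:, 1], fD[:, :, 0])
        np.add.at(f, tri[:, 2], fD[:, :, 1])
        np.add.at(f, tri[:, 0], -(fD[:, :, 0] + fD[:, :, 1]))

        B = self.Binv
        F0, F1 = F[:, :, 0], F[:, :, 1]
        Bm = np.zeros((M, 3, 6))
        Bm[:, 0, 0:3] = B[:, 0, 0, None] * F0
        Bm[:, 0, 3:6] = B[:, 1, 0, None] * F0
        Bm[:, 1, 0:3] = B[:, 0, 1, None] * F1
        Bm[:, 1, 3:6] = B[:, 1, 1, None] * F1
        Bm[:, 2, 0:3] = B[:, 0, 1, None] * F0 + B[:, 0, 0, None] * F1
        Bm[:, 2, 3:6] = B[:, 1, 1, None] * F0 + B[:, 1, 0, None] * F1

        Km = np.einsum("eai,ab,ebj->eij", Bm, self.Cmat, Bm)
        G = np.einsum("eab,ebc,edc->ead", B, S, B)  # B S Bᵀ, (M,2,2)
        Kg = np.einsum("ead,ij->eaidj", G, np.eye(3)).reshape(M, 6, 6)
        Krel = At[:, None, None] * (Km + Kg)
        Ke = np.einsum("ak,eab,bl->ekl", self.T, Krel, self.T)

        rows = np.repeat(self.edofs, 9, axis=1).ravel()
        cols = np.tile(self.edofs, (1, 9)).ravel()
        K = sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof)
        ).tocsc()
        return f, K


# ---------------------------------------------------------------------------
# follower pressure loads
# ---------------------------------------------------------------------------


def _triangle_pressures(mesh: MembraneMesh, load: LoadCase) -> np.ndarray:
    """Net signed pressure per triangle, along the stored orientation normal."""
    q = np.zeros(mesh.n_triangles)
    if load.cell_pressure != 0.0:
        has0 = mesh.owners[:, 0] >= 0
        has1 = mesh.owners[:, 1] >= 0
        q += load.cell_pressure * (has0.astype(float) - has1.astype(float))
    if load.lumen_pressure != 0.0:
        q -= load.lumen_pressure * (mesh.tags == TAG_LUMINAL)
    if load.abluminal_pressure != 0.0:
        q -= load.abluminal_pressure * (mesh.tags == TAG_ABLUMINAL)
    return q


def apply_pressure_loads(
    mesh: MembraneMesh,
    load: LoadCase,
    displacements: np.ndarray | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Follower nodal forces from the load case on the deformed configuration.

    Returns an (N, 3) nodal force array in nN.  Shared lateral walls between
    cells with equal internal pressure contribute exactly zero.
    """
    u = np.zeros_like(mesh.nodes) if displacements is None else displacements
    q = scale * _triangle_pressures(mesh, load)
    x = mesh.nodes + u
    tri = mesh.triangles
    avec = 0.5 * np.cross(
        x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]]
    )
    fe = (q[:, None] / 3.0) * avec
    f = np.zeros_like(x)
    for k in range(3):
        np.add.at(f, tri[:, k], fe)
    return f


def _pressure_stiffness(
    mesh: MembraneMesh, q: np.ndarray, u: np.ndarray
) -> sp.csc_matrix:
    """Derivative of the follower pressure forces w.r.t. nodal positions."""
    idx = np.where(q != 0.0)[0]
    if len(idx) == 0:
        return sp.csc_matrix((3 * mesh.n_nodes, 3 * mesh.n_nodes))
    tri = mesh.triangles[idx]
    x = mesh.nodes + u
    qv = q[idx]
    # d a_vec / d x_b for b = 0, 1, 2
    dA = np.empty((len(idx), 3, 3, 3))
    dA[:, 1] = -0.5 * _skew(x[tri[:, 2]] - x[tri[:, 0]])
    dA[:, 2] = 0.5 * _skew(x[tri[:, 1]] - x[tri[:, 0]])
    dA[:, 0] = 0.5 * _skew(x[tri[:, 2]] - x[tri[:, 1]])
    blocks = (qv[:, None, None, None, None] / 3.0) * dA[:, None, :, :, :]
    blocks = np.broadcast_to(blocks, (len(idx), 3, 3, 3, 3))
    edofs = (3 * tri[:, [0, 0, 0, 1, 1, 1, 2, 2, 2]]) + np.tile([0, 1, 2], 3)
    rows = np.repeat(edofs, 9, axis=1).ravel()
    cols = np.tile(edofs, (1, 9)).ravel()
    vals = blocks.transpose(0, 1, 3, 2, 4).reshape(len(idx), 9, 9).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


# ---------------------------------------------------------------------------
# public element-level operation
# ---------------------------------------------------------------------------


def element_stress(
    reference_triangle: np.ndarray,
    deformed_triangle: np.ndarray,
    material: MaterialParams,
):
    """St. Venant plane-stress second Piola–Kirchhoff stress of one element.

    Both triangles are (3, 3) [or (3, 2), taken as planar] vertex arrays.
    Returns ``(S, trace)`` with ``S`` the 2x2 stress in the reference element
    plane, in kPa.  Rigid-body motions give exactly zero stress.
    """

    ref = np.asarray(reference_triangle, dtype=float)
    cur = np.asarray(deformed_triangle, dtype=float)
    if ref.shape[1] == 2:
        ref = np.column_stack([ref, np.zeros(3)])
    if cur.shape[1] == 2:
        cur = np.column_stack([cur, np.zeros(3)])
    d1, d2 = ref[1] - ref[0], ref[2] - ref[0]
    nrm = np.cross(d1, d2)
    if np.linalg.norm(nrm) < 1e-14:
        raise ValueError("degenerate (zero-area) reference triangle")
    l1 = np.linalg.norm(d1)
    e1 = d1 / l1
    e2 = np.cross(nrm / np.linalg.norm(nrm), e1)
    Dm = np.array([[l1, d2 @ e1], [0.0, d2 @ e2]])
    Binv = np.linalg.inv(Dm)
    D = np.stack([cur[1] - cur[0], cur[2] - cur[0]], axis=1)
    F = D @ Binv
    C = F.T @ F
    E = 0.5 * (C - np.eye(2))
    ev = np.array([E[0, 0], E[1, 1], 2.0 * E[0, 1]])
    sv = material.plane_stress_matrix @ ev
    S = np.array([[sv[0], sv[2]], [sv[2], sv[1]]])
    return S, float(np.trace(S))


def stress_component(
    mesh: MembraneMesh, state: EquilibriumState, directions: np.ndarray
) -> np.ndarray:
    """Normal stress along a spatial direction, per element (kPa).

    ``directions`` is (3,) or (M, 3); it is projected into each element's
    reference plane and normalized, then ``d'ᵀ S d'`` is evaluated with the
    in-plane second Piola–Kirchhoff tensor.  Elements whose plane is nearly
    orthogonal to the direction get ``nan``.
    """
    tri = mesh.triangles
    X = mesh.nodes
    d1 = X[tri[:, 1]] - X[tri[:, 0]]
    d2 = X[tri[:, 2]] - X[tri[:, 0]]
    nrm = np.cross(d1, d2)
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    e2 = np.cross(nrm / np.linalg.norm(nrm, axis=1, keepdims=True), e1)
    d = np.broadcast_to(np.asarray(directions, float), (len(tri), 3))
    a = np.einsum("ij,ij->i", d, e1)
    b = np.einsum("ij,ij->i", d, e2)
    norm = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b = a / norm, b / norm
    Sv = state.stress_voigt
    out = a * a * Sv[:, 0] + b * b * Sv[:, 1] + 2 * a * b * Sv[:, 2]
    out[norm < 1e-6] = np.nan
    return out


# ---------------------------------------------------------------------------
# nonlinear solve
# ---------------------------------------------------------------------------


def _fixed_dofs(mesh: MembraneMesh, load: LoadCase) -> np.ndarray:
    mask = mesh.boundary_node_mask()
    if load.end_constraint == "one_end":
        mask &= mesh.node_chart[:, 1] < 0.5 * mesh.domain.axial_length
    nodes = np.where(mask)[0]
    return (3 * nodes[:, None] + np.arange(3)).ravel()


def _pressure_energy_and_force(mesh: MembraneMesh, q: np.ndarray, x: np.ndarray):
    """Pressure–volume work and follower nodal forces, one pass.

    ``q`` is the net signed pressure per triangle, ``x`` the deformed nodes.
    """
    tri = mesh.triangles
    x0, x1, x2 = x[tri[:, 0]], x[tri[:, 1]], x[tri[:, 2]]
    avec = 0.5 * np.cross(x1 - x0, x2 - x0)
    xbar = (x0 + x1 + x2) / 3.0
    w = float(np.dot(q, np.einsum("ij,ij->i", xbar, avec)) / 3.0)
    fe = (q[:, None] / 3.0) * avec
    f = np.zeros_like(x)
    for k in range(3):
        np.add.at(f, tri[:, k], fe)
    return w, f


def pressure_work(mesh: MembraneMesh, load: LoadCase, displacements, scale=1.0):
    """Potential of the follower pressure loads (pressure × swept volume).

    The cell/lumen/abluminal pressures act on closed (or fixed-boundary)
    surfaces, so the follower load is conservative with potential
    ``q * V`` evaluated as a divergence-theorem flux over the loaded
    triangles; its gradient reproduces :func:`apply_pressure_loads` on all
    free nodes.  Defined up to a constant; differences are meaningful.
    """
    q = scale * _triangle_pressures(mesh, load)
    x = mesh.nodes + displacements
    tri = mesh.triangles
    flux = (
        np.einsum(
            "ij,ij->i",
            x[tri[:, 0]],
            np.cross(x[tri[:, 1]], x[tri[:, 2]]),
        )
        / 6.0
    )
    return float(np.dot(q, flux))


def solve_equilibrium(
    mesh: MembraneMesh,
    material: MaterialParams,
    load: LoadCase,
    options: SolverOptions | None = None,
) -> EquilibriumState:
    """Quasi-static equilibrium by total-potential-energy minimization.

    The load is ramped in ``options.n_steps`` increments; at each level the
    total potential ``U(u) - W(u)`` is minimized with a truncated-Newton
    iteration (Newton-CG on diagonally scaled variables; the analytic tangent
    supplies Hessian-vector products, and the gradient is exactly the
    out-of-balance force).  This follows the stable post-buckling branch of
    membrane bulging/collapse where load-controlled Newton stalls.
    Returns ``converged=False`` with the last iterate when the gradient
    tolerance is not reached.
    """
    from scipy.optimize import minimize

    opt = options or SolverOptions()
    asm = MembraneAssembler(mesh, material)

    fixed = _fixed_dofs(mesh, load)
    free = np.setdiff1d(np.arange(asm.ndof), fixed)
    if len(fixed) == 0:
        raise ValueError("no constrained nodes; rigid-body modes present")

    u = np.zeros_like(mesh.nodes)
    history = []
    residual = 0.0
    converged = True

    q_full = _triangle_pressures(mesh, load)
    fext0 = apply_pressure_loads(mesh, load, u, scale=1.0)
    if not fext0.any():
        Ev, Sv, trace = asm.strain_stress(u)
        return EquilibriumState(
            displacements=u,
            strain_voigt=Ev,
            stress_voigt=Sv,
            stress_trace=trace,
            residual_norm=0.0,
            converged=True,
            load_factor=1.0,
            load_history=[1.0],
        )

    # diagonal preconditioning: scale free dofs by the reference-stiffness
    # diagonal so in-plane and membrane-normal dofs see comparable curvature
    _, K0 = asm.internal_force_and_stiffness(u)
    d0 = np.asarray(K0.diagonal())[free]
    d0 = np.clip(d0, max(1e-8 * np.median(d0[d0 > 0]), 1e-30), None)
    scale_v = 1.0 / np.sqrt(d0)

    X = mesh.nodes

    for step in range(1, opt.n_steps + 1):
        lam = step / opt.n_steps
        ref = lam * np.abs(fext0).max()
        tol = max(opt.tol_rel * ref, opt.tol_abs)
        q = lam * q_full

        last_resid = [np.inf]
        cache: dict = {}

        def full_u(y):
            uu = u.ravel().copy()
            uu[free] = scale_v * y
            return uu.reshape(-1, 3)

        def objective(y):
            uu = full_u(y)
            e_int, f_int = asm.energy_and_force(uu)
            w, f_ext = _pressure_energy_and_force(mesh, q, X + uu)
            g = (f_int - f_ext).ravel()[free]
            last_resid[0] = float(np.abs(g).max())
            return e_int - w, scale_v * g

        def hessp(y, p):
            key = y.tobytes()
            if cache.get("key") != key:
                uu = full_u(y)
                _, K = asm.internal_force_and_stiffness(uu)
                Kp = _pressure_stiffness(mesh, q, uu)
                cache["J"] = (K - Kp).tocsr()[free][:, free].tocsr()
                cache["key"] = key
            return scale_v * (cache["J"] @ (scale_v * p))

        def callback(_):
            # stop as soon as the physical out-of-balance force is small
            if last_resid[0] <= tol:
                raise StopIteration

        res = minimize(
            objective,
            u.ravel()[free] / scale_v,
            jac=True,
            hessp=hessp,
            method="Newton-CG",
            callback=callback,
            options={"maxiter": opt.max_iterations, "xtol": 1e-14},
        )
        unew = u.ravel().copy()
        unew[free] = scale_v * res.x
        u = unew.reshape(-1, 3)
        r_phys = (
            asm.internal_force(u) - apply_pressure_loads(mesh, load, u, scale=lam)
        ).ravel()[free]
        residual = float(np.abs(r_phys).max())
        if opt.verbose:
            print(
                f"  lam={lam:.3f} nit={res.nit} |r|={residual:.3e} tol={tol:.3e}"
            )
        history.append(lam)
        if step == opt.n_steps and residual > tol:
            converged = False

    Ev, Sv, trace = asm.strain_stress(u)
    return EquilibriumState(
        displacements=u,
        strain_voigt=Ev,
        stress_voigt=Sv,
        stress_trace=trace,
        residual_norm=residual,
        converged=converged,
        load_factor=1.0 if converged else history[-1],
        load_history=history,
    )
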