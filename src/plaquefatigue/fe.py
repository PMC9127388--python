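"""Finite-strain inflation of the meshed thin slice.

Static equilibrium of the wall ring under luminal pressure is solved in a
total-Lagrangian displacement formulation with generalized plane strain: the
in-plane deformation is free, the axial stretch ``lambda_z`` is prescribed
(1/0.95 for 5% axial shrinkage).  A 0.5 mm extruded slice with uniform axial
stretch and plane-parallel faces has exactly this in-plane response; the
slice thickness only scales energies, never stresses.

The luminal pressure is a follower load.  In 2D a uniform pressure on a
closed cavity boundary is conservative with potential ``-p * lambda_z *
A_cavity``, where the cavity area is evaluated on the deformed quadratic
boundary edges; its gradient gives the consistent nodal load and its
(constant) Hessian the load stiffness.  The outer boundary is traction-free
and rigid-body modes are removed by Lagrange-multiplier constraints on net
translation and rotation.

Newton-Raphson runs over load increments with backtracking line search; the
element tangent is a finite-difference of the analytic internal force (the
stresses themselves are analytic, see :mod:`plaquefatigue.material`).  Nodal
stress/strain fields are recovered by volume-weighted averaging of element
quadrature values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import MaterialParams, pk2_inplane_vec
from .preprocess import Mesh

__all__ = ["SolverConfig", "FESolution", "SolverError", "solve_inflation", "solve_pair"]


@dataclass(frozen=True)
class SolverConfig:
    n_load_increments: int = 10
    newton_tol: float = 1e-8  # relative residual
    max_newton_iter: int = 30
    axial_stretch: float = 1.0 / 0.95

    def __post_init__(self) -> None:
        if self.n_load_increments < 1:
            raise ValueError("need at least one load increment")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


class SolverError(RuntimeError):
    """Newton divergence or inverted element; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[int, int, float]]):
        super().__init__(message)
        self.trace = trace  # (increment, iteration, residual norm)


@dataclass
class FESolution:
    """Converged state at one pressure."""

    mesh: Mesh
    pressure: float  # kPa
    displacements: np.ndarray  # (N, 2) mm
    node_max_stress: np.ndarray  # (N,) kPa, max principal Cauchy
    node_max_strain: np.ndarray  # (N,) Green-Lagrange, max principal
    lumen_area: float  # mm^2, deformed
    wall_area: float  # mm^2, deformed
    axial_stretch: float = 1.0

    @property
    def eem_area(self) -> float:
        return self.lumen_area + self.wall_area

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacements


# --- quadratic triangle reference data -------------------------------------

_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.full(3, 1 / 6)


def _shape_grads(xi: float, eta: float) -> np.ndarray:
    """d N_a / d(xi, eta) for the 6-node triangle, shape (6, 2)."""
    l1 = 1.0 - xi - eta
    return np.array(
        [
            [-(4 * l1 - 1), -(4 * l1 - 1)],
            [4 * xi - 1, 0.0],
            [0.0, 4 * eta - 1],
            [4 * (l1 - xi), -4 * xi],
            [4 * eta, 4 * xi],
            [-4 * eta, 4 * (l1 - eta)],
        ]
    )


_DN_DXI = np.stack([_shape_grads(*q) for q in _QP])  # (3 qp, 6, 2)

# 1D quadratic edge (nodes at xi = -1, +1, 0): matrix M with
# edge cavity-area contribution a_e = x_e^T M y_e (bilinear in coordinates).
_G1D = np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)])
_W1D = np.array([5 / 9, 8 / 9, 5 / 9])


def _edge_area_matrix() -> np.ndarray:
    def N(xi):
        return np.array([0.5 * xi * (xi - 1.0), 0.5 * xi * (xi + 1.0), 1.0 - xi**2])

    def dN(xi):
        return np.array([xi - 0.5, xi + 0.5, -2.0 * xi])

    K = np.zeros((3, 3))
    for xi, w in zip(_G1D, _W1D):
        K += w * np.outer(N(xi), dN(xi))  # int N_a N'_b dxi
    return 0.5 * (K - K.T)


_EDGE_M = _edge_area_matrix()


class _Assembly:
    """Precomputed reference-configuration data for one mesh + material map."""

    def __init__(self, mesh: Mesh, materials: dict[str, MaterialParams],
                 axial_stretch: float):
        self.mesh = mesh
        self.lz = axial_stretch
        X_e = mesh.nodes[mesh.elements]  # (E, 6, 2)
        # Jacobian dX/dxi at each qp: J[e,q,i,k] = sum_a X[e,a,i] dN[q,a,k]
        J = np.einsum("eai,qak->eqik", X_e, _DN_DXI)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains elements with non-positive Jacobian")
        invJ = np.empty_like(J)
        invJ[..., 0, 0] = J[..., 1, 1]
        invJ[..., 1, 1] = J[..., 0, 0]
        invJ[..., 0, 1] = -J[..., 0, 1]
        invJ[..., 1, 0] = -J[..., 1, 0]
        invJ /= detJ[..., None, None]
        self.dNdX = np.einsum("qak,eqki->eqai", _DN_DXI, invJ)  # (E, Q, 6, 2)
        self.wdet = detJ * _QW[None, :]  # (E, Q)

        def per_elem(attr):
            return np.array(
                [getattr(materials[t], attr) for t in mesh.tissue], dtype=float
            )[:, None]

        self.pars = (
            per_elem("c1"), per_elem("c2"), per_elem("D1"), per_elem("D2"),
            per_elem("K1"), per_elem("K2"),
            np.array([materials[t].anisotropic for t in mesh.tissue])[:, None],
            per_elem("kappa_vol"),
        )
        self.fibers = mesh.fibers[:, None, :]  # (E, 1, 2)
        self.ndof = 2 * mesh.n_nodes
        self._load_hessian = self._build_load_hessian()
        self._constraints = self._build_constraints()
        # characteristic length for finite-difference element tangents
        self.fd_h = 1e-6 * float(np.sqrt(np.mean(2.0 * self.wdet.sum(axis=1))))

    # -- internal force / energy --------------------------------------------

    def _kinematics(self, u_e: np.ndarray):
        G = np.einsum("eai,eqaj->eqij", u_e, self.dNdX)
        F2 = G + np.eye(2)
        return F2

    def elem_internal(self, u_e: np.ndarray) -> np.ndarray:
        """Internal nodal forces per element, shape (E, 6, 2)."""
        F2 = self._kinematics(u_e)
        S2, _, _ = pk2_inplane_vec(F2, self.lz, self.fibers, *self.pars)
        P2 = np.einsum("eqik,eqkj->eqij", F2, S2)
        return np.einsum("eq,eqij,eqaj->eai", self.wdet, P2, self.dNdX)

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        f = np.zeros((self.mesh.n_nodes, 2))
        np.add.at(f, self.mesh.elements, self.elem_internal(u[self.mesh.elements]))
        return f

    def strain_energy(self, u: np.ndarray) -> float:
        F2 = self._kinematics(u[self.mesh.elements])
        _, _, W = pk2_inplane_vec(F2, self.lz, self.fibers, *self.pars)
        return float(np.sum(self.wdet * W))

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        """FD of the analytic element internal force; 12x12 blocks assembled."""
        elems = self.mesh.elements
        u_e = u[elems]
        f0 = self.elem_internal(u_e).reshape(-1, 12)
        E = len(elems)
        Ke = np.empty((E, 12, 12))
        h = self.fd_h
        for k in range(12):
            up = u_e.copy().reshape(-1, 12)
            up[:, k] += h
            Ke[:, :, k] = (self.elem_internal(up.reshape(-1, 6, 2)).reshape(-1, 12) - f0) / h
        dof = (2 * elems[:, :, None] + np.array([0, 1])).reshape(E, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof))
        return K.tocsr()

    # -- follower pressure ----------------------------------------------------

    def cavity_area(self, coords: np.ndarray) -> float:
        """Lumen cavity area from the (deformed) quadratic boundary edges."""
        xe = coords[self.mesh.lumen_edges, 0]  # (n_edges, 3)
        ye = coords[self.mesh.lumen_edges, 1]
        return float(np.einsum("ea,ab,eb->", xe, _EDGE_M, ye))

    def cavity_area_grad(self, coords: np.ndarray) -> np.ndarray:
        g = np.zeros((self.mesh.n_nodes, 2))
        edges = self.mesh.lumen_edges
        xe = coords[edges, 0]
        ye = coords[edges, 1]
        np.add.at(g[:, 0], edges.ravel(), (ye @ _EDGE_M.T).ravel())
        np.add.at(g[:, 1], edges.ravel(), (xe @ _EDGE_M).ravel())
        return g

    def _build_load_hessian(self) -> sp.csr_matrix:
        """d^2 A / d coords^2 — constant since A is bilinear in coordinates."""
        edges = self.mesh.lumen_edges
        rows, cols, vals = [], [], []
        for e in edges:
            for a in range(3):
                for b in range(3):
                    m = _EDGE_M[a, b]
                    if m == 0.0:
                        continue
                    rows += [2 * e[a], 2 * e[b] + 1]
                    cols += [2 * e[b] + 1, 2 * e[a]]
                    vals += [m, m]
        H = sp.coo_matrix((vals, (rows, cols)), shape=(self.ndof, self.ndof))
        return H.tocsr()

    # -- rigid-body constraints ------------------------------------------------

    def _build_constraints(self) -> sp.csr_matrix:
        n = self.mesh.n_nodes
        X = self.mesh.nodes - self.mesh.center
        C = sp.lil_matrix((3, self.ndof))
        C[0, 0::2] = 1.0
        C[1, 1::2] = 1.0
        C[2, 0::2] = -X[:, 1]
        C[2, 1::2] = X[:, 0]
        return (C / n).tocsr()

    # -- Newton solve ----------------------------------------------------------

    def solve(self, pressure: float, config: SolverConfig,
              u0: np.ndarray | None = None, p_start: float = 0.0,
              trace: list | None = None) -> np.ndarray:
        """Incremental loading from p_start to pressure with adaptive substeps.

        A Newton failure halves the current load step (down to 1/64 of the
        nominal increment) instead of aborting; successful substeps grow
        back toward the nominal increment.
        """
        u = np.zeros((self.mesh.n_nodes, 2)) if u0 is None else u0.copy()
        trace = [] if trace is None else trace
        if u0 is None and self.lz != 1.0:
            # equilibrate the axial pre-stretch before any pressure is
            # applied; starting the load loop off-equilibrium mixes two
            # hard problems into one Newton solve.  Damping can make this
            # first solve take many short steps, so give it extra headroom.
            from dataclasses import replace as _replace

            equil = _replace(config, max_newton_iter=max(120, config.max_newton_iter))
            u = self._newton(u, p_start, equil, 0, trace)
        span = pressure - p_start
        if span == 0.0:
            return self._newton(u, pressure, config, 1, trace)
        dp_nominal = span / config.n_load_increments
        dp = dp_nominal
        p_cur, inc = p_start, 0
        while p_cur < pressure - 1e-12 * max(abs(pressure), 1.0):
            p_next = min(p_cur + dp, pressure)
            inc += 1
            try:
                u = self._newton(u, p_next, config, inc, trace)
            except SolverError:
                dp *= 0.5
                if dp < dp_nominal / 64.0:
                    raise
                continue
            p_cur = p_next
            dp = min(2.0 * dp, dp_nominal)
        return u

    def _residual(self, u: np.ndarray, p: float) -> np.ndarray:
        coords = self.mesh.nodes + u
        f_int = self.internal_force(u)
        f_ext = p * self.lz * self.cavity_area_grad(coords)
        return (f_int - f_ext).ravel()

    def _potential(self, u: np.ndarray, p: float) -> float:
        """Total potential energy: internal energy minus cavity-pressure work."""
        return self.strain_energy(u) - p * self.lz * self.cavity_area(self.mesh.nodes + u)

    def _newton(self, u, p, config, inc, trace):
        """Damped Newton on the (conservative) potential.

        The wall's energy has weakly non-convex directions at moderate
        strain (negative c1), so the plain Newton tangent can be indefinite
        near the solution path.  A Levenberg-style diagonal damping tau,
        adapted from the line-search outcome, keeps every step a descent
        direction for the potential; tau -> 0 restores quadratic
        convergence once the iterate is in the convex basin.
        """
        C = self._constraints
        # reference force scale: external load plus the element-level
        # internal force magnitude *before* assembly cancellation, which
        # stays finite at equilibrium (unlike the net internal force)
        elem_scale = float(
            np.linalg.norm(self.elem_internal(u[self.mesh.elements]))
        )
        f_ref = max(
            np.linalg.norm(p * self.lz * self.cavity_area_grad(self.mesh.nodes + u)),
            elem_scale,
            1e-10,
        )
        u = u.copy()
        tau = 0.0
        ident = sp.identity(self.ndof, format="csr")
        best, stalled = np.inf, 0
        for it in range(config.max_newton_iter):
            R = self._residual(u, p)
            rnorm = np.linalg.norm(R)
            trace.append((inc, it, rnorm))
            # absolute floor covers unloaded states where the residual is
            # already at roundoff (forces are O(kPa * mm) ~ O(1))
            if rnorm <= config.newton_tol * f_ref or rnorm < 1e-12:
                return u
            # roundoff floor: for very stiff materials the residual plateaus
            # above newton_tol; accept once it stagnates far below the load
            if rnorm < 0.95 * best:
                best, stalled = rnorm, 0
            else:
                stalled += 1
                if stalled >= 5 and rnorm <= 1e-4 * f_ref:
                    return u
            K = self.tangent(u) - (p * self.lz) * self._load_hessian
            scale = float(np.abs(K.diagonal()).mean()) or 1.0
            pot0 = self._potential(u, p)
            for attempt in range(12):
                A = sp.bmat([[K + tau * scale * ident, C.T], [C, None]], format="csc")
                rhs = np.concatenate([-R, -(C @ u.ravel())])
                try:
                    sol = spla.spsolve(A, rhs)
                except RuntimeError as exc:
                    raise SolverError(f"linear solve failed at p={p:.4g}: {exc}", trace)
                du = sol[: self.ndof].reshape(-1, 2)
                # backtracking line search: accept on potential decrease or
                # residual decrease
                alpha, ok = 1.0, False
                for _ in range(8):
                    try:
                        u_try = u + alpha * du
                        with np.errstate(over="ignore", invalid="ignore"):
                            pot = self._potential(u_try, p)
                            rn = np.linalg.norm(self._residual(u_try, p))
                    except FloatingPointError:
                        alpha *= 0.5
                        continue
                    if np.isfinite(pot) and np.isfinite(rn) and (
                        pot < pot0 + 1e-12 * abs(pot0) or rn < 0.99 * rnorm
                    ):
                        ok = True
                        break
                    alpha *= 0.5
                if ok:
                    u = u_try
                    tau = 0.0 if (alpha == 1.0 and tau < 1e-8) else tau * 0.25
                    break
                tau = max(1e-6, tau * 10.0)
            else:
                raise SolverError(
                    f"damped Newton stalled at increment {inc}, p={p:.4g} kPa", trace)
        raise SolverError(
            f"Newton did not converge in {config.max_newton_iter} iterations "
            f"at increment {inc} (p={p:.4g} kPa)", trace)

    # -- field recovery ----------------------------------------------------------

    def recover_fields(self, u: np.ndarray):
        """Max-principal Cauchy stress and Green-Lagrange strain at nodes."""
        elems = self.mesh.elements
        F2 = self._kinematics(u[elems])
        S2, S_zz, _ = pk2_inplane_vec(F2, self.lz, self.fibers, *self.pars)
        detF2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        J = detF2 * self.lz
        sig2 = np.einsum("eqik,eqkl,eqjl->eqij", F2, S2, F2) / J[..., None, None]
        sig_zz = self.lz**2 * S_zz / J

        def eig_max_2x2(T):
            m = 0.5 * (T[..., 0, 0] + T[..., 1, 1])
            r = np.sqrt(0.25 * (T[..., 0, 0] - T[..., 1, 1]) ** 2 + T[..., 0, 1] ** 2)
            return m + r

        stress_qp = np.maximum(eig_max_2x2(sig2), sig_zz)
        C2 = np.einsum("eqki,eqkj->eqij", F2, F2)
        E2 = 0.5 * (C2 - np.eye(2))
        E_zz = 0.5 * (self.lz**2 - 1.0)
        strain_qp = np.maximum(eig_max_2x2(E2), E_zz)

        w = self.wdet
        elem_w = w.sum(axis=1)
        elem_stress = (w * stress_qp).sum(axis=1) / elem_w
        elem_strain = (w * strain_qp).sum(axis=1) / elem_w
        num_s = np.zeros(self.mesh.n_nodes)
        num_e = np.zeros(self.mesh.n_nodes)
        den = np.zeros(self.mesh.n_nodes)
        np.add.at(num_s, elems, (elem_w * elem_stress)[:, None] * np.ones(6))
        np.add.at(num_e, elems, (elem_w * elem_strain)[:, None] * np.ones(6))
        np.add.at(den, elems, elem_w[:, None] * np.ones(6))
        wall_area = float(np.sum(self.wdet * detF2))
        return num_s / den, num_e / den, wall_area


def _make_solution(asm: _Assembly, u: np.ndarray, pressure: float) -> FESolution:
    stress, strain, wall_area = asm.recover_fields(u)
    lumen_area = asm.cavity_area(asm.mesh.nodes + u)
    if lumen_area <= 0:
        raise SolverError("deformed lumen area is non-positive", [])
    sol = FESolution(
        mesh=asm.mesh, pressure=pressure, displacements=u,
        node_max_stress=stress, node_max_strain=strain,
        lumen_area=lumen_area, wall_area=wall_area, axial_stretch=asm.lz,
    )
    if not (np.all(np.isfinite(stress)) and np.all(np.isfinite(strain))):
        raise SolverError("non-finite recovered fields", [])
    return sol


def solve_inflation(
    mesh: Mesh,
    materials: dict[str, MaterialParams],
    pressure: float,
    config: SolverConfig | None = None,
) -> FESolution:
    """Inflate the slice to *pressure* (kPa) and return the converged state."""
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    config = config or SolverConfig()
    asm = _Assembly(mesh, materials, config.axial_stretch)
    u = asm.solve(pressure, config)
    return _make_solution(asm, u, pressure)


def solve_pair(
    mesh: Mesh,
    materials: dict[str, MaterialParams],
    pressure_min: float,
    pressure_max: float,
    config: SolverConfig | None = None,
) -> tuple[FESolution, FESolution]:
    """Solve at both ends of the cardiac cycle on the same mesh.

    The maximum-pressure solve warm-starts from the minimum-pressure state.
    """
    if pressure_max < pressure_min:
        raise ValueError("pressure_max must be >= pressure_min")
    config = config or SolverConfig()
    asm = _Assembly(mesh, materials, config.axial_stretch)
    u_min = asm.solve(pressure_min, config)
    sol_min = _make_solution(asm, u_min, pressure_min)
    u_max = asm.solve(pressure_max, config, u0=u_min, p_start=pressure_min)
    sol_max = _make_solution(asm, u_max, pressure_max)
    return sol_min, sol_max
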