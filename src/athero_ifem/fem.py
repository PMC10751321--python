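"""Plane-strain finite-element inflation of labeled plaque meshes.

The discretization mirrors the standard setup for 2D arterial cross
sections: three-node linear triangles (constant strain, single-point
integration) under the plane-strain assumption, lumen pressure applied as
a follower load on the deformed lumen edges, and rigid-body motion removed
either by pinning three outer-contour nodes (the clinical configuration)
or by a tangential roller on the whole outer ring (the symmetric variant
used against the thick-walled-cylinder closed forms).

Nonlinear problems are solved by Newton iteration with analytic
consistent tangents, incremental load stepping and automatic step
bisection on divergence. The small-increment linear solver performs a
single Hooke-law solve on the current configuration.

Units: mm, kPa; lumen pressures are given in mmHg and converted with
1 mmHg = 0.1333224 kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import LabeledMesh
from .materials import (
    LinearElastic,
    MaterialSet,
    plane_strain_cauchy,
    plane_strain_response,
)

__all__ = [
    "MMHG_TO_KPA",
    "SolverConfig",
    "Solution",
    "StrainField",
    "StressField",
    "SolverError",
    "PlaneStrainProblem",
    "inflate",
    "inflate_linear_increment",
    "strain_fields",
    "max_principal_stress",
    "lame_annulus",
    "neo_hooke_annulus_pressure",
]

MMHG_TO_KPA = 0.1333224


class SolverError(RuntimeError):
    """Newton divergence or a singular system, with diagnostic context."""


@dataclass(frozen=True)
class SolverConfig:
    """Newton / load-stepping controls for nonlinear inflation."""

    load_steps: int = 10
    newton_tol: float = 1e-8
    newton_max_iter: int = 25
    max_bisections: int = 4
    follower_pressure: bool = True
    bc: str = "pin3"  # or "roller_outer"

    def __post_init__(self) -> None:
        if self.load_steps < 1 or self.newton_tol <= 0:
            raise ValueError("load_steps >= 1 and newton_tol > 0 required")


@dataclass
class Solution:
    """Converged equilibrium state of an inflation analysis."""

    mesh: LabeledMesh
    displacements: np.ndarray          # (N, 2) mm
    deformation_gradients: np.ndarray  # (M, 2, 2) in-plane, F33 = 1
    cauchy: np.ndarray                 # (M, 3, 3) kPa
    pressure: float                    # mmHg
    converged: bool
    residual: float
    recorded: dict = field(default_factory=dict)   # pressure -> displacements
    external_work: float = 0.0         # kPa mm^2 (per unit thickness)
    strain_energy: float = 0.0


@dataclass
class StrainField:
    """Per-element infinitesimal strains in several coordinate frames.

    Cartesian (exx, eyy, exy), cylindrical about ``center`` (err, ett,
    ert), principal (e1 >= e2) and the von-Mises equivalent strain evm
    (plane strain: zero out-of-plane normal strain enters the deviator).
    """

    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    err: np.ndarray
    ett: np.ndarray
    ert: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    evm: np.ndarray
    center: np.ndarray
    angles: np.ndarray  # element-centroid angles about center

    @classmethod
    def from_cartesian(cls, exx, eyy, exy, center, angles) -> "StrainField":
        c, s = np.cos(angles), np.sin(angles)
        err = exx * c * c + eyy * s * s + 2.0 * exy * c * s
        ett = exx * s * s + eyy * c * c - 2.0 * exy * c * s
        ert = (eyy - exx) * c * s + exy * (c * c - s * s)
        mean = 0.5 * (exx + eyy)
        rad = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy ** 2)
        tr3 = (exx + eyy) / 3.0
        evm = np.sqrt(2.0 / 3.0 * ((exx - tr3) ** 2 + (eyy - tr3) ** 2
                                   + tr3 ** 2 + 2.0 * exy ** 2))
        return cls(exx, eyy, exy, err, ett, ert, mean + rad, mean - rad, evm,
                   np.asarray(center, float), angles)

    def copy(self) -> "StrainField":
        return StrainField(*(np.array(getattr(self, f)) for f in
                             ("exx", "eyy", "exy", "err", "ett", "ert",
                              "e1", "e2", "evm", "center", "angles")))


@dataclass
class StressField:
    """Per-element maximum principal Cauchy stress [kPa]."""

    sigma_max: np.ndarray


# --------------------------------------------------------------------------
# assembly workspace
# --------------------------------------------------------------------------

class PlaneStrainProblem:
    """Precomputed assembly data for one mesh configuration.

    Caches shape-function gradients, element groupings by tissue label, the
    rigid-body constraint matrix and the lumen edge list, so that repeated
    solves with different material parameters (the inner loop of the
    inverse characterizations) only pay for assembly.
    """

    def __init__(self, mesh: LabeledMesh, coords: np.ndarray | None = None,
                 bc: str = "pin3"):
        self.mesh = mesh
        self.coords = mesh.nodes if coords is None else \
            np.asarray(coords, dtype=float)
        t = mesh.triangles
        p = self.coords
        a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
        det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) \
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        if np.any(det <= 0):
            raise SolverError("mesh has inverted or degenerate elements "
                              f"({int(np.sum(det <= 0))} of {t.shape[0]})")
        self.area = 0.5 * det
        # dN/dX, shape (M, 3, 2): gradients of the three hat functions
        dN = np.empty((t.shape[0], 3, 2))
        dN[:, 0, 0] = b[:, 1] - c[:, 1]
        dN[:, 0, 1] = c[:, 0] - b[:, 0]
        dN[:, 1, 0] = c[:, 1] - a[:, 1]
        dN[:, 1, 1] = a[:, 0] - c[:, 0]
        dN[:, 2, 0] = a[:, 1] - b[:, 1]
        dN[:, 2, 1] = b[:, 0] - a[:, 0]
        self.dN = dN / det[:, None, None]

        self.groups: dict[str, np.ndarray] = {}
        for lab in sorted(set(mesh.labels.tolist())):
            self.groups[lab] = np.flatnonzero(mesh.labels == lab)

        dofs = 2 * t[:, :, None] + np.arange(2)[None, None, :]  # (M, 3, 2)
        edofs = dofs.reshape(t.shape[0], 6)
        self.rows = np.repeat(edofs, 6, axis=1).ravel()
        self.cols = np.tile(edofs, (1, 6)).ravel()
        self.edofs = edofs
        self.ndof = 2 * mesh.n_nodes
        self.C = self._constraints(bc)
        self.bc = bc

    # -- constraints ------------------------------------------------------
    def _constraints(self, bc: str) -> sp.csr_matrix:
        mesh, p = self.mesh, self.coords
        rows, cols, vals = [], [], []
        if bc == "pin3":
            for k, n in enumerate(mesh.fixed_nodes):
                rows += [2 * k, 2 * k + 1]
                cols += [2 * n, 2 * n + 1]
                vals += [1.0, 1.0]
            m = 2 * len(mesh.fixed_nodes)
        elif bc == "roller_outer":
            ctr = p[mesh.outer_nodes].mean(axis=0)
            for k, n in enumerate(mesh.outer_nodes):
                dx, dy = p[n] - ctr
                r = math.hypot(dx, dy)
                rows += [k, k]
                cols += [2 * n, 2 * n + 1]
                vals += [-dy / r, dx / r]  # tangential component fixed
            m = len(mesh.outer_nodes)
        else:
            raise ValueError(f"unknown bc {bc!r}")
        return sp.csr_matrix((vals, (rows, cols)), shape=(m, self.ndof))

    # -- external (pressure) load ----------------------------------------
    def pressure_load(self, p_kpa: float, u: np.ndarray, follower: bool = True):
        """Nodal force vector (and load stiffness) of the lumen pressure.

        Edge force p * W (x_v - x_u) with W the +90-degree rotation; the
        directed lumen edges keep the wall on their left, so W t points
        from the lumen into the wall.
        """
        e = self.mesh.lumen_edges
        x = self.coords + (u.reshape(-1, 2) if follower else 0.0)
        t = x[e[:, 1]] - x[e[:, 0]]
        fe = p_kpa * np.column_stack([-t[:, 1], t[:, 0]])
        f = np.zeros(self.ndof)
        for k in range(2):
            np.add.at(f, 2 * e[:, 0] + k, 0.5 * fe[:, k])
            np.add.at(f, 2 * e[:, 1] + k, 0.5 * fe[:, k])
        if not follower:
            return f, None
        # d f_node / d x: node a gets +-(p/2) W per edge end
        W = p_kpa * np.array([[0.0, -1.0], [1.0, 0.0]])
        rows, cols, vals = [], [], []
        for (na, nb) in e:
            for recv in (na, nb):
                for i in range(2):
                    for j in range(2):
                        if W[i, j] == 0.0:
                            continue
                        rows += [2 * recv + i, 2 * recv + i]
                        cols += [2 * nb + j, 2 * na + j]
                        vals += [0.5 * W[i, j], -0.5 * W[i, j]]
        Kload = sp.coo_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        return f, Kload

    # -- nonlinear assembly ----------------------------------------------
    def gradients(self, u: np.ndarray) -> np.ndarray:
        """In-plane deformation gradients F2 = I + grad u, per element."""
        ue = u.reshape(-1, 2)[self.mesh.triangles]  # (M, 3, 2)
        gradu = np.einsum("mai,maj->mij", ue, self.dN)
        F2 = gradu.copy()
        F2[:, 0, 0] += 1.0
        F2[:, 1, 1] += 1.0
        return F2

    def internal(self, materials: MaterialSet, u: np.ndarray,
                 tangent: bool = True):
        """Internal force (and tangent); raises FloatingPointError on J<=0."""
        F2 = self.gradients(u)
        M = F2.shape[0]
        fint = np.zeros(self.ndof)
        psi_tot = 0.0
        Kvals = np.empty((M, 6, 6)) if tangent else None
        for lab, idx in self.groups.items():
            mat = materials[lab]
            out = plane_strain_response(mat, F2[idx], tangent=tangent)
            psi, P = out[0], out[1]
            psi_tot += float(np.sum(psi * self.area[idx]))
            fe = np.einsum("m,mij,maj->mai", self.area[idx], P, self.dN[idx])
            np.add.at(fint, self.edofs[idx].ravel(), fe.reshape(idx.size, 6).ravel())
            if tangent:
                A = out[3]
                Ke = np.einsum("m,mijkl,maj,mbl->maibk", self.area[idx],
                               A, self.dN[idx], self.dN[idx])
                Kvals[idx] = Ke.reshape(idx.size, 6, 6)
        if not tangent:
            return fint, psi_tot, None
        K = sp.coo_matrix((Kvals.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return fint, psi_tot, K

    # -- constrained linear solve -----------------------------------------
    def _solve_kkt(self, K: sp.spmatrix, rhs: np.ndarray,
                   crhs: np.ndarray | None = None):
        C = self.C
        m = C.shape[0]
        if crhs is None:
            crhs = np.zeros(m)
        sys = sp.bmat([[K, C.T], [C, None]], format="csc")
        sol = spsolve(sys, np.concatenate([rhs, crhs]))
        if not np.all(np.isfinite(sol)):
            raise SolverError("singular constrained system (insufficient "
                              "constraints or degenerate stiffness)")
        return sol[:self.ndof], sol[self.ndof:]

    # -- nonlinear driver --------------------------------------------------
    def solve_inflate(self, materials: MaterialSet, pressure: float,
                      config: SolverConfig = SolverConfig(),
                      record_at: tuple[float, ...] = (),
                      u0: np.ndarray | None = None) -> Solution:
        """Inflate to ``pressure`` mmHg; optionally record intermediate states."""
        materials.validate(self.mesh.labels.tolist())
        targets = sorted({float(p) for p in (*record_at, pressure) if p > 0})
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        recorded: dict[float, np.ndarray] = {}
        work = 0.0
        p_prev = 0.0
        f_prev = np.zeros(self.ndof)
        lam = None
        for p_target in targets:
            n_steps = max(1, int(round(config.load_steps *
                                       (p_target - p_prev) / pressure)))
            dp = (p_target - p_prev) / n_steps
            p_cur = p_prev
            bisections = 0
            while p_cur < p_target - 1e-12:
                p_try = min(p_cur + dp, p_target)
                try:
                    u_new, lam, res = self._newton(materials, p_try, u, config)
                except (SolverError, FloatingPointError):
                    bisections += 1
                    if bisections > config.max_bisections:
                        raise SolverError(
                            f"Newton failed at {p_try:.3f} mmHg after "
                            f"{config.max_bisections} bisections")
                    dp *= 0.5
                    continue
                fref = self.pressure_load(p_try * MMHG_TO_KPA, u_new,
                                          follower=config.follower_pressure)[0]
                work += 0.5 * float((f_prev + fref) @ (u_new - u))
                f_prev = fref
                u = u_new
                p_cur = p_try
            p_prev = p_target
            recorded[p_target] = u.reshape(-1, 2).copy()

        F2 = self.gradients(u)
        cauchy = np.zeros((F2.shape[0], 3, 3))
        for lab, idx in self.groups.items():
            cauchy[idx] = plane_strain_cauchy(materials[lab], F2[idx])
        _, psi_tot, _ = self.internal(materials, u, tangent=False)
        return Solution(
            mesh=self.mesh, displacements=u.reshape(-1, 2),
            deformation_gradients=F2, cauchy=cauchy, pressure=pressure,
            converged=True, residual=0.0,
            recorded={p: recorded[p] for p in record_at if p > 0},
            external_work=work, strain_energy=psi_tot,
        )

    def _newton(self, materials: MaterialSet, p_mmhg: float,
                u0: np.ndarray, config: SolverConfig):
        p_kpa = p_mmhg * MMHG_TO_KPA
        u = u0.copy()
        lam = np.zeros(self.C.shape[0])
        ref = max(np.linalg.norm(
            self.pressure_load(p_kpa, u, follower=False)[0]), 1e-12)
        res = math.inf
        for it in range(config.newton_max_iter):
            fint, _, K = self.internal(materials, u)
            fext, Kload = self.pressure_load(p_kpa, u,
                                             follower=config.follower_pressure)
            R = fint - fext
            res = np.linalg.norm(R + self.C.T @ lam) / ref
            if res <= config.newton_tol and it > 0:
                return u, lam, res
            Ksys = K - Kload if Kload is not None else K
            du, lam = self._solve_kkt(Ksys, -R, -(self.C @ u))
            # backtracking against element inversion
            step = 1.0
            for _ in range(12):
                with np.errstate(over="ignore", invalid="ignore"):
                    F2 = self.gradients(u + step * du)
                    J = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
                    # NaN/overflowed states fail the check and shrink the step
                    if np.all(np.isfinite(J)) and np.all(J > 0):
                        break
                step *= 0.5
            else:
                raise SolverError("could not avoid element inversion")
            u = u + step * du
        # final residual check
        fint, _, _ = self.internal(materials, u, tangent=False)
        fext, _ = self.pressure_load(p_kpa, u, follower=config.follower_pressure)
        res = np.linalg.norm(fint - fext + self.C.T @ lam) / ref
        if res <= config.newton_tol * 100:
            return u, lam, res
        raise SolverError(f"Newton did not converge (residual {res:.3e})")

    # -- linear small-increment solve --------------------------------------
    def solve_linear_increment(self, materials: MaterialSet,
                               dp_mmhg: float) -> np.ndarray:
        """Single Hooke-law solve for a small pressure increment [mmHg].

        All materials must be :class:`LinearElastic`; the load acts on the
        current (stored) configuration. Returns nodal displacements (N, 2).
        """
        materials.validate(self.mesh.labels.tolist())
        for lab in self.groups:
            if not isinstance(materials[lab], LinearElastic):
                raise TypeError(f"linear increment requires LinearElastic "
                                f"materials; label {lab!r} is not")
        M = self.mesh.n_elements
        Kvals = np.empty((M, 6, 6))
        for lab, idx in self.groups.items():
            E, nu = materials[lab].E, materials[lab].nu
            fac = E / ((1 + nu) * (1 - 2 * nu))
            D = fac * np.array([[1 - nu, nu, 0.0],
                                [nu, 1 - nu, 0.0],
                                [0.0, 0.0, 0.5 - nu]])
            dN = self.dN[idx]
            B = np.zeros((idx.size, 3, 6))
            B[:, 0, 0::2] = dN[:, :, 0]
            B[:, 1, 1::2] = dN[:, :, 1]
            B[:, 2, 0::2] = dN[:, :, 1]
            B[:, 2, 1::2] = dN[:, :, 0]
            Kvals[idx] = np.einsum("m,mia,ij,mjb->mab", self.area[idx], B, D, B)
        K = sp.coo_matrix((Kvals.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        f, _ = self.pressure_load(dp_mmhg * MMHG_TO_KPA, np.zeros(self.ndof),
                                  follower=False)
        du, _ = self._solve_kkt(K, f)
        return du.reshape(-1, 2)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def inflate(mesh: LabeledMesh, materials: MaterialSet, pressure: float,
            config: SolverConfig = SolverConfig(),
            record_at: tuple[float, ...] = ()) -> Solution:
    """Inflate ``mesh`` (reference = stored coordinates) to ``pressure`` mmHg."""
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    if pressure == 0:
        M = mesh.n_elements
        F2 = np.broadcast_to(np.eye(2), (M, 2, 2)).copy()
        return Solution(mesh, np.zeros((mesh.n_nodes, 2)), F2,
                        np.zeros((M, 3, 3)), 0.0, True, 0.0)
    problem = PlaneStrainProblem(mesh, bc=config.bc)
    return problem.solve_inflate(materials, pressure, config, record_at)


def inflate_linear_increment(mesh: LabeledMesh, materials: MaterialSet,
                             dp: float, bc: str = "pin3") -> np.ndarray:
    """Displacements of a small linear-elastic pressure increment [mmHg]."""
    problem = PlaneStrainProblem(mesh, bc=bc)
    return problem.solve_linear_increment(materials, dp)


def strain_fields(mesh: LabeledMesh, displacements: np.ndarray,
                  center: np.ndarray) -> StrainField:
    """Per-element infinitesimal strains of a nodal displacement field.

    Strains are constant per linear triangle; cylindrical components are
    taken about ``center`` using each element-centroid angle.
    """
    problem = PlaneStrainProblem(mesh)
    u = np.asarray(displacements, dtype=float).reshape(-1, 2)
    ue = u[mesh.triangles]
    gradu = np.einsum("mai,maj->mij", ue, problem.dN)
    exx = gradu[:, 0, 0]
    eyy = gradu[:, 1, 1]
    exy = 0.5 * (gradu[:, 0, 1] + gradu[:, 1, 0])
    centroids = mesh.centroids()
    rel = centroids - np.asarray(center, dtype=float)
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("an element centroid coincides with the strain center")
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    return StrainField.from_cartesian(exx, eyy, exy, center, angles)


def max_principal_stress(solution: Solution) -> StressField:
    """Maximum principal Cauchy stress per element (out-of-plane included)."""
    if not solution.converged:
        raise ValueError("solution did not converge; stresses are meaningless")
    eig = np.linalg.eigvalsh(solution.cauchy)
    return StressField(sigma_max=eig[:, -1])


# --------------------------------------------------------------------------
# analytic oracles
# --------------------------------------------------------------------------

def lame_annulus(E: float, nu: float, a: float, b: float, p: float):
    """Plane-strain Lamé solution of a pressurized thick-walled cylinder.

    Internal pressure ``p`` [kPa] at r=a, traction-free at r=b. Returns a
    callable u(r) [mm] for the radial displacement.
    """
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")

    def u(r):
        r = np.asarray(r, dtype=float)
        fac = (1.0 + nu) * p * a * a / (E * (b * b - a * a))
        return fac * ((1.0 - 2.0 * nu) * r + b * b / r)

    return u


def neo_hooke_annulus_pressure(C10: float, A: float, B: float,
                               a: float, n_quad: int = 2000) -> float:
    """Inflation pressure [kPa] of an incompressible Neo-Hookean annulus.

    Plane-strain, reference radii (A, B), deformed inner radius ``a``;
    incompressibility gives r(R)^2 = R^2 - A^2 + a^2 and the equilibrium
    integral p = int_a^b (s_tt - s_rr) / r dr with
    s_tt - s_rr = 2 C10 (lam^2 - lam^-2), lam = r / R.
    """
    bb = math.sqrt(B * B - A * A + a * a)
    r = np.linspace(a, bb, n_quad)
    R = np.sqrt(r * r - a * a + A * A)
    lam = r / R
    integrand = 2.0 * C10 * (lam ** 2 - lam ** -2) / r
    return float(np.trapezoid(integrand, r))
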