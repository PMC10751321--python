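"""Constitutive models for atherosclerotic plaque tissues.

Three material families are supported, matching how the tissues of a
coronary plaque cross-section are commonly modelled:

* :class:`LinearElastic` — isotropic Hooke material (calcifications, and
  all tissues in the small-increment linear characterization).
* :class:`NeoHooke` — quasi-incompressible Neo-Hookean solid,
  ``psi = C10 (Ib1 - 3) + (1/D1) (J - 1)^2`` (lipid pools, and the ground
  truth of the linear study).
* :class:`GOH` — isotropic-fiber Gasser–Ogden–Holzapfel solid with an
  exponentially stiffening term (fibrotic tissue),
  ``psi = (1/D) (J - 1)^2 + mu (Ib1 - 3)
  + k1/(2 k2) * sum_{i=4,6} [exp(k2 * E_i^2) - 1]`` with
  ``E_i = kappa (Ib1 - 3) + (1 - 3 kappa) (Ib_i - 1)``.
  With the fiber dispersion ``kappa = 1/3`` the fiber term is isotropic and
  the fiber directions are inert.

Both models use the isochoric invariants ``Ib1 = J^(-2/3) I1`` and
``Ib4 = J^(-2/3) I4`` (the convention of the FE packages these tissues are
normally analyzed with); this is what makes the reference configuration
stress-free and the small-strain response consistent with the
(E, nu) <-> (C10, D1) conversion formulas.

Units are kPa for stress-like quantities, kPa^-1 for the volumetric
compliances D and D1, and mm for lengths throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinearElastic",
    "NeoHooke",
    "GOH",
    "Kinematics",
    "MaterialSet",
    "BehaviorCurve",
    "neo_hooke_from_linear",
    "linear_from_neo_hooke",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_curve",
    "curve_r2",
    "lhs_sample",
]


# --------------------------------------------------------------------------
# material parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearElastic:
    """Isotropic linear elastic material: Young's modulus E [kPa], Poisson nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")

    def as_neo_hooke(self) -> "NeoHooke":
        """Neo-Hookean equivalent with the same small-strain response."""
        c10, d1 = neo_hooke_from_linear(self.E, self.nu)
        return NeoHooke(c10, d1)

    def lame(self) -> tuple[float, float]:
        """Lame parameters (lambda, mu) in kPa."""
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class NeoHooke:
    """Neo-Hookean solid: psi = C10 (Ib1 - 3) + (1/D1)(J - 1)^2."""

    C10: float
    D1: float

    def __post_init__(self) -> None:
        if self.C10 <= 0:
            raise ValueError(f"C10 must be positive, got {self.C10}")
        if self.D1 <= 0:
            raise ValueError(f"D1 must be positive, got {self.D1}")


def _default_fibers() -> np.ndarray:
    return np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class GOH:
    """Gasser–Ogden–Holzapfel solid (isotropic fiber response at kappa=1/3).

    ``mu`` is the ground-state stiffness (often written C10 in plaque
    studies); ``k1`` [kPa] and ``k2`` [-] set the magnitude and shape of the
    exponential stiffening; ``D`` [kPa^-1] is the volumetric compliance and
    ``kappa`` the fiber dispersion. ``fiber_angles`` holds two unit vectors;
    they do not affect the response when kappa = 1/3.
    """

    mu: float
    k1: float
    k2: float
    D: float = 0.005
    kappa: float = 1.0 / 3.0
    fiber_angles: np.ndarray = field(default_factory=_default_fibers)

    def __post_init__(self) -> None:
        if min(self.mu, self.k1, self.k2, self.D) <= 0:
            raise ValueError("GOH parameters mu, k1, k2, D must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError(f"kappa must lie in [0, 1/3], got {self.kappa}")
        a = np.asarray(self.fiber_angles, dtype=float).reshape(2, 3)
        norms = np.linalg.norm(a, axis=1)
        object.__setattr__(self, "fiber_angles", a / norms[:, None])


Material = LinearElastic | NeoHooke | GOH


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Kinematics:
    """Deformation state described by a 3x3 deformation gradient F."""

    F: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float).reshape(3, 3)
        object.__setattr__(self, "F", F)
        if self.J <= 0:
            raise ValueError(f"detF must be positive, got {self.J}")

    @classmethod
    def plane_strain(cls, F2: np.ndarray) -> "Kinematics":
        """Embed an in-plane 2x2 gradient with F33 = 1 and no out-of-plane shear."""
        F = np.eye(3)
        F[:2, :2] = np.asarray(F2, dtype=float).reshape(2, 2)
        return cls(F)

    @classmethod
    def uniaxial(cls, lam: float) -> "Kinematics":
        """Incompressible uniaxial stretch along x: diag(lam, lam^-1/2, lam^-1/2)."""
        return cls(np.diag([lam, lam ** -0.5, lam ** -0.5]))

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def Ib1(self) -> float:
        """Isochoric first invariant J^(-2/3) I1."""
        return self.J ** (-2.0 / 3.0) * self.I1

    def I4(self, a: np.ndarray) -> float:
        a = np.asarray(a, dtype=float)
        return float(a @ self.C @ a)

    def Ib4(self, a: np.ndarray) -> float:
        """Isochoric fiber invariant J^(-2/3) I4."""
        return self.J ** (-2.0 / 3.0) * self.I4(a)


# --------------------------------------------------------------------------
# parameter conversions (linear <-> Neo-Hooke)
# --------------------------------------------------------------------------

def neo_hooke_from_linear(E: float, nu: float) -> tuple[float, float]:
    """Convert (E, nu) to Neo-Hookean (C10, D1).

    C10 = E / (4 (1 + nu)),  D1 = 6 (1 - 2 nu) / E.
    """
    if E <= 0:
        raise ValueError(f"E must be positive, got {E}")
    if not 0.0 < nu < 0.5:
        raise ValueError(f"nu must lie in (0, 0.5), got {nu}")
    return E / (4.0 * (1.0 + nu)), 6.0 * (1.0 - 2.0 * nu) / E


def linear_from_neo_hooke(C10: float, D1: float) -> tuple[float, float]:
    """Invert :func:`neo_hooke_from_linear` in closed form."""
    if C10 <= 0 or D1 <= 0:
        raise ValueError("C10 and D1 must be positive")
    x = C10 * D1
    nu = (6.0 - 4.0 * x) / (12.0 + 4.0 * x)
    if not 0.0 < nu < 0.5:
        raise ValueError(f"(C10, D1) imply nu={nu:.4f} outside (0, 0.5)")
    E = 4.0 * (1.0 + nu) * C10
    return E, nu


# --------------------------------------------------------------------------
# energy and stress (general 3x3 kinematics)
# --------------------------------------------------------------------------

def strain_energy(material: Material, kin: Kinematics) -> float:
    """Strain-energy density psi [kPa] at the given deformation state."""
    if isinstance(material, LinearElastic):
        eps = 0.5 * (kin.F + kin.F.T) - np.eye(3)
        lam, mu = material.lame()
        return float(0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps))
    if isinstance(material, NeoHooke):
        return material.C10 * (kin.Ib1 - 3.0) + (1.0 / material.D1) * (kin.J - 1.0) ** 2
    if isinstance(material, GOH):
        m = material
        psi = (1.0 / m.D) * (kin.J - 1.0) ** 2 + m.mu * (kin.Ib1 - 3.0)
        for a in m.fiber_angles:
            e = m.kappa * (kin.Ib1 - 3.0) + (1.0 - 3.0 * m.kappa) * (kin.Ib4(a) - 1.0)
            psi += m.k1 / (2.0 * m.k2) * (np.exp(m.k2 * e * e) - 1.0)
        return float(psi)
    raise TypeError(f"unsupported material type {type(material)!r}")


def _pk1(material: Material, kin: Kinematics) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dpsi/dF, analytic, 3x3.

    Uses d(Ib1)/dF = 2 beta (F - (I1/3) F^-T) and
    d(Ib4)/dF = beta (2 (Fa x a) - (2/3) I4 F^-T), beta = J^(-2/3).
    """
    F = kin.F
    J = kin.J
    Finv_T = np.linalg.inv(F).T
    beta = J ** (-2.0 / 3.0)
    dIb1 = 2.0 * beta * (F - (kin.I1 / 3.0) * Finv_T)
    if isinstance(material, NeoHooke):
        return material.C10 * dIb1 + (2.0 / material.D1) * (J - 1.0) * J * Finv_T
    if isinstance(material, GOH):
        m = material
        P = m.mu * dIb1 + (2.0 / m.D) * (J - 1.0) * J * Finv_T
        for a in m.fiber_angles:
            I4 = kin.I4(a)
            e = m.kappa * (kin.Ib1 - 3.0) + (1.0 - 3.0 * m.kappa) * (beta * I4 - 1.0)
            dpsi_de = m.k1 * e * np.exp(m.k2 * e * e)
            dIb4 = beta * (2.0 * np.outer(F @ a, a) - (2.0 / 3.0) * I4 * Finv_T)
            P = P + dpsi_de * (m.kappa * dIb1 + (1.0 - 3.0 * m.kappa) * dIb4)
        return P
    raise TypeError(f"no Piola stress for material type {type(material)!r}")


def cauchy_stress(material: Material, kin: Kinematics) -> np.ndarray:
    """Cauchy stress tensor [kPa], symmetric 3x3.

    Hyperelastic materials use the push-forward sigma = P F^T / J of the
    analytic dpsi/dF; the linear material applies Hooke's law to the
    small-strain tensor of F.
    """
    if isinstance(material, LinearElastic):
        eps = 0.5 * (kin.F + kin.F.T) - np.eye(3)
        lam, mu = material.lame()
        return lam * np.trace(eps) * np.eye(3) + 2.0 * mu * eps
    P = _pk1(material, kin)
    sig = P @ kin.F.T / kin.J
    return 0.5 * (sig + sig.T)


# --------------------------------------------------------------------------
# uniaxial behavior curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorCurve:
    """Cauchy stress vs stretch under incompressible uniaxial tension."""

    stretch: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretch and stress must be matching 1-D arrays")
        if lam[0] != 1.0 or np.any(np.diff(lam) <= 0):
            raise ValueError("stretch grid must ascend from 1.0")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)


def uniaxial_stress(material: Material, lam: float) -> float:
    """Incompressible uniaxial Cauchy stress at stretch lam.

    The transverse stretches are lam^-1/2 (J = 1) and the hydrostatic
    pressure is eliminated through the traction-free lateral condition
    sigma_22 = 0, so sigma = sigma~_11 - sigma~_22 with sigma~ from the
    isochoric part of the model.  Linear materials are represented by their
    Neo-Hookean small-strain equivalent.
    """
    if isinstance(material, LinearElastic):
        material = material.as_neo_hooke()
    kin = Kinematics.uniaxial(lam)
    sig = cauchy_stress(material, kin)
    return float(sig[0, 0] - sig[1, 1])


def uniaxial_curve(material: Material, lam_max: float = 1.3, n_points: int = 100) -> BehaviorCurve:
    """Stress-stretch behavior curve on an ascending grid from lam = 1."""
    if lam_max <= 1.0:
        raise ValueError(f"lam_max must exceed 1, got {lam_max}")
    if isinstance(material, GOH) and not 0.0 <= material.kappa <= 1.0 / 3.0 + 1e-12:
        raise ValueError("kappa outside [0, 1/3]")
    lam = np.linspace(1.0, lam_max, n_points)
    sig = np.array([uniaxial_stress(material, x) for x in lam])
    return BehaviorCurve(lam, sig)


def curve_r2(reference: BehaviorCurve, candidate: BehaviorCurve) -> float:
    """Coefficient of determination between two behavior curves.

    R^2 = 1 - SS_res / SS_tot with the reference curve as the data; the
    curves must share the same stretch grid.
    """
    if not np.array_equal(reference.stretch, candidate.stretch):
        raise ValueError("curves must share an identical stretch grid")
    ref = reference.stress
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference curve is constant; R^2 undefined")
    ss_res = float(np.sum((ref - candidate.stress) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# Latin hypercube sampling
# --------------------------------------------------------------------------

def lhs_sample(ranges: Sequence[Sequence[float]], n: int, seed: int | None = None) -> np.ndarray:
    """Stratified Latin-hypercube sample of n points over a parameter box.

    Each marginal is divided into n equal strata and each stratum receives
    exactly one point, at a uniform position inside it; strata are paired
    across dimensions by independent random permutations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    box = np.asarray(ranges, dtype=float)
    if box.ndim != 2 or box.shape[1] != 2 or np.any(box[:, 0] >= box[:, 1]):
        raise ValueError("ranges must be a list of [lo, hi] with lo < hi")
    rng = np.random.default_rng(seed)
    d = box.shape[0]
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1) + rng.uniform(size=(d, n))) / n
    return (box[:, 0:1] + u * (box[:, 1:2] - box[:, 0:1])).T


# --------------------------------------------------------------------------
# material sets
# --------------------------------------------------------------------------

@dataclass
class MaterialSet:
    """Mapping tissue label -> constitutive model, e.g. fibrotic/lipid_1/..."""

    models: dict[str, Material]

    def __getitem__(self, label: str) -> Material:
        return self.models[label]

    def __contains__(self, label: str) -> bool:
        return label in self.models

    def labels(self) -> list[str]:
        return list(self.models)

    def validate(self, mesh_labels: Sequence[str]) -> None:
        missing = sorted(set(mesh_labels) - set(self.models))
        if missing:
            raise KeyError(f"material set lacks entries for labels: {missing}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for label, m in self.models.items():
            if isinstance(m, LinearElastic):
                out[label] = {"model": "linear", "E": m.E, "nu": m.nu}
            elif isinstance(m, NeoHooke):
                out[label] = {"model": "neohooke", "C10": m.C10, "D1": m.D1}
            elif isinstance(m, GOH):
                out[label] = {
                    "model": "goh", "c10": m.mu, "k1": m.k1, "k2": m.k2,
                    "D": m.D, "kappa": m.kappa,
                }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialSet":
        models: dict[str, Material] = {}
        for label, spec in data.items():
            kind = spec["model"].lower()
            if kind == "linear":
                models[label] = LinearElastic(spec["E"], spec["nu"])
            elif kind == "neohooke":
                models[label] = NeoHooke(spec["C10"], spec["D1"])
            elif kind == "goh":
                mu = spec.get("mu", spec.get("c10"))
                models[label] = GOH(mu, spec["k1"], spec["k2"],
                                    D=spec.get("D", 0.005),
                                    kappa=spec.get("kappa", 1.0 / 3.0))
            else:
                raise ValueError(f"unknown material model {kind!r} for {label!r}")
        return cls(models)


# --------------------------------------------------------------------------
# vectorized plane-strain evaluation (used by the FE solver)
# --------------------------------------------------------------------------

def _plane_strain_invariants(F2: np.ndarray):
    """Return (J, I1, FinvT) for a batch of in-plane gradients (F33 = 1)."""
    J = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    I1 = np.sum(F2 * F2, axis=(-2, -1)) + 1.0
    FinvT = np.empty_like(F2)
    FinvT[..., 0, 0] = F2[..., 1, 1]
    FinvT[..., 1, 1] = F2[..., 0, 0]
    FinvT[..., 0, 1] = -F2[..., 1, 0]
    FinvT[..., 1, 0] = -F2[..., 0, 1]
    FinvT = FinvT / J[..., None, None]
    return J, I1, FinvT


def _ps_energy_piola(material: Material, F2: np.ndarray):
    """Analytic (psi, P_inplane, P33) for a batch of plane-strain states.

    Raises FloatingPointError on non-positive Jacobians and on overflow of
    the exponential stiffening term (extreme parameter/deformation states
    polled by the inverse loop), so callers can treat the state as
    infeasible instead of propagating NaNs.
    """
    with np.errstate(over="raise", invalid="raise"):
        return _ps_energy_piola_unchecked(material, F2)


def _ps_energy_piola_unchecked(material: Material, F2: np.ndarray):
    J, I1, FinvT = _plane_strain_invariants(F2)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian in plane-strain response")
    beta = J ** (-2.0 / 3.0)
    b_ = beta[..., None, None]
    dIb1 = 2.0 * b_ * (F2 - (I1 / 3.0)[..., None, None] * FinvT)
    dIb1_33 = 2.0 * beta * (1.0 - I1 / 3.0)

    if isinstance(material, NeoHooke):
        cvol = 1.0 / material.D1
        mu_like = material.C10
        fiber = None
    elif isinstance(material, GOH):
        cvol = 1.0 / material.D
        mu_like = material.mu
        fiber = material
    else:
        raise TypeError(f"unsupported material type {type(material)!r}")

    psi = cvol * (J - 1.0) ** 2 + mu_like * (beta * I1 - 3.0)
    P = mu_like * dIb1 + 2.0 * cvol * ((J - 1.0) * J)[..., None, None] * FinvT
    P33 = mu_like * dIb1_33 + 2.0 * cvol * (J - 1.0) * J

    if fiber is not None:
        m = fiber
        for a3 in m.fiber_angles:
            a, az = a3[:2], a3[2]
            Fa = np.einsum("...ij,j->...i", F2, a)
            I4 = np.sum(Fa * Fa, axis=-1) + az * az
            e = m.kappa * (beta * I1 - 3.0) + (1.0 - 3.0 * m.kappa) * (beta * I4 - 1.0)
            expo = np.exp(m.k2 * e * e)
            psi = psi + m.k1 / (2.0 * m.k2) * (expo - 1.0)
            g1 = m.k1 * e * expo  # dpsi/de
            dIb4 = b_ * (2.0 * np.einsum("...i,j->...ij", Fa, a)
                         - (2.0 / 3.0) * I4[..., None, None] * FinvT)
            dIb4_33 = beta * (2.0 * az * az - (2.0 / 3.0) * I4)
            P = P + g1[..., None, None] * (m.kappa * dIb1
                                           + (1.0 - 3.0 * m.kappa) * dIb4)
            P33 = P33 + g1 * (m.kappa * dIb1_33 + (1.0 - 3.0 * m.kappa) * dIb4_33)
    return psi, P, P33


def plane_strain_response(material: Material, F2: np.ndarray, tangent: bool = True):
    """Batched plane-strain response of a hyperelastic material.

    Parameters
    ----------
    material : NeoHooke | GOH | LinearElastic
        Linear materials are evaluated through their Neo-Hookean equivalent
        (identical small-strain behavior).
    F2 : (..., 2, 2) array
        In-plane deformation gradients; F33 = 1 implicitly.
    tangent : bool
        Also return the first-elasticity tensor A = dP/dF, (..., 2, 2, 2, 2),
        computed by central differencing of the analytic Piola stress.

    Returns
    -------
    psi, P, P33[, A]
        Energy density, in-plane first Piola-Kirchhoff stress, its
        out-of-plane component, and optionally the in-plane tangent.
    """
    if isinstance(material, LinearElastic):
        material = material.as_neo_hooke()
    F2 = np.asarray(F2, dtype=float)
    psi, P, P33 = _ps_energy_piola(material, F2)
    if not tangent:
        return psi, P, P33
    h = 1e-7
    A = np.empty(F2.shape[:-2] + (2, 2, 2, 2))
    for k in range(2):
        for l in range(2):
            Fp = F2.copy()
            Fp[..., k, l] += h
            Fm = F2.copy()
            Fm[..., k, l] -= h
            A[..., :, :, k, l] = (_ps_energy_piola(material, Fp)[1]
                                  - _ps_energy_piola(material, Fm)[1]) / (2.0 * h)
    return psi, P, P33, A


def plane_strain_cauchy(material: Material, F2: np.ndarray) -> np.ndarray:
    """Full 3x3 Cauchy stress batch for in-plane gradients F2 (F33 = 1)."""
    F2 = np.asarray(F2, dtype=float)
    psi, P, P33 = plane_strain_response(material, F2, tangent=False)
    J = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    sig2 = np.einsum("...ij,...kj->...ik", P, F2) / J[..., None, None]
    sig2 = 0.5 * (sig2 + np.swapaxes(sig2, -1, -2))
    out = np.zeros(F2.shape[:-2] + (3, 3))
    out[..., :2, :2] = sig2
    out[..., 2, 2] = P33 / J
    return out
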