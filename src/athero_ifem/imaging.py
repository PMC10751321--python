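"""Simulated IVUS strain measurements: two-pressure frame pairs with noise.

An intravascular ultrasound elastography acquisition is emulated as the
pair of equilibrium states of the same plaque at two nearby lumen
pressures (e.g. 110 and 115 mmHg): the node coordinates at the lower
pressure play the role of the segmented image geometry, the relative nodal
displacements between the frames play the role of the displacement
estimator output, and the infinitesimal strains derived from them are
corrupted with additive white Gaussian noise at a prescribed SNR (20 dB by
default in the studies this package reproduces). Frames share the mesh
connectivity — speckle-tracking errors other than the strain noise are out
of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fem import PlaneStrainProblem, SolverConfig, StrainField, strain_fields
from .geometry import LabeledMesh
from .materials import LinearElastic, MaterialSet

__all__ = [
    "FramePair",
    "NoisySpec",
    "simulate_frame_pair",
    "frame_strains",
    "add_noise",
    "measure_snr",
]


@dataclass(frozen=True)
class NoisySpec:
    """Additive-noise specification: target SNR in dB (math.inf = off)."""

    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must be a number (or +inf to disable noise)")


@dataclass
class FramePair:
    """Two-pressure IVUS measurement on a shared mesh topology.

    ``coords_lo`` are the nodal coordinates at ``p_lo`` [mmHg] (the
    segmented geometry); ``rel_displacements`` carry each node from the
    ``p_lo`` frame to the ``p_hi`` frame.
    """

    mesh: LabeledMesh
    coords_lo: np.ndarray
    rel_displacements: np.ndarray
    p_lo: float
    p_hi: float

    def __post_init__(self) -> None:
        self.coords_lo = np.asarray(self.coords_lo, dtype=float)
        self.rel_displacements = np.asarray(self.rel_displacements, dtype=float)
        if self.p_hi <= self.p_lo:
            raise ValueError("p_hi must exceed p_lo")
        n = self.mesh.n_nodes
        if self.coords_lo.shape != (n, 2) or self.rel_displacements.shape != (n, 2):
            raise ValueError("frame arrays inconsistent with the mesh")

    def mesh_lo(self) -> LabeledMesh:
        """The mesh topology on the lower-pressure configuration."""
        return self.mesh.with_coordinates(self.coords_lo)


def simulate_frame_pair(zp_mesh: LabeledMesh, materials: MaterialSet,
                        p_lo: float, p_hi: float,
                        config: SolverConfig = SolverConfig()) -> FramePair:
    """Inflate the zero-pressure mesh to both frame pressures.

    Linear-elastic material sets use the small-increment solver (whose
    response is exactly proportional to pressure); hyperelastic sets use
    one nonlinear load path that records both equilibrium states.
    """
    if p_hi <= p_lo:
        raise ValueError("p_hi must exceed p_lo")
    materials.validate(zp_mesh.labels.tolist())
    problem = PlaneStrainProblem(zp_mesh, bc=config.bc)
    all_linear = all(isinstance(materials[l], LinearElastic)
                     for l in set(zp_mesh.labels.tolist()))
    if all_linear:
        u_unit = problem.solve_linear_increment(materials, 1.0)
        u_lo, u_hi = p_lo * u_unit, p_hi * u_unit
    else:
        sol = problem.solve_inflate(materials, p_hi, config,
                                    record_at=(p_lo, p_hi))
        u_lo = sol.recorded[p_lo]
        u_hi = sol.recorded[p_hi]
    return FramePair(mesh=zp_mesh, coords_lo=zp_mesh.nodes + u_lo,
                     rel_displacements=u_hi - u_lo, p_lo=p_lo, p_hi=p_hi)


def frame_strains(pair: FramePair) -> StrainField:
    """Infinitesimal strains of the relative frame displacements.

    Evaluated on the lower-pressure configuration, with the cylindrical
    origin at the lumen centroid of that frame.
    """
    mesh_lo = pair.mesh_lo()
    center = mesh_lo.lumen_centroid()
    return strain_fields(mesh_lo, pair.rel_displacements, center)


def add_noise(field: StrainField, spec: NoisySpec) -> StrainField:
    """Add white Gaussian noise to the Cartesian strain components.

    Per component, the noise variance is mean(signal^2) / 10^(SNR/10);
    cylindrical, principal and equivalent strains are recomputed from the
    noised Cartesian tensor so that all rotation identities keep holding.
    """
    if math.isinf(spec.snr_db):
        return field.copy()
    comps = [field.exx, field.eyy, field.exy]
    powers = [float(np.mean(c * c)) for c in comps]
    if min(powers) == 0.0:
        raise ValueError("zero signal power; SNR-scaled noise undefined")
    rng = np.random.default_rng(spec.seed)
    factor = 10.0 ** (-spec.snr_db / 10.0)
    noised = [c + rng.normal(0.0, math.sqrt(p * factor), size=c.shape)
              for c, p in zip(comps, powers)]
    return StrainField.from_cartesian(*noised, field.center, field.angles)


def measure_snr(clean: StrainField, noisy: StrainField) -> float:
    """Realized SNR in dB: 10 log10(sum clean^2 / sum (noisy - clean)^2).

    Summed over the Cartesian strain components; returns +inf when the
    fields are identical.
    """
    sig = err = 0.0
    for name in ("exx", "eyy", "exy"):
        c = getattr(clean, name)
        n = getattr(noisy, name)
        if c.shape != n.shape:
            raise ValueError("strain fields have mismatching shapes")
        sig += float(np.sum(c * c))
        err += float(np.sum((n - c) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / err)
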