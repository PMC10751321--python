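"""Zero-pressure geometry recovery by the Pull-Back algorithm.

Clinical images show the artery at physiological pressure, but a
hyperelastic analysis must start from the unloaded (zero-pressure, ZP)
configuration. The Pull-Back algorithm estimates it from the imaged
(pressurized) geometry and a candidate material set:

1. inflate the imaged geometry by the imaging pressure and collect the
   nodal displacements u;
2. the ZP candidate is the imaged geometry displaced by -K * u, where K is
   a scalar recovery factor (imposing that displacement as a boundary
   condition on a copy of the geometry is exactly this coordinate update);
3. the candidate is scored by re-inflating it to the imaging pressure and
   measuring the RMS nodal distance to the imaged geometry; K is chosen to
   minimize that residual (golden-section search), or fixed at K = 1 for
   the cheap variant used inside material-optimization loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fem import PlaneStrainProblem, SolverConfig, SolverError
from .geometry import LabeledMesh
from .materials import MaterialSet

__all__ = [
    "PullBackResult",
    "InvertedElementsError",
    "pullback_step",
    "repressurize_error",
    "pullback_optimize",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class InvertedElementsError(RuntimeError):
    """A ZP candidate contains inverted elements (listed in ``element_ids``)."""

    def __init__(self, element_ids: np.ndarray):
        self.element_ids = np.asarray(element_ids)
        super().__init__(f"{self.element_ids.size} inverted elements in ZP "
                         "candidate; reduce the recovery factor K")


@dataclass
class PullBackResult:
    """Outcome of a pull-back recovery."""

    zp_coordinates: np.ndarray
    K_zp: float
    residual_rms: float
    iterations: int
    converged: bool


def _check_candidate(mesh: LabeledMesh, coords: np.ndarray) -> None:
    areas = mesh.signed_areas(coords)
    if np.any(areas <= 0):
        raise InvertedElementsError(np.flatnonzero(areas <= 0))


def pullback_step(pressurized_mesh: LabeledMesh, materials: MaterialSet,
                  p_img: float, K: float = 1.0,
                  config: SolverConfig = SolverConfig(),
                  displacements: np.ndarray | None = None) -> np.ndarray:
    """One pull-back update: ZP candidate coordinates X - K * u.

    ``u`` is the displacement field of inflating the *pressurized* geometry
    by the imaging pressure ``p_img`` [mmHg]; pass ``displacements`` to
    reuse a previously computed field (the optimization loop varies only
    K). Raises :class:`InvertedElementsError` if the update folds any
    element.
    """
    if displacements is None:
        problem = PlaneStrainProblem(pressurized_mesh, bc=config.bc)
        sol = problem.solve_inflate(materials, p_img, config)
        displacements = sol.displacements
    candidate = pressurized_mesh.nodes - K * displacements
    _check_candidate(pressurized_mesh, candidate)
    return candidate


def repressurize_error(zp_candidate_coords: np.ndarray, mesh: LabeledMesh,
                       materials: MaterialSet, p_img: float,
                       target_coords: np.ndarray,
                       config: SolverConfig = SolverConfig()) -> float:
    """RMS nodal distance between the re-inflated candidate and the target.

    The candidate geometry is inflated to ``p_img`` and every node's
    Euclidean distance to the corresponding target node enters the RMS.
    """
    cand_mesh = mesh.with_coordinates(zp_candidate_coords)
    problem = PlaneStrainProblem(cand_mesh, bc=config.bc)
    sol = problem.solve_inflate(materials, p_img, config)
    final = cand_mesh.nodes + sol.displacements
    d2 = np.sum((final - np.asarray(target_coords, float)) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def pullback_optimize(pressurized_mesh: LabeledMesh, materials: MaterialSet,
                      p_img: float, K_bounds: tuple[float, float] = (0.5, 1.5),
                      config: SolverConfig = SolverConfig(),
                      k_tol: float = 1e-3, rms_plateau: float = 1e-4,
                      max_iterations: int = 40) -> PullBackResult:
    """Pull-back with an optimized recovery factor K.

    The inflation displacement of the imaged geometry is computed once;
    a golden-section search over K then minimizes the re-pressurization
    residual. Terminates when the K bracket shrinks below ``k_tol``, the
    best residual plateaus below ``rms_plateau`` [mm], or after
    ``max_iterations`` residual evaluations.
    """
    lo, hi = K_bounds
    if not (0.0 <= lo < hi <= 2.0):
        raise ValueError("K_bounds must satisfy 0 <= lo < hi <= 2")
    problem = PlaneStrainProblem(pressurized_mesh, bc=config.bc)
    sol = problem.solve_inflate(materials, p_img, config)
    u = sol.displacements

    cache: dict[float, float] = {}
    failures: list[float] = []

    def score(K: float) -> float:
        if K in cache:
            return cache[K]
        try:
            cand = pullback_step(pressurized_mesh, materials, p_img, K,
                                 config, displacements=u)
            rms = repressurize_error(cand, pressurized_mesh, materials,
                                     p_img, pressurized_mesh.nodes, config)
        except (InvertedElementsError, SolverError):
            failures.append(K)
            rms = math.inf
        cache[K] = rms
        return rms

    a, b = lo, hi
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = score(x1), score(x2)
    iterations = 2
    best_prev = min(f1, f2)
    while iterations < max_iterations and (b - a) > k_tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = score(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = score(x2)
        iterations += 1
        best = min(f1, f2)
        # plateau stop only after the bracket has been worked a few times
        if best < rms_plateau or \
                (iterations >= 6 and abs(best_prev - best) < rms_plateau):
            break
        best_prev = best

    finite = {k: v for k, v in cache.items() if math.isfinite(v)}
    if not finite:
        raise SolverError("pull-back failed for every K candidate "
                          f"(tried {sorted(cache)})")
    K_best = min(finite, key=finite.get)
    zp = pressurized_mesh.nodes - K_best * u
    return PullBackResult(zp_coordinates=zp, K_zp=float(K_best),
                          residual_rms=finite[K_best], iterations=iterations,
                          converged=True)
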