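"""Derivative-free inverse characterization of plaque tissue properties.

The measured quantity is the per-element radial strain between two IVUS
frames; candidate material parameters are scored by re-simulating that
strain and computing the normalized root-mean-square error

    J0 = 100 * RMS(eps_rr_meas - eps_rr_sim) / |mean(eps_rr_meas)|   [%]

which a Generating-Set-Search (GSS) pattern search minimizes inside a
parameter box. Two end-to-end pipelines are provided:

* :func:`characterize_linear` — one Young's modulus per tissue, scored by
  a single small-increment (5 mmHg) linear solve on the imaged
  configuration; quantifies the *relative* stiffness at the working
  pressure (success rate sr = 100 (1 - |E_real - E_est| / E_real)).
* :func:`characterize_nonlinear` — GOH fibrotic tissue, Neo-Hookean
  lipids, linear-elastic calcifications; every cost evaluation first
  recovers a zero-pressure candidate with a fixed-K pull-back, then
  re-inflates it through both frame pressures. After convergence the
  pull-back is re-run with a free recovery factor, and fibrotic tissues
  are judged by the R^2 between true and recovered uniaxial
  stress-stretch curves.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .fem import PlaneStrainProblem, SolverConfig, SolverError, strain_fields
from .geometry import LabeledMesh
from .imaging import FramePair
from .materials import (
    GOH,
    LinearElastic,
    MaterialSet,
    NeoHooke,
    curve_r2,
    uniaxial_curve,
)
from .pullback import InvertedElementsError, pullback_optimize, pullback_step

__all__ = [
    "nrmse_cost",
    "success_rate",
    "Parameter",
    "SearchSpace",
    "GSSConfig",
    "CostRecord",
    "GSSResult",
    "InverseResult",
    "gss_minimize",
    "characterize_linear",
    "characterize_nonlinear",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def nrmse_cost(eps_ref: np.ndarray, eps_it: np.ndarray) -> float:
    """Normalized RMS error J0 [%] between two radial-strain fields.

    J0 = 100 * sqrt(mean((ref - it)^2)) / |mean(ref)|. The reference mean
    must be bounded away from zero (radial strains under inflation are
    predominantly of one sign, so the normalization is well posed).
    """
    ref = np.asarray(eps_ref, dtype=float).ravel()
    it = np.asarray(eps_it, dtype=float).ravel()
    if ref.size == 0 or ref.shape != it.shape:
        raise ValueError("strain vectors must be non-empty and equal-sized")
    denom = abs(float(np.mean(ref)))
    rms = float(np.sqrt(np.mean((ref - it) ** 2)))
    if denom < 1e-12 * max(rms, 1e-30) or denom == 0.0:
        raise ValueError("mean reference strain is (numerically) zero; "
                         "NRMSE normalization undefined")
    return 100.0 * rms / denom


def success_rate(E_real: float, E_est: float) -> float:
    """Success rate sr [%] = 100 (1 - |E_real - E_est| / E_real).

    May be negative for gross over-estimates; no clamping is applied.
    """
    if E_real <= 0:
        raise ValueError("E_real must be positive")
    return 100.0 * (1.0 - abs(E_real - E_est) / E_real)


# --------------------------------------------------------------------------
# search space
# --------------------------------------------------------------------------

_ROLES = ("E", "C10", "D1", "k1", "k2")


@dataclass(frozen=True)
class Parameter:
    """One optimized scalar: (name, tissue label, role, bounds)."""

    name: str
    label: str
    role: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered box of optimized parameters with [0, 100] normalization.

    A poll step of d normalized units moves each raw parameter by
    d * range / 100, which gives parameters with wider search ranges
    proportionally more influence on the poll.
    """

    parameters: tuple[Parameter, ...]

    @property
    def dim(self) -> int:
        return len(self.parameters)

    def to_raw(self, z: np.ndarray) -> np.ndarray:
        z = np.clip(np.asarray(z, dtype=float), 0.0, 100.0)
        lo = np.array([p.lower for p in self.parameters])
        hi = np.array([p.upper for p in self.parameters])
        return lo + z / 100.0 * (hi - lo)

    def to_normalized(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([p.lower for p in self.parameters])
        hi = np.array([p.upper for p in self.parameters])
        return 100.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def by_label(self, x: np.ndarray) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for p, v in zip(self.parameters, x):
            out.setdefault(p.label, {})[p.role] = float(v)
        return out

    # -- canonical builders ----------------------------------------------
    @classmethod
    def linear(cls, labels, fibrotic_range=(390.0, 1200.0),
               lipid_range=(1.0, 100.0),
               calcification_range=(500.0, 10000.0)) -> "SearchSpace":
        """One Young's modulus per tissue label, literature search ranges."""
        params = []
        for lab in labels:
            if str(lab).startswith("lipid"):
                lo, hi = lipid_range
            elif str(lab).startswith("calcification"):
                lo, hi = calcification_range
            else:
                lo, hi = fibrotic_range
            params.append(Parameter(f"E_{lab}", str(lab), "E", lo, hi))
        return cls(tuple(params))

    @classmethod
    def nonlinear(cls, labels) -> "SearchSpace":
        """GOH fibrotic (C10, k1, k2), Neo-Hooke lipids (C10, D1),
        linear-elastic calcifications (E); standard search ranges."""
        params = []
        for lab in labels:
            lab = str(lab)
            if lab.startswith("lipid"):
                params.append(Parameter(f"C10_{lab}", lab, "C10", 0.1, 100.0))
                params.append(Parameter(f"D1_{lab}", lab, "D1", 0.005, 0.9))
            elif lab.startswith("calcification"):
                params.append(Parameter(f"E_{lab}", lab, "E", 500.0, 10000.0))
            else:
                params.append(Parameter(f"C10_{lab}", lab, "C10", 1.0, 50.0))
                params.append(Parameter(f"k1_{lab}", lab, "k1", 5.0, 100000.0))
                params.append(Parameter(f"k2_{lab}", lab, "k2", 1.0, 100.0))
        return cls(tuple(params))


# --------------------------------------------------------------------------
# generating set search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GSSConfig:
    """Pattern-search controls (normalized units: the box is [0, 100]^d).

    A successful poll doubles the mesh size, a failed poll halves it; a
    poll only counts as successful under the GSS sufficient-decrease rule
    (improvement larger than ``forcing_coeff * mesh^2``, which keeps
    noise-level improvements of weakly identifiable parameters from
    expanding the mesh). The search stops on a cost below ``cost_tol`` (a
    *fraction*: J0 percent below 100*cost_tol), a mesh below ``mesh_tol``,
    the evaluation budget, or the wall-clock budget. Re-polled lattice
    points are served from a cache and do not consume budget.
    """

    initial_mesh: float = 1.0
    expansion: float = 2.0
    contraction: float = 0.5
    cost_tol: float = 1e-4
    mesh_tol: float = 1e-3
    max_evaluations: int = 200
    max_mesh: float = 100.0
    forcing_coeff: float = 1e-4
    pattern_moves: bool = True
    n_search: int = 0
    time_budget: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.initial_mesh <= 0:
            raise ValueError("initial_mesh must be positive")
        if not self.expansion > 1.0 > self.contraction > 0.0:
            raise ValueError("need expansion > 1 > contraction > 0")


@dataclass(frozen=True)
class CostRecord:
    """One cost evaluation: index, raw parameter vector, J0 [%]."""

    index: int
    parameters: np.ndarray
    cost: float


@dataclass
class GSSResult:
    best_parameters: np.ndarray
    best_cost: float
    history: list[CostRecord]
    evaluations: int
    termination: str


def gss_minimize(cost_fn, space: SearchSpace, config: GSSConfig,
                 initial_point: np.ndarray | None = None) -> GSSResult:
    """Generating-Set-Search pattern search over a parameter box.

    Polls the 2d signed coordinate directions (opportunistic, with dynamic
    ordering: the last successful direction is polled first) from the
    incumbent in range-normalized coordinates; candidate points are
    projected onto the box, failed cost evaluations count as +inf and
    never abort the search. Deterministic for fixed inputs.
    """
    d = space.dim
    z = (np.full(d, 50.0) if initial_point is None
         else np.clip(np.asarray(initial_point, dtype=float), 0.0, 100.0))
    directions: list[tuple[int, float]] = [(i, s) for i in range(d)
                                           for s in (1.0, -1.0)]
    history: list[CostRecord] = []
    cache: dict[tuple, float] = {}
    t0 = time.monotonic()

    def evaluate(zp: np.ndarray) -> float:
        key = tuple(np.round(zp, 9))
        if key in cache:
            return cache[key]
        raw = space.to_raw(zp)
        try:
            c = float(cost_fn(raw))
            if math.isnan(c):
                c = math.inf
        except Exception:
            c = math.inf
        history.append(CostRecord(len(history), raw, c))
        cache[key] = c
        return c

    def out_of_budget() -> str | None:
        if len(history) >= config.max_evaluations:
            return "max_evaluations"
        if config.time_budget is not None and \
                time.monotonic() - t0 > config.time_budget:
            return "time_budget"
        return None

    best = evaluate(z)
    if config.n_search > 0:
        # space-filling search phase (counts against the budget): the poll
        # starts from the best sampled point if it beats the initial one
        from .materials import lhs_sample

        pts = lhs_sample([[0.0, 100.0]] * d, config.n_search,
                         seed=config.seed if config.seed is not None else 0)
        for zs in pts:
            if out_of_budget():
                break
            c = evaluate(zs)
            if c < best:
                z, best = np.asarray(zs, dtype=float), c
    mesh = config.initial_mesh
    termination = None
    while termination is None:
        if best <= 100.0 * config.cost_tol:
            termination = "cost_tol"
            break
        if mesh < config.mesh_tol:
            termination = "mesh_tol"
            break
        termination = out_of_budget()
        if termination:
            break
        success = False
        for k, (i, sign) in enumerate(directions):
            zc = z.copy()
            zc[i] = min(100.0, max(0.0, zc[i] + sign * mesh))
            if np.allclose(zc, z):
                continue
            c = evaluate(zc)
            if c < best - config.forcing_coeff * mesh * mesh:
                z_prev, z, best = z, zc, c
                success = True
                directions.insert(0, directions.pop(k))
                # Hooke-Jeeves pattern move: extrapolate the accumulated
                # step once more (follows diagonal valleys that single
                # coordinate polls traverse slowly)
                if config.pattern_moves and not out_of_budget():
                    zp = np.clip(z + (z - z_prev), 0.0, 100.0)
                    if not np.allclose(zp, z):
                        cp = evaluate(zp)
                        while cp < best - config.forcing_coeff * mesh * mesh:
                            z_prev, z, best = z, zp, cp
                            if out_of_budget():
                                break
                            zp = np.clip(z + (z - z_prev), 0.0, 100.0)
                            if np.allclose(zp, z):
                                break
                            cp = evaluate(zp)
                break
            if c < best:
                # simple decrease: accept the move but classify the poll as
                # unsuccessful, so the mesh still contracts
                z, best = zc, c
            termination = out_of_budget()
            if termination:
                break
        if termination:
            break
        mesh = min(mesh * config.expansion, config.max_mesh) if success \
            else mesh * config.contraction

    # the reported optimum is the best point ever evaluated (the poll
    # incumbent only accepts sufficient decreases)
    costs = [r.cost for r in history]
    k_best = int(np.argmin(costs))
    return GSSResult(best_parameters=history[k_best].parameters.copy(),
                     best_cost=costs[k_best],
                     history=history, evaluations=len(history),
                     termination=termination or "unknown")


# --------------------------------------------------------------------------
# end-to-end characterizations
# --------------------------------------------------------------------------

@dataclass
class InverseResult:
    """Outcome of an inverse characterization."""

    parameters: dict[str, dict[str, float]]
    best_cost: float
    history: list[CostRecord]
    metrics: dict[str, float] = field(default_factory=dict)
    weakly_identifiable: list[str] = field(default_factory=list)
    zp_coordinates: np.ndarray | None = None
    K_zp: float | None = None
    termination: str = ""
    mode: str = ""

    def materials(self) -> MaterialSet:
        """Recovered parameters as a MaterialSet."""
        models = {}
        for lab, pars in self.parameters.items():
            if "E" in pars:
                nu = 0.333 if lab.startswith("calcification") else 0.49
                models[lab] = LinearElastic(pars["E"], nu)
            elif "D1" in pars:
                models[lab] = NeoHooke(pars["C10"], pars["D1"])
            else:
                models[lab] = GOH(pars["C10"], pars["k1"], pars["k2"])
        return MaterialSet(models)


def _measured_radial(measured) -> np.ndarray:
    return np.asarray(measured.err if hasattr(measured, "err") else measured,
                      dtype=float)


def _linear_materials(space: SearchSpace, raw: np.ndarray,
                      nu_soft: float, nu_calc: float) -> MaterialSet:
    models = {}
    for p, v in zip(space.parameters, raw):
        nu = nu_calc if p.label.startswith("calcification") else nu_soft
        models[p.label] = LinearElastic(v, nu)
    return MaterialSet(models)


def characterize_linear(pair: FramePair, measured, space: SearchSpace | None = None,
                        config: GSSConfig | None = None,
                        truth: dict[str, float] | None = None,
                        nu_soft: float = 0.49, nu_calc: float = 0.333,
                        initial_point: np.ndarray | None = None) -> InverseResult:
    """Linear-elastic characterization at the working pressure.

    Optimizes one Young's modulus per tissue so that the radial strain of
    a small (p_hi - p_lo) pressure increment, solved linearly on the
    imaged (p_lo) configuration, matches the measured radial strain.
    ``measured`` is a StrainField (or a bare eps_rr vector); ``truth`` maps
    labels to ground-truth Young's moduli for success-rate reporting.
    """
    mesh_lo = pair.mesh_lo()
    labels = sorted(set(mesh_lo.labels.tolist()))
    if space is None:
        space = SearchSpace.linear(labels)
    if config is None:
        config = GSSConfig(initial_mesh=1.0, max_evaluations=200)
    missing = set(labels) - {p.label for p in space.parameters}
    if missing:
        raise ValueError(f"search space lacks parameters for labels {sorted(missing)}")
    eps_meas = _measured_radial(measured)
    problem = PlaneStrainProblem(mesh_lo, bc="pin3")
    center = mesh_lo.lumen_centroid()
    dp = pair.p_hi - pair.p_lo

    def cost(raw: np.ndarray) -> float:
        mats = _linear_materials(space, raw, nu_soft, nu_calc)
        du = problem.solve_linear_increment(mats, dp)
        eps = strain_fields(mesh_lo, du, center).err
        return nrmse_cost(eps_meas, eps)

    gss = gss_minimize(cost, space, config, initial_point)
    params = space.by_label(gss.best_parameters)

    metrics: dict[str, float] = {}
    if truth:
        for lab, pars in params.items():
            if lab in truth:
                metrics[f"sr_{lab}"] = success_rate(truth[lab], pars["E"])

    # identifiability diagnostic: profile each stiffness across its range
    weak: list[str] = []
    best_raw = gss.best_parameters.copy()
    for i, p in enumerate(space.parameters):
        probe = np.linspace(p.lower, p.upper, 5)
        js = []
        for v in probe:
            raw = best_raw.copy()
            raw[i] = v
            try:
                js.append(cost(raw))
            except (ValueError, SolverError):
                js.append(math.inf)
        js = np.asarray(js)
        finite = js[np.isfinite(js)]
        if finite.size and (finite.max() - finite.min()) < 0.01 * max(gss.best_cost, 1e-12):
            weak.append(p.label)

    return InverseResult(parameters=params, best_cost=gss.best_cost,
                         history=gss.history, metrics=metrics,
                         weakly_identifiable=weak,
                         termination=gss.termination, mode="linear")


def _nonlinear_materials(space: SearchSpace, raw: np.ndarray,
                         D_fib: float = 0.005, kappa: float = 1.0 / 3.0,
                         nu_calc: float = 0.333) -> MaterialSet:
    models: dict = {}
    for lab, pars in space.by_label(raw).items():
        if "k1" in pars:
            models[lab] = GOH(pars["C10"], pars["k1"], pars["k2"],
                              D=D_fib, kappa=kappa)
        elif "D1" in pars:
            models[lab] = NeoHooke(pars["C10"], pars["D1"])
        else:
            models[lab] = LinearElastic(pars["E"], nu_calc)
    return MaterialSet(models)


def characterize_nonlinear(pair: FramePair, measured,
                           space: SearchSpace | None = None,
                           config: GSSConfig | None = None,
                           truth: MaterialSet | None = None,
                           solver: SolverConfig | None = None,
                           initial_point: np.ndarray | None = None,
                           final_pullback: bool = True,
                           lam_max: float = 1.3) -> InverseResult:
    """Non-linear hyperelastic characterization with embedded pull-back.

    Each cost evaluation: (1) fixed-K (K=1) pull-back of the imaged
    geometry under the candidate materials; (2) inflation of the ZP
    candidate through both frame pressures; (3) NRMSE between measured and
    simulated radial strains of the frame increment. Solver failures score
    +inf and the poll continues. After termination the pull-back is re-run
    with a free recovery factor, and — when ``truth`` is given — each GOH
    tissue is scored by the R^2 between true and recovered uniaxial
    stress-stretch curves on [1, lam_max].
    """
    mesh_lo = pair.mesh_lo()
    labels = sorted(set(mesh_lo.labels.tolist()))
    if space is None:
        space = SearchSpace.nonlinear(labels)
    if config is None:
        config = GSSConfig(initial_mesh=100.0, max_evaluations=150)
    if solver is None:
        solver = SolverConfig(load_steps=6, newton_tol=1e-7)
    eps_meas = _measured_radial(measured)
    problem_img = PlaneStrainProblem(mesh_lo, bc="pin3")
    # consecutive poll points are close in parameter space, so each solve
    # warm-starts from the previous equilibrium (cold load stepping as
    # fallback on divergence)
    warm: dict[str, np.ndarray | None] = {"img": None, "cand": None}
    fast = SolverConfig(load_steps=1, newton_tol=solver.newton_tol,
                        newton_max_iter=solver.newton_max_iter,
                        max_bisections=6, bc=solver.bc)

    def _solve(problem: PlaneStrainProblem, mats: MaterialSet, p: float,
               record, key: str):
        u0 = warm[key]
        try:
            if u0 is None:
                raise SolverError("no warm state yet")
            sol = problem.solve_inflate(mats, p, fast, record_at=record,
                                        u0=u0.ravel())
        except (SolverError, FloatingPointError):
            sol = problem.solve_inflate(mats, p, solver, record_at=record)
        warm[key] = sol.displacements.copy()
        return sol

    def cost(raw: np.ndarray) -> float:
        mats = _nonlinear_materials(space, raw)
        sol = _solve(problem_img, mats, pair.p_lo, (), "img")
        cand = mesh_lo.nodes - sol.displacements  # pull-back, K = 1
        cand_mesh = mesh_lo.with_coordinates(cand)
        cand_problem = PlaneStrainProblem(cand_mesh, bc="pin3")
        sol2 = _solve(cand_problem, mats, pair.p_hi,
                      (pair.p_lo, pair.p_hi), "cand")
        u_lo, u_hi = sol2.recorded[pair.p_lo], sol2.recorded[pair.p_hi]
        conf_lo = cand_mesh.with_coordinates(cand + u_lo)
        center = conf_lo.lumen_centroid()
        eps = strain_fields(conf_lo, u_hi - u_lo, center).err
        return nrmse_cost(eps_meas, eps)

    gss = gss_minimize(cost, space, config, initial_point)
    params = space.by_label(gss.best_parameters)
    best_mats = _nonlinear_materials(space, gss.best_parameters)

    zp = None
    K = None
    if final_pullback:
        try:
            pb = pullback_optimize(mesh_lo, best_mats, pair.p_lo, config=solver)
            zp, K = pb.zp_coordinates, pb.K_zp
        except (SolverError, InvertedElementsError):
            zp, K = None, None

    metrics: dict[str, float] = {}
    if truth is not None:
        for lab in labels:
            if isinstance(truth[lab], GOH) and "k1" in params.get(lab, {}):
                ref = uniaxial_curve(truth[lab], lam_max=lam_max)
                est = uniaxial_curve(best_mats[lab], lam_max=lam_max)
                metrics[f"r2_{lab}"] = curve_r2(ref, est)

    return InverseResult(parameters=params, best_cost=gss.best_cost,
                         history=gss.history, metrics=metrics,
                         zp_coordinates=zp, K_zp=K,
                         termination=gss.termination, mode="nonlinear")
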