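"""Model/Results interface for the inverse characterizations.

Follows the familiar fitting-package idiom: a model object is built from
the data (an IVUS frame pair plus its measured strain field), ``fit()``
runs the optimization and returns a results object carrying the
estimates, fit diagnostics and a ``summary()`` table; simulation and
plotting helpers hang off the two objects.

    >>> model = LinearElastography(pair, noisy_strains, truth={...})
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import SolverConfig, StrainField
from .imaging import FramePair
from .inverse import (
    GSSConfig,
    InverseResult,
    SearchSpace,
    characterize_linear,
    characterize_nonlinear,
)
from .materials import GOH, MaterialSet, uniaxial_curve

__all__ = ["LinearElastography", "HyperelasticCharacterization",
           "CharacterizationResults"]


@dataclass
class CharacterizationResults:
    """Estimates and diagnostics of an inverse characterization fit."""

    model: object
    raw: InverseResult

    # -- accessors --------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Recovered parameters as a flat (label, role) -> value series."""
        data = {(lab, role): v for lab, pars in self.raw.parameters.items()
                for role, v in pars.items()}
        return pd.Series(data).sort_index()

    @property
    def cost(self) -> float:
        """Best NRMSE cost J0 [%]."""
        return self.raw.best_cost

    @property
    def cost_history(self) -> pd.DataFrame:
        rec = self.raw.history
        return pd.DataFrame({
            "evaluation": [r.index for r in rec],
            "cost": [r.cost for r in rec],
        })

    @property
    def metrics(self) -> pd.Series:
        return pd.Series(self.raw.metrics, dtype=float)

    @property
    def K_zp(self):
        return self.raw.K_zp

    @property
    def zp_coordinates(self):
        return self.raw.zp_coordinates

    def materials(self) -> MaterialSet:
        return self.raw.materials()

    def behavior_curve(self, label: str, lam_max: float = 1.3, n_points: int = 100):
        """Recovered uniaxial stress-stretch curve for one tissue."""
        return uniaxial_curve(self.materials()[label], lam_max, n_points)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Inverse plaque characterization",
            "=" * 55,
            f"mode:               {self.raw.mode}",
            f"best cost J0 [%]:   {self.raw.best_cost:.4f}",
            f"evaluations:        {len(self.raw.history)}",
            f"termination:        {self.raw.termination}",
        ]
        if self.raw.K_zp is not None:
            lines.append(f"recovery factor K:  {self.raw.K_zp:.4f}")
        if self.raw.weakly_identifiable:
            lines.append("weakly identifiable: "
                         + ", ".join(self.raw.weakly_identifiable))
        lines += ["", "Parameters", "-" * 55,
                  self.params.rename("estimate").to_string()]
        if len(self.metrics):
            lines += ["", "Per-tissue metrics (sr [%] / R^2)", "-" * 55,
                      self.metrics.rename("value").to_string()]
        return "\n".join(lines) + "\n"

    def plot_cost_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.cost_history
        best = np.minimum.accumulate(np.where(np.isfinite(h["cost"]),
                                              h["cost"], np.inf))
        ax.plot(h["evaluation"], best, drawstyle="steps-post")
        ax.set_xlabel("cost evaluation")
        ax.set_ylabel("best J0 [%]")
        ax.set_title("pattern-search convergence")
        return ax

    def plot_behavior_curves(self, truth: MaterialSet | None = None,
                             lam_max: float = 1.3, ax=None):
        """Overlay recovered (and true) uniaxial curves for GOH tissues."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mats = self.materials()
        for lab in mats.labels():
            if not isinstance(mats[lab], GOH):
                continue
            c = uniaxial_curve(mats[lab], lam_max)
            ax.plot(c.stretch, c.stress, label=f"{lab} (recovered)")
            if truth is not None and isinstance(truth[lab], GOH):
                t = uniaxial_curve(truth[lab], lam_max)
                ax.plot(t.stretch, t.stress, "--", label=f"{lab} (true)")
        ax.set_xlabel("stretch λ [-]")
        ax.set_ylabel("Cauchy stress σ [kPa]")
        ax.legend()
        return ax


class _CharacterizationModel:
    """Shared constructor/validation of the two characterization models."""

    def __init__(self, pair: FramePair, measured: StrainField,
                 truth=None, space: SearchSpace | None = None):
        if pair.mesh.n_elements != np.size(getattr(measured, "err", measured)):
            raise ValueError("measured strain field does not match the mesh")
        self.pair = pair
        self.measured = measured
        self.truth = truth
        self.space = space

    @property
    def exog_labels(self) -> list[str]:
        return sorted(set(self.pair.mesh.labels.tolist()))


class LinearElastography(_CharacterizationModel):
    """Relative-stiffness (Young's modulus) estimation at a working pressure.

    Parameters
    ----------
    pair : FramePair
        Simulated or imported IVUS frame pair (small pressure increment).
    measured : StrainField
        Measured (noisy) strains of the frame increment.
    truth : dict[str, float], optional
        Ground-truth Young's moduli per label, enabling success-rate metrics.
    space : SearchSpace, optional
        Defaults to one E per tissue with the literature search ranges.
    """

    def fit(self, config: GSSConfig | None = None, **kw) -> CharacterizationResults:
        res = characterize_linear(self.pair, self.measured, space=self.space,
                                  config=config, truth=self.truth, **kw)
        return CharacterizationResults(self, res)


class HyperelasticCharacterization(_CharacterizationModel):
    """Full non-linear (GOH) characterization with zero-pressure recovery.

    ``truth`` here is a :class:`MaterialSet` (enables curve-R^2 metrics).
    """

    def fit(self, config: GSSConfig | None = None,
            solver: SolverConfig | None = None, **kw) -> CharacterizationResults:
        res = characterize_nonlinear(self.pair, self.measured, space=self.space,
                                     config=config, truth=self.truth,
                                     solver=solver, **kw)
        return CharacterizationResults(self, res)
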