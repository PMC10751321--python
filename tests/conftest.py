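"""Shared fixtures: small meshes and simulated IVUS studies.

Expensive objects (meshes, forward simulations, fitted characterizations)
are session-scoped so the suite pays for each exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from athero_ifem import (
    GOH,
    LinearElastic,
    MaterialSet,
    NeoHooke,
    annulus_mesh,
    default_plaque_spec,
    generate_plaque,
    mesh_plaque,
    neo_hooke_from_linear,
    simulate_frame_pair,
)
from athero_ifem.fem import SolverConfig
from athero_ifem.imaging import frame_strains

# reference GOH parameter sets for fibrotic tissue (calcified/cellular/...)
CALCIFIED_1 = GOH(9.58, 17564.0, 0.51)
CALCIFIED_2 = GOH(17.29, 13968.82, 3.36)
CELLULAR = GOH(0.1, 1948.80, 3.36)
HYPOCELLULAR = GOH(139.32, 15918.0, 0.1)


@pytest.fixture(scope="session")
def small_annulus():
    """Coarse structured annulus (inner 1.5 mm, outer 4 mm)."""
    return annulus_mesh(1.5, 4.0, 8, 40)


@pytest.fixture(scope="session")
def fib600():
    return MaterialSet({"fibrotic": LinearElastic(600.0, 0.49)})


@pytest.fixture(scope="session")
def plaque_mesh():
    """Default calcified plaque surrogate at the working resolution."""
    spec = default_plaque_spec(seed=11)
    return mesh_plaque(generate_plaque(spec), 0.065)


@pytest.fixture(scope="session")
def linear_study(plaque_mesh):
    """Forward Neo-Hooke simulation of the linear characterization study."""
    truth_E = {"fibrotic": 600.0, "lipid_1": 10.0, "calcification_1": 5000.0}
    materials = MaterialSet({
        "fibrotic": NeoHooke(*neo_hooke_from_linear(600.0, 0.45)),
        "lipid_1": NeoHooke(*neo_hooke_from_linear(10.0, 0.45)),
        "calcification_1": LinearElastic(5000.0, 0.333),
    })
    pair = simulate_frame_pair(plaque_mesh, materials, 110.0, 115.0,
                               SolverConfig(load_steps=10))
    return {"mesh": plaque_mesh, "truth_E": truth_E, "materials": materials,
            "pair": pair, "clean": frame_strains(pair)}


@pytest.fixture(scope="session")
def nonlinear_study():
    """Forward GOH simulation of the non-linear study (single-lipid plaque)."""
    spec = default_plaque_spec(include_calcification=False,
                               min_cap_thickness=0.3, seed=11)
    mesh = mesh_plaque(generate_plaque(spec), 0.1)
    truth = MaterialSet({
        "fibrotic": CALCIFIED_1,
        "lipid_1": NeoHooke(*neo_hooke_from_linear(10.0, 0.45)),
    })
    pair = simulate_frame_pair(mesh, truth, 110.0, 115.0,
                               SolverConfig(load_steps=10))
    return {"mesh": mesh, "truth": truth, "pair": pair,
            "clean": frame_strains(pair)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
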