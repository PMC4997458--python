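"""Shared fixtures: small graphs, grids, and one expensive recovery fit."""

import math

import numpy as np
import pytest

from stbhm import (
    MCMCConfig,
    PriorSpec,
    make_truth,
    queen_lattice,
    run_mcmc,
    simulate_panel,
)
from stbhm.synthetic import HotspotSpec, TruthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def lattice_3x3():
    return queen_lattice(3, 3)


@pytest.fixture
def path_graph_4():
    """4-node path graph 0-1-2-3."""
    from stbhm import AdjacencyStructure

    return AdjacencyStructure(
        n_units=4,
        neighbors=[np.array([1]), np.array([0, 2]), np.array([1, 3]), np.array([2])],
    )


RECOVERY_LATTICE = (6, 10)  # 60 units
RECOVERY_TRUTH = TruthConfig(
    alpha=math.log(30.0),
    b0=0.02,
    s_hotspots=(
        HotspotSpec(center=(1, 2), radius=2.0, amplitude=0.8),
        HotspotSpec(center=(4, 7), radius=2.0, amplitude=0.65),
        HotspotSpec(center=(1, 7), radius=1.5, amplitude=0.5),
    ),
    sigma0=1.5,  # 5% of the 30 μg/m³ level
    sigma1=1.0,
    sigma_eps=0.0,
)


@pytest.fixture(scope="session")
def recovery_fit():
    """One full fit of a 60-unit, 17-year panel simulated from the model.

    Ground-truth level exp(alpha) = 30 μg/m³, common trend b0 = 0.02/yr,
    hotspots pushing exp(S) up to ~2, observation sds at most 5% of the
    level, over-dispersion disabled. Returned as (truth, panel, draws);
    shared across the recovery and convergence tests because the fit is the
    expensive part.
    """
    adj = queen_lattice(*RECOVERY_LATTICE)
    truth = make_truth(adj, RECOVERY_TRUTH, seed=42, lattice_shape=RECOVERY_LATTICE)
    panel = simulate_panel(truth, seed=7)
    draws = run_mcmc(
        panel,
        adj,
        PriorSpec(overdispersion=False),
        MCMCConfig(n_chains=3, n_iter=5000, n_burnin=2500, thin=5, seed=1),
    )
    return truth, panel, draws
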