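"""The hierarchy's density, CAR conditionals, sampler, and convergence tooling."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from stbhm import (
    AdjacencyStructure,
    MCMCConfig,
    PriorSpec,
    SpaceTimePanel,
    car_full_conditional,
    gelman_rubin,
    linear_predictor,
    log_joint_density,
    queen_lattice,
    run_mcmc,
)
from stbhm.model import ModelState, _icar_logkernel


def _random_state(rng, n, T, tstar=None):
    tstar = np.arange(T, dtype=float) - (T - 1) / 2 if tstar is None else tstar
    return ModelState(
        alpha=float(rng.normal(3, 0.2)),
        b0=float(rng.normal(0, 0.02)),
        S_struct=rng.normal(0, 0.2, n),
        S_unstruct=rng.normal(0, 0.1, n),
        b1_struct=rng.normal(0, 0.01, n),
        b1_unstruct=rng.normal(0, 0.005, n),
        v=rng.normal(0, 0.05, T),
        eps=rng.normal(0, 0.02, (n, T)),
        mu=rng.normal(25, 3, (n, T)),
        tstar=tstar,
        sigma0=1.4,
        sigma1=0.9,
        sigma_eps=0.02,
        tau_s=0.3,
        sd_s_unstruct=0.15,
        tau_b1=0.02,
        sd_b1_unstruct=0.01,
        sd_v=0.06,
    )


def _oracle_log_joint(state, panel, adj, priors):
    """Term-by-term independent re-implementation with explicit loops."""
    n, T = panel.values.shape
    lp = 0.0
    for i in range(n):
        for t in range(T):
            eta = (
                state.alpha
                + state.S_struct[i] + state.S_unstruct[i]
                + state.b0 * state.tstar[t]
                + state.v[t]
                + (state.b1_struct[i] + state.b1_unstruct[i]) * state.tstar[t]
                + state.eps[i, t]
            )
            lp += stats.norm.logpdf(panel.values[i, t], state.mu[i, t], state.sigma0)
            lp += stats.norm.logpdf(state.mu[i, t], math.exp(eta), state.sigma1)
    for fieldvals, tau in ((state.S_struct, state.tau_s), (state.b1_struct, state.tau_b1)):
        q = 0.0
        for i in range(n):
            for j in adj.neighbors[i]:
                if j > i:
                    q += (fieldvals[i] - fieldvals[j]) ** 2
        rank = adj.n_units - adj.n_components
        lp += -rank * math.log(tau) - 0.5 * q / tau**2
    for i in range(n):
        lp += stats.norm.logpdf(state.S_unstruct[i], 0, state.sd_s_unstruct)
        lp += stats.norm.logpdf(state.b1_unstruct[i], 0, state.sd_b1_unstruct)
    for t in range(T):
        lp += stats.norm.logpdf(state.v[t], 0, state.sd_v)
    for sd, scale in (
        (state.sigma0, priors.sigma0_scale),
        (state.sigma1, priors.sigma1_scale),
        (state.tau_s, priors.tau_s_scale),
        (state.sd_s_unstruct, priors.sd_s_unstruct_scale),
        (state.tau_b1, priors.tau_b1_scale),
        (state.sd_b1_unstruct, priors.sd_b1_unstruct_scale),
        (state.sd_v, priors.sd_v_scale),
    ):
        lp += stats.halfnorm.logpdf(sd, scale=scale)
    if priors.overdispersion:
        for i in range(n):
            for t in range(T):
                lp += stats.norm.logpdf(state.eps[i, t], 0, state.sigma_eps)
        lp += stats.halfnorm.logpdf(state.sigma_eps, scale=priors.sigma_eps_scale)
    return lp


class TestLinearPredictor:
    def test_zero_state_gives_zero(self):
        st = _random_state(np.random.default_rng(0), 2, 3)
        for name in ("S_struct", "S_unstruct", "b1_struct", "b1_unstruct"):
            setattr(st, name, np.zeros_like(getattr(st, name)))
        st.alpha = 0.0
        st.b0 = 0.0
        st.v = np.zeros(3)
        st.eps = np.zeros((2, 3))
        assert linear_predictor(st, 0, 0) == 0.0

    def test_overall_level_only(self):
        st = _random_state(np.random.default_rng(0), 2, 3)
        for name in ("S_struct", "S_unstruct", "b1_struct", "b1_unstruct"):
            setattr(st, name, np.zeros_like(getattr(st, name)))
        st.alpha = math.log(30.0)
        st.b0 = 0.0
        st.v = np.zeros(3)
        st.eps = np.zeros((2, 3))
        assert linear_predictor(st, 1, 2) == pytest.approx(math.log(30.0))

    def test_hand_sum(self):
        """alpha=1, S=0.5, b0=0.1, t*=2, v=-0.05, b1=0.02, eps=0.01 -> 1.70."""
        st = _random_state(np.random.default_rng(0), 1, 3, tstar=np.array([-2.0, 0.0, 2.0]))
        st.alpha = 1.0
        st.S_struct = np.array([0.5])
        st.S_unstruct = np.array([0.0])
        st.b0 = 0.1
        st.v = np.array([0.0, 0.0, -0.05])
        st.b1_struct = np.array([0.02])
        st.b1_unstruct = np.array([0.0])
        st.eps = np.array([[0.0, 0.0, 0.01]])
        assert linear_predictor(st, 0, 2) == pytest.approx(1.70)

    def test_index_out_of_range(self):
        st = _random_state(np.random.default_rng(0), 2, 3)
        with pytest.raises(IndexError):
            linear_predictor(st, 2, 0)


class TestCARFullConditional:
    def test_symmetric_neighbors_mean_zero(self):
        adj = AdjacencyStructure(
            n_units=3, neighbors=[np.array([1, 2]), np.array([0]), np.array([0])]
        )
        mean, _ = car_full_conditional(0, np.array([9.0, 1.0, -1.0]), adj, tau=1.0)
        assert mean == pytest.approx(0.0)

    def test_constant_neighbors(self):
        adj = queen_lattice(2, 2)
        mean, var = car_full_conditional(0, np.array([0.0, 2.0, 2.0, 2.0]), adj, tau=0.5)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(0.25 / 3)

    def test_isolated_unit_rejected(self):
        adj = AdjacencyStructure(n_units=2, neighbors=[np.array([]), np.array([])])
        with pytest.raises(ValueError, match="isolated"):
            car_full_conditional(0, np.zeros(2), adj, tau=1.0)

    def test_conditional_matches_joint_density_ratio(self, rng):
        """N(mean, var) log-ratio at two values of x_i equals the ICAR joint
        log-kernel difference (5-node graph, 20 random pairs)."""
        adj = AdjacencyStructure(
            n_units=5,
            neighbors=[
                np.array([1, 2]), np.array([0, 2, 3]), np.array([0, 1, 4]),
                np.array([1, 4]), np.array([2, 3]),
            ],
        )
        tau = 0.8
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            i = int(rng.integers(0, 5))
            a, b = rng.normal(0, 1, 2)
            mean, var = car_full_conditional(i, x, adj, tau)
            lr_cond = stats.norm.logpdf(a, mean, math.sqrt(var)) - stats.norm.logpdf(
                b, mean, math.sqrt(var)
            )
            xa, xb = x.copy(), x.copy()
            xa[i], xb[i] = a, b
            lr_joint = _icar_logkernel(xa, adj, tau) - _icar_logkernel(xb, adj, tau)
            assert lr_cond == pytest.approx(lr_joint, abs=1e-6)


class TestLogJointDensity:
    @pytest.fixture
    def setup(self, rng):
        adj = queen_lattice(2, 2)
        panel = SpaceTimePanel(values=rng.uniform(20, 35, (4, 3)), years=np.arange(2000, 2003))
        state = _random_state(rng, 4, 3, tstar=panel.tstar)
        return adj, panel, state

    @pytest.mark.parametrize("overdispersion", [True, False])
    def test_matches_independent_oracle(self, setup, overdispersion):
        adj, panel, state = setup
        priors = PriorSpec(overdispersion=overdispersion)
        got = log_joint_density(state, panel, adj, priors)
        want = _oracle_log_joint(state, panel, adj, priors)
        assert got == pytest.approx(want, abs=1e-10)

    def test_doubling_sigma0_with_zero_residuals(self, setup):
        adj, panel, state = setup
        state = copy.deepcopy(state)
        state.mu = panel.values.copy()  # zero observation residuals
        priors = PriorSpec(sigma0_scale=1e8, overdispersion=False)
        lp1 = log_joint_density(state, panel, adj, priors)
        state2 = copy.deepcopy(state)
        state2.sigma0 *= 2.0
        lp2 = log_joint_density(state2, panel, adj, priors)
        NT = panel.values.size
        assert lp2 - lp1 == pytest.approx(-NT * math.log(2.0), abs=1e-9)

    def test_icar_term_shift_invariant(self, setup):
        adj, panel, state = setup
        shifted = copy.deepcopy(state)
        shifted.S_struct = shifted.S_struct + 3.7
        shifted.alpha -= 3.7  # keep eta identical
        priors = PriorSpec(overdispersion=False)
        assert log_joint_density(shifted, panel, adj, priors) == pytest.approx(
            log_joint_density(state, panel, adj, priors), abs=1e-8
        )

    def test_single_site_delta_matches_joint(self, setup):
        """Local acceptance deltas (likelihood row + CAR neighbor terms) equal
        full joint-density differences — the sampler's decisions are exact."""
        adj, panel, state = setup
        priors = PriorSpec(overdispersion=False)
        i, delta = 2, 0.3
        lp1 = log_joint_density(state, panel, adj, priors)
        new = copy.deepcopy(state)
        new.S_struct = new.S_struct.copy()
        new.S_struct[i] += delta
        lp2 = log_joint_density(new, panel, adj, priors)
        # local computation as the sampler performs it
        theta_old = np.exp(state.eta())[i]
        theta_new = theta_old * math.exp(delta)
        dll = (
            -0.5 * np.sum((state.mu[i] - theta_new) ** 2) / state.sigma1**2
            + 0.5 * np.sum((state.mu[i] - theta_old) ** 2) / state.sigma1**2
        )
        nbr_sum = state.S_struct[adj.neighbors[i]].sum()
        m = adj.degrees[i]
        old, newv = state.S_struct[i], state.S_struct[i] + delta
        dprior = -0.5 / state.tau_s**2 * (m * (newv**2 - old**2) - 2 * (newv - old) * nbr_sum)
        assert lp2 - lp1 == pytest.approx(dll + dprior, abs=1e-8)

    def test_nonpositive_sd_rejected(self, setup):
        adj, panel, state = setup
        state = copy.deepcopy(state)
        state.sigma1 = 0.0
        with pytest.raises(ValueError):
            log_joint_density(state, panel, adj, PriorSpec())


class TestRunMCMC:
    def test_noise_free_constant_panel_recovers_level(self):
        """All y = 30 -> posterior of alpha concentrates at ln(30)."""
        panel = SpaceTimePanel(values=np.full((10, 5), 30.0), years=np.arange(2000, 2005))
        adj = queen_lattice(2, 5)
        draws = run_mcmc(
            panel, adj, PriorSpec(overdispersion=False),
            MCMCConfig(n_chains=2, n_iter=2000, n_burnin=1000, thin=2, seed=3),
        )
        assert np.median(draws.pooled("alpha")) == pytest.approx(math.log(30.0), abs=0.02)

    def test_identical_seed_bit_identical(self):
        rng = np.random.default_rng(1)
        panel = SpaceTimePanel(values=rng.uniform(25, 35, (9, 4)), years=np.arange(2000, 2004))
        adj = queen_lattice(3, 3)
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burnin=150, thin=1, seed=11)
        d1 = run_mcmc(panel, adj, PriorSpec(), cfg)
        d2 = run_mcmc(panel, adj, PriorSpec(), cfg)
        for name in d1.names():
            np.testing.assert_array_equal(d1.draws[name], d2.draws[name])
        d3 = run_mcmc(panel, adj, PriorSpec(), MCMCConfig(
            n_chains=2, n_iter=300, n_burnin=150, thin=1, seed=12))
        assert not np.array_equal(d1.draws["alpha"], d3.draws["alpha"])

    def test_adjacency_mismatch_rejected(self):
        panel = SpaceTimePanel(values=np.ones((4, 3)) * 30, years=np.arange(2000, 2003))
        with pytest.raises(ValueError, match="cover"):
            run_mcmc(panel, queen_lattice(3, 3), config=MCMCConfig(
                n_chains=2, n_iter=20, n_burnin=10, thin=1))

    def test_scaling_y_shifts_alpha_by_log_k(self):
        """Multiplying all observations by k shifts the posterior of alpha by
        ~ln(k) in the small-noise regime (log-link equivariance)."""
        rng = np.random.default_rng(5)
        base = 30.0 + rng.normal(0, 0.3, (9, 5))
        years = np.arange(2000, 2005)
        adj = queen_lattice(3, 3)
        cfg = MCMCConfig(n_chains=2, n_iter=1500, n_burnin=750, thin=2, seed=2)
        priors = PriorSpec(overdispersion=False)
        a1 = np.median(run_mcmc(SpaceTimePanel(base, years), adj, priors, cfg).pooled("alpha"))
        k = 2.5
        a2 = np.median(run_mcmc(SpaceTimePanel(base * k, years), adj, priors, cfg).pooled("alpha"))
        assert a2 - a1 == pytest.approx(math.log(k), abs=0.02)


class TestGelmanRubin:
    def test_identical_chains_report_one(self):
        chain = np.linspace(0, 1, 50)
        assert gelman_rubin(np.stack([chain, chain])) == 1.0

    def test_diverged_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert gelman_rubin(chains) > 1.1

    def test_toy_arrays_match_hand_formula(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        n = 3
        W = (np.var([1, 2, 3], ddof=1) + np.var([2, 3, 4], ddof=1)) / 2
        B_over_n = np.var([2.0, 3.0], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(np.ones((1, 100)))
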