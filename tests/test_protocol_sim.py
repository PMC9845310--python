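"""Protocol construction and the Metropolis-Hastings learner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_1samp

from fluctlearn import (
    ConfigError,
    EnergyModel,
    InvalidStateError,
    LearnerConfig,
    build_protocol,
    equilibrium_cdf,
    equilibrium_pdf,
    extract_work_samples,
    metropolis_acceptance,
    mh_step,
    simulate_run,
)
from fluctlearn.simulate import _run_chain


class TestProtocol:
    def test_default_structure(self):
        p = build_protocol()
        assert p.cycle_length == 66
        assert p.n_cycles == 20
        assert p.baseline_length == 100
        assert p.forward_range == (1, 25)
        assert p.backward_range == (34, 58)
        assert p.n_trials == 100 + 20 * 66

    def test_backward_is_reversed_forward(self):
        p = build_protocol(theta_peak=42.0, forward_length=13, plateau_length=3)
        a = np.asarray(p.cycle_angles)
        fwd = a[p.forward_range[0] - 1 : p.forward_range[1]]
        bwd = a[p.backward_range[0] - 1 : p.backward_range[1]]
        assert np.array_equal(bwd, fwd[::-1])

    def test_washouts_and_baseline_are_unperturbed(self):
        p = build_protocol()
        thetas = p.thetas
        assert np.all(thetas[:100] == 0.0)
        assert np.all(thetas[p.plateau_mask()] == 0.0)

    def test_flat_protocol_yields_zero_work(self):
        p = build_protocol(theta_peak=0.0, n_cycles=3, baseline_length=10)
        m = EnergyModel()
        traj = simulate_run(m, p, LearnerConfig(), seed=0)
        w = extract_work_samples(m, p, traj)
        assert np.all(w.forward == 0.0) and np.all(w.backward == 0.0)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            build_protocol(theta_peak=-5.0)
        with pytest.raises(ConfigError):
            build_protocol(forward_length=3)

    @settings(max_examples=30, deadline=None)
    @given(
        peak=st.floats(0.0, 90.0),
        length=st.integers(4, 40),
        plateau=st.integers(0, 12),
        cycles=st.integers(1, 5),
    )
    def test_reversal_invariant_over_random_configs(self, peak, length, plateau, cycles):
        p = build_protocol(
            theta_peak=peak,
            forward_length=length,
            plateau_length=plateau,
            n_cycles=cycles,
            baseline_length=0,
        )
        a = np.asarray(p.cycle_angles)
        assert p.cycle_length == 2 * (length + plateau)
        fwd = a[p.forward_range[0] - 1 : p.forward_range[1]]
        bwd = a[p.backward_range[0] - 1 : p.backward_range[1]]
        assert np.array_equal(bwd, fwd[::-1])


class TestMHStep:
    def setup_method(self):
        self.m = EnergyModel()
        self.cfg = LearnerConfig()
        self.rng = np.random.default_rng(0)

    def test_identity_proposal_returns_state(self):
        assert mh_step(self.m, 0.0, 5.0, self.cfg, self.rng, proposal=5.0) == 5.0

    def test_downhill_proposal_always_accepted(self):
        # proposal at the target has strictly lower energy than x = 20
        for _ in range(50):
            assert mh_step(self.m, 0.0, 20.0, self.cfg, self.rng, proposal=0.0) == 0.0

    def test_out_of_support_proposal_stays(self):
        assert mh_step(self.m, 0.0, 80.0, self.cfg, self.rng, proposal=95.0) == 80.0

    def test_state_outside_support_raises(self):
        with pytest.raises(InvalidStateError):
            mh_step(self.m, 0.0, 120.0, self.cfg, self.rng)

    def test_uphill_acceptance_probability_is_boltzmann(self):
        a = metropolis_acceptance(self.m, 0.0, 0.0, 90.0)
        assert a == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_discretized_chain_satisfies_detailed_balance(self):
        states = np.linspace(-50.0, 50.0, 21)
        n = states.size
        weights = equilibrium_pdf(self.m, 0.0, states)
        p = weights / weights.sum()
        T = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    T[i, j] = (1.0 / n) * metropolis_acceptance(
                        self.m, 0.0, states[i], states[j]
                    )
            T[i, i] = 1.0 - T[i].sum()
        flux = p[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-10


class TestChain:
    def test_long_stationary_chain_matches_equilibrium(self):
        m = EnergyModel()
        cfg = LearnerConfig(steps_per_trial=1)
        rng = np.random.default_rng(3)
        xs = _run_chain(m, np.zeros(200_000), 0.0, cfg, rng)
        assert ks_1samp(xs[1000:], equilibrium_cdf(m, 0.0)).statistic < 0.01

    def test_same_seed_reproduces_trajectory(self):
        m = EnergyModel()
        p = build_protocol(n_cycles=2)
        a = simulate_run(m, p, LearnerConfig(), seed=5)
        b = simulate_run(m, p, LearnerConfig(), seed=5)
        assert np.array_equal(a.responses, b.responses)

    def test_stationary_run_centers_on_bias(self):
        m = EnergyModel(bias=4.0, support=(-86.0, 94.0))
        p = build_protocol(theta_peak=0.0, n_cycles=30, baseline_length=0)
        # many transitions per trial so the chain decorrelates quickly
        traj = simulate_run(m, p, LearnerConfig(steps_per_trial=20), seed=2)
        # near-uniform equilibrium on [b-90, b+90]: mean approaches the bias
        assert abs(traj.responses.mean() - 4.0) < 8.0

    def test_washout_plateaus_reach_equilibrium(self, default_model, default_protocol):
        mask = default_protocol.plateau_mask()
        pool = []
        for child in np.random.SeedSequence(9).spawn(35):
            traj = simulate_run(
                default_model, default_protocol, LearnerConfig(), seed=np.random.default_rng(child)
            )
            pool.append(traj.responses[mask])
        pooled = np.concatenate(pool)
        assert pooled.size >= 10_000
        stat = ks_1samp(pooled, equilibrium_cdf(default_model, 0.0)).statistic
        assert stat < 0.05
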