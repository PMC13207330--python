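"""Hopfield attractors against brute-force enumeration, BCM sign structure,
homeostatic scaling, STDP kernel, and the rate-network twin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop.plasticity import (
    BCMState,
    HopfieldNet,
    STDPKernel,
    ScalingState,
    TwinConfig,
    basin_of,
    bcm_dw,
    bcm_threshold_update,
    enumerate_fixed_points,
    hebbian_store,
    hopfield_energy,
    hopfield_energy_pairwise,
    hopfield_relax,
    hopfield_step,
    reinforce_weights,
    scaling_dG,
    stdp_dw,
    synthetic_connectome,
    twin_simulate,
)


def random_net(rng, n):
    a = rng.normal(size=(n, n))
    w = (a + a.T) / 2.0
    np.fill_diagonal(w, 0.0)
    s = rng.choice([-1, 1], size=n)
    th = 0.1 * rng.normal(size=n)
    return HopfieldNet(w, s, th)


class TestHopfieldEnergy:
    def test_zero_everything(self):
        net = HopfieldNet(np.zeros((3, 3)), np.ones(3, dtype=int), np.zeros(3))
        assert hopfield_energy(net) == 0.0

    def test_two_unit_hand_enumeration(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = HopfieldNet(w, np.array([1, 1]), np.zeros(2))
        # -1/2 (w12 + w21) = -1
        assert hopfield_energy(net) == pytest.approx(-1.0)

    def test_global_flip_symmetry_without_thresholds(self):
        rng = np.random.default_rng(0)
        net = random_net(rng, 6)
        net = HopfieldNet(net.weights, net.states, np.zeros(6))
        flipped = HopfieldNet(net.weights, -net.states, np.zeros(6))
        assert hopfield_energy(net) == pytest.approx(hopfield_energy(flipped))

    def test_conventions_agree_at_zero_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_net(rng, 5)
            net = HopfieldNet(net.weights, net.states, np.zeros(5))
            assert hopfield_energy(net) == pytest.approx(
                hopfield_energy_pairwise(net))

    def test_asymmetric_weights_rejected(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            HopfieldNet(w, np.array([1, 1]), np.zeros(2))


class TestHopfieldDynamics:
    def test_stored_pattern_is_fixed_point(self):
        p = np.array([1, -1, 1, -1, 1])
        net = HopfieldNet(hebbian_store([p]), p, np.zeros(5))
        _, changed = hopfield_step(net)
        assert not changed

    def test_hamming_one_converges_to_stored(self):
        p = np.array([1, 1, -1, 1, -1])
        start = p.copy()
        start[0] = -1
        net = hopfield_relax(HopfieldNet(hebbian_store([p]), start, np.zeros(5)))
        assert np.array_equal(net.states, p)

    def test_energy_never_increases(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            net = random_net(rng, 7)
            for _ in range(30):
                before = hopfield_energy(net)
                net, changed = hopfield_step(net)
                assert hopfield_energy(net) <= before + 1e-12
                if not changed:
                    break

    def test_random_update_orders_still_terminate(self):
        rng = np.random.default_rng(3)
        net = random_net(rng, 8)
        end = hopfield_relax(net, update_order=5)
        fixed = enumerate_fixed_points(net)
        assert tuple(int(v) for v in end.states) in fixed


class TestHebbianStore:
    def test_single_all_ones_pattern(self):
        w = hebbian_store([np.ones(4)])
        off = w[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.25)
        assert np.allclose(np.diag(w), 0.0)

    def test_pattern_and_negation_store_identically(self):
        p = np.array([1, -1, 1, -1])
        assert np.allclose(hebbian_store([p]), hebbian_store([-p]))

    def test_orthogonal_patterns_are_energy_minima(self):
        """Brute-force energy over all 16 states: each stored pattern (and
        its negation) attains the global minimum."""
        p1 = np.array([1, 1, -1, -1])
        p2 = np.array([1, -1, 1, -1])
        w = hebbian_store([p1, p2])
        energies = {}
        for bits in range(16):
            s = np.array([1 if bits >> i & 1 else -1 for i in range(4)])
            energies[tuple(s)] = hopfield_energy(
                HopfieldNet(w, s, np.zeros(4)))
        emin = min(energies.values())
        assert energies[tuple(p1)] == pytest.approx(emin)
        assert energies[tuple(p2)] == pytest.approx(emin)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            hebbian_store([[1, -1], [1, -1, 1]])


class TestReinforceWeights:
    def test_zero_rate_no_change(self):
        rng = np.random.default_rng(4)
        net = random_net(rng, 5)
        out = reinforce_weights(net, np.ones(5), rate=0.0)
        assert np.array_equal(out.weights, net.weights)

    def test_reinforcement_lowers_target_energy(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, 6)
        target = rng.choice([-1, 1], size=6)
        before = hopfield_energy(HopfieldNet(net.weights, target, net.thresholds))
        out = reinforce_weights(net, target, rate=0.1)
        after = hopfield_energy(HopfieldNet(out.weights, target, out.thresholds))
        assert after < before

    def test_basin_deepening_is_monotone(self):
        """Brute-force basin fraction never shrinks under reinforcement."""
        p = np.array([1, -1, 1, 1, -1, 1])
        net = HopfieldNet(hebbian_store([p]), p, np.zeros(6))
        fractions = [basin_of(net, p)]
        for _ in range(3):
            net = reinforce_weights(net, p, rate=0.2)
            fractions.append(basin_of(net, p))
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestBCM:
    def test_zero_at_threshold(self):
        s = BCMState(postsynaptic_activity=1.0, sliding_threshold=1.0)
        assert bcm_dw(s) == 0.0

    @pytest.mark.parametrize("y, theta, sign", [
        (2.0, 1.0, 1),    # LTP above threshold
        (0.5, 1.0, -1),   # LTD below
        (1.5, 2.0, -1),
        (3.0, 0.5, 1),
    ])
    def test_sign_structure(self, y, theta, sign):
        s = BCMState(postsynaptic_activity=y, sliding_threshold=theta,
                     presynaptic_input=1.0)
        assert np.sign(bcm_dw(s)) == sign

    def test_no_presynaptic_drive_no_change(self):
        s = BCMState(postsynaptic_activity=5.0, sliding_threshold=1.0,
                     presynaptic_input=0.0)
        assert bcm_dw(s) == 0.0

    def test_sliding_threshold_fixed_point(self):
        s = BCMState(y0=1.0)
        assert bcm_threshold_update(s, [1.0] * 20) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self):
        s = BCMState(y0=1.0)
        base = bcm_threshold_update(s, [0.5, 1.0, 1.5])
        doubled = bcm_threshold_update(s, [1.0, 2.0, 3.0])
        assert doubled == pytest.approx(4.0 * base)

    def test_sliding_threshold_stabilizes_runaway_activity(self):
        """Closed loop: activity grows with weight, the sliding threshold
        chases it quadratically, and dw/dt settles to ~0 (scalar fixed-point
        oracle: equilibrium at y = y0)."""
        y0 = 1.0
        w = 1.2
        x = 1.0
        theta = 0.8
        history = []
        for _ in range(4000):
            y = w * x
            history.append(y)
            theta = bcm_threshold_update(BCMState(y0=y0),
                                         history[-20:])
            dw = bcm_dw(BCMState(weight=w, presynaptic_input=x,
                                 postsynaptic_activity=y,
                                 sliding_threshold=theta))
            w += 0.01 * dw
        assert y == pytest.approx(y0, abs=1e-2)
        assert abs(dw) < 1e-3


class TestScaling:
    def test_at_target_no_drive(self):
        assert scaling_dG(ScalingState(firing_rate=5.0, target_rate=5.0)) == 0.0

    def test_underactivity_upscales(self):
        assert scaling_dG(ScalingState(firing_rate=2.0, target_rate=5.0)) > 0

    def test_hand_arithmetic(self):
        s = ScalingState(rate_constant=2.0, target_rate=5.0, firing_rate=3.0)
        assert scaling_dG(s) == pytest.approx(4.0)

    def test_closed_loop_drives_rate_to_target(self):
        """R = G * drive with G following the scaling equation converges to
        R_target."""
        g, drive, dt = 1.0, 2.0, 0.05
        target = 5.0
        for _ in range(2000):
            r = g * drive
            g += dt * scaling_dG(ScalingState(global_factor=g, firing_rate=r,
                                              target_rate=target,
                                              rate_constant=0.5))
        assert g * drive == pytest.approx(target, abs=1e-3)


class TestSTDP:
    kernel = STDPKernel(potentiation_amp=1.0, depression_amp=1.0,
                        time_constant=20.0, cutoff_window=40.0)

    def test_empty_trains(self):
        assert stdp_dw([], [0.0], self.kernel) == 0.0
        assert stdp_dw([0.0], [], self.kernel) == 0.0

    def test_pair_outside_window_fails_to_reinforce(self):
        assert stdp_dw([0.0], [50.0], self.kernel) == 0.0
        assert stdp_dw([50.0], [0.0], self.kernel) == 0.0

    def test_kernel_value_at_ten_ms(self):
        assert stdp_dw([0.0], [10.0], self.kernel) == pytest.approx(
            np.exp(-0.5))

    def test_reversed_order_depresses(self):
        assert stdp_dw([10.0], [0.0], self.kernel) == pytest.approx(
            -np.exp(-0.5))

    def test_simultaneous_spikes_contribute_nothing(self):
        assert stdp_dw([5.0], [5.0], self.kernel) == 0.0

    def test_unsorted_trains_rejected(self):
        with pytest.raises(ValueError):
            stdp_dw([5.0, 1.0], [0.0], self.kernel)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 100), min_size=0, max_size=6),
           st.lists(st.floats(200, 300), min_size=0, max_size=6),
           st.lists(st.floats(0, 300), min_size=1, max_size=6))
    def test_additive_over_disjoint_pre_trains(self, pre_a, pre_b, post):
        pre_a, pre_b, post = sorted(pre_a), sorted(pre_b), sorted(post)
        whole = stdp_dw(pre_a + pre_b, post, self.kernel)
        parts = (stdp_dw(pre_a, post, self.kernel)
                 + stdp_dw(pre_b, post, self.kernel))
        assert whole == pytest.approx(parts)


class TestTwin:
    def test_uncoupled_network_decays_to_baseline(self):
        cfg = TwinConfig(n_regions=20, coupling_strength=0.0, noise_sd=0.0,
                         duration_ms=500.0, seed=1)
        traj, report = twin_simulate(cfg)
        # fixed point of r = S(0) with the logistic centered at 1/2
        expected = 1.0 / (1.0 + np.exp(0.5 / 0.3))
        assert np.allclose(report.final_rates, expected, atol=1e-3)
        assert report.settled and not report.diverged

    def test_deterministic_under_seed(self):
        cfg = TwinConfig(n_regions=20, duration_ms=300.0, seed=9)
        t1, _ = twin_simulate(cfg)
        t2, _ = twin_simulate(cfg)
        assert np.array_equal(t1, t2)

    def test_default_operating_point_settles(self):
        """76 regions, G = 0.015, d = 0.3, 2000 ms: the twin reaches a
        stable attractor (configuration smoke test)."""
        traj, report = twin_simulate(TwinConfig())
        assert report.settled
        assert not report.diverged

    def test_serialization_round_trips(self, tmp_path):
        import json

        import pandas as pd

        from neuroloop.plasticity import (write_connectome_csv,
                                          write_trajectories_csv,
                                          write_twin_report)

        cfg = TwinConfig(n_regions=12, duration_ms=200.0, seed=4)
        traj, report = twin_simulate(cfg)
        c = cfg.resolved_connectome()
        write_connectome_csv(c, tmp_path / "c.csv")
        back = pd.read_csv(tmp_path / "c.csv", index_col="region")
        assert np.allclose(back.values, c)
        write_trajectories_csv(traj, tmp_path / "traj.csv")
        t_back = pd.read_csv(tmp_path / "traj.csv")
        assert len(t_back) == traj.shape[0]
        write_twin_report(report, tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["settled"] == report.settled

    def test_connectome_validation(self):
        c = synthetic_connectome(10, seed=0)
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 0.0)
        assert np.all(c >= 0)
        bad = c.copy()
        bad[0, 0] = 1.0
        with pytest.raises(ValueError):
            TwinConfig(n_regions=10, connectome=bad).resolved_connectome()
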