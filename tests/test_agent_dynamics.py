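"""Prediction-error flows, stepping, trajectories."""

import numpy as np
import pytest

from packetsim.agent_dynamics import (
    IntegrationError,
    belief_rate,
    emitter_update,
    free_energy_proxy,
    motion_rates,
    particle_rates,
    prediction_errors,
    run,
    step,
)
from packetsim.config import SimulationConfig
from packetsim.core_model import GenerativeModelParams, softmax_beliefs
from packetsim.field_signaling import SensorySample, sense
from packetsim.stimulus import preset_experiment

from conftest import make_ensemble, random_ensemble


def near_vertex_mu(i, j, c=40.0):
    """Log evidence concentrating belief 50/50 on identities i and j."""
    mu = np.full(4, -c)
    mu[i] = 0.0
    mu[j] = 0.0
    return mu


@pytest.fixture
def balanced_pair(raw_params):
    """Two particles whose expectations exactly match what they sense.

    Beliefs split between internal_A and internal_B give expected flow
    1.5 in every channel (for D=1); at separation 1.5 the sensed
    magnitudes match, so every prediction error vanishes.  Log evidence
    is stored in its saturated canonical form so it is a true fixed
    point of the update.
    """
    from packetsim.core_model import saturate_evidence

    mu = np.stack([near_vertex_mu(0, 3), near_vertex_mu(0, 3)])
    mu = saturate_evidence(mu, raw_params.mu_max)
    return make_ensemble([[0.0, 0.0], [1.5, 0.0]], mu=mu, params=raw_params)


class TestPredictionErrors:
    def test_zero_when_sample_matches_expectation(self):
        psi = np.full(4, 0.25)
        sample = SensorySample(s_psi=psi.copy(), s_R=np.ones(4))
        eps_psi, eps_R = prediction_errors(sample, psi, np.ones(4))
        assert np.allclose(eps_psi, 0) and np.allclose(eps_R, 0)

    def test_unit_offset_passes_through(self):
        psi = np.full(4, 0.25)
        sample = SensorySample(s_psi=psi.copy(), s_R=np.array([2.0, 1, 1, 1]))
        _, eps_R = prediction_errors(sample, psi, np.ones(4))
        assert np.allclose(eps_R, [1, 0, 0, 0])

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        psi = softmax_beliefs(rng.normal(size=4))
        s = SensorySample(s_psi=rng.normal(size=4), s_R=rng.normal(size=4))
        e1 = prediction_errors(s, psi, np.ones(4))
        swapped = SensorySample(s_psi=2 * psi - s.s_psi, s_R=2 * np.ones(4) - s.s_R)
        e2 = prediction_errors(swapped, psi, np.ones(4))
        assert np.allclose(e1[0], -e2[0]) and np.allclose(e1[1], -e2[1])


class TestBeliefRate:
    def test_fixed_point_at_zero_evidence(self, raw_params):
        mu = np.zeros(4)
        out = belief_rate((np.zeros(4), np.zeros(4)), mu, raw_params)
        assert np.allclose(out, 0.0)

    def test_uniform_belief_hand_value(self):
        p = GenerativeModelParams(D=1.0, prec_R=0.0, prec_psi=1.0, prec_mu=0.0)
        mu = np.zeros(4)
        out = belief_rate((np.array([1.0, -1.0, 0, 0]), np.zeros(4)), mu, p)
        assert np.allclose(out, [0.25, -0.25, 0, 0], atol=1e-12)

    def test_components_sum_to_decay_plus_drive(self):
        """The softmax Jacobian annihilates constants, so the total log
        evidence moves only with decay and stimulus drive."""
        rng = np.random.default_rng(1)
        p = GenerativeModelParams(D=1.2, prec_R=1.7, prec_psi=0.6, prec_mu=0.3)
        for _ in range(10):
            mu = rng.normal(size=4)
            errors = (rng.normal(size=4), rng.normal(size=4))
            drive = rng.normal(size=4)
            out = belief_rate(errors, mu, p, stim_drive=drive)
            assert out.sum() == pytest.approx(
                -p.prec_mu * mu.sum() + drive.sum(), abs=1e-10)

    def test_batched_matches_per_particle(self):
        rng = np.random.default_rng(2)
        p = GenerativeModelParams()
        mu = rng.normal(size=(5, 4))
        errors = (rng.normal(size=(5, 4)), rng.normal(size=(5, 4)))
        batch = belief_rate(errors, mu, p)
        for i in range(5):
            single = belief_rate((errors[0][i], errors[1][i]), mu[i], p)
            assert np.allclose(batch[i], single, atol=1e-12)


class TestEmitterUpdate:
    def test_noise_free_resets_to_belief(self, raw_params):
        psi = softmax_beliefs(np.array([1.0, 0, 0, -1.0]))
        assert np.allclose(emitter_update(psi, raw_params, None, 0.1), psi)

    def test_seeded_reproducibility(self):
        p = GenerativeModelParams(noise_free=False)
        psi = np.full(4, 0.25)
        a = emitter_update(psi, p, np.random.default_rng(5), 0.1)
        b = emitter_update(psi, p, np.random.default_rng(5), 0.1)
        assert np.array_equal(a, b)

    def test_monte_carlo_mean_is_belief(self):
        p = GenerativeModelParams(noise_free=False, prec_psi=1.0)
        psi = softmax_beliefs(np.array([0.5, 0, 0, 0]))
        rng = np.random.default_rng(6)
        n, dt = 10000, 0.1
        draws = np.array([emitter_update(psi, p, rng, dt) for _ in range(n)])
        sigma = float(np.asarray(p.prec_psi)) * dt
        assert np.abs(draws.mean(axis=0) - psi).max() < 3 * sigma / np.sqrt(n)

    def test_std_scaling_flag_changes_amplitude(self):
        psi = np.full(4, 0.25)
        dt = 0.1
        for prec, wider in ((4.0, False), (0.25, True)):
            p1 = GenerativeModelParams(noise_free=False, prec_psi=prec)
            p2 = GenerativeModelParams(noise_free=False, prec_psi=prec,
                                       emitter_noise_std=True)
            a1 = emitter_update(psi, p1, np.random.default_rng(7), dt) - psi
            a2 = emitter_update(psi, p2, np.random.default_rng(7), dt) - psi
            # precision scaling vs 1/sqrt(precision) scaling
            ratio = np.abs(a2 / a1).mean()
            assert (ratio > 1) == wider

    def test_rejects_nonpositive_dt(self, raw_params):
        with pytest.raises(ValueError):
            emitter_update(np.full(4, 0.25), raw_params, None, 0.0)


class TestMotionRates:
    def test_zero_errors_are_stationary(self, balanced_pair):
        errors = (np.zeros(4), np.zeros(4))
        x_dot, x_ddot = motion_rates(balanced_pair, 0, errors, np.zeros(4),
                                     balanced_pair.params)
        assert np.allclose(x_dot, 0) and np.allclose(x_ddot, 0)

    def test_velocity_descends_squared_flow_error(self, raw_params):
        """Positive error (source farther than expected) pulls the
        particle toward the source, reducing the error."""
        mu = np.stack([near_vertex_mu(0, 0), near_vertex_mu(2, 2)])
        ens = make_ensemble([[0.0, 0.0], [2.5, 0.0]], mu=mu, params=raw_params)
        sample = sense(ens, 0)
        rates = particle_rates(ens, 0, sample)
        assert np.any(rates.eps_R > 0.1)
        assert rates.x_dot[0] > 0  # toward the neighbour at +x
        # finite-difference check: the move reduces the weighted error
        def sq_err(x0):
            e2 = make_ensemble(np.array([x0, [2.5, 0.0]]), mu=mu, params=raw_params)
            s = sense(e2, 0)
            r = particle_rates(e2, 0, s)
            prec = e2.params.prec_R_vec
            return float((prec * r.eps_R**2).sum())
        step_len = 1e-4
        direction = rates.x_dot / np.linalg.norm(rates.x_dot)
        assert sq_err(direction * step_len) < sq_err(np.zeros(2))

    def test_zero_smoothness_kills_acceleration(self, raw_params):
        p = raw_params.copy(lambda_smooth=0.0)
        ens = random_ensemble(np.random.default_rng(3), params=p)
        sample = sense(ens, 0)
        rates = particle_rates(ens, 0, sample)
        assert np.allclose(rates.x_ddot, 0.0)


class TestStep:
    def test_zero_error_configuration_is_stationary(self, balanced_pair):
        after = step(balanced_pair, None, None, dt=0.1)
        assert np.allclose(after.x, balanced_pair.x, atol=1e-10)
        assert np.allclose(after.mu, balanced_pair.mu, atol=1e-10)
        assert after.t == balanced_pair.t + 1

    def test_same_seed_identical_successor(self):
        p = GenerativeModelParams(noise_free=False)
        ens = random_ensemble(np.random.default_rng(0), params=p)
        a = step(ens, None, np.random.default_rng(10), dt=0.1)
        b = step(ens, None, np.random.default_rng(10), dt=0.1)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.a_psi, b.a_psi)

    def test_permutation_equivariance(self, default_params):
        p = default_params.copy(noise_free=True)
        ens = random_ensemble(np.random.default_rng(4), n=10, params=p)
        perm = np.random.default_rng(5).permutation(10)
        permuted = make_ensemble(ens.x[perm], mu=ens.mu[perm],
                                 a_psi=ens.a_psi[perm], params=p)
        out = step(ens, None, None, dt=0.1)
        out_perm = step(permuted, None, None, dt=0.1)
        assert np.allclose(out.x[perm], out_perm.x, atol=1e-12)
        assert np.allclose(out.mu[perm], out_perm.mu, atol=1e-12)

    def test_simplex_preserved_after_step(self, default_params):
        ens = random_ensemble(np.random.default_rng(6), params=default_params)
        out = step(ens, None, np.random.default_rng(0), dt=0.1)
        assert np.allclose(out.psi.sum(axis=1), 1.0, atol=1e-12)

    def test_blowup_names_particle_and_step(self, raw_params):
        p = raw_params.copy(prec_psi=1e200)
        a = np.full((2, 4), 0.25)
        a[1] = 1e200  # emitter overflow makes the evidence rate non-finite
        ens = make_ensemble([[0.0, 0.0], [1.0, 0.0]], a_psi=a, params=p, t=7)
        with np.errstate(all="ignore"):
            with pytest.raises(IntegrationError, match=r"particle \d+ at step 8"):
                step(ens, None, None, dt=0.1)


class TestRun:
    def test_stride_equal_steps_gives_two_snapshots(self):
        cfg = SimulationConfig(N=8, steps=20, output={"stride": 20})
        traj = run(cfg)
        assert len(traj) == 2
        assert traj.times.tolist() == [0, 20]

    def test_zero_gain_stimulus_leaves_beliefs_near_uniform(self):
        cfg = preset_experiment(1, N=16, seed=0)
        cfg.steps = 100
        cfg.model = cfg.model.copy(stim_gain=0.0)
        traj = run(cfg)
        final = traj.snapshots[-1]
        # decay plus zero drive: evidence stays within the noise scale
        assert np.abs(final.mu).max() < 3.0
        assert np.abs(final.psi - 0.25).max() < 0.5

    def test_identical_config_and_seed_identical_trajectory(self):
        cfg = SimulationConfig(N=12, steps=30, seed=77, output={"stride": 10})
        t1, t2 = run(cfg), run(cfg)
        for s1, s2 in zip(t1.snapshots, t2.snapshots):
            assert np.array_equal(s1.x, s2.x)
            assert np.array_equal(s1.mu, s2.mu)

    def test_snapshot_count_and_times_strictly_increasing(self):
        cfg = SimulationConfig(N=8, steps=45, output={"stride": 10})
        traj = run(cfg)
        times = traj.times
        assert np.all(np.diff(times) > 0)
        assert len(traj) == int(np.ceil(45 / 10)) + 1

    def test_simplex_conserved_over_full_run(self):
        cfg = preset_experiment(1, N=16, seed=3)
        cfg.steps = 120
        traj = run(cfg)
        for snap in traj.snapshots:
            assert np.allclose(snap.psi.sum(axis=1), 1.0, atol=1e-12)

    def test_trajectory_round_trips_through_csv(self, tmp_path):
        cfg = SimulationConfig(N=6, steps=10, seed=5, output={"stride": 5})
        traj = run(cfg)
        traj.save(tmp_path / "t")
        back = traj.load(tmp_path / "t")
        assert back.times.tolist() == traj.times.tolist()
        assert np.allclose(back.snapshots[-1].x, traj.snapshots[-1].x)
        assert back.config.to_dict() == traj.config.to_dict()


class TestFreeEnergyProxy:
    def test_nonnegative_and_zero_at_fixed_point(self, balanced_pair):
        assert free_energy_proxy(balanced_pair) == pytest.approx(0.0, abs=1e-12)
        ens = random_ensemble(np.random.default_rng(1))
        assert free_energy_proxy(ens) >= 0.0

    def test_decreases_during_packet_formation(self):
        cfg = preset_experiment(1, N=48, seed=1)
        traj = run(cfg)
        fes = [free_energy_proxy(s) for s in traj.snapshots]
        onset_window = np.mean(fes[1:4])  # just after stimulus onset
        final_window = np.mean(fes[-3:])
        assert final_window < onset_window
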