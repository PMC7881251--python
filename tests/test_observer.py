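"""Kalman ideal observer: oracle equivalence, posterior, log-odds."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from kinetree import (
    STRUCTURE_LABELS,
    Scene,
    evaluate_positions,
    evaluate_scene,
    kalman_loglik,
    log_odds,
    make_prototype,
    simulate_scenes,
    structure_posterior,
)
from kinetree.observer import (
    StructureLikelihoods,
    build_kalman_model,
    _run_filter,
)
from kinetree.simulate import SimulationSettings
from kinetree.structures import PERMUTATIONS, hypothesis_pairs


def joint_gaussian_loglik(positions: np.ndarray, model) -> float:
    """Brute-force oracle: unroll the linear-Gaussian model into the full
    covariance of the stacked observations x(1:T) given x(0) and evaluate
    one multivariate normal density.  Independent of the recursive filter.
    """
    T = positions.shape[0] - 1
    F, Q, P0 = model.transition, model.process_noise, model.initial_cov
    H = np.zeros((3, 6))
    H[:, :3] = np.eye(3)
    r = model.sigma_obs**2
    mu0 = np.zeros(6)
    mu0[:3] = positions[0]
    powers = [np.eye(6)]
    for _ in range(T):
        powers.append(F @ powers[-1])
    mean = np.concatenate([H @ powers[t] @ mu0 for t in range(1, T + 1)])
    cov = np.zeros((3 * T, 3 * T))
    for t in range(1, T + 1):
        for u in range(1, T + 1):
            c = powers[t] @ P0 @ powers[u].T
            for k in range(1, min(t, u) + 1):
                c += powers[t - k] @ Q @ powers[u - k].T
            cov[3 * (t - 1):3 * t, 3 * (u - 1):3 * u] = H @ c @ H.T
    cov += r * np.eye(3 * T)
    return float(multivariate_normal.logpdf(positions[1:].ravel(), mean, cov))


def unwrapped_toy_scene(rng, n_frames):
    """Angles near pi with small steps, far from the 0/2pi seam."""
    steps = 0.08 * rng.standard_normal((n_frames, 3))
    return np.pi + np.cumsum(steps, axis=0)


class TestOracleEquivalence:
    def test_recursive_equals_joint_gaussian(self, rng):
        """Recursive innovation-form likelihood == closed-form joint density."""
        for _ in range(30):
            label = rng.choice(STRUCTURE_LABELS)
            m = int(rng.integers(1, 4))
            sigma = float(rng.uniform(0.05, 1.5))
            n_frames = int(rng.integers(2, 11))
            pos = unwrapped_toy_scene(rng, n_frames)
            model = build_kalman_model(make_prototype(label), m, sigma)
            recursive = _run_filter(pos[None], model)[0]
            oracle = joint_gaussian_loglik(pos, model)
            assert recursive == pytest.approx(oracle, abs=1e-8)

    def test_batched_matches_single(self, rng):
        pos = np.stack([unwrapped_toy_scene(rng, 6) for _ in range(5)])
        model = build_kalman_model(make_prototype("H"), 2, 0.7)
        batched = _run_filter(pos, model)
        singles = [_run_filter(p[None], model)[0] for p in pos]
        assert np.allclose(batched, singles)


class TestKalmanLoglik:
    def test_single_frame_scene_gives_zero(self):
        sc = Scene(frame_times=np.array([0.0]), positions=np.array([[0.1, 2.0, 4.0]]))
        for label in STRUCTURE_LABELS:
            assert kalman_loglik(sc, make_prototype(label), 1, 1.1) == 0.0

    def test_nonfinite_positions_rejected(self):
        pos = np.full((5, 3), np.nan)
        sc = Scene(frame_times=np.arange(5) * 0.02, positions=pos)
        with pytest.raises(ValueError):
            kalman_loglik(sc, make_prototype("G"), 1, 1.1)

    def test_permutation_consistency(self, rng):
        """Permuting the dots of a scene == evaluating under the permuted
        hypothesis; I and G are invariant under all permutations."""
        settings = SimulationSettings(duration=0.6, sim_dt=0.002, frame_dt=0.02)
        pos, _ = simulate_scenes(make_prototype("C"), 1, settings, seed=21)
        pos = pos[0]
        sc = Scene(frame_times=np.arange(pos.shape[0]) * 0.02, positions=pos)
        for label in ("I", "G"):
            s = make_prototype(label)
            vals = [kalman_loglik(sc, s, m, 0.9) for m in (1, 2, 3)]
            assert np.allclose(vals, vals[0])
        # scene permuted by P: likelihood under C equals original under the
        # hypothesis whose mixing matrix is P^-1-composed
        s = make_prototype("C")
        perm = PERMUTATIONS[2]
        sc_perm = Scene(frame_times=sc.frame_times, positions=pos @ perm.T)
        # (P_m B) applied to permuted scene: solve which m' matches
        direct = sorted(kalman_loglik(sc, s, m, 0.9) for m in (1, 2, 3))
        permuted = sorted(kalman_loglik(sc_perm, s, m, 0.9) for m in (1, 2, 3))
        assert np.allclose(direct, permuted, atol=1e-6)

    def test_wrapping_leaves_likelihood_invariant(self, rng):
        """Shifting a scene by a constant angle (mod 2pi) crosses the seam
        but cannot change the likelihood of a rotation-symmetric model."""
        settings = SimulationSettings(duration=0.6, sim_dt=0.002, frame_dt=0.02)
        pos, _ = simulate_scenes(make_prototype("G"), 1, settings, seed=33)
        pos = pos[0]
        sc = Scene(frame_times=np.arange(pos.shape[0]) * 0.02, positions=pos)
        shifted = Scene(frame_times=sc.frame_times,
                        positions=(pos + 3.0) % (2 * np.pi))
        s = make_prototype("G")
        assert kalman_loglik(shifted, s, 1, 1.1) == pytest.approx(
            kalman_loglik(sc, s, 1, 1.1), abs=1e-6)

    def test_correct_model_wins_on_average(self):
        settings = SimulationSettings(duration=2.0, sim_dt=0.002, frame_dt=0.02)
        pos, _ = simulate_scenes(make_prototype("G"), 60, settings, seed=5)
        table = evaluate_positions(pos, ("I", "G"), sigma_obs=1.1,
                                   frame_dt=settings.frame_dt)
        ll_i = table.values[:, 0]
        ll_g = table.values[:, 1]
        assert np.mean(ll_g - ll_i) > 0


class TestStructurePosterior:
    def _liks(self, values):
        return StructureLikelihoods(hypothesis_pairs(STRUCTURE_LABELS),
                                    np.asarray(values, dtype=float))

    def test_equal_likelihoods_give_uniform_posterior(self):
        # the multiplicity penalty exactly offsets C/H's three permutations
        post = structure_posterior(self._liks(np.zeros(8)))
        assert np.allclose(post.to_numpy(), 0.25)

    def test_dominant_entry_concentrates_posterior(self):
        vals = np.zeros(8)
        vals[1] = 10.0  # the single G hypothesis
        post = structure_posterior(self._liks(vals))
        assert post["G"] > 0.99

    def test_shift_invariance(self, rng):
        vals = rng.normal(size=8)
        a = structure_posterior(self._liks(vals)).to_numpy()
        b = structure_posterior(self._liks(vals + 123.4)).to_numpy()
        assert np.allclose(a, b)

    def test_prior_logits_shift_posterior(self):
        post = structure_posterior(self._liks(np.zeros(8)),
                                   prior_logits=[np.log(0.7), np.log(0.1),
                                                 np.log(0.1), np.log(0.1)])
        assert post["I"] == pytest.approx(0.7)

    def test_incomplete_entries_rejected(self):
        liks = StructureLikelihoods(
            (("I", 1), ("G", 1), ("C", 1), ("H", 1), ("H", 2), ("H", 3)),
            np.zeros(6),
        )
        with pytest.raises(ValueError):
            structure_posterior(liks)


class TestLogOdds:
    def _liks(self, values):
        return StructureLikelihoods(hypothesis_pairs(STRUCTURE_LABELS),
                                    np.asarray(values, dtype=float))

    def test_uniform_posterior_log_odds(self):
        assert log_odds(self._liks(np.zeros(8)), "I") == pytest.approx(-np.log(3))

    def test_dominant_structure_log_odds(self):
        vals = np.zeros(8)
        vals[1] = 10.0
        assert log_odds(self._liks(vals), "G") > 4.6

    def test_two_way_tie(self):
        vals = np.full(8, -np.inf)
        vals[0] = 0.0  # I
        vals[1] = 0.0  # G
        liks = self._liks(np.where(np.isfinite(vals), vals, -1e9))
        assert log_odds(liks, "I") == pytest.approx(0.0, abs=1e-6)


class TestLikelihoodTableIO:
    def test_round_trip(self, tmp_path, rng):
        settings = SimulationSettings(duration=0.4, sim_dt=0.002, frame_dt=0.02)
        pos, _ = simulate_scenes(make_prototype("H"), 4, settings, seed=2)
        table = evaluate_positions(pos, STRUCTURE_LABELS, 1.1,
                                   frame_dt=settings.frame_dt)
        path = tmp_path / "liks.tsv"
        table.save(path)
        back = type(table).load(path)
        assert back.pairs == table.pairs
        assert np.allclose(back.values, table.values)
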