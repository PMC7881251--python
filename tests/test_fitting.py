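"""Fitting machinery: gradients, ML properties, CV, shuffle, transfer."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from kinetree import (
    ChoiceModelParams,
    SyntheticParticipantSpec,
    confusion_matrix,
    fit_participant,
    fit_shared,
    generate_4afc_session,
    loo_cv_predict,
    make_cohort,
    shuffle_control,
    simulate_responses,
    transfer_params,
)
from kinetree.fitting import _design, _nll_and_grad, predict_choice_probs
from kinetree.sessions import SessionDataset
from kinetree.structures import hypothesis_pairs


@pytest.fixture(scope="module")
def small_cohort_module(small_settings_module):
    from kinetree import make_cohort

    datasets, specs = make_cohort(n_participants=3, seed=99, n_unique=30,
                                  settings=small_settings_module)
    return datasets, specs


@pytest.fixture(scope="module")
def small_settings_module():
    from kinetree import SimulationSettings

    return SimulationSettings(duration=1.0, sim_dt=0.002, frame_dt=0.02, tau=1.5)


class TestGradient:
    def test_analytic_gradient_matches_numerical(self, rng):
        labels = ("I", "G", "C", "H")
        pairs = hypothesis_pairs(labels)
        core = rng.normal(scale=3.0, size=(40, 8))
        choice_idx = rng.integers(0, 4, size=40)
        label_idx, log_mult = _design(core, pairs, labels)
        free_idx = np.array([1, 2, 3])
        x = np.array([0.3, 0.5, -0.4, 0.2])
        nll, grad = _nll_and_grad(x, core, label_idx, log_mult, choice_idx,
                                  0.14, 4, free_idx)
        num = approx_fprime(
            x,
            lambda v: _nll_and_grad(v, core, label_idx, log_mult, choice_idx,
                                    0.14, 4, free_idx)[0],
            1e-6,
        )
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-4)


class TestFitParticipant:
    def test_duplicating_data_doubles_loglik(self, small_cohort_module):
        datasets, _ = small_cohort_module
        ds = datasets[0]
        doubled = SessionDataset(
            participant=ds.participant,
            task=ds.task,
            positions=ds.positions,
            scene_index=np.concatenate([ds.scene_index, ds.scene_index]),
            scene_labels=ds.scene_labels,
            scene_morphs=ds.scene_morphs,
            pair_ids=None,
            choices=np.concatenate([ds.choices, ds.choices]),
            frame_dt=ds.frame_dt,
            tau=ds.tau,
        )
        doubled._tables = ds._tables
        f1 = fit_participant(ds, (1.1, 0.14))
        f2 = fit_participant(doubled, (1.1, 0.14))
        assert f2.beta == pytest.approx(f1.beta, rel=1e-3)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-5)

    def test_random_responses_drive_beta_to_floor(self, small_cohort_module):
        datasets, _ = small_cohort_module
        ds = datasets[0]
        rng = np.random.default_rng(4)
        random_ds = ds.with_responses(rng.choice(list(ds.choice_labels),
                                                 size=ds.n_trials))
        fit = fit_participant(random_ds, (1.1, 0.14))
        assert fit.beta < 0.05

    def test_determinism(self, small_cohort_module):
        datasets, _ = small_cohort_module
        a = fit_participant(datasets[1], (1.1, 0.14))
        b = fit_participant(datasets[1], (1.1, 0.14))
        assert np.array_equal(a.x, b.x)

    def test_bias_free_is_nested(self, small_cohort_module):
        """The full model's in-sample loglik dominates the b=0 restriction."""
        datasets, _ = small_cohort_module
        for ds in datasets:
            full = fit_participant(ds, (1.1, 0.14), free_biases=True)
            restricted = fit_participant(ds, (1.1, 0.14), free_biases=False)
            assert full.loglik >= restricted.loglik - 1e-6


class TestFitShared:
    def test_recovers_on_coarse_grid(self, small_cohort_module):
        datasets, _ = small_cohort_module
        sf = fit_shared(datasets, scale_grid=[0.6, 1.1, 1.6],
                        pi_grid=[0.02, 0.14, 0.30])
        assert sf.scale == pytest.approx(1.1)
        assert sf.grid_loglik.shape == (3, 3)
        assert not sf.failures

    def test_boundary_lapse_recovery(self, small_settings_module):
        ds = generate_4afc_session(n_unique=40, seed=31,
                                   settings=small_settings_module)
        spec = SyntheticParticipantSpec(
            ChoiceModelParams(pi_lapse=0.0, beta=8.0), seed=31)
        ds = simulate_responses(ds, spec)
        sf = fit_shared([ds], scale_grid=[1.1], pi_grid=[0.02, 0.10, 0.20])
        assert sf.pi_lapse == pytest.approx(0.02)

    def test_empty_grid_rejected(self, small_cohort_module):
        datasets, _ = small_cohort_module
        with pytest.raises(ValueError):
            fit_shared(datasets, scale_grid=[], pi_grid=[0.1])


class TestTransfer:
    def test_bias_difference(self, small_cohort_module):
        datasets, _ = small_cohort_module
        fit = fit_participant(datasets[0], (1.1, 0.14))
        params = transfer_params(fit)
        assert params.biases["H"] == pytest.approx(
            fit.biases["H"] - fit.biases["C"])
        assert params.beta == pytest.approx(fit.beta)

    def test_equal_biases_transfer_to_zero(self):
        from kinetree.fitting import ParticipantFit

        fit = ParticipantFit(beta=1.5, biases={"G": 0.2, "C": 0.7, "H": 0.7},
                             loglik=-10.0, free_bias_labels=("G", "C", "H"),
                             x=np.zeros(4), success=True)
        assert transfer_params(fit).biases["H"] == pytest.approx(0.0)


class TestLooCv:
    def test_two_trials_two_folds(self, small_settings_module):
        ds = generate_4afc_session(n_unique=1, seed=5,
                                   settings=small_settings_module)
        spec = SyntheticParticipantSpec(ChoiceModelParams(beta=1.0), seed=5)
        ds = simulate_responses(ds, spec)
        cv = loo_cv_predict(ds, (1.1, 0.14))
        assert cv.probs.shape == (2, 4)

    def test_heldout_not_better_than_insample(self, small_cohort_module):
        datasets, _ = small_cohort_module
        diffs = []
        for ds in datasets:
            cv = loo_cv_predict(ds, (1.1, 0.14))
            diffs.append(cv.heldout_loglik - cv.insample_loglik)
        assert np.mean(diffs) <= 0

    def test_single_trial_rejected(self, small_cohort_module):
        datasets, _ = small_cohort_module
        ds = datasets[0]
        tiny = SessionDataset(
            participant="t", task="4afc", positions=ds.positions,
            scene_index=np.array([0]), scene_labels=ds.scene_labels,
            scene_morphs=ds.scene_morphs, choices=np.array(["I"], dtype=object),
            frame_dt=ds.frame_dt, tau=ds.tau)
        with pytest.raises(ValueError):
            loo_cv_predict(tiny, (1.1, 0.14))


class TestShuffleControl:
    def test_confusion_matrix_preserved_exactly(self, small_cohort_module):
        datasets, _ = small_cohort_module
        ds = datasets[0]
        shuffled = shuffle_control(ds, seed=3)
        assert confusion_matrix(ds).equals(confusion_matrix(shuffled))
        assert not np.array_equal(ds.choices, shuffled.choices)  # really moved

    def test_seeded_reproducibility(self, small_cohort_module):
        datasets, _ = small_cohort_module
        a = shuffle_control(datasets[0], seed=7)
        b = shuffle_control(datasets[0], seed=7)
        assert np.array_equal(a.choices, b.choices)

    def test_singleton_stratum_unchanged(self, small_settings_module):
        ds = generate_4afc_session(n_unique=2, seed=17,
                                   settings=small_settings_module)
        spec = SyntheticParticipantSpec(ChoiceModelParams(), seed=17)
        ds = simulate_responses(ds, spec)
        labels = ds.trial_labels
        shuffled = shuffle_control(ds, seed=0)
        for lab in set(labels):
            idx = np.flatnonzero(labels == lab)
            assert sorted(ds.choices[idx]) == sorted(shuffled.choices[idx])

    def test_requires_responses(self, small_settings_module):
        ds = generate_4afc_session(n_unique=2, seed=18,
                                   settings=small_settings_module)
        with pytest.raises(ValueError):
            shuffle_control(ds, seed=0)


class TestPredictions:
    def test_predicted_probs_normalized(self, small_cohort_module):
        datasets, _ = small_cohort_module
        fit = fit_participant(datasets[2], (1.1, 0.14))
        probs = predict_choice_probs(datasets[2], fit, (1.1, 0.14))
        assert probs.shape == (datasets[2].n_trials, 4)
        assert np.allclose(probs.sum(axis=1), 1.0)
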