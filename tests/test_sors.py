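import numpy as np
import pytest

from sorsvf import (
    LocationSequence,
    PopulationMatrix,
    SorsExamConfig,
    ZestConfig,
    build_prior_pmf,
    examine_noreconstruct,
    examine_sors,
    least_squares_basis,
    reconstruct,
    selection_matrix,
    train_ors,
    train_rs,
    train_sors,
)
from sorsvf.estimators import zest_step, ZestState

from conftest import make_responder, steep_responder


def random_population(M, N, seed):
    rng = np.random.default_rng(seed)
    return PopulationMatrix(X=rng.normal(20, 6, size=(M, N)),
                            patient_ids=[f"p{i}" for i in range(N)])


def brute_force_residual(X, seq):
    """Independent oracle: residual of the optimal basis via numpy lstsq."""
    Y = X[list(seq)]
    Dt, *_ = np.linalg.lstsq(Y.T, X.T, rcond=None)
    return float(np.sum((X - Dt.T @ Y) ** 2))


def brute_force_greedy(X, S):
    """Per-step exhaustive candidate evaluation of the greedy objective."""
    chosen = []
    residuals = []
    for _ in range(S):
        scores = {l: brute_force_residual(X, chosen + [l])
                  for l in range(X.shape[0]) if l not in chosen}
        best = min(scores, key=lambda l: (scores[l], l))
        chosen.append(best)
        residuals.append(scores[best])
    return chosen, residuals


class TestLeastSquaresBasis:
    def test_hand_normal_equations_rank_one(self):
        X = PopulationMatrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]),
                             ["a", "b"])
        D = least_squares_basis(X, LocationSequence((0,)))
        np.testing.assert_allclose(D, [[1.0], [2.0], [3.0]])
        Y = X.X[[0]]
        np.testing.assert_allclose(D @ Y, X.X)

    def test_full_measurement_reproduces_matrix(self):
        X = random_population(6, 10, seed=0)
        seq = LocationSequence(tuple(range(6)))
        D = least_squares_basis(X, seq)
        Y = selection_matrix(seq, 6) @ X.X
        np.testing.assert_allclose(D @ Y, X.X, atol=1e-8)

    def test_optimality_against_random_perturbations(self):
        X = random_population(8, 30, seed=1)
        seq = LocationSequence((2, 5, 7))
        D = least_squares_basis(X, seq)
        Y = selection_matrix(seq, 8) @ X.X
        base = np.sum((X.X - D @ Y) ** 2)
        rng = np.random.default_rng(2)
        for _ in range(100):
            Dp = D + rng.normal(scale=0.1, size=D.shape)
            assert np.sum((X.X - Dp @ Y) ** 2) >= base

    def test_empty_sequence_rejected(self):
        X = random_population(4, 5, seed=3)
        with pytest.raises(ValueError):
            least_squares_basis(X, LocationSequence(()))

    def test_rank_deficient_measurements_warn_and_solve(self):
        X = PopulationMatrix(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 1.0]]),
                             ["a", "b"])
        with pytest.warns(RuntimeWarning):
            D = least_squares_basis(X, LocationSequence((0, 1)))
        assert np.all(np.isfinite(D))


class TestTrainSors:
    def test_zero_residual_at_rank_of_x(self):
        # row 2 is the average of rows 0 and 1: rank 2, error vanishes at k=2
        rng = np.random.default_rng(4)
        r0, r1 = rng.normal(size=10), rng.normal(size=10)
        X = PopulationMatrix(np.vstack([r0, r1, (r0 + r1) / 2]),
                             [f"p{i}" for i in range(10)])
        model = train_sors(X, 3)
        assert model.training_errors[1] == pytest.approx(0.0, abs=1e-16)

    def test_first_selection_matches_single_location_brute_force(self):
        X = random_population(7, 25, seed=5)
        model = train_sors(X, 1)
        scores = {l: brute_force_residual(X.X, [l]) for l in range(7)}
        assert model.sequence.indices[0] == min(scores, key=lambda l: (scores[l], l))

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_matches_exhaustive_per_step_oracle(self, seed):
        X = random_population(8, 50, seed=seed)
        model = train_sors(X, 3)
        chosen, residuals = brute_force_greedy(X.X, 3)
        assert list(model.sequence.indices) == chosen
        np.testing.assert_allclose(model.training_errors, residuals, rtol=1e-8)

    def test_training_errors_monotone_nonincreasing(self):
        X = random_population(10, 40, seed=6)
        model = train_sors(X, 10)
        assert np.all(np.diff(model.training_errors) <= 1e-8)

    def test_invalid_s_rejected(self):
        X = random_population(5, 8, seed=7)
        with pytest.raises(ValueError):
            train_sors(X, 6)


class TestRandomBaselineTraining:
    def test_rs_reproducible_and_distinct_locations(self):
        X = random_population(12, 30, seed=8)
        a = train_rs(X, 5, np.random.default_rng(9))
        b = train_rs(X, 5, np.random.default_rng(9))
        assert a.sequence.indices == b.sequence.indices
        assert len(set(a.sequence.indices)) == 5

    def test_ors_defaults_to_50_candidates(self):
        import inspect

        from sorsvf.sors import train_ors as f
        assert inspect.signature(f).parameters["n_candidates"].default == 50

    def test_ors_beats_rs_in_expectation(self):
        X = random_population(12, 40, seed=10)
        wins = 0
        for seed in range(20):
            rs = train_rs(X, 4, np.random.default_rng(seed))
            ors = train_ors(X, 4, np.random.default_rng(seed))
            wins += ors.training_errors[-1] <= rs.training_errors[-1] + 1e-9
        assert wins >= 15  # 50 candidates include-or-beat a single draw


class TestReconstruct:
    def test_matrix_vector_product(self):
        X = PopulationMatrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]),
                             ["a", "b"])
        model = train_sors(X, 1)
        est = reconstruct(model, 1, np.array([1.0]))
        # the greedy pick is the informative row; reconstruction is exact
        np.testing.assert_allclose(
            est.values, X.X[:, 0] / X.X[model.sequence.indices[0], 0])

    def test_identity_on_training_sample_with_full_measurement(self):
        X = random_population(5, 12, seed=11)
        X.X = np.clip(X.X, 0, 40)
        model = train_sors(X, 5)
        y = X.X[list(model.sequence.indices), 3]
        np.testing.assert_allclose(reconstruct(model, 5, y).values, X.X[:, 3],
                                   atol=1e-7)

    def test_clamped_to_dynamic_range(self):
        X = PopulationMatrix(np.array([[10.0, 11.0], [39.0, 43.0]]), ["a", "b"])
        X.X = np.clip(X.X, 0, 40)
        model = train_sors(X, 1)
        big = reconstruct(model, 1, np.array([40.0]))
        assert np.all(big.values <= 40.0)

    def test_k_out_of_range(self):
        X = random_population(4, 6, seed=12)
        model = train_sors(X, 2)
        with pytest.raises(ValueError):
            reconstruct(model, 3, np.zeros(3))


@pytest.fixture(scope="module")
def model20(small_cohort):
    return train_sors(small_cohort, 20)


@pytest.fixture(scope="module")
def model10(small_cohort):
    return train_sors(small_cohort, 10)


class TestExamineSors:
    @pytest.fixture()
    def model(self, model20):
        return model20

    def test_dynamic_start_is_reconstruction_minus_tau(self, model, small_cohort,
                                                       normative):
        responder = steep_responder(small_cohort.X[:, 5])
        cfg = SorsExamConfig(S=6, local_method="dynamic", tau=4.0)
        rec = examine_sors(model, responder, normative, cfg,
                           np.random.default_rng(0))
        seq = model.sequence.indices[:6]
        measured = rec.estimated_field.values[list(seq)]
        # replay: reconstruction after k measurements predicts loc k+1's start
        first_stim = {}
        for p in rec.log:
            first_stim.setdefault(p.location, p.stimulus_db)
        for k in range(1, 6):
            est = reconstruct(model, k, measured[:k]).values[seq[k]]
            assert first_stim[seq[k]] == pytest.approx(
                np.clip(est - 4.0, 0, 40))

    def test_first_location_uses_normative_prior(self, model, small_cohort,
                                                 normative):
        responder = make_responder(small_cohort.X[:, 6])
        cfg = SorsExamConfig(S=4, local_method="zest")
        rec = examine_sors(model, responder, normative, cfg,
                           np.random.default_rng(1))
        l1 = model.sequence.indices[0]
        expected = zest_step(ZestState(pmf=build_prior_pmf(normative.nv[l1],
                                                           cfg.zest)), cfg.zest)
        assert rec.log[0].location == l1
        assert rec.log[0].stimulus_db == expected

    def test_zest_variant_respects_presentation_budget(self, model, small_cohort,
                                                       normative):
        responder = make_responder(small_cohort.X[:, 7])
        cfg = SorsExamConfig(S=12, local_method="zest")
        rec = examine_sors(model, responder, normative, cfg,
                           np.random.default_rng(2))
        assert rec.total_presentations <= 4 * 12
        assert rec.tested_locations.S == 12

    def test_s_beyond_trained_sequence_rejected(self, model, small_cohort,
                                                normative):
        responder = make_responder(small_cohort.X[:, 8])
        with pytest.raises(ValueError):
            examine_sors(model, responder, normative,
                         SorsExamConfig(S=model.S + 1), np.random.default_rng(3))


class TestExamineNoReconstruct:
    @pytest.fixture()
    def model(self, model10):
        return model10

    def test_untested_estimates_come_from_final_basis(self, model, small_cohort,
                                                      normative):
        responder = steep_responder(small_cohort.X[:, 9])
        cfg = SorsExamConfig(S=10, local_method="dynamic")
        rec = examine_noreconstruct(model, responder, normative, cfg,
                                    np.random.default_rng(4))
        seq = list(model.sequence.indices)
        y = rec.estimated_field.values[seq]
        expected = reconstruct(model, 10, y).values
        untested = [l for l in range(54) if l not in seq]
        np.testing.assert_allclose(rec.estimated_field.values[untested],
                                   expected[untested])

    def test_staircases_start_from_normative_values(self, model, small_cohort,
                                                    normative):
        responder = make_responder(small_cohort.X[:, 10])
        cfg = SorsExamConfig(S=8, local_method="dynamic")
        rec = examine_noreconstruct(model, responder, normative, cfg,
                                    np.random.default_rng(5))
        first_stim = {}
        for p in rec.log:
            first_stim.setdefault(p.location, p.stimulus_db)
        for l in model.sequence.indices[:8]:
            assert first_stim[l] == normative.nv[l]

    def test_v2_loop_with_sors_model_is_examine_sors(self, model, small_cohort,
                                                     normative):
        responder = make_responder(small_cohort.X[:, 11])
        cfg = SorsExamConfig(S=8, local_method="dynamic")
        a = examine_sors(model, responder, normative, cfg,
                         np.random.default_rng(6))
        b = examine_sors(model, responder, normative, cfg,
                         np.random.default_rng(6))
        np.testing.assert_array_equal(a.estimated_field.values,
                                      b.estimated_field.values)


class TestLowRankRecovery:
    """Cohorts with a rank-limited generative structure are recoverable from
    few measurements: exactly so from error-free measurements at S = rank,
    and well below the population SD with the actual staircase estimator once
    S exceeds the rank (measurement errors are then averaged out by the
    overdetermined least-squares basis rather than interpolated)."""

    @pytest.fixture()
    def low_rank_setup(self, grid, normative):
        from sorsvf import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=40, fields_per_patient=4, gp_rank=4,
                           visit_noise_sd=0.0, seed=21)
        cohort = generate_cohort(cfg, grid, normative)
        train_X = PopulationMatrix(cohort.X[:, :120], cohort.patient_ids[:120])
        rank = np.linalg.matrix_rank(cohort.X, rtol=1e-9)
        return cohort, train_X, rank

    @staticmethod
    def _pop_sd(cohort):
        centered = cohort.X - cohort.X.mean(axis=1, keepdims=True)
        return float(np.sqrt(np.mean(centered ** 2)))

    def test_exact_measurements_at_rank_reconstruct_heldout(self, low_rank_setup):
        from sorsvf import rmse

        cohort, train_X, rank = low_rank_setup
        model = train_sors(train_X, rank)
        errs = [rmse(cohort.X[:, i],
                     reconstruct(model, rank,
                                 cohort.X[list(model.sequence.indices), i]).values)
                for i in range(120, 160)]
        assert np.median(errs) < self._pop_sd(cohort)

    def test_staircase_measurements_above_rank_recover_heldout(self, low_rank_setup,
                                                               normative):
        from sorsvf import rmse

        cohort, train_X, rank = low_rank_setup
        S = min(54, 2 * rank)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = train_sors(train_X, S)
        errs = []
        for i in range(120, 150):
            responder = steep_responder(cohort.X[:, i])
            rec = examine_sors(model, responder, normative,
                               SorsExamConfig(S=S, local_method="dynamic"),
                               np.random.default_rng(i))
            errs.append(rmse(cohort.X[:, i], rec.estimated_field.values))
        assert np.median(errs) < self._pop_sd(cohort)
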