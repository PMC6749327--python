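"""Objective evaluation, multiplicative updates, solver behaviour."""

import numpy as np
import pytest

from mdapred import Hyperparameters, fit, objective, predict_scores
from mdapred.model import (ModelState, candidate_ranking, gradients,
                           kkt_residuals, update_U, update_X, update_Y,
                           update_Z, _objective)

from conftest import random_instance, scalar_instance
from oracles import (objective_by_summation, update_U_by_substitution,
                     update_X_by_substitution, update_Y_by_substitution,
                     update_Z_by_substitution)


class TestObjective:
    def test_perfect_fit_no_penalties_is_zero(self):
        state, (A, M, D, C), _ = random_instance(0)
        state.U = A.copy()
        h = Hyperparameters(alpha1=0, alpha2=0, alpha3=0, alpha4=0, c=2,
                            k_neighbors=2)
        b = objective(state, (A, M, D, C), h)
        assert b.total == 0.0

    def test_all_zero_matrices_give_zero(self):
        state, (A, M, D, C), h = random_instance(1)
        zero = lambda a: np.zeros_like(a)
        b = _objective(zero(state.U), zero(state.X), zero(state.Y),
                       zero(state.Z), zero(A), M, D, C, state.L, h)
        assert b.total == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_summation(self, seed):
        state, (A, M, D, C), h = random_instance(seed)
        b = objective(state, (A, M, D, C), h)
        fit_o, sim_o, attr_o, graph_o, sp_o, total_o = objective_by_summation(
            state.U, state.X, state.Y, state.Z, A, M, D, C, state.L, h)
        for got, want in [(b.fit_term, fit_o), (b.similarity_term, sim_o),
                          (b.attribute_term, attr_o), (b.graph_term, graph_o),
                          (b.sparsity_term, sp_o), (b.total, total_o)]:
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_total_is_exact_weighted_sum(self):
        state, data, h = random_instance(7, alphas=(0.3, 0.7, 1.1, 0.05))
        b = objective(state, data, h)
        assert b.total == (b.fit_term + h.alpha1 * b.similarity_term
                           + h.alpha2 * b.attribute_term
                           + h.alpha3 * b.graph_term
                           + h.alpha4 * b.sparsity_term)

    def test_dimension_mismatch_names_offender(self):
        state, (A, M, D, C), h = random_instance(0)
        with pytest.raises(ValueError, match="M"):
            objective(state, (A, M[:2, :2], D, C), h)


class TestUpdateRules:
    def test_update_U_scalar_reduces_to_A_over_U(self):
        state, data, h = scalar_instance(A=1.0, U=0.5, alpha1=0, alpha2=0,
                                         alpha3=0, alpha4=0)
        assert update_U(state, data, h)[0, 0] == pytest.approx(1.0)

    def test_update_U_fixed_point_when_all_targets_equal_U(self):
        # U = A > 0, MX(DY)^T = A and CZ(DY)^T = A, alpha3 = alpha4 = 0
        rng = np.random.default_rng(2)
        nm, nd = 4, 3
        h = Hyperparameters(alpha1=0.3, alpha2=0.2, alpha3=0, alpha4=0,
                            c=nd, k_neighbors=2)
        U = rng.uniform(0.5, 1.5, size=(nm, nd))
        # identity M, D, C with X = Z = U and Y = I make both projections
        # equal U; with A = U the update ratio is exactly 1
        state = ModelState(U=U, X=U.copy(), Y=np.eye(nd), Z=U.copy(),
                           S=np.zeros((nm, nm)), W=np.zeros((nm, nm)),
                           L=np.zeros((nm, nm)))
        new = update_U(state, (U, np.eye(nm), np.eye(nd), np.eye(nm)), h)
        np.testing.assert_allclose(new, U, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_U_matches_direct_substitution(self, seed):
        state, (A, M, D, C), h = random_instance(seed, nm=3, nd=2, c=2, k=1)
        want = update_U_by_substitution(state.U, state.X, state.Y, state.Z,
                                        A, M, D, C, state.S, state.W, h)
        np.testing.assert_allclose(update_U(state, (A, M, D, C), h), want,
                                   rtol=1e-12, atol=1e-15)

    def test_update_X_scalar_hand_case(self):
        state, data, h = scalar_instance(U=1.0, X=0.5)
        assert update_X(state, data, h)[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_update_X_fixed_point(self):
        # at a point where MX(DY)^T = U exactly, numerator = denominator
        state, (A, M, D, C), h = random_instance(3)
        state.U = M @ state.X @ (D @ state.Y).T
        np.testing.assert_allclose(update_X(state, (A, M, D, C), h), state.X,
                                   rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_X_matches_direct_substitution(self, seed):
        state, (A, M, D, C), h = random_instance(seed, nm=4, nd=3, c=2)
        want = update_X_by_substitution(state.U, state.X, state.Y, A, M, D, h)
        np.testing.assert_allclose(update_X(state, (A, M, D, C), h), want,
                                   rtol=1e-12, atol=1e-15)

    def test_update_Y_scalar_hand_case(self):
        state, data, h = scalar_instance(U=1.0, Y=2.0, alpha1=1.0, alpha2=0.0)
        # all other quantities 1: Y_new = 2 * (1/2) = 1
        assert update_Y(state, data, h)[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_update_Y_fixed_point(self):
        state, (A, M, D, C), _ = random_instance(4)
        h = Hyperparameters(alpha1=0.1, alpha2=0.1, c=2, k_neighbors=2)
        state.Z = state.X.copy()
        C_eq = M.copy()  # make CZ = MX so both projections coincide
        state.U = M @ state.X @ (D @ state.Y).T
        np.testing.assert_allclose(update_Y(state, (A, M, D, C_eq), h),
                                   state.Y, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_Y_matches_direct_substitution(self, seed):
        state, (A, M, D, C), h = random_instance(seed)
        want = update_Y_by_substitution(state.U, state.X, state.Y, state.Z,
                                        A, M, D, C, h)
        np.testing.assert_allclose(update_Y(state, (A, M, D, C), h), want,
                                   rtol=1e-12, atol=1e-15)

    def test_update_Z_scalar_hand_case(self):
        state, data, h = scalar_instance(U=1.0, Z=4.0)
        assert update_Z(state, data, h)[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_update_Z_fixed_point(self):
        state, (A, M, D, C), h = random_instance(5)
        state.U = C @ state.Z @ (D @ state.Y).T
        np.testing.assert_allclose(update_Z(state, (A, M, D, C), h), state.Z,
                                   rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_Z_matches_direct_substitution(self, seed):
        state, (A, M, D, C), h = random_instance(seed)
        want = update_Z_by_substitution(state.U, state.Y, state.Z, D, C, h)
        np.testing.assert_allclose(update_Z(state, (A, M, D, C), h), want,
                                   rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("seed", range(3))
    def test_updates_preserve_nonnegativity(self, seed):
        state, data, h = random_instance(seed)
        for fn in (update_U, update_X, update_Y, update_Z):
            assert fn(state, data, h).min() >= 0.0


class TestGradients:
    @pytest.mark.parametrize("seed", range(4))
    def test_finite_difference_agreement(self, seed):
        """Each block gradient matches central differences of its
        sub-objective to 1e-5 relative."""
        state, (A, M, D, C), h = random_instance(seed, nm=4, nd=3, c=2)
        grads = gradients(state, (A, M, D, C), h)
        eps = 1e-6

        def sub_obj(U=None, X=None, Y=None, Z=None, which="U"):
            U = state.U if U is None else U
            X = state.X if X is None else X
            Y = state.Y if Y is None else Y
            Z = state.Z if Z is None else Z
            b = _objective(U, X, Y, Z, A, M, D, C, state.L, h)
            if which == "U":
                return b.total
            if which == "X":
                return h.alpha1 * b.similarity_term
            if which == "Y":
                return (h.alpha1 * b.similarity_term
                        + h.alpha2 * b.attribute_term)
            return h.alpha2 * b.attribute_term

        for which, block in [("U", state.U), ("X", state.X),
                             ("Y", state.Y), ("Z", state.Z)]:
            fd = np.zeros_like(block)
            for idx in np.ndindex(block.shape):
                up, dn = block.copy(), block.copy()
                up[idx] += eps
                dn[idx] -= eps
                fd[idx] = (sub_obj(**{which: up}, which=which)
                           - sub_obj(**{which: dn}, which=which)) / (2 * eps)
            np.testing.assert_allclose(grads[which], fd, rtol=1e-5, atol=1e-6)


class TestFit:
    def _tiny(self, **kw):
        kw.setdefault("c", 2)
        kw.setdefault("k_neighbors", 2)
        state, data, _ = random_instance(kw.pop("inst_seed", 0), nm=6, nd=4,
                                         c=kw["c"], k=kw["k_neighbors"])
        return data, Hyperparameters(**kw)

    def test_max_iter_zero_returns_initialization(self):
        data, h = self._tiny(max_iter=0, seed=1)
        st = fit(data, h)
        assert st.n_iter == 0 and not st.converged
        assert len(st.objective_trace) == 1

    def test_alpha_zero_converges_to_A_in_one_U_update(self):
        data, h = self._tiny(alpha1=0, alpha2=0, alpha3=0, alpha4=0,
                             max_iter=3, seed=2)
        st = fit(data, h)
        assert st.objective_trace[1].fit_term == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(st.U, data[0], atol=1e-6)

    def test_same_seed_reproduces_fit(self):
        data, h = self._tiny(max_iter=10, seed=3)
        np.testing.assert_array_equal(fit(data, h).U, fit(data, h).U)

    def test_objective_non_increasing(self, tiny_synthetic):
        ds = tiny_synthetic.dataset()
        for seed in range(10):
            h = Hyperparameters(c=5, seed=seed, max_iter=60)
            tot = fit(ds, h).objective_totals
            diffs = np.diff(tot)
            assert (diffs <= 1e-9 * np.abs(tot[:-1]) + 1e-12).all()

    def test_factors_stay_nonnegative(self, tiny_synthetic):
        st = fit(tiny_synthetic.dataset(), Hyperparameters(c=5, max_iter=40))
        for block in (st.U, st.X, st.Y, st.Z):
            assert block.min() >= 0.0

    def test_kkt_residuals_small_at_convergence(self, tiny_synthetic):
        ds = tiny_synthetic.dataset()
        h = Hyperparameters(c=5, max_iter=4000, epsilon=1e-13, seed=0)
        st = fit(ds, h)
        thr = 1e-4 * np.linalg.norm(ds.A.values)
        assert max(kkt_residuals(st, ds, h).values()) < thr

    def test_doubling_sparsity_weight_never_increases_l1(self, tiny_synthetic):
        ds = tiny_synthetic.dataset()
        for seed in range(5):
            l1 = []
            for a4 in (0.1, 0.2):
                h = Hyperparameters(alpha4=a4, c=5, seed=seed, max_iter=100)
                l1.append(np.abs(fit(ds, h).U).sum())
            assert l1[1] <= l1[0] + 1e-9

    @pytest.mark.parametrize("c", [5, 10])
    def test_latent_dimension_sweep_runs(self, tiny_synthetic, c):
        st = fit(tiny_synthetic.dataset(),
                 Hyperparameters(c=c, max_iter=15, seed=1))
        assert st.X.shape[1] == c and np.isfinite(st.objective_totals).all()

    def test_empty_attribute_matrix_supported(self):
        state, (A, M, D, _), _ = random_instance(0, nm=6, nd=4)
        h = Hyperparameters(c=2, k_neighbors=2, max_iter=20)
        st = fit((A, M, D, None), h)
        assert st.Z.shape == (0, 2)
        assert st.objective_trace[-1].attribute_term == 0.0

    def test_uniform_random_init_scheme(self):
        data, h = self._tiny(init_scheme="uniform_random", max_iter=5, seed=4)
        st = fit(data, h)
        assert np.isfinite(st.objective_totals).all()

    def test_relative_convergence_mode(self):
        data, h = self._tiny(convergence="relative", epsilon=1e-4,
                             max_iter=500, seed=5)
        st = fit(data, h)
        assert st.converged and st.n_iter < 500


class TestPrediction:
    def test_predict_scores_returns_copy_of_U(self, tiny_synthetic):
        st = fit(tiny_synthetic.dataset(), Hyperparameters(c=5, max_iter=10))
        U = predict_scores(st)
        assert U is not st.U
        np.testing.assert_array_equal(U, st.U)
        assert U.min() >= 0.0

    def test_candidate_ranking_excludes_training_positives(self):
        scores = np.array([[0.9], [0.5], [0.7]])
        A_train = np.array([[1.0], [0.0], [0.0]])
        ranked = candidate_ranking(scores, A_train, disease=0)
        assert list(ranked) == [2, 1]

    def test_held_out_positives_outrank_median_negative(self, tiny_synthetic):
        """Planted recovery at small scale: masked positives should score
        above the median never-associated cell."""
        from mdapred import make_folds, mask_fold, rank_auc
        ds = tiny_synthetic.dataset()
        plan = make_folds(ds.A, seed=0)
        fold = plan.folds[0]
        A_train = mask_fold(ds.A, fold)
        h = Hyperparameters(c=5, seed=0)
        st = fit((A_train, ds.M.values, ds.D.values, ds.C.values), h)
        pos = st.U[fold[:, 0], fold[:, 1]]
        neg = st.U[ds.A.values < 0.5]
        assert np.median(pos) > np.median(neg)
        assert rank_auc(pos, neg) > 0.6
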