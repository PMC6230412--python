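import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fddlelm.datasets import FDDLHyperparams, LabeledDataset
from fddlelm.fddl import (
    CodingCoefficients,
    StructuredDictionary,
    _block_smooth_grad,
    code_samples,
    discrimination_term,
    fddl_fit,
    fddl_objective,
    fidelity_term,
    fisher_scatter,
    init_dictionary,
    reconstruct,
    soft_threshold,
    update_coefficients,
    update_dictionary,
    zero_coefficients,
)
from conftest import random_dataset
from oracles import fidelity_bruteforce, lasso_sign_enumeration, scatter_bruteforce


def _hand_example():
    """2 classes x 2 samples in K=2: columns (1,0),(1,2) | (3,0),(3,2)."""
    X = np.array([[1.0, 1.0, 3.0, 3.0], [0.0, 2.0, 0.0, 2.0]])
    ds = LabeledDataset.from_arrays(
        np.ones((2, 4)), [1, 1, 2, 2], normalize=False
    )
    return X, ds


class TestScatter:
    def test_hand_computed_traces(self):
        # m1=(1,1), m2=(3,1), m=(2,1): within-deviations (0,+-1) per class
        # give tr S_W = 4; n_i |m_i - m|^2 = 2*1 + 2*1 gives tr S_B = 4
        # (confirmed by the brute-force double-loop oracle)
        X, ds = _hand_example()
        stats = fisher_scatter(X, ds)
        S_W, S_B = scatter_bruteforce(X, ds.labels)
        assert np.trace(stats.S_W) == pytest.approx(4.0)
        assert np.trace(stats.S_B) == pytest.approx(4.0)
        assert np.trace(S_W) == pytest.approx(4.0)
        assert np.trace(S_B) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        ds = random_dataset(seed, p=4, n_per_class=(4, 3, 5))
        rng = np.random.default_rng(seed + 100)
        X = rng.normal(size=(6, ds.N))
        stats = fisher_scatter(X, ds)
        S_W, S_B = scatter_bruteforce(X, ds.labels)
        np.testing.assert_allclose(stats.S_W, S_W, atol=1e-12)
        np.testing.assert_allclose(stats.S_B, S_B, atol=1e-12)
        # symmetry / PSD structure
        for S in (stats.S_W, stats.S_B):
            assert np.abs(S - S.T).max() < 1e-10
            assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_identical_columns_per_class_zero_within(self):
        _, ds = _hand_example()
        X = np.repeat(np.array([[1.0, 5.0], [2.0, -1.0]]), 2, axis=1)
        stats = fisher_scatter(X, ds)
        assert np.all(stats.S_W == 0)

    def test_equal_class_means_zero_between(self):
        _, ds = _hand_example()
        X = np.array([[1.0, -1.0, 2.0, -2.0], [0.0, 0.0, 3.0, -3.0]])
        stats = fisher_scatter(X, ds)
        assert np.all(stats.S_B == 0)


class TestDiscriminationTerm:
    def test_zero_coefficients_zero_value(self):
        _, ds = _hand_example()
        assert discrimination_term(np.zeros((2, 4)), ds, eta=1.0) == 0.0

    def test_hand_example_value(self):
        # tr S_W - tr S_B + eta ||X||_F^2 = 4 - 4 + 28 (brute-force verified)
        X, ds = _hand_example()
        S_W, S_B = scatter_bruteforce(X, ds.labels)
        expected = np.trace(S_W) - np.trace(S_B) + np.sum(X**2)
        assert discrimination_term(X, ds, eta=1.0) == pytest.approx(expected)
        assert expected == pytest.approx(28.0)

    def test_sample_duplication_doubles_every_piece(self):
        X, ds = _hand_example()
        X2 = np.concatenate([X[:, :2], X[:, :2], X[:, 2:], X[:, 2:]], axis=1)
        ds2 = LabeledDataset.from_arrays(
            np.ones((2, 8)), [1] * 4 + [2] * 4, normalize=False
        )
        assert discrimination_term(X2, ds2, 1.0) == pytest.approx(
            2 * discrimination_term(X, ds, 1.0)
        )


class TestFidelityAndObjective:
    def test_zero_codes_give_twice_signal_energy(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        X = np.zeros((D.K, small_dataset.N))
        expected = 2 * np.linalg.norm(small_dataset.A, "fro") ** 2
        assert fidelity_term(small_dataset, D, X) == pytest.approx(expected)
        hyper = FDDLHyperparams(lambda1=0.3, lambda2=0.7, atoms_per_class=2)
        assert fddl_objective(small_dataset, D, X, hyper) == pytest.approx(expected)

    def test_single_class_reduces_to_double_residual(self):
        ds = random_dataset(1, p=4, n_per_class=(6,))
        D = init_dictionary(ds, 3, seed=1)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 6))
        expected = 2 * np.linalg.norm(ds.A - D.D @ X, "fro") ** 2
        assert fidelity_term(ds, D, X) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_termwise_bruteforce(self, seed):
        ds = random_dataset(seed, p=4, n_per_class=(3, 3))
        D = init_dictionary(ds, 2, seed=seed)
        rng = np.random.default_rng(seed + 50)
        X = rng.normal(size=(4, 6))
        assert fidelity_term(ds, D, X) == pytest.approx(
            fidelity_bruteforce(ds, D, X), abs=1e-12
        )

    def test_objective_composes_from_parts(self):
        ds = random_dataset(9, p=5, n_per_class=(4, 4))
        D = init_dictionary(ds, 3, seed=9)
        rng = np.random.default_rng(99)
        X = rng.normal(size=(6, 8))
        hyper = FDDLHyperparams(lambda1=0.05, lambda2=0.2, eta=0.7, atoms_per_class=3)
        expected = (
            fidelity_term(ds, D, X)
            + 0.05 * np.abs(X).sum()
            + 0.2 * discrimination_term(X, ds, 0.7)
        )
        assert fddl_objective(ds, D, X, hyper) == pytest.approx(expected)


class TestInitDictionary:
    def test_deterministic_unit_norm(self, small_dataset):
        D1 = init_dictionary(small_dataset, 2, seed=5)
        D2 = init_dictionary(small_dataset, 2, seed=5)
        assert np.array_equal(D1.D, D2.D)
        np.testing.assert_allclose(np.linalg.norm(D1.D, axis=0), 1.0, atol=1e-10)
        assert D1.class_blocks == [slice(0, 2), slice(2, 4)]

    def test_single_sample_class_gives_normalized_sample(self):
        A = np.array([[3.0, 0.0], [4.0, 1.0]])
        ds = LabeledDataset.from_arrays(A, [1, 2], normalize=False)
        D = init_dictionary(ds, 1, seed=0)
        np.testing.assert_allclose(D.D[:, 0], [0.6, 0.8])

    def test_oversized_request_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            init_dictionary(small_dataset, 10, seed=0)

    def test_svd_init_orthonormal_atoms(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0, method="svd")
        block = D.block(1)
        np.testing.assert_allclose(block.T @ block, np.eye(2), atol=1e-10)


class TestCoefficientUpdate:
    def test_huge_lambda1_drives_codes_to_exact_zero(self, small_dataset):
        """Above the instance's zero-threshold level (the max smooth-gradient
        magnitude at X = 0; the own-class fidelity term doubles it relative
        to a plain lasso) the proximal update keeps every code at zero."""
        D = init_dictionary(small_dataset, 2, seed=0)
        hyper0 = FDDLHyperparams(lambda1=0.0, lambda2=0.0, atoms_per_class=2)
        Xa0 = np.zeros((D.K, small_dataset.N))
        lam = 1.0 + max(
            np.abs(_block_smooth_grad(small_dataset, D, Xa0, i, hyper0)).max()
            for i in range(small_dataset.c)
        )
        assert lam <= 4.0 * np.abs(D.D.T @ small_dataset.A).max() + 1.0
        hyper = FDDLHyperparams(lambda1=lam, lambda2=0.0, atoms_per_class=2)
        X = update_coefficients(small_dataset, D, zero_coefficients(D, small_dataset), hyper)
        assert np.all(X.X == 0)

    def test_unregularized_single_class_reaches_least_squares(self):
        ds = random_dataset(3, p=4, n_per_class=(4,))
        D = init_dictionary(ds, 4, seed=3)  # square, generically invertible
        hyper = FDDLHyperparams(lambda1=0.0, lambda2=0.0, atoms_per_class=4, tol=1e-12)
        X = zero_coefficients(D, ds)
        for _ in range(100):
            X = update_coefficients(ds, D, X, hyper, max_inner=500, inner_tol=0.0)
        assert np.linalg.norm(ds.A - D.D @ X.X, "fro") < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_descent_property(self, seed):
        ds = random_dataset(seed, p=5, n_per_class=(5, 4))
        D = init_dictionary(ds, 3, seed=seed)
        rng = np.random.default_rng(seed + 7)
        X0 = CodingCoefficients(
            X=rng.normal(size=(6, 9)),
            class_cols=list(ds.class_slices),
            row_blocks=list(D.class_blocks),
        )
        hyper = FDDLHyperparams(lambda1=0.05, lambda2=0.1, atoms_per_class=3)
        before = fddl_objective(ds, D, X0, hyper)
        after = fddl_objective(ds, D, update_coefficients(ds, D, X0, hyper), hyper)
        assert after <= before + 1e-10 * max(1.0, abs(before))

    def test_eta_one_keeps_block_quadratic_psd(self):
        """The class-block subproblem's quadratic part, probed numerically
        through the (affine) gradient map, has no negative curvature."""
        ds = random_dataset(17, p=4, n_per_class=(4, 3))
        D = init_dictionary(ds, 2, seed=17)
        hyper = FDDLHyperparams(lambda1=0.0, lambda2=0.5, eta=1.0, atoms_per_class=2)
        Xa = np.zeros((4, 7))
        for i, sl in enumerate(ds.class_slices):
            n_i = sl.stop - sl.start
            dim = 4 * n_i
            G0 = _block_smooth_grad(ds, D, Xa, i, hyper).ravel()
            Hess = np.empty((dim, dim))
            for k in range(dim):
                pert = Xa.copy()
                e = np.zeros(dim)
                e[k] = 1.0
                pert[:, sl] += e.reshape(4, n_i)
                Hess[:, k] = _block_smooth_grad(ds, D, pert, i, hyper).ravel() - G0
            Hess = 0.5 * (Hess + Hess.T)
            assert np.linalg.eigvalsh(Hess).min() >= -1e-8


class TestDictionaryUpdate:
    @pytest.mark.parametrize("seed", range(20))
    def test_descent_property(self, seed):
        ds = random_dataset(seed, p=5, n_per_class=(5, 4))
        D = init_dictionary(ds, 3, seed=seed)
        hyper = FDDLHyperparams(lambda1=0.05, lambda2=0.1, atoms_per_class=3)
        X = update_coefficients(ds, D, zero_coefficients(D, ds), hyper)
        before = fddl_objective(ds, D, X, hyper)
        after = fddl_objective(ds, update_dictionary(ds, D, X), X, hyper)
        assert after <= before + 1e-10 * max(1.0, abs(before))
        norms = np.linalg.norm(update_dictionary(ds, D, X).D, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_rank_one_closed_form(self):
        """One class, one atom: the optimal unit atom is the normalized
        direction of A X^T."""
        ds = random_dataset(5, p=2, n_per_class=(4,))
        D = init_dictionary(ds, 1, seed=5)
        x_row = np.array([[1.0, -2.0, 0.5, 3.0]])
        X = CodingCoefficients(
            X=x_row, class_cols=list(ds.class_slices), row_blocks=[slice(0, 1)]
        )
        new = update_dictionary(ds, D, X)
        expected = (ds.A @ x_row[0])
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(new.D[:, 0] @ expected), 1.0, atol=1e-10)

    def test_all_zero_codes_reseed_keeps_objective(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        X = zero_coefficients(D, small_dataset)
        hyper = FDDLHyperparams(lambda1=0.1, lambda2=0.1, atoms_per_class=2)
        before = fddl_objective(small_dataset, D, X, hyper)
        new = update_dictionary(small_dataset, D, X)
        after = fddl_objective(small_dataset, new, X, hyper)
        assert after == pytest.approx(before)  # dead atoms cost nothing
        np.testing.assert_allclose(np.linalg.norm(new.D, axis=0), 1.0, atol=1e-10)


class TestFit:
    def test_trace_monotone_and_deterministic(self, gaussian_split):
        train, _ = gaussian_split
        hyper = FDDLHyperparams(
            lambda1=0.01, lambda2=0.01, atoms_per_class=10, max_outer_iter=6, seed=2
        )
        D1, X1, trace1 = fddl_fit(train, hyper)
        D2, X2, trace2 = fddl_fit(train, hyper)
        assert np.array_equal(D1.D, D2.D) and np.array_equal(X1.X, X2.X)
        for a, b in zip(trace1, trace1[1:]):
            assert b <= a * (1 + 1e-8) + 1e-8
        np.testing.assert_allclose(np.linalg.norm(D1.D, axis=0), 1.0, atol=1e-10)

    def test_learned_codes_cluster_by_class(self, gaussian_split):
        train, _ = gaussian_split
        hyper = FDDLHyperparams(
            lambda1=0.01, lambda2=0.05, atoms_per_class=10, max_outer_iter=8, seed=0
        )
        _, X, _ = fddl_fit(train, hyper)
        Xa = X.X
        n1 = train.n_per_class[0]
        within = []
        between = []
        for a in range(train.N):
            for b in range(a + 1, train.N):
                d = np.linalg.norm(Xa[:, a] - Xa[:, b])
                (within if (a < n1) == (b < n1) else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_more_atoms_reconstruct_no_worse(self):
        """Plain dictionary learning (c=1, lambda2=0): reconstruction error
        is non-increasing in dictionary size."""
        ds = random_dataset(21, p=6, n_per_class=(24,))
        errs = []
        for atoms in (2, 4, 8):
            hyper = FDDLHyperparams(
                lambda1=0.001, lambda2=0.0, atoms_per_class=atoms,
                max_outer_iter=10, seed=1,
            )
            D, X, _ = fddl_fit(ds, hyper)
            errs.append(np.linalg.norm(ds.A - D.D @ X.X, "fro"))
        assert errs[0] >= errs[1] >= errs[2]


class TestCoding:
    def test_atom_reproduced_exactly_without_penalty(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        a = D.D[:, [1]]
        X = code_samples(D, a, lambda1=0.0, tol=1e-12)
        assert np.linalg.norm(a - D.D @ X.X) < 1e-8

    def test_zero_threshold_condition(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        a = small_dataset.A[:, [0]]
        lam = 2.0 * np.abs(D.D.T @ a).max() + 1e-6
        X = code_samples(D, a, lambda1=lam)
        assert np.all(X.X == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p, K = 3, 4
        D = rng.normal(size=(p, K))
        D /= np.linalg.norm(D, axis=0)
        a = rng.normal(size=p)
        a /= np.linalg.norm(a)
        lam = 0.05
        sd = StructuredDictionary(D=D, class_blocks=[slice(0, K)], c=1)
        X = code_samples(sd, a[:, None], lam)
        mine = np.sum((a - D @ X.X[:, 0]) ** 2) + lam * np.abs(X.X).sum()
        assert mine - lasso_sign_enumeration(D, a, lam) < 1e-6

    def test_dimension_mismatch_rejected(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            code_samples(D, np.ones((3, 1)), 0.1)


class TestReconstruct:
    def test_linear_algebra_contracts(self, small_dataset):
        D = init_dictionary(small_dataset, 2, seed=0)
        assert np.all(reconstruct(D, np.zeros((4, 6))) == 0)
        Q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(4, 4)))
        sd = StructuredDictionary(D=Q, class_blocks=[slice(0, 2), slice(2, 4)], c=2)
        B = reconstruct(sd, Q.T @ small_dataset.A)
        np.testing.assert_allclose(B, small_dataset.A, atol=1e-12)
        assert reconstruct(D, np.ones((4, 6))).shape == (4, 6)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(-10, 10), min_size=1, max_size=20),
    st.floats(0, 5),
)
def test_soft_threshold_properties(values, thresh):
    z = np.array(values)
    out = soft_threshold(z, thresh)
    assert np.all(np.abs(out) <= np.maximum(np.abs(z) - thresh, 0.0) + 1e-12)
    # shrinkage never flips sign; at-threshold magnitudes map to exactly 0
    assert np.all((out == 0) | (np.sign(out) == np.sign(z)))
    assert np.all(out[np.abs(z) <= thresh] == 0)
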