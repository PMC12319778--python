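import numpy as np
import pytest
from scipy import stats

from plsperm import (
    METHODS,
    PermutationConfig,
    TwoBlockDataset,
    decompose,
    make_shuffle_indices,
    permuted_decomposition,
    rotated_null_values,
    run_all_permutation_tests,
    run_permutation_test,
    solve_procrustes,
)

from conftest import make_rank1_dataset


class TestPermutationConfig:
    def test_rejects_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            PermutationConfig(method="varimax")

    def test_rejects_nonpositive_n_perm(self):
        with pytest.raises(ValueError, match="positive"):
            PermutationConfig(n_perm=0)

    def test_rejects_invalid_index_table(self):
        bad = np.array([[0, 1, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="permutation of 0"):
            PermutationConfig(shuffle_indices=bad)

    def test_precomputed_table_reproduces_seeded_run(self, toy_dataset):
        table = make_shuffle_indices(toy_dataset.n, 50, seed=9)
        a = run_permutation_test(toy_dataset, PermutationConfig(method="behaviour", n_perm=50, seed=9))
        b = run_permutation_test(toy_dataset, PermutationConfig(method="behaviour", shuffle_indices=table))
        np.testing.assert_array_equal(a.values, b.values)

    def test_table_row_count_overrides_n_perm(self):
        table = make_shuffle_indices(6, 13, seed=0)
        cfg = PermutationConfig(n_perm=999, shuffle_indices=table)
        assert cfg.n_perm == 13


class TestPermutedDecomposition:
    def test_identity_permutation_is_noop(self, toy_dataset):
        a = decompose(toy_dataset)
        b = permuted_decomposition(toy_dataset, np.arange(toy_dataset.n), side="y")
        np.testing.assert_array_equal(a.singular_values, b.singular_values)
        np.testing.assert_array_equal(a.U, b.U)

    def test_matches_direct_recomputation_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((6, 4))
        Y = rng.standard_normal((6, 2))
        perm = np.array([3, 0, 5, 1, 4, 2])
        dec = permuted_decomposition(TwoBlockDataset(X, Y), perm, side="y")
        C = np.array([[stats.pearsonr(X[:, i], Y[perm][:, j])[0] for j in range(2)]
                      for i in range(4)])
        expected = np.linalg.svd(C, compute_uv=False)
        np.testing.assert_allclose(dec.singular_values, expected, atol=1e-10)

    def test_x_side_shuffle(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal((8, 2))
        perm = rng.permutation(8)
        a = permuted_decomposition(TwoBlockDataset(X, Y), perm, side="x")
        b = decompose(TwoBlockDataset(X[perm], Y))
        np.testing.assert_array_equal(a.singular_values, b.singular_values)

    def test_invalid_permutation_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="permutation"):
            permuted_decomposition(toy_dataset, np.zeros(toy_dataset.n, dtype=int))
        with pytest.raises(ValueError, match="side"):
            permuted_decomposition(toy_dataset, np.arange(toy_dataset.n), side="z")


class TestSolveProcrustes:
    def test_identity_when_already_aligned(self):
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((5, 3)))
        np.testing.assert_allclose(solve_procrustes(Q, Q), np.eye(3), atol=1e-10)

    def test_column_swap_recovered(self):
        Q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((6, 2)))
        swapped = Q[:, [1, 0]]
        R = solve_procrustes(swapped, Q)
        np.testing.assert_allclose(R, [[0, 1], [1, 0]], atol=1e-10)

    def test_orthogonality_of_solution(self):
        rng = np.random.default_rng(2)
        A, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        B, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        R = solve_procrustes(A, B)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)

    def test_beats_grid_of_rotations_and_reflections(self):
        rng = np.random.default_rng(3)
        A, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        B, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        R = solve_procrustes(A, B)
        best = np.linalg.norm(A @ R - B)
        for theta in np.linspace(0, 2 * np.pi, 1440, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            for cand in (np.array([[c, -s], [s, c]]), np.array([[c, s], [s, -c]])):
                assert best <= np.linalg.norm(A @ cand - B) + 1e-12

    def test_shape_and_orthonormality_validation(self):
        rng = np.random.default_rng(4)
        A, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        with pytest.raises(ValueError, match="shape mismatch"):
            solve_procrustes(A, A[:, :1])
        with pytest.raises(ValueError, match="orthonormal"):
            solve_procrustes(A * 2.0, A)


class TestRotatedNullValues:
    def test_rank_one_collapse(self):
        # k = 1: the rotation is +/-1 and the permuted singular value survives
        rng = np.random.default_rng(5)
        data = TwoBlockDataset(rng.standard_normal((20, 6)), rng.standard_normal((20, 1)))
        ref = decompose(data)
        perm = rng.permutation(20)
        pd_ = permuted_decomposition(data, perm, side="y")
        vals = rotated_null_values(pd_, ref, component="v")
        np.testing.assert_allclose(vals, pd_.singular_values, atol=1e-12)

    def test_self_alignment_returns_singular_values(self, toy_dataset):
        dec = decompose(toy_dataset)
        for comp in ("u", "v"):
            np.testing.assert_allclose(
                rotated_null_values(dec, dec, comp), dec.singular_values, atol=1e-10
            )

    @pytest.mark.parametrize("component", ["u", "v"])
    def test_conservation_and_lv1_dominance(self, null_dataset, component):
        # rotation redistributes but never creates covariance: the squared
        # values sum to the permuted squared singular values, and no value
        # can exceed the permuted LV1 strength
        ref = decompose(null_dataset)
        rng = np.random.default_rng(6)
        for _ in range(10):
            pd_ = permuted_decomposition(null_dataset, rng.permutation(null_dataset.n), "y")
            vals = rotated_null_values(pd_, ref, component)
            sp = pd_.singular_values
            assert abs((vals**2).sum() - (sp**2).sum()) < 1e-8
            assert vals.max() <= sp[0] + 1e-10

    def test_component_validation(self, toy_dataset):
        dec = decompose(toy_dataset)
        with pytest.raises(ValueError, match="component"):
            rotated_null_values(dec, dec, "w")


class TestRunPermutationTest:
    def test_vectorised_core_matches_per_instance_operations(self, toy_dataset):
        # the chunked/batched implementation must agree with the explicit
        # one-instance route through permuted_decomposition + rotation
        cfg = PermutationConfig(method="none", n_perm=8, seed=13)
        table = cfg.indices_for(toy_dataset.n)
        nulls = run_all_permutation_tests(toy_dataset, cfg)
        ref = decompose(toy_dataset)
        for r, perm in enumerate(table):
            pd_ = permuted_decomposition(toy_dataset, perm, side="y")
            np.testing.assert_allclose(nulls["none"].values[r], pd_.singular_values, atol=1e-10)
            vv = rotated_null_values(pd_, ref, "v")
            vu = rotated_null_values(pd_, ref, "u")
            np.testing.assert_allclose(nulls["behaviour"].values[r], vv, atol=1e-10)
            np.testing.assert_allclose(nulls["brain"].values[r], vu, atol=1e-10)
            np.testing.assert_allclose(nulls["both"].values[r], 0.5 * (vu + vv), atol=1e-10)

    def test_p_value_boundary_and_add_one(self):
        data = make_rank1_dataset(n=300, strength=0.95, seed=21, q_noise=0.1)
        plain = run_permutation_test(data, PermutationConfig("none", n_perm=99, seed=0))
        assert plain.p_values[0] == 0.0
        addone = run_permutation_test(
            data, PermutationConfig("none", n_perm=99, seed=0, add_one=True)
        )
        np.testing.assert_allclose(addone.p_values[0], 1.0 / 100.0)
        np.testing.assert_array_equal(plain.values, addone.values)

    def test_p_values_match_literal_proportion(self, toy_dataset):
        nd = run_permutation_test(toy_dataset, PermutationConfig("behaviour", n_perm=60, seed=2))
        manual = (nd.values >= nd.observed[None, :]).mean(axis=0)
        np.testing.assert_allclose(nd.p_values, manual)
        assert np.all((nd.p_values >= 0) & (nd.p_values <= 1))

    def test_single_y_column_all_methods_identical(self):
        rng = np.random.default_rng(8)
        data = TwoBlockDataset(rng.standard_normal((40, 6)), rng.standard_normal((40, 1)))
        nulls = run_all_permutation_tests(data, PermutationConfig("none", n_perm=200, seed=4))
        base = nulls["none"]
        for m in METHODS[1:]:
            np.testing.assert_allclose(nulls[m].values, base.values, rtol=1e-12)
            np.testing.assert_array_equal(nulls[m].p_values, base.p_values)

    def test_seeded_runs_bit_identical(self, null_dataset):
        a = run_permutation_test(null_dataset, PermutationConfig("both", n_perm=40, seed=5))
        b = run_permutation_test(null_dataset, PermutationConfig("both", n_perm=40, seed=5))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_rotated_lv1_p_never_exceeds_unrotated(self):
        # per-instance dominance implies, with shared indices, that every
        # rotated method's LV1 p-value is <= the unrotated one
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            data = TwoBlockDataset(rng.standard_normal((50, 30)), rng.standard_normal((50, 6)))
            nulls = run_all_permutation_tests(data, PermutationConfig("none", n_perm=200, seed=seed))
            for m in ("behaviour", "brain", "both"):
                assert nulls[m].p_values[0] <= nulls["none"].p_values[0]

    def test_null_distribution_summary_table(self, toy_dataset):
        nd = run_permutation_test(toy_dataset, PermutationConfig("behaviour", n_perm=30, seed=1))
        tab = nd.summary()
        assert list(tab["lv"]) == [1, 2, 3]
        assert {"observed", "null_mean", "null_q95", "p_value"} <= set(tab.columns)
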