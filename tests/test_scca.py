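import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lingbrain.errors import (BudgetOutOfRange, ConstantColumn, EmptyGrid,
                              NegativeLambda, NotZscored, TooFewPermutations,
                              ZeroVector, ZstateError)
from lingbrain.scca import (default_grid, extract_further_modes,
                            grid_search_sparsity, l1_unit_project,
                            permutation_test, pmd_rank1, run_scca_analysis,
                            soft_threshold, zscore_block)
from lingbrain.synthgen import generate_linked_blocks, make_planted_truth

from conftest import block_from_array


def zscored_pair(rng, n=30, p1=6, p2=5):
    bx = zscore_block(block_from_array(rng.normal(size=(n, p1)), prefix="x"))
    by = zscore_block(block_from_array(rng.normal(size=(n, p2)), prefix="y"))
    return bx, by


def angular_grid_oracle(Xv, Yv, c1, c2, step_deg=1.0):
    """Exhaustive maximizer of the PMD objective u'X'Yv over the discretized
    constraint set (unit circle intersected with the L1 ball); returns the
    canonical correlation achieved at the optimum."""
    th = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    P = np.vstack([np.cos(th), np.sin(th)])
    Pu = P[:, np.abs(P).sum(axis=0) <= c1 + 1e-12]
    Pv = P[:, np.abs(P).sum(axis=0) <= c2 + 1e-12]
    cov = Pu.T @ (Xv.T @ Yv) @ Pv
    iu, iv = np.unravel_index(np.argmax(cov), cov.shape)
    su = Xv @ Pu[:, iu]
    sv = Yv @ Pv[:, iv]
    su = su - su.mean()
    sv = sv - sv.mean()
    return float(su @ sv / np.sqrt((su @ su) * (sv @ sv)))


class TestZscore:
    def test_hand_computed(self):
        b = block_from_array(np.array([[1.0, 5.0], [2.0, 5.5], [3.0, 6.0]]))
        z = zscore_block(b)
        np.testing.assert_allclose(z.values[:, 0], [-1, 0, 1])
        assert z.state == "zscored"

    def test_columns_standardized(self, rng):
        z = zscore_block(block_from_array(rng.normal(2, 3, size=(40, 6))))
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_no_silent_double_scaling(self, rng):
        z = zscore_block(block_from_array(rng.normal(size=(10, 3))))
        with pytest.raises(ZstateError):
            zscore_block(z)

    def test_constant_column_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ConstantColumn):
            zscore_block(block_from_array(X))


class TestSoftThreshold:
    def test_identity_at_zero(self, rng):
        x = rng.normal(size=8)
        np.testing.assert_allclose(soft_threshold(x, 0.0), x)

    def test_elementwise_closed_form(self):
        np.testing.assert_allclose(soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0),
                                   [2.0, 0.0, 0.0])

    def test_large_lambda_zeroes_everything(self, rng):
        x = rng.normal(size=8)
        np.testing.assert_allclose(soft_threshold(x, np.abs(x).max() + 1), 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(NegativeLambda):
            soft_threshold(np.ones(3), -0.1)


class TestL1UnitProject:
    def test_inactive_budget_returns_normalized_input(self, rng):
        a = rng.normal(size=5)
        u = l1_unit_project(a, np.sqrt(5))
        np.testing.assert_allclose(u, a / np.linalg.norm(a), atol=1e-10)

    def test_tied_maxima_at_unit_budget_one_hot_lowest_index(self):
        np.testing.assert_allclose(l1_unit_project(np.array([1.0, 1.0]), 1.0),
                                   [1.0, 0.0])

    def test_matches_constraint_set_grid_oracle(self):
        a = np.array([2.0, 1.0])
        c = 1.2
        u = l1_unit_project(a, c)
        th = np.arange(0, 2 * np.pi, 1e-3)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        feas = pts[np.abs(pts).sum(axis=1) <= c]
        best = feas[np.argmax(feas @ a)]
        assert u @ a == pytest.approx(best @ a, abs=1e-3)

    def test_zero_vector_rejected(self):
        with pytest.raises(ZeroVector):
            l1_unit_project(np.zeros(4), 1.5)

    @pytest.mark.parametrize("c", [0.5, 10.0])
    def test_budget_out_of_range(self, c):
        with pytest.raises(BudgetOutOfRange):
            l1_unit_project(np.ones(4), c)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 10_000), st.floats(0.0, 1.0))
    def test_unit_norm_and_budget_respected(self, dim, seed, frac):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=dim)
        c = 1.0 + frac * (np.sqrt(dim) - 1.0)
        u = l1_unit_project(a, c)
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
        assert np.abs(u).sum() <= c + 1e-6

    def test_objective_matches_bisection_oracle(self, rng):
        from lingbrain.scca import _project_bisect
        for _ in range(200):
            dim = int(rng.integers(2, 25))
            a = rng.normal(size=dim)
            c = float(rng.uniform(1, np.sqrt(dim)))
            u = l1_unit_project(a, c)
            ub = _project_bisect(a, c)
            assert u @ a >= ub @ a - 1e-8


class TestPmdRank1:
    def test_unconstrained_equals_leading_singular_pair(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            p1, p2 = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            bx, by = zscored_pair(rng, n, p1, p2)
            mode = pmd_rank1(bx, by, np.sqrt(p1), np.sqrt(p2))
            M = bx.values.T @ by.values
            U, _, Vt = np.linalg.svd(M)
            sign = np.sign(U[np.argmax(np.abs(U[:, 0])), 0]) or 1.0
            np.testing.assert_allclose(mode.u, sign * U[:, 0], atol=1e-6)
            np.testing.assert_allclose(mode.v, sign * Vt[0], atol=1e-6)

    def test_column_permuted_copy_has_unit_correlation(self, rng):
        bx, _ = zscored_pair(rng, 20, 5, 5)
        perm = rng.permutation(5)
        by = block_from_array(bx.values[:, perm], prefix="y",
                              ids=bx.subjects, state="zscored")
        mode = pmd_rank1(bx, by, np.sqrt(5), np.sqrt(5))
        assert mode.r == pytest.approx(1.0, abs=1e-6)

    def test_matches_angular_grid_oracle_at_binding_constraints(self, rng):
        for _ in range(10):
            n = 6
            bx, by = zscored_pair(rng, n, 2, 2)
            c1 = c2 = 1.2
            mode = pmd_rank1(bx, by, c1, c2)
            oracle = angular_grid_oracle(bx.values, by.values, c1, c2)
            assert mode.r == pytest.approx(oracle, abs=2e-2)

    def test_requires_zscored_blocks(self, rng):
        raw = block_from_array(rng.normal(size=(10, 3)))
        z = zscore_block(block_from_array(rng.normal(size=(10, 3)), prefix="y"))
        with pytest.raises(NotZscored):
            pmd_rank1(raw, z, 1.0, 1.0)

    def test_invariants_after_fit(self, rng):
        for _ in range(25):
            p1, p2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            bx, by = zscored_pair(rng, 25, p1, p2)
            c1 = float(rng.uniform(1, np.sqrt(p1)))
            c2 = float(rng.uniform(1, np.sqrt(p2)))
            mode = pmd_rank1(bx, by, c1, c2)
            assert np.linalg.norm(mode.u) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(mode.v) == pytest.approx(1.0, abs=1e-8)
            assert np.abs(mode.u).sum() <= c1 + 1e-6
            assert np.abs(mode.v).sum() <= c2 + 1e-6
            assert -1 <= mode.r <= 1
            assert mode.u[np.argmax(np.abs(mode.u))] > 0   # sign convention

    def test_r_invariant_to_joint_row_permutation(self, rng):
        bx, by = zscored_pair(rng, 24, 5, 4)
        mode = pmd_rank1(bx, by, 1.8, 1.6)
        perm = rng.permutation(24)
        ids = [bx.subjects[i] for i in perm]
        mode_p = pmd_rank1(bx.subset(ids), by.subset(ids), 1.8, 1.6)
        assert mode_p.r == pytest.approx(mode.r, abs=1e-10)


class TestGridSearch:
    def test_single_point_grid(self, rng):
        bx, by = zscored_pair(rng, 20, 4, 4)
        c1, c2, mode, trace = grid_search_sparsity(bx, by, [(1.5, 1.5)])
        assert (c1, c2) == (1.5, 1.5)
        assert len(trace) == 1

    def test_trace_covers_grid_and_contains_optimum(self, rng):
        bx, by = zscored_pair(rng, 30, 5, 5)
        grid = default_grid(5, 5, size=4)
        c1, c2, mode, trace = grid_search_sparsity(bx, by, grid)
        assert len(trace) == len(grid)
        assert mode.r == pytest.approx(max(trace.values()), abs=1e-6)

    def test_empty_grid_rejected(self, rng):
        bx, by = zscored_pair(rng, 20, 4, 4)
        with pytest.raises(EmptyGrid):
            grid_search_sparsity(bx, by, [])

    def test_planted_sparse_mode_support_precision(self):
        truth = make_planted_truth(50, 50, k_active=5, rho=0.8, seed=21)
        bx, by, _ = generate_linked_blocks(200, 50, 50, truth=truth, seed=21)
        zx, zy = zscore_block(bx), zscore_block(by)
        _, _, mode, _ = grid_search_sparsity(zx, zy)
        top_u = np.argsort(-np.abs(mode.u))[:5]
        top_v = np.argsort(-np.abs(mode.v))[:5]
        assert len(set(top_u) & set(truth.support_x)) / 5 >= 0.8
        assert len(set(top_v) & set(truth.support_y)) / 5 >= 0.8


class TestPermutationTest:
    def test_strong_signal_beats_every_permutation(self):
        truth = make_planted_truth(10, 10, k_active=3, rho=0.95, seed=2)
        bx, by, _ = generate_linked_blocks(80, 10, 10, truth=truth, seed=2,
                                           noise_on_support=False)
        zx, zy = zscore_block(bx), zscore_block(by)
        p, maxima = permutation_test(zx, zy, n_perm=200, seed=0, allow_few=True)
        assert p == 0.0                      # k/N convention: none higher
        assert maxima.shape == (200,)

    def test_reproducible_with_seed(self, rng):
        bx, by = zscored_pair(rng, 25, 5, 5)
        p1, m1 = permutation_test(bx, by, n_perm=150, seed=9, allow_few=True)
        p2, m2 = permutation_test(bx, by, n_perm=150, seed=9, allow_few=True)
        assert p1 == p2
        np.testing.assert_array_equal(m1, m2)

    def test_identity_permutation_reproduces_observed_r(self, rng):
        # the permutation statistic recomputes exactly the observed grid max
        # when handed unpermuted data
        from lingbrain.scca import _grid_max_many
        bx, by = zscored_pair(rng, 25, 5, 5)
        grid = default_grid(5, 5)
        _, _, mode, trace = grid_search_sparsity(bx, by, grid)
        got = _grid_max_many(bx.values, by.values[None], grid)[0]
        assert got == pytest.approx(mode.r, abs=1e-9)

    def test_too_few_permutations_rejected(self, rng):
        bx, by = zscored_pair(rng, 20, 4, 4)
        with pytest.raises(TooFewPermutations):
            permutation_test(bx, by, n_perm=50, seed=0)


class TestFurtherModes:
    def test_deflation_identity(self, rng):
        bx, by = zscored_pair(rng, 30, 6, 6)
        _, _, mode, _ = grid_search_sparsity(bx, by, default_grid(6, 6, size=3))
        M = bx.values.T @ by.values
        d = mode.u @ M @ mode.v
        M_def = M - d * np.outer(mode.u, mode.v)
        assert abs(mode.u @ M_def @ mode.v) < 1e-8

    def test_k_max_one_returns_empty(self, rng):
        bx, by = zscored_pair(rng, 20, 4, 4)
        _, _, mode, _ = grid_search_sparsity(bx, by, [(1.5, 1.5)])
        assert extract_further_modes(bx, by, mode, k_max=1) == []

    def test_rank_one_truth_leaves_mode_two_in_the_null(self):
        truth = make_planted_truth(12, 12, k_active=4, rho=0.9, seed=3)
        bx, by, _ = generate_linked_blocks(100, 12, 12, truth=truth, seed=3,
                                           noise_on_support=False)
        zx, zy = zscore_block(bx), zscore_block(by)
        _, _, mode, _ = grid_search_sparsity(zx, zy)
        further = extract_further_modes(zx, zy, mode, k_max=2, n_perm=200,
                                        seed=4, allow_few=True)
        assert len(further) == 1
        assert further[0].permutation_p > 0.05


class TestRunAnalysis:
    def test_planted_mode_recovered_end_to_end(self):
        truth = make_planted_truth(40, 40, k_active=5, rho=0.8, seed=6)
        bx, by, _ = generate_linked_blocks(150, 40, 40, truth=truth, seed=6)
        res = run_scca_analysis(bx, by, analysis="planted", n_perm=99,
                                k_max=1, seed=0, allow_few=True)
        mode = res.modes[0]
        top = np.argsort(-np.abs(mode.u))[:5]
        assert len(set(top) & set(truth.support_x)) >= 4   # >= 80 % of support
        assert mode.permutation_p <= 0.05

    def test_serialization_is_deterministic(self, tmp_path, rng):
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 5))
        out = []
        for run in (1, 2):
            bx = block_from_array(X, prefix="x")
            by = block_from_array(Y, prefix="y")
            res = run_scca_analysis(bx, by, analysis="det", n_perm=60,
                                    k_max=2, seed=5, allow_few=True)
            path = tmp_path / f"run{run}.json"
            res.to_json(path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_indicator_on_null_data_gets_negligible_weight(self, rng):
        # a diagnosis indicator uncorrelated with Y should not dominate u
        X = rng.normal(size=(60, 10))
        Y = rng.normal(size=(60, 10))
        diagnosis = pd.Series(rng.integers(0, 2, size=60).astype(float),
                              index=[f"sub{i:03d}" for i in range(60)],
                              name="diagnosis")
        bx = block_from_array(X, prefix="x")
        by = block_from_array(Y, prefix="y")
        res = run_scca_analysis(bx, by, analysis="null_ind",
                                indicators=diagnosis.to_frame(), n_perm=60,
                                k_max=1, seed=8, allow_few=True)
        weights = dict(zip(res.feature_names_x, res.modes[0].u))
        ranks = sorted(np.abs(res.modes[0].u))[::-1]
        assert abs(weights["diagnosis"]) <= ranks[2]   # never a top-2 driver

    def test_sorted_weights_table(self, rng):
        bx = block_from_array(rng.normal(size=(20, 4)), prefix="x")
        by = block_from_array(rng.normal(size=(20, 4)), prefix="y")
        res = run_scca_analysis(bx, by, analysis="w", n_perm=60, k_max=1,
                                seed=0, allow_few=True)
        table = res.sorted_weights("x")
        assert list(table.columns) == ["feature", "weight"]
        assert (table["weight"].abs().diff().dropna() <= 1e-12).all()
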