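"""Network construction: bicor, adjacency, TOM, soft threshold, modules,
eigengenes and trait correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquenet.network import (
    CoexpressionNetwork,
    bicor,
    bicor_matrix,
    detect_modules,
    eigengene_trait_correlation,
    intramodular_connectivity,
    module_eigengene,
    scale_free_fit,
    select_soft_threshold,
    signed_adjacency,
    topological_overlap,
    ModulePartition,
)
from plaquenet.synthetic import SimulationDesign, generate_two_strata_expression


def bicor_oracle(x, y):
    """Independent definitional transcription of the biweight midcorrelation."""
    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    xt, yt = transform(x), transform(y)
    if xt is None or yt is None:
        return stats.pearsonr(x, y).statistic
    return float(
        np.sum(xt * yt) / np.sqrt(np.sum(xt**2) * np.sum(yt**2))
    )


class TestBicor:
    def test_perfect_linear_pairs(self, rng):
        x = rng.standard_normal(25)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)
        assert bicor(x, 3.0 * x + 2.0) == pytest.approx(1.0)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 50))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_outlier_moves_bicor_less_than_pearson(self, rng):
        x = rng.standard_normal(20)
        y = x + 0.1 * rng.standard_normal(20)
        clean = stats.pearsonr(x, y).statistic
        y_out = y.copy()
        y_out[0] = 40.0
        pearson_shift = abs(stats.pearsonr(x, y_out).statistic - clean)
        bicor_shift = abs(bicor(x, y_out) - clean)
        assert bicor_shift < pearson_shift

    def test_mad_zero_falls_back_to_pearson(self, rng):
        x = np.zeros(10)
        x[0] = 5.0  # median deviation zero
        y = rng.standard_normal(10)
        assert bicor(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_matrix_agrees_with_pairwise_and_handles_fallback_rows(self, rng):
        X = rng.standard_normal((8, 30))
        X[3, :] = 0.0
        X[3, 0] = 1.0  # MAD = 0 row
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(8)])
        C = bicor_matrix(df)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = bicor(X[i], X[j])
                assert C.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_rejects_short_and_nonfinite_input(self):
        with pytest.raises(ValueError):
            bicor(np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            bicor(np.array([1.0, np.nan, 2, 3, 4]), np.arange(5.0))


class TestSignedAdjacency:
    def test_closed_forms(self):
        C = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(C, 6).iloc[0, 1] == 1.0
        C.iloc[0, 1] = C.iloc[1, 0] = -1.0
        assert signed_adjacency(C, 6).iloc[0, 1] == 0.0
        C.iloc[0, 1] = C.iloc[1, 0] = 0.0
        assert signed_adjacency(C, 24).iloc[0, 1] == pytest.approx(2.0**-24)

    def test_monotone_decreasing_in_beta(self, rng):
        C = pd.DataFrame(np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1))
        C = (C + C.T) / 2
        np.fill_diagonal(C.values, 1.0)
        prev = signed_adjacency(C, 2).to_numpy()
        for beta in (3, 5, 9):
            cur = signed_adjacency(C, beta).to_numpy()
            off = ~np.eye(6, dtype=bool)
            assert np.all(cur[off] <= prev[off] + 1e-15)
            prev = cur


def tom_oracle(A):
    """Triple-loop brute-force topological overlap."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A0[i, u] * A0[u, j] for u in range(n))
            ki = sum(A0[i, u] for u in range(n) if u != i)
            kj = sum(A0[j, u] for u in range(n) if u != j)
            T[i, j] = (l + A0[i, j]) / (min(ki, kj) + 1 - A0[i, j])
    return T


class TestTopologicalOverlap:
    def test_triangle_hand_value(self):
        A = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(A.values, 1.0)
        T = topological_overlap(A)
        off = T.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_zero_adjacency_gives_zero_overlap(self):
        A = pd.DataFrame(np.eye(4))
        T = topological_overlap(A)
        assert np.all(T.to_numpy()[~np.eye(4, dtype=bool)] == 0.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            T = topological_overlap(pd.DataFrame(A)).to_numpy()
            np.testing.assert_allclose(T, tom_oracle(A), atol=1e-12)
            assert np.all((T >= 0) & (T <= 1))

    def test_rejects_asymmetric_input(self):
        A = pd.DataFrame(np.eye(3))
        A.iloc[0, 1] = 0.4
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(A)


class TestSoftThreshold:
    def test_chosen_power_is_lowest_complying_by_oracle_recomputation(self):
        design = SimulationDesign(seed=2)
        expr, _, _ = generate_two_strata_expression(design)
        report = select_soft_threshold(expr)
        # independent pass: recompute both statistics per power
        C = bicor_matrix(expr).to_numpy()
        sim = (1 + C) / 2
        np.fill_diagonal(sim, 0.0)
        complying = []
        for beta in range(2, 31):
            k = (sim**beta).sum(axis=1)
            if scale_free_fit(k) >= 0.8 and np.median(k) < 100:
                complying.append(beta)
        assert report.power == complying[0]
        row = report.table.set_index("power").loc[report.power]
        assert row["r_squared"] >= 0.8 and row["median_k"] < 100

    def test_pure_noise_has_no_complying_power(self, rng):
        expr = pd.DataFrame(rng.standard_normal((120, 60)))
        with pytest.raises(ValueError, match="no power"):
            select_soft_threshold(expr)

    def test_single_power_grid_returns_it_when_complying(self):
        design = SimulationDesign(seed=2)
        expr, _, _ = generate_two_strata_expression(design)
        full = select_soft_threshold(expr)
        report = select_soft_threshold(expr, grid=[full.power])
        assert report.power == full.power

    def test_invalid_grid_rejected(self, small_expr):
        with pytest.raises(ValueError, match="grid"):
            select_soft_threshold(small_expr, grid=[4, 2])


class TestDetectModules:
    @staticmethod
    def _block_tom(rng, sizes, within=0.6, between=0.02):
        n = sum(sizes)
        T = rng.uniform(0, between, (n, n))
        start = 0
        for s in sizes:
            T[start : start + s, start : start + s] = rng.uniform(
                within, within + 0.2, (s, s)
            )
            start += s
        T = (T + T.T) / 2
        np.fill_diagonal(T, 1.0)
        genes = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame(T, index=genes, columns=genes)

    def test_two_planted_blocks_recovered_exactly(self, rng):
        tom = self._block_tom(rng, [50, 50])
        part = detect_modules(tom, deep_split=3, min_cluster_size=20)
        assert len(part) == 2
        blocks = [set(tom.index[:50]), set(tom.index[50:])]
        detected = [set(g) for g in part.modules.values()]
        assert all(b in detected for b in blocks)
        assert part.grey == []

    def test_min_cluster_size_larger_than_blocks_gives_all_grey(self, rng):
        tom = self._block_tom(rng, [10, 10])
        part = detect_modules(tom, min_cluster_size=15)
        assert len(part) == 0
        assert set(part.grey) == set(tom.index)

    def test_partition_invariant_to_gene_order(self, rng):
        tom = self._block_tom(rng, [30, 25])
        part = detect_modules(tom)
        perm = rng.permutation(len(tom))
        shuffled = tom.iloc[perm, perm]
        part2 = detect_modules(shuffled)
        assert part.labels.sort_index().equals(part2.labels.sort_index())

    def test_module_names_follow_size_order(self, rng):
        tom = self._block_tom(rng, [40, 25])
        part = detect_modules(tom)
        assert part.module_names[0] == "turquoise"
        assert len(part.modules["turquoise"]) == 40
        assert part.module_names[1] == "blue"


class TestEigengene:
    def test_identical_profiles_give_that_profile(self, rng):
        profile = rng.standard_normal(30)
        expr = pd.DataFrame(
            np.tile(2.0 * profile + 1.0, (5, 1)),
            index=[f"g{i}" for i in range(5)],
        )
        eig, ve = module_eigengene(expr, list(expr.index))
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.to_numpy(), z, atol=1e-10)
        assert ve == pytest.approx(1.0)

    def test_matches_full_decomposition_up_to_sign(self, rng):
        expr = pd.DataFrame(rng.standard_normal((12, 25)))
        eig, ve = module_eigengene(expr, list(expr.index))
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        w, V = np.linalg.eigh(Xs.T @ Xs)  # independent decomposition route
        lead = V[:, -1]
        lead = (lead - lead.mean()) / lead.std()
        agree = min(
            np.max(np.abs(eig.to_numpy() - lead)),
            np.max(np.abs(eig.to_numpy() + lead)),
        )
        assert agree < 1e-10
        assert ve == pytest.approx(w[-1] / w.sum())

    def test_sign_orientation_favors_majority(self, rng):
        factor = rng.standard_normal(40)
        rows = [factor + 0.05 * rng.standard_normal(40) for _ in range(7)]
        rows += [-factor + 0.05 * rng.standard_normal(40) for _ in range(3)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(10)])
        eig, _ = module_eigengene(expr, list(expr.index))
        corrs = [stats.pearsonr(expr.loc[g], eig).statistic for g in expr.index]
        assert np.mean(corrs) >= 0
        assert sum(c > 0 for c in corrs) == 7

    def test_constant_gene_dropped(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 20)))
        expr.iloc[0] = 3.14
        eig, _ = module_eigengene(expr, list(expr.index))
        assert eig.to_numpy().std() == pytest.approx(1.0)
        assert abs(eig.mean()) < 1e-12


class TestTraitCorrelation:
    def test_self_correlation(self, rng):
        eig = pd.Series(rng.standard_normal(50))
        r, p = eigengene_trait_correlation(eig, eig)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_p_matches_t_distribution_oracle(self, rng):
        # construct a pair with empirical r very close to 0.5, n = 100
        n = 100
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(n)
        r, p = eigengene_trait_correlation(pd.Series(x), pd.Series(y))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-12)
        # the exemplar value at exactly r = 0.5 from the same oracle
        t_exact = 0.5 * np.sqrt(98) / np.sqrt(0.75)
        assert 2 * stats.t.sf(t_exact, 98) == pytest.approx(1.1805e-7, rel=1e-3)

    def test_null_p_values_are_uniform(self, rng):
        pvals = []
        x = rng.standard_normal(60)
        for _ in range(500):
            y = rng.standard_normal(60)
            pvals.append(eigengene_trait_correlation(pd.Series(x), pd.Series(y))[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_trait_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            eigengene_trait_correlation(
                pd.Series(rng.standard_normal(10)), np.ones(10)
            )


class TestIntramodularConnectivity:
    def test_two_gene_module(self):
        A = pd.DataFrame(
            [[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        part = ModulePartition.from_labels(pd.Series({"a": "blue", "b": "blue"}))
        kim = intramodular_connectivity(A, part)
        np.testing.assert_allclose(kim["kim"], 0.3, atol=1e-15)

    def test_grey_genes_absent_and_matches_masked_row_sum(self, rng):
        n = 12
        A = rng.uniform(0, 1, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        genes = [f"g{i}" for i in range(n)]
        adf = pd.DataFrame(A, index=genes, columns=genes)
        labels = pd.Series(
            ["blue"] * 5 + ["brown"] * 4 + ["grey"] * 3, index=genes
        )
        part = ModulePartition.from_labels(labels)
        kim = intramodular_connectivity(adf, part).set_index("gene")
        assert set(kim.index) == set(genes[:9])
        for g in genes[:9]:
            mod = labels[g]
            peers = [h for h in genes if labels[h] == mod and h != g]
            assert kim.loc[g, "kim"] == pytest.approx(adf.loc[g, peers].sum())


def test_model_results_facade_summary_and_consistency():
    design = SimulationDesign(seed=4, n_modules=2, genes_per_module=40,
                              n_background_genes=60, n_samples_per_stratum=80)
    expr, _, truth = generate_two_strata_expression(design)
    results = CoexpressionNetwork(expr, power=12, min_cluster_size=20).fit()
    assert results.power == 12
    A = results.adjacency.to_numpy()
    expected = ((1 + results.correlation.to_numpy()) / 2) ** 12
    np.fill_diagonal(expected, 1.0)
    np.testing.assert_allclose(A, expected, atol=1e-12)
    text = results.summary()
    assert "soft power beta: 12" in text
    for name in results.partition.module_names:
        assert name in text
    eigs = results.eigengenes
    assert list(eigs.columns) == list(expr.columns)
    np.testing.assert_allclose(eigs.mean(axis=1), 0.0, atol=1e-10)
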