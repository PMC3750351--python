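"""Network construction: correlation, adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comirnet.coexpression import (AdjacencyMatrix, adjacency, build_network,
                                   correlation_matrix, decompose,
                                   detect_modules, gene_significance,
                                   merge_close_modules, module_eigengene,
                                   module_membership, select_soft_threshold,
                                   tom)
from comirnet.io_formats import PhenotypeTable, ValidationError
from comirnet.preprocess import DesignSpec, adjust_for_effects
from comirnet.simulate import SimulationParams, simulate_dataset

from conftest import make_expression


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop oracle: the overlap definition written out literally."""
    n = a.shape[0]
    w = np.eye(n)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            w[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return w


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestCorrelationMatrix:
    def test_duplicated_probe_has_unit_correlation(self, rng):
        x = rng.standard_normal(10)
        mat = make_expression([x, x, rng.standard_normal(10)])
        c = correlation_matrix(mat)
        assert c.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_probe_has_minus_one(self, rng):
        x = rng.standard_normal(10)
        c = correlation_matrix(make_expression([x, -x]))
        assert c.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_manual_covariance_oracle(self, rng):
        vals = rng.standard_normal((5, 4))
        c = correlation_matrix(make_expression(vals)).to_numpy()
        centered = vals - vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1)
        expect = (centered @ centered.T) / 3 / np.outer(sd, sd)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(c, expect, atol=1e-12)

    def test_zero_variance_probe_named(self, rng):
        mat = make_expression([np.ones(5), rng.standard_normal(5)])
        with pytest.raises(ValidationError, match="g0"):
            correlation_matrix(mat)


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        corr = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], ["a", "b"], ["a", "b"])
        for beta in (1, 4, 9):
            assert adjacency(corr, beta).values[0, 1] == pytest.approx(1.0)

    def test_unsigned_arithmetic(self):
        corr = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], ["a", "b"], ["a", "b"])
        assert adjacency(corr, 2).values[0, 1] == pytest.approx(0.25)

    def test_signed_arithmetic(self):
        corr = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], ["a", "b"], ["a", "b"])
        assert adjacency(corr, 2, "signed").values[0, 1] == pytest.approx(0.0625)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_larger_beta_never_increases_unsigned_entries(self, seed):
        rng = np.random.default_rng(seed)
        r = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r, list("abcdef"), list("abcdef"))
        a1 = adjacency(corr, 2).values
        a2 = adjacency(corr, 5).values
        off = ~np.eye(6, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_beta_below_one_rejected(self):
        corr = pd.DataFrame(np.eye(2), ["a", "b"], ["a", "b"])
        with pytest.raises(ValidationError):
            adjacency(corr, 0.5)


class TestTOM:
    def test_three_node_clique_has_unit_overlap(self):
        a = np.ones((3, 3))
        w = tom(AdjacencyMatrix(list("abc"), a, 1.0)).values
        np.testing.assert_allclose(w, 1.0)

    def test_zero_adjacency_has_zero_overlap(self):
        a = np.eye(4)
        w = tom(AdjacencyMatrix(list("abcd"), a, 1.0)).values
        assert w[~np.eye(4, dtype=bool)].max() == 0.0
        np.testing.assert_allclose(np.diag(w), 1.0)

    def test_matches_triple_loop_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 12))
            a = random_adjacency(rng, n)
            w = tom(AdjacencyMatrix([f"p{i}" for i in range(n)], a, 1.0)).values
            np.testing.assert_allclose(w, tom_bruteforce(a), atol=1e-12)

    def test_symmetric_bounded(self, rng):
        a = random_adjacency(rng, 15)
        w = tom(AdjacencyMatrix([f"p{i}" for i in range(15)], a, 1.0)).values
        np.testing.assert_allclose(w, w.T)
        assert w.min() >= 0.0 and w.max() <= 1.0


class TestSoftThreshold:
    def test_planted_power_law_fits_at_beta_one(self):
        # degrees drawn exactly from p(k) ~ k^-2 via the inverse CDF,
        # realized as a rank-1 weight matrix so k_i is proportional to w_i
        n = 400
        u = (np.arange(n) + 0.5) / n
        k_target = np.clip(1.0 / (1 - u), None, 400.0)
        w = k_target / k_target.sum() * 2.0
        corr = np.outer(w, w)
        np.fill_diagonal(corr, 1.0)
        ids = [f"p{i}" for i in range(n)]
        scan = select_soft_threshold(pd.DataFrame(corr, ids, ids), betas=[1])
        assert scan.r_squared[0] >= 0.99
        assert scan.selected_beta == 1.0 and scan.reached_target

    def test_two_probe_network_rejected(self):
        corr = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], ["a", "b"], ["a", "b"])
        with pytest.raises(ValidationError):
            select_soft_threshold(corr, betas=[1, 2])

    def test_simulated_data_reaches_target(self):
        ds = simulate_dataset(SimulationParams(seed=3))
        res = adjust_for_effects(ds.mrna, ds.covariates, DesignSpec())
        scan = select_soft_threshold(correlation_matrix(res))
        assert scan.reached_target
        assert max(scan.r_squared) > 0.9

    def test_selection_is_minimal_qualifying_beta(self):
        ds = simulate_dataset(SimulationParams(seed=3))
        res = adjust_for_effects(ds.mrna, ds.covariates, DesignSpec())
        scan = select_soft_threshold(correlation_matrix(res))
        qualifying = [b for b, r2 in zip(scan.betas, scan.r_squared)
                      if r2 > 0.9]
        assert scan.selected_beta == qualifying[0]


def _block_matrix(rng, sizes, n_samples=40, noise=0.05):
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(f + noise * rng.standard_normal(n_samples))
            labels.append(b)
    return make_expression(np.array(rows)), np.array(labels)


class TestDetectModules:
    def test_two_separated_blocks_recovered_purely(self, rng):
        mat, labels = _block_matrix(rng, [12, 10])
        corr = correlation_matrix(mat)
        w = tom(adjacency(corr, 6))
        found = detect_modules(w, min_module_size=5)
        assert found.nunique() == 2
        for b in (0, 1):
            assert found[labels == b].nunique() == 1

    def test_block_below_min_size_dissolves_to_grey(self, rng):
        mat, labels = _block_matrix(rng, [12, 4])
        w = tom(adjacency(correlation_matrix(mat), 6))
        found = detect_modules(w, min_module_size=8)
        assert set(found[labels == 1]) == {"grey"}
        assert (found[labels == 0] != "grey").all()

    def test_min_module_size_validated(self, rng):
        mat, _ = _block_matrix(rng, [6])
        w = tom(adjacency(correlation_matrix(mat), 2))
        with pytest.raises(ValidationError):
            detect_modules(w, min_module_size=1)

    def test_planted_modules_recovered_on_simulated_data(self):
        from sklearn.metrics import adjusted_rand_score
        ds = simulate_dataset(SimulationParams(seed=11))
        res = adjust_for_effects(ds.mrna, ds.covariates, DesignSpec())
        _, decomp = build_network(res, min_module_size=30)
        ari = adjusted_rand_score(ds.truth.module_assignment.values,
                                  decomp.labels.loc[
                                      ds.truth.module_assignment.index].values)
        assert ari >= 0.9

    def test_pipeline_is_deterministic(self):
        ds = simulate_dataset(SimulationParams(seed=4, n_genes=300,
                                               n_mirnas=12))
        res = adjust_for_effects(ds.mrna, ds.covariates, DesignSpec())
        _, d1 = build_network(res, min_module_size=30)
        _, d2 = build_network(res, min_module_size=30)
        assert d1.labels.equals(d2.labels)
        assert d1.eigengenes.equals(d2.eigengenes)


class TestModuleEigengene:
    def test_identical_profiles_fully_explained(self, rng):
        x = rng.standard_normal(20)
        mat = make_expression([x, x, x])
        me, ve = module_eigengene(mat, mat.probe_ids)
        assert ve == pytest.approx(1.0)
        xs = (x - x.mean()) / x.std(ddof=1)
        assert abs(np.corrcoef(me, xs)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, xs)[0, 1] > 0  # sign convention

    def test_sign_flip_of_members_flips_eigengene(self, rng):
        vals = rng.standard_normal((5, 15))
        mat = make_expression(vals)
        me, _ = module_eigengene(mat, mat.probe_ids)
        me_neg, _ = module_eigengene(make_expression(-vals), mat.probe_ids)
        np.testing.assert_allclose(me_neg, -me, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        vals = rng.standard_normal((10, 20))
        mat = make_expression(vals)
        me, ve = module_eigengene(mat, mat.probe_ids)
        xs = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1,
                                                             keepdims=True)
        evals, evecs = np.linalg.eigh(xs.T @ xs)
        lead = evecs[:, -1]
        assert abs(abs(np.dot(me, lead)) - 1.0) < 1e-10
        assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_unit_norm(self, rng):
        mat = make_expression(rng.standard_normal((6, 12)))
        me, _ = module_eigengene(mat, mat.probe_ids)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_constant_probe_rejected(self, rng):
        mat = make_expression([np.ones(8), rng.standard_normal(8)])
        with pytest.raises(ValidationError, match="constant"):
            module_eigengene(mat, mat.probe_ids)


class TestMergeModules:
    def test_split_module_remerged(self, rng):
        mat, labels = _block_matrix(rng, [16])
        split = pd.Series(np.where(np.arange(16) < 8, "blue", "red"),
                          index=mat.data.index)
        decomp = decompose(mat, split, min_module_size=4)
        merged = merge_close_modules(decomp, mat, merge_threshold=0.2)
        assert len(merged.modules) == 1

    def test_orthogonal_modules_not_merged(self, rng):
        mat, labels = _block_matrix(rng, [10, 10])
        lab = pd.Series(np.where(labels == 0, "blue", "red"),
                        index=mat.data.index)
        decomp = decompose(mat, lab, min_module_size=4)
        merged = merge_close_modules(decomp, mat, merge_threshold=0.2)
        assert len(merged.modules) == 2

    def test_chain_merge_matches_independent_trace(self, rng):
        # A and B overlap strongly, C sits between; compare against a
        # stand-alone re-implementation of the iterative closest-pair rule
        f1 = rng.standard_normal(60)
        f2 = f1 + 0.35 * rng.standard_normal(60)
        f3 = f1 + 1.2 * rng.standard_normal(60)
        rows, labs = [], []
        for name, f in (("blue", f1), ("red", f2), ("green", f3)):
            for _ in range(6):
                rows.append(f + 0.05 * rng.standard_normal(60))
                labs.append(name)
        mat = make_expression(np.array(rows))
        labels = pd.Series(labs, index=mat.data.index)

        def trace_count(threshold):
            groups = {name: [p for p, l in labels.items() if l == name]
                      for name in ("blue", "red", "green")}
            while len(groups) > 1:
                names = sorted(groups)
                mes = {n: module_eigengene(mat, groups[n])[0] for n in names}
                best, pair = np.inf, None
                for i, a in enumerate(names):
                    for b in names[i + 1:]:
                        d = 1 - np.corrcoef(mes[a], mes[b])[0, 1]
                        if d < best - 1e-15:
                            best, pair = d, (a, b)
                if best >= threshold:
                    break
                a, b = pair
                keep, drop = (a, b) if len(groups[a]) > len(groups[b]) else (
                    (b, a) if len(groups[b]) > len(groups[a])
                    else tuple(sorted((a, b))))
                groups[keep] += groups.pop(drop)
            return len(groups)

        decomp = decompose(mat, labels, min_module_size=3)
        merged = merge_close_modules(decomp, mat, merge_threshold=0.4)
        assert len(merged.modules) == trace_count(0.4)


class TestGSandMM:
    def test_probe_equal_to_trait_has_unit_gs(self, rng):
        x = rng.standard_normal(15)
        mat = make_expression([x, rng.standard_normal(15)])
        ph = PhenotypeTable(pd.DataFrame({"t": x}, index=mat.sample_ids))
        gs = gene_significance(mat, ph)
        assert gs.loc["g0", "t"] == pytest.approx(1.0)

    def test_gs_invariant_to_probe_sign_flip(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        ph = PhenotypeTable(pd.DataFrame(
            {"t": y}, index=[f"s{j}" for j in range(15)]))
        g1 = gene_significance(make_expression([x]), ph)
        g2 = gene_significance(make_expression([-x]), ph)
        assert g1.iloc[0, 0] == pytest.approx(g2.iloc[0, 0])

    def test_mm_is_signed_and_unit_for_rank_one_module(self, rng):
        f = rng.standard_normal(25)
        mat = make_expression([f, 2 * f, -f])
        labels = pd.Series(["blue"] * 3, index=mat.data.index)
        decomp = decompose(mat, labels, min_module_size=2)
        mm = module_membership(mat, decomp)
        np.testing.assert_allclose(np.abs(mm["blue"]), 1.0, atol=1e-10)
        assert mm.loc["g2", "blue"] == pytest.approx(
            -mm.loc["g0", "blue"], abs=1e-10)

    def test_own_module_mm_dominates_in_noiseless_case(self, rng):
        mat, labels = _block_matrix(rng, [8, 8], noise=1e-6)
        lab = pd.Series(np.where(labels == 0, "blue", "red"),
                        index=mat.data.index)
        decomp = decompose(mat, lab, min_module_size=4)
        mm = module_membership(mat, decomp)
        own = np.abs(mm.to_numpy()[np.arange(16), (labels != 0).astype(int) *
                                   (list(decomp.modules).index("red")
                                    if "red" in decomp.modules else 0)])
        for i in range(16):
            mine = lab.iloc[i]
            other = [m for m in decomp.modules if m != mine]
            assert abs(mm.iloc[i][mine]) >= max(
                abs(mm.iloc[i][o]) for o in other)
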