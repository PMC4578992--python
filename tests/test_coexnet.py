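"""Co-expression network core: adjacency, TOM, modules, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest

from lncbcell.coexnet import (
    NetworkConfig,
    adjacency,
    detect_modules,
    export_edges,
    intramodular_connectivity,
    merge_modules,
    module_eigengene,
    pick_soft_threshold,
    tom,
    top_hubs,
)


def _df(x, prefix="g"):
    ids = [f"{prefix}{i}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=ids, columns=[f"s{j}" for j in range(x.shape[1])])


class TestAdjacency:
    def test_perfect_correlation_is_one(self):
        x = _df(np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]]))
        a = adjacency(x, NetworkConfig(beta=6))
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_pair_is_zero(self):
        x = _df(np.array([[1.0, -1, 1, -1], [1.0, 1, -1, -1]]))
        a = adjacency(x, NetworkConfig(beta=6))
        assert a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        x = _df(rng.normal(size=(10, 8)))
        a = adjacency(x, NetworkConfig(beta=6)).to_numpy()
        for i in range(10):
            for j in range(10):
                r = np.corrcoef(x.iloc[i], x.iloc[j])[0, 1]
                expected = 1.0 if i == j else abs(r) ** 6
                assert abs(a[i, j] - expected) < 1e-12

    def test_signed_network(self, rng):
        x = _df(rng.normal(size=(6, 8)))
        a = adjacency(x, NetworkConfig(network_type="signed", beta=2)).to_numpy()
        r = np.corrcoef(x.to_numpy())
        expected = ((1 + r) / 2) ** 2
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(a, expected, atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        x = _df(np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4]]))
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(x, NetworkConfig())


def _tom_oracle(A):
    n = A.shape[0]
    out = np.eye(n)
    k = A.sum(axis=1) - 1
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


class TestTom:
    def test_complete_graph(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        assert np.allclose(tom(a).to_numpy(), 1.0)

    def test_empty_graph(self):
        a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        t = tom(a).to_numpy()
        assert np.allclose(t - np.eye(4), 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for n in (8, 20):
            r = rng.uniform(0, 1, size=(n, n))
            A = (r + r.T) / 2
            np.fill_diagonal(A, 1.0)
            labels = [f"g{i}" for i in range(n)]
            t = tom(pd.DataFrame(A, index=labels, columns=labels)).to_numpy()
            expected = _tom_oracle(A)
            assert np.abs(t - expected).max() < 1e-12
            assert t.min() >= 0 and t.max() <= 1
            assert np.allclose(t, t.T)

    def test_asymmetric_rejected(self):
        a = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            tom(a)


class TestSoftThreshold:
    def test_single_candidate_returned(self, rng):
        x = _df(rng.normal(size=(40, 10)))
        beta, table = pick_soft_threshold(x, NetworkConfig(candidate_betas=(6,)))
        assert beta == 6
        assert list(table["beta"]) == [6]

    def test_modular_data_reaches_target(self, default_pipeline_report):
        net = default_pipeline_report["objects"]["net_expr"]
        beta, table = pick_soft_threshold(net, NetworkConfig())
        assert table.loc[table["beta"] == beta, "r2"].iloc[0] >= 0.8

    def test_small_input_falls_back_with_warning(self, rng):
        x = _df(rng.normal(size=(10, 6)))
        with pytest.warns(UserWarning, match="fewer than 30"):
            beta, _ = pick_soft_threshold(x, NetworkConfig())
        assert beta == 6

    def test_pure_noise_returns_argmax(self, rng):
        x = _df(rng.normal(size=(60, 8)))
        beta, table = pick_soft_threshold(
            x, NetworkConfig(candidate_betas=(1, 2), scale_free_r2_target=0.999)
        )
        assert beta == int(table.loc[table["r2"].idxmax(), "beta"])


def _block_adjacency(sizes, within=0.9, between=0.05):
    n = sum(sizes)
    A = np.full((n, n), between)
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(A, 1.0)
    labels = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(A, index=labels, columns=labels)


class TestDetectModules:
    def test_two_planted_blocks_recovered_with_color_order(self):
        a = _block_adjacency([40, 35])
        omega = tom(a)
        labels, _ = detect_modules(omega, NetworkConfig(min_module_size=30))
        assert set(labels) == {"turquoise", "blue"}
        assert (labels.iloc[:40] == "turquoise").all()  # larger block first
        assert (labels.iloc[40:] == "blue").all()

    def test_min_size_above_n_gives_all_grey(self):
        a = _block_adjacency([10, 10])
        with pytest.warns(UserWarning, match="no module"):
            labels, _ = detect_modules(tom(a), NetworkConfig(min_module_size=50))
        assert (labels == "grey").all()

    def test_default_synthetic_recovery(self, default_pipeline_report):
        from sklearn.metrics import adjusted_rand_score

        obj = default_pipeline_report["objects"]
        planted = pd.Series(obj["truth"].gene_module).reindex(obj["assignment"].index)
        assert adjusted_rand_score(planted, obj["assignment"]) >= 0.9


class TestEigengene:
    def test_affinely_identical_genes(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = _df(np.vstack([base, 2 * base + 1, 0.5 * base - 3]))
        assignment = pd.Series("turquoise", index=x.index)
        eig = module_eigengene(x, assignment)["turquoise"]
        assert eig.variance_explained == pytest.approx(1.0)
        z = (base - base.mean()) / base.std(ddof=1)
        r = np.corrcoef(eig.values, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented along the mean member profile

    def test_two_anticorrelated_genes_defined(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = _df(np.vstack([base, -base]))
        eig = module_eigengene(x, pd.Series("blue", index=x.index))["blue"]
        assert eig.variance_explained == pytest.approx(1.0)
        assert np.isfinite(eig.values).all()

    def test_variance_explained_matches_eigen_oracle(self, rng):
        x = _df(rng.normal(size=(20, 12)))
        eig = module_eigengene(x, pd.Series("brown", index=x.index))["brown"]
        z = x.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)
        assert eig.variance_explained == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)


class TestMergeModules:
    def _expr_two_modules(self, rng, rho):
        base = rng.normal(size=10)
        other = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=10)
        rows = [base + rng.normal(0, 0.01, 10) for _ in range(5)]
        rows += [other + rng.normal(0, 0.01, 10) for _ in range(5)]
        x = _df(np.vstack(rows))
        assignment = pd.Series(["turquoise"] * 5 + ["blue"] * 5, index=x.index)
        return x, assignment

    def test_near_identical_eigengenes_merged(self, rng):
        x, assignment = self._expr_two_modules(rng, 0.999)
        merged, eigs = merge_modules(x, assignment, merge_height=0.25)
        assert merged.nunique() == 1

    def test_orthogonal_eigengenes_not_merged(self, rng):
        x, assignment = self._expr_two_modules(rng, 0.0)
        merged, _ = merge_modules(x, assignment, merge_height=0.25)
        assert merged.nunique() == 2

    def test_zero_height_changes_nothing(self, rng):
        x, assignment = self._expr_two_modules(rng, 0.9)
        merged, _ = merge_modules(x, assignment, merge_height=0.0)
        assert (merged == assignment).all()


class TestConnectivityAndEdges:
    def test_complete_triangle_kwithin(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        assignment = pd.Series("turquoise", index=list("abc"))
        k = intramodular_connectivity(a, assignment)
        assert np.allclose(k, 2.0)

    def test_masked_row_sum_oracle(self, rng):
        n = 12
        r = rng.uniform(0, 1, size=(n, n))
        A = (r + r.T) / 2
        np.fill_diagonal(A, 1.0)
        labels = [f"g{i}" for i in range(n)]
        a = pd.DataFrame(A, index=labels, columns=labels)
        assignment = pd.Series(["turquoise"] * 5 + ["blue"] * 4 + ["grey"] * 3, index=labels)
        k = intramodular_connectivity(a, assignment)
        for i, g in enumerate(labels):
            expected = sum(
                A[i, j]
                for j, h in enumerate(labels)
                if j != i and assignment[h] == assignment[g]
            )
            assert abs(k[g] - expected) < 1e-12

    def test_top_hubs_ties_by_gene_id(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("cab"), columns=list("cab"))
        assignment = pd.Series("m", index=list("cab"))
        k = intramodular_connectivity(a, assignment)
        assert top_hubs(k, assignment, "m", n=2) == ["a", "b"]

    def test_edge_export_counts(self, rng):
        n = 4
        r = rng.uniform(0, 0.9, size=(n, n))
        A = (r + r.T) / 2
        np.fill_diagonal(A, 1.0)
        labels = list("abcd")
        a = pd.DataFrame(A, index=labels, columns=labels)
        assignment = pd.Series("m", index=labels)
        with pytest.warns(UserWarning, match="empty"):
            assert len(export_edges(a, assignment, threshold=1.0)) == 0
        assert len(export_edges(a, assignment, top_fraction=1.0)) == 6
        assert len(export_edges(a, assignment, threshold=0.0)) == 6

    def test_exactly_one_selection_mode(self):
        a = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            export_edges(a, pd.Series("m", index=list("ab")))


def test_eigengene_recovery_on_default_synthetic(default_pipeline_report):
    obj = default_pipeline_report["objects"]
    truth, assignment = obj["truth"], obj["assignment"]
    planted = pd.Series(truth.gene_module).reindex(assignment.index)
    eig = truth.planted_eigengenes
    for module, e in obj["eigengenes"].items():
        counterpart = planted[assignment == module].value_counts().idxmax()
        r = np.corrcoef(e.values.reindex(eig.columns), eig.loc[counterpart])[0, 1]
        assert abs(r) >= 0.9
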