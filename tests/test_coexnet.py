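import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from modrep import coexnet
from modrep.coexnet import BACKGROUND, NetworkConfig
from modrep.counts_io import ValidationError


def _blocks(rng, sizes, n_samples, noise=0.5, loading=1.0):
    rows, truth = [], []
    for b, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        rows.append(loading * f[None, :] + noise * rng.normal(size=(size, n_samples)))
        truth += [b] * size
    X = np.vstack(rows)
    genes = [f"g{i}" for i in range(X.shape[0])]
    return (
        pd.DataFrame(X, index=genes, columns=[f"s{j}" for j in range(n_samples)]),
        truth,
    )


class TestCorrelation:
    def test_duplicated_gene_correlation_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        vsd = pd.DataFrame([x, x], index=["a", "b"], columns=[f"s{i}" for i in range(20)])
        cor = coexnet.correlation_matrix(vsd)
        assert cor.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        vsd = pd.DataFrame([x, -x], index=["a", "b"],
                           columns=[f"s{i}" for i in range(20)])
        assert coexnet.correlation_matrix(vsd).loc["a", "b"] == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        vsd = pd.DataFrame([x, np.exp(x)], index=["a", "b"],
                           columns=[f"s{i}" for i in range(25)])
        assert coexnet.correlation_matrix(vsd).loc["a", "b"] == pytest.approx(1.0)

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        vsd = pd.DataFrame(
            [rng.normal(size=10), np.zeros(10), rng.normal(size=10)],
            index=["a", "flat", "b"], columns=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="constant"):
            cor = coexnet.correlation_matrix(vsd)
        assert "flat" not in cor.index

    def test_too_few_samples(self):
        vsd = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValidationError, match="4 samples"):
            coexnet.correlation_matrix(vsd)


class TestAdjacency:
    @pytest.mark.parametrize(
        "c,expected", [(0.5, 0.015625), (-0.5, 0.015625), (1.0, 1.0), (0.0, 0.0)]
    )
    def test_powers(self, c, expected):
        cor = pd.DataFrame([[1.0, c], [c, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = coexnet.adjacency(cor, power=6.0)
        assert adj.loc["a", "b"] == pytest.approx(expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        vsd, _ = _blocks(rng, [10, 10], 30)
        cor = coexnet.correlation_matrix(vsd)
        adj = coexnet.adjacency(cor, 6)
        perm = rng.permutation(vsd.index)
        adj_p = coexnet.adjacency(coexnet.correlation_matrix(vsd.loc[perm]), 6)
        assert np.allclose(adj.loc[perm, perm].to_numpy(), adj_p.to_numpy())


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        # expected-degree (Chung-Lu style) adjacency whose row sums follow the
        # planted power-law sequence
        rng = np.random.default_rng(5)
        n = 300
        k = (1.0 + rng.pareto(2.0, size=n)) * 2
        k = np.sort(k)
        a = np.minimum(np.outer(k, k) / k.sum(), 1.0)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        assert coexnet.scale_free_fit(adj) > 0.9

    def test_equal_degrees_nan(self):
        n = 30
        a = np.full((n, n), 0.2)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        assert np.isnan(coexnet.scale_free_fit(adj))

    def test_beta_sweep_trend_on_module_data(self):
        rng = np.random.default_rng(6)
        vsd, _ = _blocks(rng, [40, 40], 30, noise=0.7)
        noise = pd.DataFrame(
            rng.normal(size=(120, 30)), index=[f"n{i}" for i in range(120)],
            columns=vsd.columns,
        )
        both = pd.concat([vsd, noise])
        cor = coexnet.correlation_matrix(both)
        r2 = [coexnet.scale_free_fit(coexnet.adjacency(cor, b)) for b in (1, 6)]
        assert r2[1] > r2[0]


class TestDetectModules:
    def test_two_planted_blocks(self):
        rng = np.random.default_rng(7)
        vsd, truth = _blocks(rng, [50, 50], 40)
        adj = coexnet.adjacency(coexnet.correlation_matrix(vsd), 6)
        assign = coexnet.detect_modules(adj, NetworkConfig(), vsd=vsd)
        assert len(assign.module_labels) == 2
        assert adjusted_rand_score(truth, list(assign.labels)) >= 0.9

    def test_pure_noise_mostly_background(self):
        rng = np.random.default_rng(8)
        vsd = pd.DataFrame(
            rng.normal(size=(300, 25)), index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(25)],
        )
        adj = coexnet.adjacency(coexnet.correlation_matrix(vsd), 6)
        assign = coexnet.detect_modules(adj, NetworkConfig(), vsd=vsd)
        assert (assign.labels == BACKGROUND).mean() >= 0.9

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        vsd, _ = _blocks(rng, [40, 40], 35)
        adj = coexnet.adjacency(coexnet.correlation_matrix(vsd), 6)
        a1 = coexnet.detect_modules(adj, NetworkConfig())
        perm = list(rng.permutation(vsd.index))
        adj_p = adj.loc[perm, perm]
        a2 = coexnet.detect_modules(adj_p, NetworkConfig())
        joined = pd.concat([a1.labels, a2.labels.reindex(a1.labels.index)], axis=1)
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_all_background(self):
        rng = np.random.default_rng(10)
        vsd, _ = _blocks(rng, [10], 20)
        adj = coexnet.adjacency(coexnet.correlation_matrix(vsd), 6)
        assign = coexnet.detect_modules(adj, NetworkConfig(min_module_size=30))
        assert (assign.labels == BACKGROUND).all()


class TestEigengene:
    def test_identical_genes_recover_common_profile(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        vsd = pd.DataFrame([x, x, x], index=["a", "b", "c"],
                           columns=[f"s{i}" for i in range(30)])
        eig = coexnet.module_eigengene(vsd, ["a", "b", "c"])
        z = (x - x.mean()) / x.std()
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        assert np.dot(eig, z) > 0  # oriented with the mean profile

    def test_scaling_invariance(self):
        rng = np.random.default_rng(12)
        vsd, _ = _blocks(rng, [10], 25)
        e1 = coexnet.module_eigengene(vsd, list(vsd.index))
        e2 = coexnet.module_eigengene(vsd * 2.0, list(vsd.index))
        assert np.allclose(e1, e2, atol=1e-10)

    def test_unit_norm(self):
        rng = np.random.default_rng(13)
        vsd, _ = _blocks(rng, [15], 20)
        eig = coexnet.module_eigengene(vsd, list(vsd.index))
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_anticorrelated_halves_deterministic_orientation(self):
        rng = np.random.default_rng(14)
        f = rng.normal(size=30)
        up = f[None, :] + 0.1 * rng.normal(size=(10, 30))
        down = -f[None, :] + 0.1 * rng.normal(size=(10, 30))
        vsd = pd.DataFrame(np.vstack([up, down]),
                           index=[f"g{i}" for i in range(20)],
                           columns=[f"s{j}" for j in range(30)])
        e1 = coexnet.module_eigengene(vsd, list(vsd.index))
        e2 = coexnet.module_eigengene(vsd.copy(), list(vsd.index))
        assert np.allclose(e1, e2)
        assert abs(np.corrcoef(e1, f)[0, 1]) > 0.95

    def test_too_small_module_rejected(self):
        vsd = pd.DataFrame(np.ones((2, 5)), index=["a", "b"],
                           columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            coexnet.module_eigengene(vsd, ["a"])


class TestConnectivity:
    def _assignment(self, labels):
        s = pd.Series(labels)
        return coexnet.ModuleAssignment(s)

    def test_affine_map_to_unit_interval(self):
        genes = ["a", "b", "c"]
        a = np.array([[1.0, 0.5, 1.5], [0.5, 1.0, 4.5], [1.5, 4.5, 1.0]])
        adj = pd.DataFrame(a, index=genes, columns=genes)
        conn = coexnet.connectivity(adj, self._assignment({g: "M1" for g in genes}))
        k_raw = conn["k_raw"].sort_values()
        expected_norm = (k_raw - k_raw.min()) / (k_raw.max() - k_raw.min())
        assert np.allclose(conn.loc[k_raw.index, "k_norm"], expected_norm)
        assert conn["k_norm"].min() == 0.0 and conn["k_norm"].max() == 1.0

    def test_known_values(self):
        genes = ["a", "b", "c"]
        # k_raw: a=0.1+0.9=1.0, b=0.1+0.4=0.5, c=0.9+0.4=1.3
        a = np.array([[1.0, 0.1, 0.9], [0.1, 1.0, 0.4], [0.9, 0.4, 1.0]])
        adj = pd.DataFrame(a, index=genes, columns=genes)
        conn = coexnet.connectivity(adj, self._assignment({g: "M1" for g in genes}))
        assert conn.loc["b", "k_norm"] == pytest.approx(0.0)
        assert conn.loc["c", "k_norm"] == pytest.approx(1.0)
        assert conn.loc["a", "k_norm"] == pytest.approx((1.0 - 0.5) / 0.8)

    def test_all_equal_maps_to_zero(self):
        genes = ["a", "b", "c"]
        a = np.full((3, 3), 0.3)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=genes, columns=genes)
        conn = coexnet.connectivity(adj, self._assignment({g: "M1" for g in genes}))
        assert (conn["k_norm"] == 0.0).all()

    def test_planted_hub_attains_max(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(20):
            f = rng.normal(size=40)
            loadings = np.full(30, 0.6)
            loadings[0] = 0.95
            noise = rng.normal(size=(30, 40)) * np.sqrt(1 - loadings**2)[:, None]
            X = loadings[:, None] * f[None, :] + noise
            vsd = pd.DataFrame(X, index=[f"g{i}" for i in range(30)],
                               columns=[f"s{j}" for j in range(40)])
            adj = coexnet.adjacency(coexnet.correlation_matrix(vsd), 6)
            conn = coexnet.connectivity(
                adj, self._assignment({g: "M1" for g in vsd.index})
            )
            if conn.loc["g0", "k_norm"] == 1.0:
                hits += 1
        assert hits >= 18

    def test_single_gene_module_excluded_with_warning(self):
        genes = ["a", "b", "c"]
        a = np.full((3, 3), 0.3)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=genes, columns=genes)
        with pytest.warns(UserWarning, match="< 2 genes"):
            conn = coexnet.connectivity(
                adj, self._assignment({"a": "M1", "b": "M1", "c": "M2"})
            )
        assert "c" not in conn.index
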