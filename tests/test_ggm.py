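"""GGM estimation: residualisation, shrinkage pcor, edges, subnetworks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from glyconet import simulate as sim
from glyconet.ggm import (
    ShrinkagePartialCorrelation,
    Subnetwork,
    call_edges,
    export_graphml,
    export_sif,
    filter_and_extract,
    partial_correlations_from_correlation,
    residualize,
    shrinkage_intensity,
)


def brute_force_pcor(X: np.ndarray) -> np.ndarray:
    """Independent oracle: correlate residuals after regressing each pair
    on all remaining variables (with intercept)."""
    n, p = X.shape
    out = np.eye(p)
    for i, j in itertools.combinations(range(p), 2):
        others = [k for k in range(p) if k not in (i, j)]
        Z = np.column_stack([np.ones(n), X[:, others]])
        ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
        rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
        out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestResidualize:
    def test_measure_equal_to_covariate_zeroed(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"age": rng.uniform(20, 70, 40)})
        data = pd.DataFrame({"m": cov["age"].to_numpy()})
        resid = residualize(data, cov)
        assert np.allclose(resid["m"], 0.0, atol=1e-10)

    def test_covariate_free_call_centres(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(5, 2, (30, 3)))
        resid = residualize(data, pd.DataFrame(index=data.index))
        assert np.allclose(resid.to_numpy(), data - data.mean(), atol=1e-10)

    def test_refit_after_residualisation_is_zero(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame({"bmi": rng.uniform(20, 40, 200)})
        y = 2.0 * cov["bmi"] + rng.normal(0, 1, 200)
        resid = residualize(pd.DataFrame({"m": y}), cov)
        X = np.column_stack([np.ones(200), cov["bmi"]])
        beta = np.linalg.lstsq(X, resid["m"], rcond=None)[0]
        assert abs(beta[1]) < 1e-10

    def test_orthogonality_to_covariates(self):
        rng = np.random.default_rng(3)
        cov = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        data = pd.DataFrame(rng.normal(size=(100, 5)))
        resid = residualize(data, cov)
        inner = np.abs(cov.to_numpy().T @ resid.to_numpy())
        assert inner.max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"a": rng.normal(size=20)})
        cov["b"] = 2.0 * cov["a"]
        with pytest.raises(ValueError, match="collinear"):
            residualize(pd.DataFrame({"m": rng.normal(size=20)}), cov)


class TestShrinkagePcor:
    def test_trivariate_closed_form(self):
        R = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        P = partial_correlations_from_correlation(R)
        expected = (0.6 - 0.3 * 0.5) / np.sqrt((1 - 0.09) * (1 - 0.25))
        assert abs(P[0, 1] - expected) < 1e-12

    def test_oracle_equivalence_unshrunk(self):
        """Inverse-correlation route equals residual brute force at λ=0."""
        rng = np.random.default_rng(5)
        for p in (3, 6, 10):
            X = rng.standard_normal((80, p))
            est = ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
            assert np.abs(est.pcor_ - brute_force_pcor(X)).max() < 1e-10

    def test_full_shrinkage_zeroes_offdiagonal(self):
        X = np.random.default_rng(6).standard_normal((50, 8))
        est = ShrinkagePartialCorrelation(shrinkage=1.0).fit(X)
        off = est.pcor_[np.triu_indices(8, 1)]
        assert np.all(off == 0.0)
        assert (est.pvalues_[np.triu_indices(8, 1)] == 1.0).all()

    def test_independence_limit(self):
        X = np.random.default_rng(7).standard_normal((10000, 5))
        est = ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
        assert np.abs(est.pcor_[np.triu_indices(5, 1)]).max() < 0.1

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n, p = rng.integers(30, 80), rng.integers(3, 12)
            X = rng.standard_normal((int(n), int(p))) @ rng.normal(
                size=(int(p), int(p))
            )
            est = ShrinkagePartialCorrelation().fit(X)
            assert np.allclose(est.pcor_, est.pcor_.T)
            off = est.pcor_[np.triu_indices(int(p), 1)]
            assert np.all(np.abs(off) < 1.0)

    def test_monotone_lambda_p2_analytic(self):
        # for p=2 the partial correlation equals the shrunk correlation
        X = np.random.default_rng(9).multivariate_normal(
            [0, 0], [[1, 0.6], [0.6, 1]], size=500
        )
        r = np.corrcoef(X, rowvar=False)[0, 1]
        prev = 1.0
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            est = ShrinkagePartialCorrelation(shrinkage=lam).fit(X)
            assert np.isclose(est.pcor_[0, 1], (1 - lam) * r, atol=1e-12)
            assert abs(est.pcor_[0, 1]) <= prev + 1e-12
            prev = abs(est.pcor_[0, 1])

    def test_monotone_lambda_numeric(self):
        # individual entries need not shrink monotonically once p > 2 (the
        # conditioning set changes weight as λ grows), but the strongest
        # partial correlation contracts toward the identity target
        X = np.random.default_rng(10).standard_normal((200, 5)) @ np.linalg.cholesky(
            np.eye(5) * 0.5 + 0.5
        )
        maxima = []
        for lam in np.linspace(0.0, 1.0, 11):
            est = ShrinkagePartialCorrelation(shrinkage=lam).fit(X)
            maxima.append(np.abs(est.pcor_[np.triu_indices(5, 1)]).max())
        for a, b in zip(maxima, maxima[1:]):
            assert b <= a + 1e-9
        assert maxima[-1] == 0.0

    def test_parameter_recovery(self):
        truth = sim.generate_network_truth(10, 0.2, (0.3, 0.5), seed=3)
        chol = np.linalg.cholesky(truth.correlation())
        X = np.random.default_rng(11).standard_normal((5000, 10)) @ chol.T
        est = ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
        assert np.abs(est.pcor_ - truth.pcor).max() < 0.05

    def test_analytic_lambda_null_data_near_one(self):
        X = np.random.default_rng(12).standard_normal((40, 200))
        assert shrinkage_intensity(X) > 0.8

    def test_constant_column_rejected(self):
        X = np.ones((30, 3))
        X[:, 1:] = np.random.default_rng(13).standard_normal((30, 2))
        with pytest.raises(ValueError, match="constant"):
            ShrinkagePartialCorrelation().fit(X)

    def test_unshrunk_singular_raises(self):
        X = np.random.default_rng(14).standard_normal((10, 20))
        with pytest.raises(np.linalg.LinAlgError):
            ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)


class TestPvaluesAndEdges:
    def test_zero_pcor_gives_p_one(self):
        X = np.random.default_rng(15).standard_normal((100, 4))
        est = ShrinkagePartialCorrelation(shrinkage=1.0).fit(X)
        assert (est.pvalues_[np.triu_indices(4, 1)] == 1.0).all()

    def test_pair_count_identity(self):
        X = np.random.default_rng(16).standard_normal((50, 12))
        est = ShrinkagePartialCorrelation().fit(X)
        assert est.n_pairs_ == 12 * 11 // 2
        assert (2178 * 2177) // 2 == 2370753

    def test_insufficient_n_effective_warns(self):
        X = np.random.default_rng(17).standard_normal((60, 4))
        with pytest.warns(UserWarning, match="effective sample size"):
            est = ShrinkagePartialCorrelation(n_effective=5, k_adjusted=10).fit(X)
        assert (est.pvalues_ == 1.0).all() or (np.diag(est.pvalues_) == 1.0).all()

    def test_all_p_one_gives_empty_edge_set(self):
        X = np.random.default_rng(18).standard_normal((60, 6))
        est = ShrinkagePartialCorrelation(shrinkage=1.0).fit(X)
        assert call_edges(est, 0.05).empty

    def test_chain_truth_recovered_exactly(self):
        p = 5
        omega = np.eye(p)
        for i in range(p - 1):
            omega[i, i + 1] = omega[i + 1, i] = -0.4
        lam_min = np.linalg.eigvalsh(omega)[0]
        assert lam_min > 0
        cov = np.linalg.inv(omega)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        X = np.random.default_rng(19).standard_normal((2000, p)) @ np.linalg.cholesky(corr).T
        est = ShrinkagePartialCorrelation().fit(X)
        edges = est.edges(0.05)
        called = {tuple(sorted((r.node_i, r.node_j))) for r in edges.itertuples()}
        expected = {(f"V{i}", f"V{i + 1}") for i in range(p - 1)}
        assert called == expected


class TestSubnetworks:
    def test_empty_nominal_set(self):
        edges = pd.DataFrame(
            {"node_i": ["a"], "node_j": ["b"], "pcor": [0.5], "p": [1e-10]}
        )
        assert filter_and_extract(edges, [], min_size=3) == []

    def test_triangle_kept_pair_dropped(self):
        edges = pd.DataFrame(
            {
                "node_i": ["a", "b", "c", "x"],
                "node_j": ["b", "c", "a", "y"],
                "pcor": [0.5] * 4,
                "p": [1e-10] * 4,
            }
        )
        subs = filter_and_extract(edges, ["a", "b", "c", "x", "y"], min_size=3)
        assert len(subs) == 1
        assert subs[0].nodes == ["a", "b", "c"]
        assert subs[0].size == 3

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(20)
        nodes = [f"n{i}" for i in range(40)]
        pairs = [
            (nodes[i], nodes[j])
            for i in range(40)
            for j in range(i + 1, 40)
            if rng.random() < 0.05
        ]
        edges = pd.DataFrame(
            {
                "node_i": [a for a, _ in pairs],
                "node_j": [b for _, b in pairs],
                "pcor": 0.3,
                "p": 1e-12,
            }
        )
        subs = filter_and_extract(edges, nodes, min_size=1)

        # union-find oracle
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        groups = {}
        for n in nodes:
            groups.setdefault(find(n), set()).add(n)
        oracle = sorted(frozenset(g) for g in groups.values() if g)
        got = sorted(frozenset(s.nodes) for s in subs)
        assert got == oracle

    def test_ordering_size_then_lexical(self):
        edges = pd.DataFrame(
            {
                "node_i": ["a", "b", "p", "x", "y"],
                "node_j": ["b", "c", "q", "y", "z"],
                "pcor": 0.4,
                "p": 1e-12,
            }
        )
        subs = filter_and_extract(
            edges, ["a", "b", "c", "p", "q", "x", "y", "z"], min_size=2
        )
        assert [s.nodes for s in subs] == [["a", "b", "c"], ["x", "y", "z"], ["p", "q"]]
        assert [s.component_id for s in subs] == [1, 2, 3]

    def test_exports_are_readable_text(self, tmp_path):
        edges = pd.DataFrame(
            {"node_i": ["a", "b"], "node_j": ["b", "c"], "pcor": [0.4, -0.2],
             "p": [1e-9, 1e-8]}
        )
        attrs = pd.DataFrame(
            {"fluid": ["urine", "plasma", "saliva"], "beta": [0.5, -0.1, np.nan]},
            index=["a", "b", "c"],
        )
        gpath, spath = tmp_path / "net.graphml", tmp_path / "net.sif"
        export_graphml(edges, gpath, attrs)
        export_sif(edges, spath)
        g = nx.read_graphml(gpath)
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.edges[("a", "b")]["pcor"] == pytest.approx(0.4)
        lines = spath.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["a", "pcor", "b"]
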