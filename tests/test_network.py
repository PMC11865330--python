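"""Network construction, RMT thresholding, modules, Zi-Pi roles, topology."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import acidonet as an
from acidonet.network import spacing_statistics


def planted_block_matrix(rng, n_blocks=5, block_size=20, within=(0.6, 0.95),
                         between=0.28):
    """Constructed correlation matrix: strong blocks, weak between-block.

    Between-block magnitudes stay below ``between`` and within-block values
    above ``within[0]``, so a correctly selected threshold must fall in the
    gap: all between-block edges gone, all blocks still internally connected.
    """
    n = n_blocks * block_size
    m = rng.uniform(-between, between, (n, n))
    m = (m + m.T) / 2
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        w = rng.uniform(*within, (block_size, block_size))
        m[sl, sl] = (w + w.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class TestPrevalenceFilter:
    def test_boundary_half(self):
        counts = pd.DataFrame(
            {f"S{j}": [1 if j < 18 else 0, 1 if j < 17 else 0, 1]
             for j in range(36)},
            index=["half", "under", "full"],
        )
        table = an.AbundanceTable(counts)
        kept = an.prevalence_filter(table, 0.5)
        assert list(kept.taxa) == ["half", "full"]

    def test_min_frac_zero_is_identity(self, tiny_table):
        assert list(an.prevalence_filter(tiny_table, 0.0).taxa) == list(tiny_table.taxa)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, tiny_table):
        r = an.correlation_matrix(tiny_table)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.values, r.values.T)

    def test_exact_multiple_gives_unit_correlation(self):
        base = np.array([3, 7, 11, 2, 9], dtype=float)
        counts = pd.DataFrame(
            {f"S{j}": [base[j], 2 * base[j], 40 - base[j]] for j in range(5)},
            index=["a", "a2", "b"],
        )
        r = an.correlation_matrix(an.AbundanceTable(counts))
        assert r.loc["a", "a2"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_taxon_fixture(self):
        counts = pd.DataFrame(
            {"S1": [1.0, 2.0, 4.0], "S2": [2.0, 4.0, 2.0],
             "S3": [4.0, 8.0, 1.0], "S4": [8.0, 16.0, 0.5]},
            index=["x", "y", "z"],
        )
        r = an.correlation_matrix(an.AbundanceTable(counts))
        # independent check on log relative abundances
        rel = counts / counts.sum(axis=0)
        logged = np.log(rel.to_numpy())
        expected = np.corrcoef(logged)
        assert np.allclose(r.values, expected, atol=1e-12)

    def test_constant_taxon_flagged_zero(self):
        counts = pd.DataFrame(
            {"S1": [5, 1], "S2": [5, 2], "S3": [5, 3], "S4": [5, 4]},
            index=["const_counts", "var"],
        )
        # constant relative abundance requires constant share, not counts:
        counts.loc["const_counts"] = counts.loc["var"].to_numpy()[::-1] * 0 + 7
        table = an.AbundanceTable(counts)
        r = an.correlation_matrix(table)
        assert np.isfinite(r.values).all()


class TestRmtThreshold:
    def test_noise_matrix_is_wigner_like_unthresholded(self):
        rng = np.random.default_rng(1)
        r = np.corrcoef(rng.normal(size=(100, 50)))
        st = spacing_statistics(r, 0.0)
        assert st["chi2_wigner"] < st["chi2_poisson"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_blocks_isolated(self, seed):
        m = planted_block_matrix(np.random.default_rng(seed))
        thr, diag = an.select_rmt_threshold(pd.DataFrame(m))
        assert diag.attrs["flag"] == "ok"
        n_blocks, bs = 5, 20
        between = np.ones(m.shape, bool)
        for b in range(n_blocks):
            between[b * bs:(b + 1) * bs, b * bs:(b + 1) * bs] = False
        assert not (np.abs(m) >= thr)[between].any(), "between-block edges remain"
        assert thr < 0.6, "threshold should retain within-block edges"

    def test_identity_matrix_degenerate(self):
        thr, diag = an.select_rmt_threshold(pd.DataFrame(np.eye(60)))
        assert diag.attrs["flag"] == "no-transition"
        assert thr == pytest.approx(0.99)

    def test_small_matrix_falls_back(self):
        with pytest.warns(UserWarning, match="falling back"):
            thr, diag = an.select_rmt_threshold(pd.DataFrame(np.eye(10)), fallback=0.7)
        assert thr == 0.7 and diag.attrs["flag"] == "too-small"


class TestBuildNetwork:
    def test_edge_inclusion_boundary(self):
        r = pd.DataFrame(
            [[1.0, 0.8, -0.69], [0.8, 1.0, 0.1], [-0.69, 0.1, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        g = an.build_network(r, 0.7)
        assert g.has_edge("a", "b") and g["a"]["b"]["weight"] == pytest.approx(0.8)
        assert not g.has_edge("a", "c")
        assert "c" not in g  # isolated and dropped
        assert g.graph["n_isolated"] == 1

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 20))
        r = pd.DataFrame(np.corrcoef(x))
        for t in (0.3, 0.5, 0.7):
            g = an.build_network(r, t)
            mat = r.to_numpy()
            brute = sum(
                1 for i in range(30) for j in range(i + 1, 30)
                if abs(mat[i, j]) >= t
            )
            assert g.number_of_edges() == brute

    def test_edges_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        r = pd.DataFrame(np.corrcoef(rng.normal(size=(40, 25))))
        counts = [an.build_network(r, t).number_of_edges()
                  for t in (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_result_not_exception(self):
        r = pd.DataFrame(np.eye(5))
        g = an.build_network(r, 0.9)
        assert g.number_of_nodes() == 0


def two_cliques_graph():
    g = nx.Graph()
    for offset in (0, 5):
        for i, j in itertools.combinations(range(offset, offset + 5), 2):
            g.add_edge(i, j, weight=0.9, sign=1)
    g.add_edge(0, 5, weight=0.8, sign=1)
    return g


class TestModulesAndRoles:
    def test_two_cliques_two_modules(self):
        part, q = an.detect_modules(two_cliques_graph())
        assert len(set(part.values())) == 2
        assert q > 0.3

    def test_partition_beats_random_shuffles(self):
        g = two_cliques_graph()
        part, q = an.detect_modules(g)
        comms = {}
        for v, m in part.items():
            comms.setdefault(m, set()).add(v)
        rng = np.random.default_rng(0)
        nodes = list(g.nodes)
        sizes = [len(c) for c in comms.values()]
        for _ in range(100):
            perm = rng.permutation(nodes)
            shuffled, k = [], 0
            for s in sizes:
                shuffled.append(set(perm[k:k + s]))
                k += s
            q_rand = nx.community.modularity(g, shuffled, weight="weight")
            assert q >= q_rand

    def test_disconnected_components_do_not_share_modules(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9, sign=1)
        g.add_edge("c", "d", weight=0.9, sign=1)
        part, _ = an.detect_modules(g)
        assert part["a"] == part["b"] and part["c"] == part["d"]
        assert part["a"] != part["c"]

    def test_pi_hand_values(self):
        g = nx.Graph()
        # hub h with 4 links split 2/2 across two modules
        for n, m in [("a", 0), ("b", 0), ("c", 1), ("d", 1)]:
            g.add_edge("h", n, weight=0.8, sign=1)
        g.add_edge("a", "b", weight=0.8, sign=1)
        g.add_edge("c", "d", weight=0.8, sign=1)
        part = {"h": 0, "a": 0, "b": 0, "c": 1, "d": 1}
        roles = an.compute_zipi(g, part)
        assert roles.loc["h", "Pi"] == pytest.approx(0.5)
        assert roles.loc["a", "Pi"] == pytest.approx(0.0)  # all links within module

    def test_role_rule(self):
        assert an.role_from_zipi(1.0, 0.70) == "connector"
        assert an.role_from_zipi(3.0, 0.1) == "module hub"
        assert an.role_from_zipi(3.0, 0.70) == "network hub"
        assert an.role_from_zipi(0.0, 0.0) == "peripheral"

    def test_zi_standardized_within_modules(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.2, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.8
            g[u][v]["sign"] = 1
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
        part, _ = an.detect_modules(g)
        roles = an.compute_zipi(g, part)
        for m, grp in roles.groupby("module"):
            if grp["Zi"].std(ddof=0) > 0:
                assert abs(grp["Zi"].mean()) < 1e-9
                assert grp["Zi"].std(ddof=0) == pytest.approx(1.0)
            m_count = roles["module"].nunique()
            assert ((grp["Pi"] >= 0) & (grp["Pi"] <= 1 - 1 / m_count + 1e-9)).all()

    def test_partition_must_cover_nodes(self):
        g = two_cliques_graph()
        with pytest.raises(ValueError):
            an.compute_zipi(g, {0: 0})


class TestTopology:
    def test_triangle(self):
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (0, 2)]:
            g.add_edge(u, v, weight=0.9, sign=1)
        top = an.topology_summary(g)
        assert top["clustering"] == pytest.approx(1.0)
        assert top["mean_path_largest_component"] == pytest.approx(1.0)
        assert top["positive_edge_fraction"] == 1.0

    def test_star_hub_degree(self):
        g = nx.star_graph(18)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.8
            g[u][v]["sign"] = 1
        top = an.topology_summary(g)
        assert len(top["neighbors"][0]) == 18
        assert top["mean_degree"] == pytest.approx(2 * 18 / 19)

    def test_indices_match_brute_force_small_graphs(self):
        rng = np.random.default_rng(2)
        for rep in range(20):
            g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(1e6)))
            g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
            if g.number_of_nodes() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(-1, 1))
                g[u][v]["sign"] = 1 if g[u][v]["weight"] > 0 else -1
            top = an.topology_summary(g)
            n, m = g.number_of_nodes(), g.number_of_edges()
            assert top["n_nodes"] == n and top["n_edges"] == m
            assert top["mean_degree"] == pytest.approx(
                sum(dict(g.degree).values()) / n
            )
            pos = sum(1 for *_, d in g.edges(data=True) if d["weight"] > 0)
            if m:
                assert top["positive_edge_fraction"] == pytest.approx(pos / m)
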