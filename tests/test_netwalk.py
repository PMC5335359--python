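"""Bi-cellular network construction, RWR stationary law, edge flux."""

import numpy as np
import pandas as pd
import pytest

from bicellnet.datatypes import LRCatalog, LRPair
from bicellnet.errors import ConfigError, DataError
from bicellnet.netwalk import (BicellEdge, BicellularNetwork, INTER, INTRA,
                               build_bicellular_network, edge_flux,
                               rwr_stationary, top_subnetwork, weights_from_t)


def _catalog(keys):
    return LRCatalog.from_pairs([LRPair(l, r, frozenset({"KEGG"})) for l, r in keys])


def _random_network(rng, n_nodes=6, p_edge=0.5):
    nodes = [(f"G{i}", "SC") for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append(BicellEdge(nodes[i], nodes[j], INTRA))
    # guarantee connectivity with a chain
    for i in range(n_nodes - 1):
        edges.append(BicellEdge(nodes[i], nodes[i + 1], INTRA))
    uniq = {}
    for e in edges:
        uniq[frozenset((e.a, e.b))] = e
    return BicellularNetwork(nodes=nodes, edges=list(uniq.values()))


def stationary_by_linear_solve(network, weights, r):
    """Independent oracle: solve (I - (1-r) T') p = r q directly."""
    n = network.n
    T = np.zeros((n, n))
    for i, nbrs in enumerate(network.neighbors):
        if not nbrs:
            T[i, :] = weights / weights.sum()
            continue
        w = weights[nbrs]
        T[i, nbrs] = w / w.sum()
    q = weights / weights.sum()
    p = np.linalg.solve(np.eye(n) - (1 - r) * T.T, r * q)
    return p / p.sum()


class TestBuildNetwork:
    def test_chain_duplicated_per_cell(self):
        net = build_bicellular_network([("A", "B"), ("B", "C")], _catalog([]))
        assert net.n == 6
        assert sum(e.kind == INTRA for e in net.edges) == 4
        assert sum(e.kind == INTER for e in net.edges) == 0

    def test_single_lr_pair_gives_four_inter_edges(self):
        net = build_bicellular_network([], _catalog([("L", "R")]))
        inter = {(e.a, e.b) for e in net.edges if e.kind == INTER}
        assert inter == {
            (("L", "SC"), ("R", "SC")), (("L", "SC"), ("R", "MAC")),
            (("L", "MAC"), ("R", "SC")), (("L", "MAC"), ("R", "MAC")),
        }

    def test_duplicate_input_edges_stored_once(self):
        net = build_bicellular_network([("A", "B"), ("B", "A"), ("A", "B")], _catalog([]))
        assert sum(e.kind == INTRA for e in net.edges) == 2  # one per cell

    def test_empty_network_rejected(self):
        with pytest.raises(DataError):
            build_bicellular_network([], _catalog([]))


class TestWeightsFromT:
    def _net(self, genes):
        edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
        return build_bicellular_network(edges, _catalog([]))

    def test_identical_vectors_identical_weights(self):
        genes = ["A", "B", "C", "D"]
        t = pd.Series([1.0, -0.5, 2.0, 0.0], index=genes)
        net = self._net(genes)
        w = weights_from_t({"SC": t, "MAC": t.copy()}, net)
        sc = [w[net.index[(g, "SC")]] for g in genes]
        mac = [w[net.index[(g, "MAC")]] for g in genes]
        assert sc == mac

    def test_sorted_weights_equal_across_cells(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(10)]
        net = self._net(genes)
        t_sc = pd.Series(rng.normal(0, 1, 10), index=genes)
        t_mac = pd.Series(rng.normal(2, 3, 10), index=genes)
        w = weights_from_t({"SC": t_sc, "MAC": t_mac}, net)
        sc = sorted(w[net.index[(g, "SC")]] for g in genes)
        mac = sorted(w[net.index[(g, "MAC")]] for g in genes)
        assert np.allclose(sc, mac)

    def test_toy_hand_computation(self):
        genes = ["A", "B", "C", "D"]
        net = self._net(genes)
        t_sc = pd.Series([1.0, 2.0, 3.0, 4.0], index=genes)
        t_mac = pd.Series([0.0, 2.0, 4.0, 6.0], index=genes)
        # joint QN reference: mean of the sorted vectors = (0.5, 2, 3.5, 5)
        w = weights_from_t({"SC": t_sc, "MAC": t_mac}, net)
        expected = 2.0 ** np.array([0.5, 2.0, 3.5, 5.0])
        got_sc = [w[net.index[(g, "SC")]] for g in genes]
        got_mac = [w[net.index[(g, "MAC")]] for g in genes]
        assert np.allclose(got_sc, expected)
        assert np.allclose(got_mac, expected)

    def test_missing_gene_gets_cell_median(self):
        genes = ["A", "B", "C"]
        net = self._net(genes)
        t_sc = pd.Series([1.0, 2.0, 3.0], index=genes)
        t_mac = pd.Series([1.0, 2.0], index=["A", "B"])  # C missing
        w = weights_from_t({"SC": t_sc, "MAC": t_mac}, net)
        mac_known = [w[net.index[(g, "MAC")]] for g in ["A", "B"]]
        assert w[net.index[("C", "MAC")]] == pytest.approx(float(np.median(mac_known)))

    def test_constant_vectors_give_uniform_weights(self):
        genes = ["A", "B", "C"]
        net = self._net(genes)
        t = pd.Series([1.0, 1.0, 1.0], index=genes)
        w = weights_from_t({"SC": t, "MAC": t.copy()}, net)
        assert np.allclose(w, w[0])
        assert (w > 0).all()


class TestRWRStationary:
    def test_complete_graph_equal_weights_uniform(self):
        nodes = [(f"G{i}", "SC") for i in range(4)]
        edges = [BicellEdge(nodes[i], nodes[j], INTRA)
                 for i in range(4) for j in range(i + 1, 4)]
        net = BicellularNetwork(nodes=nodes, edges=edges)
        for r in (0.05, 0.15, 0.5, 0.9):
            p = rwr_stationary(net, np.ones(4), restart=r)
            assert np.allclose(p, 0.25, atol=1e-9)

    def test_matches_linear_solve_oracle_on_small_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            net = _random_network(rng, n_nodes=n)
            weights = rng.uniform(0.1, 5.0, n)
            r = float(rng.uniform(0.05, 0.9))
            p = rwr_stationary(net, weights, restart=r, tol=1e-14)
            oracle = stationary_by_linear_solve(net, weights, r)
            assert np.allclose(p, oracle, atol=1e-8)
            assert abs(p.sum() - 1.0) < 1e-9

    def test_isolated_node_restarts_and_mass_conserved(self):
        nodes = [("A", "SC"), ("B", "SC"), ("C", "SC")]
        edges = [BicellEdge(nodes[0], nodes[1], INTRA)]
        net = BicellularNetwork(nodes=nodes, edges=edges)
        w = np.array([1.0, 1.0, 1.0])
        p = rwr_stationary(net, w, restart=0.3, tol=1e-13)
        assert abs(p.sum() - 1.0) < 1e-9
        oracle = stationary_by_linear_solve(net, w, 0.3)
        assert np.allclose(p, oracle, atol=1e-8)

    def test_invalid_restart_rejected(self):
        net = _random_network(np.random.default_rng(0), 4)
        with pytest.raises(ConfigError):
            rwr_stationary(net, np.ones(4), restart=1.0)

    def test_weight_monotonicity_of_stationary_probability(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            net = _random_network(rng, n_nodes=n)
            w = rng.uniform(0.5, 2.0, n)
            p0 = rwr_stationary(net, w, restart=0.15, tol=1e-13)
            k = int(rng.integers(n))
            w2 = w.copy()
            w2[k] *= 3.0
            p1 = rwr_stationary(net, w2, restart=0.15, tol=1e-13)
            assert p1[k] >= p0[k] - 1e-12


class TestEdgeFlux:
    def test_complete_graph_equal_fluxes(self):
        nodes = [(f"G{i}", "SC") for i in range(4)]
        edges = [BicellEdge(nodes[i], nodes[j], INTRA)
                 for i in range(4) for j in range(i + 1, 4)]
        net = BicellularNetwork(nodes=nodes, edges=edges)
        w = np.ones(4)
        p = rwr_stationary(net, w, restart=0.15, tol=1e-13)
        table = edge_flux(p, net, w, restart=0.15)
        assert np.allclose(table.flux["flux"], table.flux["flux"].iloc[0])

    def test_toy_path_matches_hand_formula(self):
        nodes = [("A", "SC"), ("B", "SC"), ("C", "SC")]
        edges = [BicellEdge(nodes[0], nodes[1], INTRA),
                 BicellEdge(nodes[1], nodes[2], INTRA)]
        net = BicellularNetwork(nodes=nodes, edges=edges)
        w = np.array([1.0, 2.0, 4.0])
        r = 0.2
        p = rwr_stationary(net, w, restart=r, tol=1e-14)
        table = edge_flux(p, net, w, restart=r)
        # T by hand: A->B=1, B->A=1/5, B->C=4/5, C->B=1
        f_ab = (1 - r) * (p[0] * 1.0 + p[1] * (1.0 / 5.0))
        f_bc = (1 - r) * (p[1] * (4.0 / 5.0) + p[2] * 1.0)
        got = {(row.gene_a, row.gene_b): row.flux for row in table.flux.itertuples()}
        assert got[("A", "B")] == pytest.approx(f_ab, abs=1e-12)
        assert got[("B", "C")] == pytest.approx(f_bc, abs=1e-12)

    def test_total_directed_flux_conservation(self):
        rng = np.random.default_rng(9)
        net = _random_network(rng, 7)
        w = rng.uniform(0.2, 3.0, 7)
        r = 0.15
        p = rwr_stationary(net, w, restart=r, tol=1e-13)
        table = edge_flux(p, net, w, restart=r)
        # undirected intra edges already carry both direction terms
        assert table.flux["flux"].sum() == pytest.approx(1 - r, abs=1e-9)

    def test_directed_inter_edge_uses_single_term(self):
        net = build_bicellular_network([], _catalog([("L", "R")]))
        w = np.ones(net.n)
        r = 0.15
        p = rwr_stationary(net, w, restart=r, tol=1e-13)
        table = edge_flux(p, net, w, restart=r)
        assert (table.flux["edge_type"] == INTER).all()
        # only the ligand->receptor direction is reported: by symmetry the
        # four equal directed fluxes carry half of the total (1-r) flow
        assert np.allclose(table.flux["flux"], table.flux["flux"].iloc[0])
        assert table.flux["flux"].sum() == pytest.approx((1 - r) / 2, abs=1e-9)

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(13)
        net = _random_network(rng, 8)
        w = rng.uniform(0.1, 2.0, 8)
        t1 = edge_flux(rwr_stationary(net, w, 0.15, tol=1e-13), net, w, 0.15)
        t2 = edge_flux(rwr_stationary(net, w, 0.15, tol=1e-13), net, w, 0.15)
        assert t1.flux.equals(t2.flux)


class TestTopSubnetwork:
    def _table(self, rng, n=10):
        net = _random_network(rng, n)
        w = rng.uniform(0.1, 2.0, n)
        p = rwr_stationary(net, w, 0.15, tol=1e-13)
        return edge_flux(p, net, w, 0.15)

    def test_k_equals_edge_count_returns_everything(self):
        table = self._table(np.random.default_rng(2))
        top = top_subnetwork(table, len(table.flux))
        assert len(top) == len(table.flux)

    def test_k_one_is_the_max_flux_edge(self):
        table = self._table(np.random.default_rng(3))
        top = top_subnetwork(table, 1)
        assert top["flux"].iloc[0] == table.flux["flux"].max()

    def test_oversized_k_warns_and_caps(self):
        table = self._table(np.random.default_rng(4))
        with pytest.warns(UserWarning):
            top = top_subnetwork(table, 10_000)
        assert len(top) == len(table.flux)

    def test_planted_hot_lr_edge_ranks_high(self):
        """A ligand-receptor pair whose endpoints carry top-decile weights
        should dominate edge flux in most simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sims = 20
        for sim_i in range(n_sims):
            genes = [f"G{i}" for i in range(100)]
            intra = [(genes[i], genes[i + 1]) for i in range(99)]
            extra = {tuple(sorted(rng.choice(100, 2, replace=False))) for _ in range(60)}
            intra += [(genes[i], genes[j]) for i, j in extra if i != j]
            lig, rec = genes[10], genes[20]
            t_sc = pd.Series(rng.normal(0, 1, 100), index=genes)
            t_mac = pd.Series(rng.normal(0, 1, 100), index=genes)
            t_sc[lig] = 3.5
            t_mac[rec] = 3.5
            catalog = _catalog([(lig, rec)])
            net = build_bicellular_network(intra, catalog)
            w = weights_from_t({"SC": t_sc, "MAC": t_mac}, net)
            p = rwr_stationary(net, w, 0.15, tol=1e-12)
            table = edge_flux(p, net, w, 0.15)
            flux = table.flux
            hot_mask = ((flux["gene_a"] == lig) & (flux["cell_a"] == "SC")
                        & (flux["gene_b"] == rec) & (flux["cell_b"] == "MAC"))
            rank = (flux["flux"] >= flux.loc[hot_mask, "flux"].iloc[0]).mean()
            if rank <= 0.05:
                hits += 1
        assert hits / n_sims >= 0.95
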