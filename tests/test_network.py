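"""Network assembly, edge signing, modules, hubs, marker stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ildnet import (Edge, ExpressionMatrix, Node, RegulatoryNetwork,
                    assemble_network, connectivity_ranking, detect_modules,
                    marker_stratified_module_test, sign_tf_edges)
from ildnet.matrix import MIRNA, MRNA
from ildnet.network import modularity, network_from_tsv, network_nodes_to_tsv, network_to_tsv


def _net_from_edges(edges, roles=None):
    net = RegulatoryNetwork()
    nodes = {n for e in edges for n in (e[0], e[1])}
    roles = roles or {}
    for n in sorted(nodes):
        net.nodes[n] = Node(n, roles.get(n, "DEG"))
    for e in edges:
        src, tgt, etype, sign = e
        directed = etype not in ("ppi",)
        net.add_edge(Edge(src, tgt, etype, sign, directed), etype)
    return net


class TestSignTfEdges:
    def _matrices(self, profiles_g, profiles_m=None):
        cols = [f"s{j}" for j in range(len(next(iter(profiles_g.values()))))]
        mrna = ExpressionMatrix(
            pd.DataFrame.from_dict(profiles_g, orient="index").set_axis(cols, axis=1), MRNA)
        pm = profiles_m or {"mX": [float(j) for j in range(len(cols))]}
        mirna = ExpressionMatrix(
            pd.DataFrame.from_dict(pm, orient="index").set_axis(cols, axis=1), MIRNA)
        return mrna, mirna

    def test_identical_profiles_activation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        mrna, mirna = self._matrices({"tf1": x, "g1": list(x)})
        out = sign_tf_edges({("tf1", "g1")}, mrna, mirna, ["tf1"], ["g1"])
        assert out["sign"].iloc[0] == 1 and bool(out["kept"].iloc[0])

    def test_negated_profile_repression(self):
        x = np.arange(5.0)
        mrna, mirna = self._matrices({"tf1": x.tolist(), "g1": (-x).tolist()})
        out = sign_tf_edges({("tf1", "g1")}, mrna, mirna, ["tf1"], ["g1"])
        assert out["sign"].iloc[0] == -1 and bool(out["kept"].iloc[0])

    def test_planted_regulon_signs_recovered(self, default_sim):
        truth, kb = default_sim["truth"], default_sim["kb"]
        mrna, mirna = default_sim["mrna"], default_sim["mirna"]
        tfs = sorted({tf for tf, _, _ in truth.tf_regulons})
        targets = sorted({t for _, t, _ in truth.tf_regulons}
                         | truth.de_gene_ids | truth.de_mirna_ids)
        out = sign_tf_edges(kb.tf_binding, mrna, mirna, tfs, targets)
        kept = {(r.tf, r.target): int(r.sign)
                for r in out[out["kept"]].itertuples(index=False)}
        correct = total = 0
        for tf, tgt, s in truth.tf_regulons:
            if (tf, tgt) in kept:
                total += 1
                correct += kept[(tf, tgt)] == s
        assert total >= 0.8 * len(truth.tf_regulons)  # most edges survive FDR
        assert correct / total >= 0.9                  # signs recovered


class TestAssemble:
    def test_nodes_only_when_no_edges(self):
        net = assemble_network(["g1", "g2"], ["m1"], [], {}, pd.DataFrame(), pd.DataFrame())
        assert net.counts()["n_nodes"] == 3
        assert net.counts()["n_edges"] == 0

    def test_toy_counts_by_hand(self):
        tf_edges = pd.DataFrame([
            {"tf": "t1", "target": "g1", "sign": 1, "kept": True},
            {"tf": "t1", "target": "m1", "sign": -1, "kept": True},
            {"tf": "t2", "target": "g2", "sign": -1, "kept": True},
            {"tf": "t2", "target": "g3", "sign": 1, "kept": False},  # dropped
        ])
        pairs = pd.DataFrame([
            {"mirna": "m1", "gene": "g1", "retained": True},
            {"mirna": "m2", "gene": "g2", "retained": True},
            {"mirna": "m2", "gene": "g3", "retained": False},
        ])
        net = assemble_network(
            ["t1", "t2", "g1", "g2", "g3"], ["m1", "m2"], ["t1", "t2"],
            {}, tf_edges, pairs, ppi_edges=[("g1", "g2")], pathway_edges=[("g2", "g3")])
        c = net.counts()
        assert c["nodes_by_role"] == {"DEG": 3, "DETF": 2, "DEmiRNA": 2}
        assert c["edges_by_type"] == {"mirna_repress": 2, "pathway": 1, "ppi": 1,
                                      "tf_activate": 1, "tf_repress": 2}
        assert c["n_edges"] == 7

    def test_duplicate_edge_collapses_with_provenance(self):
        net = _net_from_edges([("a", "b", "ppi", 0)])
        net.add_edge(Edge("b", "a", "ppi", 0, False), "second_source")
        assert net.counts()["n_edges"] == 1
        e = net.edge_list()[0]
        assert net.provenance(e) == ["ppi", "second_source"]

    def test_dangling_endpoint_rejected(self):
        net = RegulatoryNetwork()
        net.nodes["a"] = Node("a", "DEG")
        with pytest.raises(KeyError):
            net.add_edge(Edge("a", "zzz", "ppi", 0, False), "x")

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            Edge("a", "a", "ppi", 0, False)

    def test_sign_type_consistency_enforced(self):
        with pytest.raises(ValueError):
            Edge("a", "b", "tf_activate", -1, True)
        with pytest.raises(ValueError):
            Edge("a", "b", "ppi", 1, False)

    def test_scope_flag_drops_mirna_to_non_tf_edges(self):
        pairs = pd.DataFrame([
            {"mirna": "m1", "gene": "g1", "retained": True},
            {"mirna": "m1", "gene": "t1", "retained": True},
        ])
        net = assemble_network(["g1", "t1"], ["m1"], ["t1"], {}, pd.DataFrame(), pairs,
                               include_mirna_gene_edges=False)
        kept_targets = {e.target for e in net.edge_list()}
        assert kept_targets == {"t1"}  # miRNA->DETF kept, miRNA->DEG dropped

    def test_serialization_roundtrip_preserves_counts(self, tmp_path):
        net = _net_from_edges([
            ("t1", "g1", "tf_activate", 1), ("t1", "m1", "tf_repress", -1),
            ("m1", "g1", "mirna_repress", -1), ("g1", "g2", "ppi", 0),
        ], roles={"t1": "DETF", "m1": "DEmiRNA"})
        network_to_tsv(net, tmp_path / "e.tsv")
        network_nodes_to_tsv(net, tmp_path / "n.tsv")
        back = network_from_tsv(tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert back.counts() == net.counts()


class TestModules:
    def _two_cliques(self):
        cliques = []
        for prefix in ("a", "b"):
            nodes = [f"{prefix}{i}" for i in range(5)]
            cliques += [(u, v, "ppi", 0) for u, v in itertools.combinations(nodes, 2)]
        cliques.append(("a0", "b0", "ppi", 0))  # bridge
        return _net_from_edges(cliques)

    def test_two_cliques_split_at_bridge(self):
        net = self._two_cliques()
        part = detect_modules(net)
        assert part.max() == 2
        assert len(set(part[[f"a{i}" for i in range(5)]])) == 1
        assert len(set(part[[f"b{i}" for i in range(5)]])) == 1

    def test_two_clique_partition_is_modularity_optimal_over_2_partitions(self):
        net = self._two_cliques()
        part = detect_modules(net)
        q_found = modularity(net, part)
        nodes = sorted(net.nodes)
        best = -1.0
        for bits in range(1, 2 ** (len(nodes) - 1)):  # exhaustive 2-partitions
            lab = pd.Series([(bits >> i) & 1 for i in range(len(nodes))], index=nodes)
            best = max(best, modularity(net, lab))
        assert q_found == pytest.approx(best, abs=1e-9)

    def test_edgeless_network_all_singletons(self):
        net = RegulatoryNetwork()
        for n in "abc":
            net.nodes[n] = Node(n, "DEG")
        part = detect_modules(net)
        assert sorted(part) == [1, 2, 3]
        assert len(part) == 3

    def test_single_clique_one_module(self):
        edges = [(u, v, "ppi", 0) for u, v in itertools.combinations("abcd", 2)]
        part = detect_modules(_net_from_edges(edges))
        assert part.max() == 1

    def test_partition_total_and_deterministic(self, default_sim):
        # determinism: same input twice gives identical labels
        net = self._two_cliques()
        assert detect_modules(net).equals(detect_modules(net))

    def test_modularity_at_least_trivial(self):
        net = self._two_cliques()
        part = detect_modules(net)
        trivial = pd.Series(1, index=sorted(net.nodes))
        assert modularity(net, part) >= modularity(net, trivial)


class TestDegreeRanking:
    def test_star_center_first(self):
        edges = [("hub", f"x{i}", "ppi", 0) for i in range(4)]
        rk = connectivity_ranking(_net_from_edges(edges))
        assert rk.iloc[0]["node"] == "hub"
        assert rk.iloc[0]["degree"] == 4

    def test_ties_lexicographic(self):
        rk = connectivity_ranking(_net_from_edges([("b", "c", "ppi", 0)]))
        assert rk["node"].tolist() == ["b", "c"]

    def test_toy_degrees_hand_counted(self):
        net = _net_from_edges([
            ("t1", "g1", "tf_activate", 1), ("m1", "g1", "mirna_repress", -1),
            ("g1", "g2", "ppi", 0),
        ], roles={"t1": "DETF", "m1": "DEmiRNA"})
        deg = dict(connectivity_ranking(net).itertuples(index=False, name=None))
        assert deg == {"g1": 3, "g2": 1, "m1": 1, "t1": 1}


class TestMarkerStratification:
    def _matrix(self, n_cases=20, n_ctrl=4, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = n_cases + n_ctrl
        marker = np.concatenate([rng.standard_normal(n_cases) * 2, rng.standard_normal(n_ctrl)])
        genes = rng.standard_normal((10, n))
        if shift:
            high = marker[:n_cases] > np.median(marker[:n_cases])
            genes[:, :n_cases][:, high] += shift
        X = np.vstack([marker, genes])
        cols = [f"c{j}" for j in range(n)]
        m = ExpressionMatrix(pd.DataFrame(
            X, index=["MARKER"] + [f"g{i}" for i in range(10)], columns=cols), MRNA)
        labels = ["case"] * n_cases + ["control"] * n_ctrl
        return m, labels

    def test_planted_module_shift_flags_majority(self):
        flagged = total = 0
        for seed in range(20):
            m, labels = self._matrix(shift=1.5, seed=seed)
            _, summary = marker_stratified_module_test(
                m, labels, "MARKER", [f"g{i}" for i in range(10)])
            flagged += summary["n_flagged"]
            total += summary["n_tested"]
        assert flagged / total > 0.5

    def test_null_strata_flag_few(self):
        flagged = total = 0
        for seed in range(20):
            m, labels = self._matrix(shift=0.0, seed=seed)
            _, summary = marker_stratified_module_test(
                m, labels, "MARKER", [f"g{i}" for i in range(10)])
            flagged += summary["n_flagged"]
            total += summary["n_tested"]
        assert flagged / total <= 0.1

    def test_odd_count_median_sample_goes_low(self):
        m, labels = self._matrix(n_cases=7, n_ctrl=4)
        _, summary = marker_stratified_module_test(m, labels, "MARKER", ["g0", "g1", "g2"])
        assert summary["n_low"] == 4 and summary["n_high"] == 3

    def test_missing_module_gene_rejected(self):
        m, labels = self._matrix()
        with pytest.raises(KeyError):
            marker_stratified_module_test(m, labels, "MARKER", ["nope"])

    def test_too_few_cases_rejected(self):
        m, labels = self._matrix(n_cases=3, n_ctrl=4)
        with pytest.raises(ValueError):
            marker_stratified_module_test(m, labels, "MARKER", ["g0"])
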