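"""Signed TF/miRNA/gene regulatory network: assembly, modules, hubs, strata.

Nodes are DEGs, DETFs (DEGs found in a TF catalog) and DEmiRNAs.  Edges
are typed: ``tf_activate`` (+1) and ``tf_repress`` (-1) from
correlation-signed binding predictions, ``mirna_repress`` (-1) from the
retained anticorrelated miRNA-target pairs, and unsigned ``ppi`` /
``pathway`` context edges that never enter sign logic.  Modules come
from deterministic greedy modularity maximisation on the undirected,
unsigned projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .diffexpr import welch_t

SIGNED_TYPES = {"tf_activate": 1, "tf_repress": -1, "mirna_repress": -1}
CONTEXT_TYPES = {"ppi", "pathway"}


@dataclass(frozen=True)
class Node:
    id: str
    role: str      # DEG | DETF | DEmiRNA
    log2fc: float = 0.0


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    type: str
    sign: int          # +1 activate, -1 repress, 0 context
    directed: bool

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r}")
        if self.type in SIGNED_TYPES and self.sign != SIGNED_TYPES[self.type]:
            raise ValueError(f"edge type {self.type} requires sign {SIGNED_TYPES[self.type]}")
        if self.type in CONTEXT_TYPES and self.sign != 0:
            raise ValueError(f"context edge type {self.type} must be unsigned")


@dataclass
class RegulatoryNetwork:
    nodes: dict[str, Node] = field(default_factory=dict)
    # key: (source, target, type) -> provenance list
    edges: dict[tuple[str, str, str], list[str]] = field(default_factory=dict)
    edge_meta: dict[tuple[str, str, str], Edge] = field(default_factory=dict)

    def add_edge(self, edge: Edge, provenance: str) -> None:
        for end in (edge.source, edge.target):
            if end not in self.nodes:
                raise KeyError(f"edge endpoint {end!r} not in node universe")
        src, tgt = edge.source, edge.target
        if not edge.directed and tgt < src:
            src, tgt = tgt, src
        key = (src, tgt, edge.type)
        self.edges.setdefault(key, [])
        if provenance not in self.edges[key]:
            self.edges[key].append(provenance)
        self.edge_meta[key] = Edge(src, tgt, edge.type, edge.sign, edge.directed)

    def edge_list(self) -> list[Edge]:
        return [self.edge_meta[k] for k in sorted(self.edges)]

    def provenance(self, edge: Edge) -> list[str]:
        return self.edges[(edge.source, edge.target, edge.type)]

    def counts(self) -> dict:
        by_role: dict[str, int] = {}
        for n in self.nodes.values():
            by_role[n.role] = by_role.get(n.role, 0) + 1
        by_type: dict[str, int] = {}
        for _, _, t in self.edges:
            by_type[t] = by_type.get(t, 0) + 1
        return {
            "n_nodes": len(self.nodes), "n_edges": len(self.edges),
            "nodes_by_role": dict(sorted(by_role.items())),
            "edges_by_type": dict(sorted(by_type.items())),
        }

    def to_undirected_graph(self) -> nx.Graph:
        """Unsigned undirected projection (parallel typed edges collapse)."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for src, tgt, _ in sorted(self.edges):
            g.add_edge(src, tgt)
        return g

    def degrees(self) -> dict[str, int]:
        """Unweighted degree; each typed edge counts once for both ends."""
        deg = {n: 0 for n in self.nodes}
        for src, tgt, _ in self.edges:
            deg[src] += 1
            deg[tgt] += 1
        return deg


def sign_tf_edges(
    tf_binding: Iterable[tuple[str, str]],
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    tfs: Sequence[str],
    targets: Sequence[str],
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Correlation-sign binding predictions restricted to DE entities.

    For every predicted (tf, target) with tf in *tfs* and target in
    *targets*: Pearson r across all samples, two-sided p, BH q across all
    such pairs; kept iff q < q_max; sign +1 (activation) when r > 0 else
    -1 (repression).
    """
    tf_set, tgt_set = set(tfs), set(targets)
    shared = [s for s in mrna.sample_ids if s in set(mirna.sample_ids)]
    n = len(shared)
    Xg, Xm = mrna.values[shared], mirna.values[shared]

    def profile(fid: str) -> np.ndarray | None:
        if fid in Xg.index:
            return Xg.loc[fid].to_numpy(dtype=float)
        if fid in Xm.index:
            return Xm.loc[fid].to_numpy(dtype=float)
        return None

    rows = []
    for tf, tgt in sorted(set(tf_binding)):
        if tf not in tf_set or tgt not in tgt_set or tf == tgt:
            continue
        x, y = profile(tf), profile(tgt)
        if x is None or y is None:
            continue
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance profile for ({tf}, {tgt}); skipped", RuntimeWarning)
            continue
        r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append({"tf": tf, "target": tgt, "r": r, "p": p})
    table = pd.DataFrame(rows, columns=["tf", "target", "r", "p"])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        table["kept"] = pd.Series(dtype=bool)
        table["sign"] = pd.Series(dtype=int)
        return table
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["kept"] = table["q"] < q_max
    table["sign"] = np.where(table["r"] > 0, 1, -1)
    return table


def assemble_network(
    de_genes: Sequence[str],
    de_mirnas: Sequence[str],
    tf_catalog: Sequence[str],
    log2fc: dict[str, float],
    tf_edges: pd.DataFrame,
    mirna_pairs: pd.DataFrame,
    ppi_edges: Iterable[tuple[str, str]] = (),
    pathway_edges: Iterable[tuple[str, str]] = (),
    include_mirna_gene_edges: bool = True,
) -> RegulatoryNetwork:
    """Build the signed network over DE entities.

    *tf_edges* is the kept subset of :func:`sign_tf_edges` output;
    *mirna_pairs* the retained subset from the integration stage.  When
    ``include_mirna_gene_edges`` is False, miRNA->gene edges to non-TF
    genes are dropped (the miRNA-to-DETF focus of the global network
    figure) while miRNA->DETF edges remain.
    """
    cat = set(tf_catalog)
    net = RegulatoryNetwork()
    for g in sorted(set(de_genes)):
        role = "DETF" if g in cat else "DEG"
        net.nodes[g] = Node(g, role, float(log2fc.get(g, 0.0)))
    for m in sorted(set(de_mirnas)):
        net.nodes[m] = Node(m, "DEmiRNA", float(log2fc.get(m, 0.0)))

    if len(tf_edges):
        kept = tf_edges[tf_edges["kept"]] if "kept" in tf_edges else tf_edges
        for row in kept.itertuples(index=False):
            etype = "tf_activate" if row.sign > 0 else "tf_repress"
            net.add_edge(Edge(row.tf, row.target, etype, int(row.sign), True), "tf_binding")
    if len(mirna_pairs):
        kept = mirna_pairs[mirna_pairs["retained"]] if "retained" in mirna_pairs else mirna_pairs
        for row in kept.itertuples(index=False):
            if not include_mirna_gene_edges and net.nodes[row.gene].role != "DETF":
                continue
            net.add_edge(Edge(row.mirna, row.gene, "mirna_repress", -1, True), "target_predictions")
    universe = set(net.nodes)
    for a, b in sorted(set(ppi_edges)):
        if a in universe and b in universe and a != b:
            net.add_edge(Edge(min(a, b), max(a, b), "ppi", 0, False), "ppi")
    for a, b in sorted(set(pathway_edges)):
        if a in universe and b in universe and a != b:
            net.add_edge(Edge(a, b, "pathway", 0, True), "pathway")
    return net


def detect_modules(net: RegulatoryNetwork) -> pd.Series:
    """Connectivity modules by greedy modularity maximisation.

    Runs on the undirected, unsigned projection; isolated nodes get
    singleton modules.  Modules are canonically renumbered 1..k by
    (size descending, smallest member id).
    """
    g = net.to_undirected_graph()
    if g.number_of_nodes() == 0:
        return pd.Series(dtype=int, name="module")
    if g.number_of_edges() == 0:
        comms = [{n} for n in sorted(g.nodes)]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    assign: dict[str, int] = {}
    for i, c in enumerate(comms, start=1):
        for node in sorted(c):
            assign[node] = i
    return pd.Series(assign, name="module").sort_index()


def modularity(net: RegulatoryNetwork, partition: pd.Series) -> float:
    g = net.to_undirected_graph()
    if g.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set] = {}
    for node, mod in partition.items():
        groups.setdefault(int(mod), set()).add(node)
    return float(nx.community.modularity(g, groups.values()))


def connectivity_ranking(net: RegulatoryNetwork) -> pd.DataFrame:
    """Nodes ranked by total unweighted degree, ties lexicographic."""
    deg = net.degrees()
    rows = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node", "degree"])


def marker_stratified_module_test(
    mrna: ExpressionMatrix,
    labels: Sequence,
    marker: str,
    module_genes: Sequence[str],
    q_max: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Split cases at the marker's median and test module genes between strata.

    Case samples are ordered by (marker value, sample id) and the lower
    half -- including the median sample when the count is odd -- forms
    the "low" stratum.  Welch t per module gene between strata, BH within
    the module; the summary reports the count with q < q_max and the mean
    |log2fc|.
    """
    lab = np.asarray(labels)
    case_ids = [s for s, l in zip(mrna.sample_ids, lab) if l == "case"]
    if len(case_ids) < 4:
        raise ValueError("need at least 4 case samples to stratify")
    if marker not in mrna.values.index:
        raise KeyError(f"marker gene {marker!r} not in matrix")
    missing = [g for g in module_genes if g not in mrna.values.index]
    if missing:
        raise KeyError(f"module genes absent from matrix: {missing[:5]}")
    marker_vals = mrna.values.loc[marker, case_ids]
    ordered = sorted(case_ids, key=lambda s: (marker_vals[s], s))
    n_low = (len(ordered) + 1) // 2  # median sample goes to "low"
    low, high = ordered[:n_low], ordered[n_low:]
    genes = [g for g in module_genes if g != marker]
    Xh = mrna.values.loc[genes, high].to_numpy(dtype=float)
    Xl = mrna.values.loc[genes, low].to_numpy(dtype=float)
    t, p, log2fc = welch_t(Xh, Xl)
    table = pd.DataFrame({"t": t, "p": p, "log2fc": log2fc}, index=genes)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["flagged"] = table["q"] < q_max
    summary = {
        "marker": marker,
        "n_low": len(low), "n_high": len(high),
        "n_flagged": int(table["flagged"].sum()),
        "n_tested": int(len(table)),
        "mean_abs_log2fc": float(np.abs(table["log2fc"]).mean()) if len(table) else 0.0,
    }
    return table, summary


# --- serialization ------------------------------------------------------

def network_to_tsv(net: RegulatoryNetwork, path: str | Path) -> None:
    rows = [
        {"source": e.source, "target": e.target, "type": e.type, "sign": e.sign,
         "directed": int(e.directed), "provenance": ",".join(net.provenance(e))}
        for e in net.edge_list()
    ]
    pd.DataFrame(rows, columns=["source", "target", "type", "sign", "directed", "provenance"]).to_csv(
        path, sep="\t", index=False)


def network_nodes_to_tsv(net: RegulatoryNetwork, path: str | Path) -> None:
    rows = [{"node": n.id, "role": n.role, "log2fc": n.log2fc}
            for n in (net.nodes[k] for k in sorted(net.nodes))]
    pd.DataFrame(rows, columns=["node", "role", "log2fc"]).to_csv(path, sep="\t", index=False)


def network_from_tsv(nodes_path: str | Path, edges_path: str | Path) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    nodes = pd.read_csv(nodes_path, sep="\t")
    for row in nodes.itertuples(index=False):
        net.nodes[row.node] = Node(row.node, row.role, float(row.log2fc))
    edges = pd.read_csv(edges_path, sep="\t")
    for row in edges.itertuples(index=False):
        e = Edge(row.source, row.target, row.type, int(row.sign), bool(row.directed))
        for prov in str(row.provenance).split(","):
            net.add_edge(e, prov)
    return net


def network_to_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    g = nx.DiGraph()
    for n in net.nodes.values():
        g.add_node(n.id, role=n.role, log2fc=n.log2fc)
    for e in net.edge_list():
        g.add_edge(e.source, e.target, type=e.type, sign=e.sign, directed=e.directed)
    nx.write_graphml(g, path)
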