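"""End-to-end orchestration: simulate/load -> normalize -> DE -> cluster ->
TSP -> miRNA integration -> network/modules -> FFLs -> enrichment.

`run_pipeline` writes every stage artifact as TSV/JSON under the output
directory and returns a summary dict (also written as summary.json).
When the inputs come from the synthetic generator, a recovery block
scores each stage against the planted ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import diffexpr as _de
from . import enrichment as _enr
from . import ffl as _ffl
from . import integrate as _int
from . import network as _net
from . import preprocess as _pre
from . import tsp as _tsp
from .matrix import ExpressionMatrix, SampleMetadata, MRNA, MIRNA
from .simulate import (GroundTruth, KnowledgeBase, SimulationConfig,
                       read_gmt, read_pairs_tsv, simulate_cohort,
                       simulate_knowledge, write_dataset)

log = logging.getLogger("ildnet")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and scope flags for one pipeline run."""

    # either synthetic generation ...
    synthetic: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # ... or file inputs (all required when synthetic=False)
    mrna_path: str | None = None
    mirna_path: str | None = None
    metadata_path: str | None = None
    targets_path: str | None = None
    tf_binding_path: str | None = None
    ppi_path: str | None = None
    pathway_path: str | None = None
    gene_sets_path: str | None = None
    tf_catalog_path: str | None = None

    fc_min: float = 1.5
    q_max_de: float = 0.1
    q_max_corr: float = 0.1
    q_max_tf: float = 0.1
    pfdr_lambda: float = 0.5
    cluster_k: int = 2
    tsp_max_features: int = 40
    include_mirna_gene_edges: bool = True
    marker_gene: str | None = None  # None -> top-degree DETF
    out_dir: str = "ildnet_out"
    seed: int = 0

    def validate(self) -> None:
        if not (self.fc_min >= 1):
            raise ValueError("fc_min must be >= 1")
        for name in ("q_max_de", "q_max_corr", "q_max_tf"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.pfdr_lambda < 1:
            raise ValueError("pfdr_lambda must be in [0, 1)")
        if not self.synthetic:
            required = ["mrna_path", "mirna_path", "metadata_path", "targets_path",
                        "tf_binding_path", "gene_sets_path", "tf_catalog_path"]
            missing = [f for f in required if getattr(self, f) is None]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
            for f in required + ["ppi_path", "pathway_path"]:
                p = getattr(self, f)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{f}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic:
        sim = SimulationConfig(**{**cfg.sim.__dict__, "seed": cfg.seed})
        mrna, mirna, meta, truth = simulate_cohort(sim)
        kb = simulate_knowledge(truth, sim)
        return mrna, mirna, meta, kb, truth
    mrna = ExpressionMatrix.from_tsv(cfg.mrna_path, MRNA)
    mirna = ExpressionMatrix.from_tsv(cfg.mirna_path, MIRNA)
    meta = SampleMetadata.from_tsv(cfg.metadata_path)
    kb = KnowledgeBase(
        target_predictions=read_pairs_tsv(cfg.targets_path),
        tf_binding=read_pairs_tsv(cfg.tf_binding_path),
        ppi_edges=read_pairs_tsv(cfg.ppi_path) if cfg.ppi_path else set(),
        pathway_edges=read_pairs_tsv(cfg.pathway_path) if cfg.pathway_path else set(),
        gene_sets=read_gmt(cfg.gene_sets_path),
        tf_catalog=[l.strip() for l in Path(cfg.tf_catalog_path).read_text().splitlines() if l.strip()],
    )
    return mrna, mirna, meta, kb, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write artifacts under cfg.out_dir, return summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "fc_min": cfg.fc_min, "q_max_de": cfg.q_max_de, "q_max_corr": cfg.q_max_corr,
        "q_max_tf": cfg.q_max_tf, "pfdr_lambda": cfg.pfdr_lambda, "seed": cfg.seed,
        "synthetic": cfg.synthetic,
    }}

    mrna_raw, mirna_raw, meta, kb, truth = _load_inputs(cfg)
    if cfg.synthetic:
        write_dataset(out / "dataset", mrna_raw, mirna_raw, meta, truth, kb)
    log.info("inputs: %d genes x %d samples, %d miRNAs", mrna_raw.n_features,
             mrna_raw.n_samples, mirna_raw.n_features)

    # --- preprocess -----------------------------------------------------
    mrna_qn = _pre.quantile_normalize(mrna_raw)
    mirna_qn = _pre.quantile_normalize(mirna_raw)
    calls = _pre.call_presence(mrna_qn)
    calls.to_tsv(out / "presence_calls.tsv")
    mrna = _pre.apply_presence_filter(mrna_qn, calls)
    mirna = _pre.apply_presence_filter(mirna_qn, calls)  # all miRNA probes pass
    summary["preprocess"] = {
        "n_genes_present": mrna.n_features,
        "n_genes_total": mrna_raw.n_features,
        "n_mirnas": mirna.n_features,
    }

    labels = meta.labels_for(mrna.sample_ids)
    mir_labels = meta.labels_for(mirna.sample_ids)

    # --- differential expression ---------------------------------------
    params = _de.PFDRParams(lam=cfg.pfdr_lambda)
    de_genes_tbl = _de.add_qvalues(_de.two_sample_stats(mrna, labels), params)
    up_g, down_g = _de.call_differential(de_genes_tbl, cfg.fc_min, cfg.q_max_de)
    de_mirnas_tbl = _de.add_qvalues(
        _de.two_sample_stats(mirna, mir_labels), _de.PFDRParams(lam=cfg.pfdr_lambda))
    up_m, down_m = _de.call_differential(de_mirnas_tbl, cfg.fc_min, cfg.q_max_de)
    _de.de_table_to_tsv(de_genes_tbl, out / "de_genes.tsv")
    _de.de_table_to_tsv(de_mirnas_tbl, out / "de_mirnas.tsv")
    deg_ids = up_g + down_g
    demir_ids = up_m + down_m
    summary["differential_expression"] = {
        "n_de_genes": len(deg_ids), "n_up_genes": len(up_g), "n_down_genes": len(down_g),
        "n_de_mirnas": len(demir_ids), "n_up_mirnas": len(up_m), "n_down_mirnas": len(down_m),
    }

    # --- clustering -----------------------------------------------------
    clustering: dict = {}
    if len(deg_ids) >= 2:
        dend, groups = _cluster.hierarchical_cluster(mrna, deg_ids, k=cfg.cluster_k)
        _cluster.groups_to_tsv(groups, out / "cluster_groups.tsv")
        (out / "dendrogram.txt").write_text(dend.render() + "\n")
        clustering["k"] = cfg.cluster_k
        clustering["group_sizes"] = groups.value_counts().sort_index().tolist()
        if truth is not None:
            true_lab = meta.labels_for(list(groups.index))
            clustering["rand_index_vs_truth"] = _cluster.rand_index(groups.to_numpy(), true_lab)
    summary["clustering"] = clustering

    # --- top-scoring pairs ----------------------------------------------
    tsp_block: dict = {}
    for kind, mat, ids, lab in (("mrna", mrna, deg_ids, labels),
                                ("mirna", mirna, demir_ids, mir_labels)):
        if len(ids) < 2:
            continue
        tbl = de_genes_tbl if kind == "mrna" else de_mirnas_tbl
        top_feats = tbl.loc[ids].sort_values("p").index[: cfg.tsp_max_features]
        sub = mat.subset_features(list(top_feats))
        scores = _tsp.tsp_scores(sub, lab)
        _tsp.scores_to_tsv(scores, out / f"tsp_{kind}.tsv", top=25)
        cv = _tsp.tsp_cv(sub, lab)
        (out / f"tsp_{kind}_cv.json").write_text(json.dumps(
            {"accuracy": cv["accuracy"], "folds": cv["folds"]}, indent=1, default=str))
        best = scores[0]
        tsp_block[kind] = {
            "top_pair": [best.feature_i, best.feature_j],
            "delta": best.delta, "loocv_accuracy": cv["accuracy"],
        }
    summary["tsp"] = tsp_block

    # --- miRNA-target integration ---------------------------------------
    candidates = _int.candidate_interactions(kb.target_predictions, demir_ids, deg_ids)
    inter = _int.filter_anticorrelated(candidates, mrna, mirna, q_max=cfg.q_max_corr)
    _int.interactions_to_tsv(inter, out / "interactions.tsv")
    summary["integration"] = _int.interaction_summary(inter)

    # --- network ----------------------------------------------------------
    detfs = [g for g in deg_ids if g in set(kb.tf_catalog)]
    tf_edges = _net.sign_tf_edges(kb.tf_binding, mrna, mirna,
                                  tfs=detfs, targets=deg_ids + demir_ids,
                                  q_max=cfg.q_max_tf)
    tf_edges.to_csv(out / "tf_edges.tsv", sep="\t", index=False)
    lfc = pd.concat([de_genes_tbl["log2fc"], de_mirnas_tbl["log2fc"]]).to_dict()
    net = _net.assemble_network(
        deg_ids, demir_ids, kb.tf_catalog, lfc, tf_edges, inter,
        ppi_edges=kb.ppi_edges, pathway_edges=kb.pathway_edges,
        include_mirna_gene_edges=cfg.include_mirna_gene_edges)
    _net.network_to_tsv(net, out / "network_edges.tsv")
    _net.network_nodes_to_tsv(net, out / "network_nodes.tsv")
    _net.network_to_graphml(net, out / "network.graphml")
    modules = _net.detect_modules(net)
    modules.rename_axis("node").to_frame().to_csv(out / "modules.tsv", sep="\t")
    ranking = _net.connectivity_ranking(net)
    ranking.to_csv(out / "degree_ranking.tsv", sep="\t", index=False)
    summary["network"] = net.counts() | {
        "n_modules": int(modules.max()) if len(modules) else 0,
        "modularity": _net.modularity(net, modules) if len(modules) else 0.0,
        "top_connected": ranking.head(4)["node"].tolist(),
    }

    # --- marker stratification -------------------------------------------
    marker_block: dict = {}
    marker = cfg.marker_gene
    if marker is None and detfs:
        ranked_detfs = [n for n in ranking["node"] if n in set(detfs)]
        marker = ranked_detfs[0] if ranked_detfs else None
    if marker is not None and marker in modules.index:
        module_genes = [n for n in modules.index
                        if modules[n] == modules[marker]
                        and net.nodes[n].role in ("DEG", "DETF") and n != marker]
        if len(module_genes) >= 2:
            mtable, msummary = _net.marker_stratified_module_test(
                mrna, labels, marker, module_genes, q_max=cfg.q_max_de)
            mtable.to_csv(out / "marker_strata.tsv", sep="\t")
            marker_block = msummary
    summary["marker_stratification"] = marker_block

    # --- feed-forward loops ----------------------------------------------
    ffls = _ffl.enumerate_ffls(net)
    _ffl.ffls_to_tsv(ffls, out / "ffls.tsv")
    summary["ffl"] = _ffl.ffl_summary(ffls)

    # --- enrichment --------------------------------------------------------
    universe = mrna.feature_ids
    enr_block = {}
    for name, query in (("up_genes", up_g), ("down_genes", down_g)):
        results, discarded = _enr.enrich_sets(query, kb.gene_sets, universe)
        _enr.enrichment_to_tsv(results, out / f"enrichment_{name}.tsv")
        enr_block[name] = {
            "n_sets_tested": len(results), "n_query_discarded": discarded,
            "top_set": results[0].set_id if results else None,
            "top_p": results[0].p if results else None,
        }
    summary["enrichment"] = enr_block

    # --- recovery vs ground truth -----------------------------------------
    if truth is not None:
        summary["recovery"] = _recovery_block(
            truth, deg_ids, demir_ids, inter, tf_edges, ffls)

    _check_count_identities(summary, modules, net)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def _recovery_block(truth: GroundTruth, deg_ids, demir_ids, inter, tf_edges, ffls) -> dict:
    de_called = set(deg_ids)
    de_true = truth.de_gene_ids
    tp = len(de_called & de_true)
    sens = tp / len(de_true) if de_true else float("nan")
    fdr = (len(de_called) - tp) / len(de_called) if de_called else 0.0

    retained = set()
    if len(inter):
        retained = {(r.mirna, r.gene) for r in inter[inter["retained"]].itertuples(index=False)}
    true_pairs = set(truth.true_targets)
    pair_sens = len(retained & true_pairs) / len(true_pairs) if true_pairs else float("nan")

    kept_tf = set()
    signs = {}
    if len(tf_edges):
        for r in tf_edges[tf_edges["kept"]].itertuples(index=False):
            kept_tf.add((r.tf, r.target))
            signs[(r.tf, r.target)] = int(r.sign)
    found = {(f.tf, f.mirna, f.gene) for f in ffls}
    eligible = recovered = 0
    for tf, m, g, s_direct, s_tm in truth.planted_ffls:
        if (tf, m) in kept_tf and (tf, g) in kept_tf and (m, g) in retained:
            eligible += 1
            if (tf, m, g) in found:
                recovered += 1
    return {
        "de_gene_sensitivity": sens,
        "de_gene_fdr": fdr,
        "mirna_pair_sensitivity": pair_sens,
        "n_planted_ffls": len(truth.planted_ffls),
        "n_ffls_eligible": eligible,
        "n_ffls_recovered": recovered,
        "ffl_conditional_recovery": recovered / eligible if eligible else None,
    }


def _check_count_identities(summary: dict, modules: pd.Series, net) -> None:
    de = summary["differential_expression"]
    assert de["n_up_genes"] + de["n_down_genes"] == de["n_de_genes"]
    assert de["n_up_mirnas"] + de["n_down_mirnas"] == de["n_de_mirnas"]
    integ = summary["integration"]
    assert integ["n_retained_pairs"] <= integ["n_candidate_pairs"]
    assert len(modules) == summary["network"]["n_nodes"]
    f = summary["ffl"]
    assert f["n_coherent"] + f["n_incoherent"] == f["n_ffls"]
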