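"""Synthetic two-arm cohort generator with planted regulatory ground truth.

Emulates the statistical structure of a small interstitial-lung-disease
expression study: an unbalanced case/control cohort profiled on an mRNA
and a miRNA platform, with

* planted differentially expressed genes and miRNAs (additive log2 effect),
* a low-intensity "absent" mixture component among mRNA features,
* miRNA repression of target genes (additive on the log2 scale, producing
  the negative pooled case/control correlation the integration stage
  assumes),
* signed transcription-factor regulons over genes and miRNAs, and
* feed-forward loops (TF -> gene directly and TF -> miRNA -| gene
  indirectly) assembled consistently from those regulons and targets,

plus knowledge tables (target predictions, TF binding, PPI, pathway edges,
gene sets) that contain the planted truth diluted with decoys.  The
emitted :class:`GroundTruth` lets every downstream stage be scored for
recovery of what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleMetadata, MRNA, MIRNA

# Spread of per-feature baseline means around baseline_mean / absent_mean.
# Kept well below the present/absent gap so presence calls are learnable.
BASELINE_SD = 0.5

# Knowledge-table sizes not exposed in SimulationConfig: context-edge and
# decoy-annotation volumes, chosen to dilute truth roughly 5-15x.
N_PPI_EDGES = 400
N_PATHWAY_EDGES = 250
N_DECOY_GENE_SETS = 15
GENE_SET_SIZE = 30
N_TRUE_GENE_SETS = 3

_DIAGNOSES = ("UIP/IPF", "NSIP", "HP", "COP", "RB-ILD")
_FVC = ("FVC1", "FVC2", "FVC3")


@dataclass
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults mirror the cohort scale the analysis is designed for: 23 case
    and 6 control profiles, a few thousand mRNA features, planted
    differential expression of |log2 fold change| 1.5 against per-feature
    Gaussian noise of sd 0.7 on the log2 scale.
    """

    n_case: int = 23
    n_control: int = 6
    n_genes: int = 2000
    n_mirnas: int = 300
    n_tfs: int = 100          # first n_tfs gene ids form the TF catalog
    n_de_genes: int = 60
    n_de_mirnas: int = 30
    effect_log2fc: float = 1.5
    noise_sd: float = 0.7
    baseline_mean: float = 8.0
    absent_mean: float = 3.0
    frac_absent: float = 0.25
    n_target_pairs_true: int = 40
    n_target_pairs_decoy: int = 500
    repression_strength: float = 0.8  # coupling for miRNA repression and TF regulons
    n_regulons: int = 8
    regulon_size: int = 8
    n_ffls_planted: int = 10
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case, "n_control": self.n_control,
            "n_genes": self.n_genes, "n_mirnas": self.n_mirnas,
            "n_tfs": self.n_tfs, "n_de_genes": self.n_de_genes,
            "n_de_mirnas": self.n_de_mirnas,
            "n_target_pairs_true": self.n_target_pairs_true,
            "n_target_pairs_decoy": self.n_target_pairs_decoy,
            "n_regulons": self.n_regulons, "regulon_size": self.regulon_size,
            "n_ffls_planted": self.n_ffls_planted,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("n_de_mirnas cannot exceed n_mirnas")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if not 0.0 <= self.frac_absent <= 1.0:
            raise ValueError("frac_absent must be in [0, 1]")
        if not 0.0 <= self.repression_strength <= 1.0:
            raise ValueError("repression_strength must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    de_genes: list[tuple[str, int]] = field(default_factory=list)
    de_mirnas: list[tuple[str, int]] = field(default_factory=list)
    true_targets: list[tuple[str, str]] = field(default_factory=list)
    tf_regulons: list[tuple[str, str, int]] = field(default_factory=list)
    planted_ffls: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    pathway_truth: dict[str, list[str]] = field(default_factory=dict)

    @property
    def de_gene_ids(self) -> set[str]:
        return {g for g, _ in self.de_genes}

    @property
    def de_mirna_ids(self) -> set[str]:
        return {m for m, _ in self.de_mirnas}

    def direction_of(self, feature: str) -> int:
        for fid, d in self.de_genes + self.de_mirnas:
            if fid == feature:
                return d
        raise KeyError(feature)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            de_genes=[tuple(x) for x in raw["de_genes"]],
            de_mirnas=[tuple(x) for x in raw["de_mirnas"]],
            true_targets=[tuple(x) for x in raw["true_targets"]],
            tf_regulons=[tuple(x) for x in raw["tf_regulons"]],
            planted_ffls=[tuple(x) for x in raw["planted_ffls"]],
            pathway_truth={k: list(v) for k, v in raw["pathway_truth"].items()},
        )


@dataclass
class KnowledgeBase:
    """Prediction/interaction tables: planted truth diluted with decoys."""

    target_predictions: set[tuple[str, str]] = field(default_factory=set)
    tf_binding: set[tuple[str, str]] = field(default_factory=set)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)      # canonical (min, max)
    pathway_edges: set[tuple[str, str]] = field(default_factory=set)  # directed
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    tf_catalog: list[str] = field(default_factory=list)


def gene_id(i: int) -> str:
    return f"G{i:05d}"


def mirna_id(i: int) -> str:
    return f"MIR{i:04d}"


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    cases = [f"CASE{i + 1:02d}" for i in range(config.n_case)]
    controls = [f"CTRL{i + 1:02d}" for i in range(config.n_control)]
    return cases, controls


def _metadata(config: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    cases, controls = _sample_ids(config)
    rows = []
    for i, sid in enumerate(cases):
        rows.append({
            "sample_id": sid, "group": "case",
            "fvc_class": _FVC[i % 3],                 # round-robin strata
            "diagnosis": _DIAGNOSES[i % len(_DIAGNOSES)],
            "sex": "F" if i % 2 else "M",
        })
    for i, sid in enumerate(controls):
        rows.append({
            "sample_id": sid, "group": "control", "fvc_class": "-",
            "diagnosis": "control", "sex": "F" if i % 2 else "M",
        })
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(table)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Simulate paired mRNA/miRNA matrices with planted effects.

    Returns the two expression matrices, the sample metadata, and the
    :class:`GroundTruth` describing everything that was planted.  The same
    config (including seed) always yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases, controls = _sample_ids(config)
    samples = cases + controls
    n_samples = len(samples)
    case_mask = np.array([s in set(cases) for s in samples])

    genes = [gene_id(i) for i in range(config.n_genes)]
    mirnas = [mirna_id(i) for i in range(config.n_mirnas)]
    tf_catalog = genes[: config.n_tfs]

    # --- present/absent split (mRNA only; all miRNA probes are used) ----
    n_absent = int(round(config.frac_absent * config.n_genes))
    absent_idx = rng.choice(config.n_genes, size=n_absent, replace=False)
    absent = np.zeros(config.n_genes, dtype=bool)
    absent[absent_idx] = True
    present_genes = [g for g, a in zip(genes, absent) if not a]
    present_set = set(present_genes)

    # --- choose DE features --------------------------------------------
    present_tfs = [t for t in tf_catalog if t in present_set]
    n_reg = min(config.n_regulons, len(present_tfs))
    regulon_tfs = list(rng.choice(present_tfs, size=n_reg, replace=False)) if n_reg else []

    non_tf_present = [g for g in present_genes if g not in set(tf_catalog)]
    n_extra = max(0, config.n_de_genes - len(regulon_tfs))
    if n_extra > len(non_tf_present):
        raise ValueError("not enough present non-TF genes to plant n_de_genes")
    extra_de = list(rng.choice(non_tf_present, size=n_extra, replace=False))
    de_gene_ids = regulon_tfs + extra_de

    de_mirna_ids = list(rng.choice(mirnas, size=config.n_de_mirnas, replace=False))

    dir_of: dict[str, int] = {}
    for fid in de_gene_ids + de_mirna_ids:
        dir_of[fid] = int(rng.choice([-1, 1]))

    # --- plant FFLs constructively -------------------------------------
    # Direction constraints: the TF->X edge sign s must equal
    # dir_X * dir_TF so the coupling reinforces the planted effect and the
    # correlation-based edge signing can recover s.  Coherent loops
    # (s_direct == -s_tm) additionally make the miRNA->gene pair
    # opposite-direction, i.e. genuinely anticorrelated.
    ffl_records: list[tuple[str, str, str, int, int]] = []
    ffl_mirnas: list[str] = []
    ffl_genes: list[str] = []
    avail_m = [m for m in de_mirna_ids]
    avail_g = [g for g in extra_de]
    n_ffl = 0 if n_reg == 0 else min(config.n_ffls_planted, len(avail_m), len(avail_g))
    for k in range(n_ffl):
        tf = regulon_tfs[k % n_reg]
        m = avail_m.pop(0)
        g = avail_g.pop(0)
        s_tm = int(rng.choice([-1, 1]))
        coherent = k % 2 == 0            # plant both classes
        s_direct = -s_tm if coherent else s_tm
        dir_of[m] = s_tm * dir_of[tf]
        dir_of[g] = s_direct * dir_of[tf]
        ffl_records.append((tf, m, g, s_direct, s_tm))
        ffl_mirnas.append(m)
        ffl_genes.append(g)

    # --- true miRNA->target pairs --------------------------------------
    # FFL pairs first; remaining pairs take an unused DE miRNA/DE gene of
    # opposite planted directions, one repressor per gene.
    true_targets: list[tuple[str, str]] = [(m, g) for _, m, g, _, _ in ffl_records]
    used_genes = set(ffl_genes)
    free_genes = [g for g in extra_de if g not in used_genes]
    pool_m = {+1: [m for m in de_mirna_ids if dir_of[m] == 1],
              -1: [m for m in de_mirna_ids if dir_of[m] == -1]}
    for g in free_genes:
        if len(true_targets) >= config.n_target_pairs_true:
            break
        cand = pool_m[-dir_of[g]]
        if not cand:
            continue
        m = cand[int(rng.integers(len(cand)))]
        true_targets.append((m, g))
    true_targets = true_targets[: max(config.n_target_pairs_true, len(ffl_records))]

    # --- TF regulons ----------------------------------------------------
    regulons: list[tuple[str, str, int]] = []
    reg_edges = set()
    for tf, m, g, s_direct, s_tm in ffl_records:
        for tgt, s in ((m, s_tm), (g, s_direct)):
            if (tf, tgt) not in reg_edges:
                regulons.append((tf, tgt, s))
                reg_edges.add((tf, tgt))
    gene_pool = [g for g in extra_de]
    mirna_pool = [m for m in de_mirna_ids]
    for tf in regulon_tfs:
        have = sum(1 for t, _, _ in regulons if t == tf)
        need = max(0, config.regulon_size - have)
        # ~1/4 miRNA targets, rest genes
        n_m = need // 4
        picks: list[str] = []
        if mirna_pool and n_m:
            picks += list(rng.choice(mirna_pool, size=min(n_m, len(mirna_pool)), replace=False))
        n_g = need - len(picks)
        cand_g = [g for g in gene_pool if g != tf]
        if cand_g and n_g:
            picks += list(rng.choice(cand_g, size=min(n_g, len(cand_g)), replace=False))
        for tgt in picks:
            if (tf, tgt) in reg_edges or tgt == tf:
                continue
            s = dir_of[tgt] * dir_of[tf]
            regulons.append((tf, tgt, s))
            reg_edges.add((tf, tgt))

    # --- pathway truth: gene sets enriched in planted DE genes ----------
    pathway_truth: dict[str, list[str]] = {}
    for k in range(N_TRUE_GENE_SETS):
        n_de_members = min(GENE_SET_SIZE * 2 // 3, len(de_gene_ids))
        members = list(rng.choice(de_gene_ids, size=n_de_members, replace=False))
        background = [g for g in present_genes if g not in set(members)]
        n_bg = min(GENE_SET_SIZE - n_de_members, len(background))
        members += list(rng.choice(background, size=n_bg, replace=False))
        pathway_truth[f"SET_TRUE_{k + 1}"] = sorted(members)

    # --- expression values ---------------------------------------------
    base_g = np.where(
        absent,
        config.absent_mean + BASELINE_SD * rng.standard_normal(config.n_genes),
        config.baseline_mean + BASELINE_SD * rng.standard_normal(config.n_genes),
    )
    base_m = config.baseline_mean + BASELINE_SD * rng.standard_normal(config.n_mirnas)

    Xg = base_g[:, None] + config.noise_sd * rng.standard_normal((config.n_genes, n_samples))
    Xm = base_m[:, None] + config.noise_sd * rng.standard_normal((config.n_mirnas, n_samples))

    gi = {g: i for i, g in enumerate(genes)}
    mi = {m: i for i, m in enumerate(mirnas)}

    for fid, d in dir_of.items():
        if fid in gi:
            Xg[gi[fid], case_mask] += d * config.effect_log2fc
        else:
            Xm[mi[fid], case_mask] += d * config.effect_log2fc

    beta = config.repression_strength
    # TF coupling first so TF perturbations propagate through miRNAs.
    for tf, tgt, s in regulons:
        reg = Xg[gi[tf]]
        centred = reg - reg.mean()
        if tgt in gi:
            Xg[gi[tgt]] += s * beta * centred
        else:
            Xm[mi[tgt]] += s * beta * centred
    # miRNA repression: additive on the log2 scale.
    for m, g in true_targets:
        centred = Xm[mi[m]] - Xm[mi[m]].mean()
        Xg[gi[g]] -= beta * centred

    mrna = ExpressionMatrix(pd.DataFrame(Xg, index=genes, columns=samples), MRNA)
    mirna = ExpressionMatrix(pd.DataFrame(Xm, index=mirnas, columns=samples), MIRNA)
    meta = _metadata(config, rng)
    truth = GroundTruth(
        de_genes=sorted((g, dir_of[g]) for g in de_gene_ids),
        de_mirnas=sorted((m, dir_of[m]) for m in de_mirna_ids),
        true_targets=sorted(true_targets),
        tf_regulons=sorted(regulons),
        planted_ffls=sorted(ffl_records),
        pathway_truth=pathway_truth,
    )
    return mrna, mirna, meta, truth


def simulate_knowledge(
    truth: GroundTruth, config: SimulationConfig, seed: int | None = None
) -> KnowledgeBase:
    """Emit knowledge tables consistent with *truth*, diluted with decoys.

    Decoy target predictions never coincide with true targets, and never
    pair a planted-DE miRNA with a planted-DE gene of opposite direction:
    such a pair is genuinely anticorrelated in the simulated expression,
    so calling it a decoy would contradict the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = [gene_id(i) for i in range(config.n_genes)]
    mirnas = [mirna_id(i) for i in range(config.n_mirnas)]
    tf_catalog = genes[: config.n_tfs]

    dir_of = dict(truth.de_genes) | dict(truth.de_mirnas)
    true_set = set(truth.true_targets)

    def confounded(m: str, g: str) -> bool:
        return m in dir_of and g in dir_of and dir_of[m] == -dir_of[g]

    universe = config.n_mirnas * config.n_genes
    if config.n_target_pairs_decoy > universe - len(true_set):
        raise ValueError("decoy count exceeds available miRNA-gene pair universe")

    decoys: set[tuple[str, str]] = set()
    while len(decoys) < config.n_target_pairs_decoy:
        need = config.n_target_pairs_decoy - len(decoys)
        ms = rng.integers(config.n_mirnas, size=need * 2 + 8)
        gs = rng.integers(config.n_genes, size=need * 2 + 8)
        for a, b in zip(ms, gs):
            m, g = mirnas[a], genes[b]
            if (m, g) in true_set or (m, g) in decoys or confounded(m, g):
                continue
            decoys.add((m, g))
            if len(decoys) >= config.n_target_pairs_decoy:
                break

    target_predictions = true_set | decoys

    # TF binding: unsigned cover of the regulons plus uniform decoys.
    tf_binding = {(tf, tgt) for tf, tgt, _ in truth.tf_regulons}
    feature_univ = genes + mirnas
    n_tf_decoys = config.n_target_pairs_decoy
    if tf_catalog:
        while len(tf_binding) < len(truth.tf_regulons) + n_tf_decoys:
            tf = tf_catalog[int(rng.integers(len(tf_catalog)))]
            tgt = feature_univ[int(rng.integers(len(feature_univ)))]
            if tgt != tf:
                tf_binding.add((tf, tgt))

    # Context edges concentrated around DE genes so they appear in the
    # DE-restricted network, plus random background.
    de_genes = sorted(truth.de_gene_ids)
    pool = de_genes + [genes[int(i)] for i in rng.integers(config.n_genes, size=200)]
    ppi: set[tuple[str, str]] = set()
    while len(ppi) < min(N_PPI_EDGES, len(pool) * (len(pool) - 1) // 2):
        a = pool[int(rng.integers(len(pool)))]
        b = pool[int(rng.integers(len(pool)))]
        if a != b:
            ppi.add((min(a, b), max(a, b)))
    pathway: set[tuple[str, str]] = set()
    while len(pathway) < min(N_PATHWAY_EDGES, len(pool) * (len(pool) - 1)):
        a = pool[int(rng.integers(len(pool)))]
        b = pool[int(rng.integers(len(pool)))]
        if a != b:
            pathway.add((a, b))

    gene_sets = {k: list(v) for k, v in truth.pathway_truth.items()}
    for k in range(N_DECOY_GENE_SETS):
        members = rng.choice(genes, size=min(GENE_SET_SIZE, config.n_genes), replace=False)
        gene_sets[f"SET_DECOY_{k + 1}"] = sorted(members)

    return KnowledgeBase(
        target_predictions=target_predictions,
        tf_binding=tf_binding,
        ppi_edges=ppi,
        pathway_edges=pathway,
        gene_sets=gene_sets,
        tf_catalog=list(tf_catalog),
    )


# --- file writers -------------------------------------------------------

def write_pairs_tsv(pairs, path: str | Path, columns: tuple[str, str]) -> None:
    df = pd.DataFrame(sorted(pairs), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {tuple(r) for r in df.itertuples(index=False, name=None)}


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, name] + list(gene_sets[name])) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        sets[parts[0]] = parts[2:]
    return sets


def write_dataset(
    out_dir: str | Path,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    meta: SampleMetadata,
    truth: GroundTruth,
    kb: KnowledgeBase,
) -> None:
    """Write the full simulated dataset as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrna.to_tsv(out / "mrna.tsv")
    mirna.to_tsv(out / "mirna.tsv")
    meta.to_tsv(out / "samples.tsv")
    truth.to_json(out / "ground_truth.json")
    write_pairs_tsv(kb.target_predictions, out / "target_predictions.tsv", ("mirna", "gene"))
    write_pairs_tsv(kb.tf_binding, out / "tf_binding.tsv", ("tf", "target"))
    write_pairs_tsv(kb.ppi_edges, out / "ppi.tsv", ("gene_a", "gene_b"))
    write_pairs_tsv(kb.pathway_edges, out / "pathway_edges.tsv", ("source", "target"))
    write_gmt(kb.gene_sets, out / "gene_sets.gmt")
    (out / "tf_catalog.txt").write_text("\n".join(kb.tf_catalog) + "\n")
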