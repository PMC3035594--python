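"""Generate a synthetic ILD-style cohort with planted ground truth.

Builds the default two-arm cohort (23 cases vs 6 controls) with planted
differentially expressed genes/miRNAs, miRNA repression of targets,
signed TF regulons and feed-forward loops, then prints what was planted.
"""

from ildnet import SimulationConfig, simulate_cohort, simulate_knowledge

cfg = SimulationConfig(seed=1)
mrna, mirna, meta, truth = simulate_cohort(cfg)
kb = simulate_knowledge(truth, cfg)

print(f"mRNA matrix:  {mrna.n_features} genes x {mrna.n_samples} samples")
print(f"miRNA matrix: {mirna.n_features} miRNAs x {mirna.n_samples} samples")
print(f"groups: {list(meta.table['group'].value_counts().items())}")
print(f"planted DE genes: {len(truth.de_genes)}, DE miRNAs: {len(truth.de_mirnas)}")
print(f"planted miRNA->target pairs: {len(truth.true_targets)} "
      f"(among {len(kb.target_predictions)} predictions incl. decoys)")
print(f"planted TF regulon edges: {len(truth.tf_regulons)}, "
      f"feed-forward loops: {len(truth.planted_ffls)}")
# The planted quantities are the recovery targets every later stage is
# scored against; the knowledge tables dilute them with decoy annotations
# the way real target/binding predictions would.
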