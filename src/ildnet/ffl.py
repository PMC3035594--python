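"""Feed-forward loop (FFL) enumeration and coherence classification.

An FFL is a triad in which a transcription factor regulates a target
gene directly (signed edge s_direct) and indirectly through a miRNA:
TF -> miRNA (signed s_tm) and miRNA -| gene (always repression, -1).
The indirect branch's net sign is s_tm * (-1); the loop is *coherent*
when both branches push the target the same way (s_direct == -s_tm) and
*incoherent* otherwise.  Exactly 2 of the 4 sign configurations are
coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .network import RegulatoryNetwork

S_MT = -1  # miRNA-mediated regulation is always repression

COHERENT = "coherent"
INCOHERENT = "incoherent"


@dataclass(frozen=True)
class FFLRecord:
    tf: str
    mirna: str
    gene: str
    s_direct: int
    s_tm: int
    coherence: str

    @property
    def s_mt(self) -> int:
        return S_MT


def classify_coherence(s_direct: int, s_tm: int) -> str:
    """Coherent iff the direct sign equals the indirect branch sign s_tm * (-1)."""
    if s_direct not in (-1, 1) or s_tm not in (-1, 1):
        raise ValueError("FFL branch signs must be +1 or -1 (unsigned edges are not allowed)")
    indirect = s_tm * S_MT
    return COHERENT if s_direct == indirect else INCOHERENT


def enumerate_ffls(net: RegulatoryNetwork) -> list[FFLRecord]:
    """All (TF, miRNA, gene) triads closed by signed edges in *net*.

    Requires tf->mirna and tf->gene edges of type tf_activate/tf_repress
    and a mirna->gene edge of type mirna_repress; context (ppi/pathway)
    edges never participate.  Degenerate triads with gene == tf or
    gene == mirna are excluded.
    """
    tf_targets: dict[str, dict[str, int]] = {}
    mirna_targets: dict[str, set[str]] = {}
    for (src, tgt, etype), _ in net.edges.items():
        sign = net.edge_meta[(src, tgt, etype)].sign
        if etype in ("tf_activate", "tf_repress"):
            tf_targets.setdefault(src, {})[tgt] = sign
        elif etype == "mirna_repress":
            mirna_targets.setdefault(src, set()).add(tgt)

    records = []
    for tf in sorted(tf_targets):
        targets = tf_targets[tf]
        mirnas = [t for t in targets if t in mirna_targets]
        for m in sorted(mirnas):
            s_tm = targets[m]
            for g in sorted(mirna_targets[m]):
                if g == tf or g == m or g not in targets:
                    continue
                s_direct = targets[g]
                records.append(FFLRecord(tf, m, g, s_direct, s_tm,
                                         classify_coherence(s_direct, s_tm)))
    return records


def ffl_summary(records: list[FFLRecord]) -> dict:
    """Totals by coherence plus distinct TF/miRNA/gene counts."""
    return {
        "n_ffls": len(records),
        "n_coherent": sum(r.coherence == COHERENT for r in records),
        "n_incoherent": sum(r.coherence == INCOHERENT for r in records),
        "n_tfs": len({r.tf for r in records}),
        "n_mirnas": len({r.mirna for r in records}),
        "n_genes": len({r.gene for r in records}),
    }


def ffls_to_tsv(records: list[FFLRecord], path: str | Path) -> None:
    rows = [
        {"tf": r.tf, "mirna": r.mirna, "gene": r.gene,
         "s_direct": r.s_direct, "s_tm": r.s_tm, "coherence": r.coherence}
        for r in records
    ]
    pd.DataFrame(rows, columns=["tf", "mirna", "gene", "s_direct", "s_tm", "coherence"]).to_csv(
        path, sep="\t", index=False)
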