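"""Hypergeometric over-representation of gene sets in query lists.

For a query of n ids inside a universe of N, and a gene set covering K
universe members with k in the query, the enrichment p-value is the
exact hypergeometric upper tail

    p = sum_{i = k}^{min(n, K)} C(K, i) C(N - K, n - i) / C(N, n)

computed via scipy's log-gamma combinatorics (stable to N ~ 1e5).
Only over-representation is tested; BH adjustment runs across sets
within one query.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    n: int  # query size in universe
    K: int  # set size in universe
    N: int  # universe size
    p: float
    q: float = float("nan")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > N or n > N or k > min(n, K):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_sets(
    query: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> tuple[list[EnrichmentResult], int]:
    """Test every gene set for over-representation in *query*.

    Query ids outside the universe are discarded (the count of discards
    is returned).  Sets with no universe member are skipped.  Results
    carry BH q-values across the tested sets and are sorted by
    (p, set id).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q_raw = set(query)
    q_ids = q_raw & uni
    discarded = len(q_raw) - len(q_ids)
    n, N = len(q_ids), len(uni)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q_ids)
        rows.append((set_id, k, K, hypergeom_pvalue(k, K, n, N)))
    if not rows:
        return [], discarded
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(set_id, k, n, K, N, p, float(qv))
        for (set_id, k, K, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_id))
    return results, discarded


def enrichment_to_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {"set_id": r.set_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q}
        for r in results
    ]
    pd.DataFrame(rows, columns=["set_id", "k", "n", "K", "N", "p", "q"]).to_csv(
        path, sep="\t", index=False)
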