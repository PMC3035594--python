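"""miRNA-target integration: predicted targets x DE lists, anticorrelation filter.

Candidate interactions are the predicted miRNA->gene pairs whose miRNA is
differentially expressed and whose gene is a DEG.  Because miRNAs act
predominantly as negative regulators, candidates are then filtered to the
inversely correlated ones: Pearson r across all shared samples, one-sided
p for r < 0 through the t transform with n - 2 df, Benjamini-Hochberg
across all candidates, retained iff r < 0 and q < q_max.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .diffexpr import qvalues_pfdr, PFDRParams


def candidate_interactions(
    target_predictions: Iterable[tuple[str, str]],
    de_mirnas: Sequence[str],
    de_genes: Sequence[str],
) -> list[tuple[str, str]]:
    """Predicted (miRNA, gene) pairs with both ends differentially expressed."""
    dm, dg = set(de_mirnas), set(de_genes)
    pairs = {(m, g) for m, g in target_predictions if m in dm and g in dg}
    return sorted(pairs)


def correlate_pairs(
    pairs: Sequence[tuple[str, str]],
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
) -> pd.DataFrame:
    """Pearson r and one-sided (r < 0) p-value per pair on shared samples."""
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    Xm = mirna.values[shared]
    Xg = mrna.values[shared]
    rows = []
    for m, g in pairs:
        if m not in Xm.index:
            raise KeyError(f"miRNA {m!r} absent from miRNA matrix")
        if g not in Xg.index:
            raise KeyError(f"gene {g!r} absent from mRNA matrix")
        x = Xm.loc[m].to_numpy(dtype=float)
        y = Xg.loc[g].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance profile for pair ({m}, {g}); skipped", RuntimeWarning)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = min(1.0, max(-1.0, r))
        if abs(r) >= 1.0:
            p = 0.0 if r < 0 else 1.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(stats.t.cdf(t, df=n - 2))  # lower tail: evidence for r < 0
        rows.append({"mirna": m, "gene": g, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "p", "n"])


def filter_anticorrelated(
    pairs: Sequence[tuple[str, str]],
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    q_max: float = 0.1,
    method: str = "bh",
) -> pd.DataFrame:
    """Score candidates and retain inversely correlated pairs at FDR < q_max.

    ``method`` selects the adjustment: ``"bh"`` (default) or ``"pfdr"``
    for the Storey-style q-values used by the DE stage.
    """
    table = correlate_pairs(pairs, mrna, mirna)
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        table["retained"] = pd.Series(dtype=bool)
        return table
    if method == "bh":
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    elif method == "pfdr":
        table["q"] = qvalues_pfdr(table["p"].to_numpy(), PFDRParams())
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    table["retained"] = (table["r"] < 0) & (table["q"] < q_max)
    return table


def interaction_summary(table: pd.DataFrame) -> dict:
    """Pair/miRNA/gene counts for candidates and the retained subset."""
    kept = table[table["retained"]] if "retained" in table else table.iloc[0:0]
    return {
        "n_candidate_pairs": int(len(table)),
        "n_retained_pairs": int(len(kept)),
        "n_retained_mirnas": int(kept["mirna"].nunique()) if len(kept) else 0,
        "n_retained_genes": int(kept["gene"].nunique()) if len(kept) else 0,
    }


def interactions_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
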