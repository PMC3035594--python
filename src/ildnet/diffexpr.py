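"""Differential expression: Welch t per feature, pFDR q-values, DE calls.

A feature is differentially expressed when its fold change is at least
1.5-fold in either direction and its positive-false-discovery-rate
q-value is below 0.1.  The q-values follow the Storey construction:
pi0(lambda) = min(1, #{p > lambda} / (m (1 - lambda))) and
q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values,
which reduces to Benjamini-Hochberg step-up when pi0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, group_masks

VAR_FLOOR = 1e-9  # floor on the squared standard error of the mean difference


@dataclass
class PFDRParams:
    """pi0 estimation settings/results for the pFDR q-values."""

    lam: float = 0.5
    pi0: float | None = None  # filled after estimation; force by setting it
    m: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lambda must be in [0, 1)")


def welch_t(
    case: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample t over rows.

    Returns (t, p, log2fc) where log2fc = mean(case) - mean(control).
    A variance floor keeps the statistic finite for zero-variance rows.
    """
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    se2 = np.maximum(v1 / n1 + v2 / n2, VAR_FLOOR)
    t = (m1 - m2) / np.sqrt(se2)
    num = se2**2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = np.where(den > 0, num / np.maximum(den, 1e-300), n1 + n2 - 2)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p, m1 - m2


def two_sample_stats(m: ExpressionMatrix, labels: Sequence) -> pd.DataFrame:
    """Per-feature Welch statistics between case and control samples.

    Returns a DataFrame indexed by feature id with columns mean_case,
    mean_control, log2fc, fc, t, p, direction.
    """
    case_mask, control_mask = group_masks(labels)
    X = m.values.to_numpy(dtype=float)
    case, control = X[:, case_mask], X[:, control_mask]
    t, p, log2fc = welch_t(case, control)
    return pd.DataFrame(
        {
            "mean_case": case.mean(axis=1),
            "mean_control": control.mean(axis=1),
            "log2fc": log2fc,
            "fc": np.power(2.0, log2fc),
            "t": t,
            "p": p,
            "direction": np.where(log2fc >= 0, 1, -1),
        },
        index=m.values.index,
    )


def qvalues_pfdr(pvalues: Sequence[float], params: PFDRParams | None = None) -> np.ndarray:
    """Storey-style pFDR q-values (BH step-up scaled by the pi0 estimate)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    params = params or PFDRParams()
    m = p.size
    if params.pi0 is None:
        pi0 = min(1.0, np.sum(p > params.lam) / (m * (1.0 - params.lam)))
        if pi0 <= 0:
            pi0 = 1.0 / m
    else:
        pi0 = params.pi0
    params.pi0, params.m = float(pi0), int(m)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def add_qvalues(records: pd.DataFrame, params: PFDRParams | None = None) -> pd.DataFrame:
    out = records.copy()
    out["q"] = qvalues_pfdr(out["p"].to_numpy(), params)
    return out


def call_differential(
    records: pd.DataFrame, fc_min: float = 1.5, q_max: float = 0.1
) -> tuple[list[str], list[str]]:
    """Flag DE features: |fold change| >= fc_min and q strictly < q_max.

    Adds an ``is_de`` column in place and returns (up ids, down ids).
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    if "q" not in records.columns:
        raise ValueError("records need q-values; run add_qvalues first")
    lfc_min = np.log2(fc_min)
    is_de = (np.abs(records["log2fc"]) >= lfc_min) & (records["q"] < q_max)
    records["is_de"] = is_de
    up = list(records.index[is_de & (records["direction"] > 0)])
    down = list(records.index[is_de & (records["direction"] < 0)])
    return up, down


def de_table_to_tsv(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
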