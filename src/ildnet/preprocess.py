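"""Normalization and present/absent calling.

Quantile normalization forces every sample column onto the common
per-rank mean distribution (ties receive the mean of the reference
values their rank block spans).  Presence calls fit a two-component,
equal-variance 1-D Gaussian mixture to per-feature mean log2 intensity
by EM; a feature is "present" when the posterior of the high component
exceeds 0.5.  Per the study's filtering policy, only present mRNA
features enter downstream statistics while miRNA matrices are used in
full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MIRNA


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the per-rank cross-sample means.

    After normalization every sample holds the identical multiset of
    values and within-sample feature ranks are preserved.  Tied input
    values all receive the mean of the reference values over the rank
    range the tie block occupies.
    """
    X = m.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("NaN or infinite values in input")
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)  # per-rank cross-sample means
    out = np.empty_like(X)
    rows = np.arange(n_feat)
    for j in range(n_samp):
        col_sorted_idx = order[:, j]
        assigned = np.empty(n_feat)
        assigned[col_sorted_idx] = reference
        # average reference values across tie blocks
        col = X[:, j]
        svals = col[col_sorted_idx]
        block_start = np.concatenate(([True], svals[1:] != svals[:-1]))
        block_id = np.cumsum(block_start) - 1
        sums = np.bincount(block_id, weights=reference)
        counts = np.bincount(block_id)
        block_mean = sums / counts
        assigned[col_sorted_idx] = block_mean[block_id]
        out[rows, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.feature_kind,
    )


@dataclass
class MixtureParams:
    mu_low: float
    mu_high: float
    sigma: float
    weight_high: float
    log_likelihood: float
    n_iter: int
    converged: bool
    fallback: bool  # True when the EM fit degenerated and a median split was used


@dataclass
class PresenceCalls:
    """Per-feature presence calls with the fitted mixture parameters."""

    table: pd.DataFrame  # columns: mean_log2, posterior_present, call
    params: MixtureParams

    @property
    def present_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "present"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def _em_two_gaussian(x: np.ndarray, tol: float, max_iter: int) -> MixtureParams:
    """Equal-variance 2-component 1-D Gaussian mixture via EM.

    Deterministic initialisation: split at the median.  The shared
    variance guarantees a single monotone decision boundary.
    """
    med = np.median(x)
    low = x[x <= med]
    high = x[x > med]
    if len(high) == 0 or len(low) == 0:
        return _fallback_params(x, med)
    mu1, mu2 = float(low.mean()), float(high.mean())
    sigma = float(np.sqrt(((low - mu1) ** 2).sum() + ((high - mu2) ** 2).sum()) / np.sqrt(len(x)))
    w = 0.5
    if sigma <= 0 or mu2 - mu1 < 1e-9:
        return _fallback_params(x, med)

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_p1 = np.log(1 - w) - 0.5 * ((x - mu1) / sigma) ** 2
        log_p2 = np.log(w) - 0.5 * ((x - mu2) / sigma) ** 2
        mx = np.maximum(log_p1, log_p2)
        denom = np.exp(log_p1 - mx) + np.exp(log_p2 - mx)
        r2 = np.exp(log_p2 - mx) / denom  # responsibility of high component
        ll = float(np.sum(mx + np.log(denom)) - len(x) * np.log(np.sqrt(2 * np.pi) * sigma))
        # M step
        w = float(r2.mean())
        if w <= 0 or w >= 1:
            return _fallback_params(x, med)
        mu1 = float(np.sum((1 - r2) * x) / np.sum(1 - r2))
        mu2 = float(np.sum(r2 * x) / np.sum(r2))
        var = float(np.sum((1 - r2) * (x - mu1) ** 2 + r2 * (x - mu2) ** 2) / len(x))
        if var <= 1e-12 or abs(mu2 - mu1) < 1e-9:
            return _fallback_params(x, med)
        sigma = float(np.sqrt(var))
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll
    if mu1 > mu2:
        mu1, mu2, w = mu2, mu1, 1 - w
    if not converged:
        warnings.warn(f"presence-call EM did not converge in {it} iterations", RuntimeWarning)
    return MixtureParams(mu1, mu2, sigma, w, ll, it, converged, fallback=False)


def _fallback_params(x: np.ndarray, med: float) -> MixtureParams:
    warnings.warn("degenerate mixture fit; falling back to median threshold", RuntimeWarning)
    return MixtureParams(
        mu_low=float(med), mu_high=float(med), sigma=float(x.std() or 1.0),
        weight_high=0.5, log_likelihood=np.nan, n_iter=0, converged=False, fallback=True,
    )


def call_presence(m: ExpressionMatrix, em_tol: float = 1e-8, max_iter: int = 500) -> PresenceCalls:
    """Fit the presence mixture on per-feature mean log2 intensity."""
    if m.n_features < 10:
        raise ValueError("need at least 10 features to fit the presence mixture")
    means = m.values.mean(axis=1).to_numpy(dtype=float)
    params = _em_two_gaussian(means, em_tol, max_iter)
    if params.fallback:
        posterior = (means > params.mu_low).astype(float)
    else:
        s = params.sigma
        log_p1 = np.log(1 - params.weight_high) - 0.5 * ((means - params.mu_low) / s) ** 2
        log_p2 = np.log(params.weight_high) - 0.5 * ((means - params.mu_high) / s) ** 2
        posterior = 1.0 / (1.0 + np.exp(log_p1 - log_p2))
    call = np.where(posterior > 0.5, "present", "absent")
    table = pd.DataFrame(
        {"mean_log2": means, "posterior_present": posterior, "call": call},
        index=m.values.index,
    )
    return PresenceCalls(table, params)


def apply_presence_filter(m: ExpressionMatrix, calls: PresenceCalls) -> ExpressionMatrix:
    """Keep only present mRNA features; miRNA matrices pass unfiltered."""
    if m.feature_kind == MIRNA:
        return m
    if set(calls.table.index) != set(m.values.index):
        raise ValueError("presence calls do not match matrix features")
    keep = [f for f in m.feature_ids if calls.table.loc[f, "call"] == "present"]
    return ExpressionMatrix(m.values.loc[keep], m.feature_kind)
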