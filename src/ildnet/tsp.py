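"""Top-scoring-pair (TSP) rank classifiers.

A pair of features (i, j) is scored by the between-class difference of
the empirical probability of the strict event X_i < X_j:

    Delta_ij = | P(X_i < X_j | class 1) - P(X_i < X_j | class 2) |

Ties X_i == X_j count as event-false, making scores deterministic on
discretised data.  Because only the within-sample order of the two
features matters, Delta is invariant under any strictly monotone
per-sample transformation.  A secondary rank-difference score Gamma
(between-class gap of the mean within-sample rank difference) breaks
ties among Delta-equal pairs, and a fully deterministic ordering falls
back to lexicographic pair ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class PairScore:
    feature_i: str
    feature_j: str
    delta: float
    gamma: float
    p_event_class1: float  # P(X_i < X_j) within class 1
    p_event_class2: float
    class1: str
    class2: str

    @property
    def rule(self) -> str:
        favored = self.class1 if self.p_event_class1 >= self.p_event_class2 else self.class2
        return f"predict {favored} iff {self.feature_i} < {self.feature_j}"


def _two_classes(labels: Sequence) -> tuple[np.ndarray, list]:
    lab = np.asarray(labels)
    classes = sorted(set(lab.tolist()))
    if len(classes) != 2:
        raise ValueError(f"TSP requires exactly 2 classes, got {classes}")
    return lab, classes


def tsp_scores(m: ExpressionMatrix, labels: Sequence) -> list[PairScore]:
    """Score and rank all feature pairs.

    Ranking: Delta descending, then Gamma descending, then lexicographic
    (feature_i, feature_j); each unordered pair is listed once with
    i < j lexicographically.
    """
    lab, classes = _two_classes(labels)
    c1, c2 = classes
    order = np.argsort(np.asarray(m.feature_ids))
    ids = [m.feature_ids[k] for k in order]
    X = m.values.to_numpy(dtype=float)[order]
    mask1 = lab == c1
    mask2 = lab == c2
    if mask1.sum() < 1 or mask2.sum() < 1:
        raise ValueError("each class needs at least one sample")

    # strict event X_i < X_j, per class; p x p x n broadcast
    less = X[:, None, :] < X[None, :, :]
    p1 = less[:, :, mask1].mean(axis=2)
    p2 = less[:, :, mask2].mean(axis=2)
    delta = np.abs(p1 - p2)

    # within-sample ranks across features, for the secondary score
    R = np.apply_along_axis(rankdata, 0, X)
    d = R[:, None, :] - R[None, :, :]
    gamma = np.abs(d[:, :, mask1].mean(axis=2) - d[:, :, mask2].mean(axis=2))

    iu, ju = np.triu_indices(len(ids), k=1)
    scores = [
        PairScore(ids[i], ids[j], float(delta[i, j]), float(gamma[i, j]),
                  float(p1[i, j]), float(p2[i, j]), str(c1), str(c2))
        for i, j in zip(iu, ju)
    ]
    scores.sort(key=lambda s: (-s.delta, -s.gamma, s.feature_i, s.feature_j))
    return scores


def tsp_classify(pair: PairScore, sample: pd.Series | dict) -> str:
    """Label one sample by the pair's orientation rule.

    The strict event X_i < X_j votes for the class where it was more
    prevalent in training; a false event (including exact ties) votes
    for the class with the higher training prevalence of the false
    event.  Equal prevalences resolve to the lexicographically smaller
    class label.
    """
    for f in (pair.feature_i, pair.feature_j):
        if f not in sample:
            raise KeyError(f"feature {f!r} missing from sample")
    event = sample[pair.feature_i] < sample[pair.feature_j]
    w1 = pair.p_event_class1 if event else 1.0 - pair.p_event_class1
    w2 = pair.p_event_class2 if event else 1.0 - pair.p_event_class2
    if w1 > w2:
        return pair.class1
    if w2 > w1:
        return pair.class2
    return min(pair.class1, pair.class2)


def tsp_cv(m: ExpressionMatrix, labels: Sequence) -> dict:
    """Leave-one-out cross-validation with per-fold pair re-selection.

    Deterministic: no randomness is involved.  Returns accuracy and the
    pair chosen in each fold.
    """
    lab, classes = _two_classes(labels)
    n = m.n_samples
    correct = 0
    folds = []
    for k in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[k] = False
        train_labels = lab[train_mask]
        for c in classes:
            if (train_labels == c).sum() == 0:
                raise ValueError(f"class {c!r} absent from training fold {k}")
        train = m.subset_samples([s for s, keep in zip(m.sample_ids, train_mask) if keep])
        best = tsp_scores(train, train_labels)[0]
        held_out = m.values.iloc[:, k]
        pred = tsp_classify(best, held_out)
        truth = str(lab[k])
        correct += pred == truth
        folds.append({
            "sample": m.sample_ids[k], "pair": (best.feature_i, best.feature_j),
            "predicted": pred, "true": truth,
        })
    return {"accuracy": correct / n, "folds": folds}


def scores_to_tsv(scores: list[PairScore], path: str | Path, top: int | None = None) -> None:
    rows = [
        {"feature_i": s.feature_i, "feature_j": s.feature_j, "delta": s.delta,
         "gamma": s.gamma, "rule": s.rule}
        for s in (scores[:top] if top else scores)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
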