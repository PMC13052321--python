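"""Diverse-subset selection by farthest-point (max-min) sampling.

A small subset drawn at random from the generator may not cover the learned
feature space; selecting candidates that are maximally spread out in scaled
feature space avoids skewing the downstream population fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

__all__ = ["pairwise_distances", "maxmin_select", "MaxMinSelector", "selection_report"]


def _as_array(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def pairwise_distances(table) -> np.ndarray:
    """Symmetric Euclidean distance matrix over all (scaled) columns."""
    x = _as_array(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return squareform(pdist(x))


def maxmin_select(pool, k: int) -> np.ndarray:
    """Greedy farthest-point subset of size ``k``.

    The first pick is the row farthest from the pool centroid; each later
    pick maximizes the minimum distance to the rows already selected.  Ties
    break toward the lowest row index, so the result is deterministic.
    Returns the selected row indices in pick order.
    """
    x = _as_array(pool)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    centroid = x.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(x - centroid, axis=1)))
    selected = [first]
    # running min distance of every row to the selected set
    min_d = np.linalg.norm(x - x[first], axis=1)
    for _ in range(k - 1):
        min_d[selected] = -np.inf
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        d_new = np.linalg.norm(x - x[nxt], axis=1)
        min_d = np.minimum(min_d, d_new)
    return np.asarray(selected, dtype=int)


class MaxMinSelector(BaseEstimator):
    """sklearn-style wrapper around :func:`maxmin_select`.

    ``fit(X)`` records ``selected_idx_`` and ``min_distance_trace_``;
    ``transform(X)`` returns the selected rows in pick order.
    """

    def __init__(self, k: int = 20):
        self.k = k

    def fit(self, X, y=None):
        self.selected_idx_ = maxmin_select(X, self.k)
        x = _as_array(X)
        trace = [float("inf")]
        for j in range(1, len(self.selected_idx_)):
            picked = x[self.selected_idx_[:j]]
            d = np.linalg.norm(picked - x[self.selected_idx_[j]], axis=1)
            trace.append(float(d.min()))
        self.min_distance_trace_ = np.asarray(trace)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.iloc[self.selected_idx_]
        return _as_array(X)[self.selected_idx_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def selection_report(selector: MaxMinSelector) -> dict:
    """JSON-ready record of the selection (indices + min-distance trace)."""
    return {
        "k": int(selector.k),
        "selected_indices": [int(i) for i in selector.selected_idx_],
        "min_distance_trace": [
            None if np.isinf(d) else float(d) for d in selector.min_distance_trace_
        ],
    }
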