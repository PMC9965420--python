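"""Component-matching helpers shared by tests, reports, and the pipeline."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["match_rows", "align_by_correlation", "pearson_columns"]


def match_rows(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permutation p minimizing total Euclidean distance estimated[p[i]] <-> truth[i].

    Minimum-cost assignment on the pairwise distance matrix; used to align
    recovered components (vertices, topics) with a planted ground truth
    before measuring errors.
    """
    cost = cdist(np.atleast_2d(truth), np.atleast_2d(estimated))
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix between columns of a and columns of b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    denom = np.outer(np.linalg.norm(az, axis=0), np.linalg.norm(bz, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az.T @ bz) / denom
    return np.where(denom > 0, r, np.nan)


def align_by_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Permutation p maximizing sum of Pearson r between a[:, p[j]] and b[:, j]."""
    r = pearson_columns(a, b)
    cost = np.where(np.isnan(r), 0.0, r)
    rows, cols = linear_sum_assignment(-cost.T)  # rows index b's columns
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm
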