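"""Jenks natural-breaks classification.

Exact dynamic programming over sorted values minimising the total
within-class sum of squared deviations (the Fisher-Jenks optimisation);
ties between equally good partitions break towards smaller upper bounds.
District choropleth classification reserves the lowest of the five classes
for no-data and zero-value districts, as conventional for maps where some
districts contribute no observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import McprError

__all__ = [
    "jenks_breaks",
    "goodness_of_variance_fit",
    "JenksNaturalBreaks",
    "JenksResult",
    "classify_districts",
]


def _class_ssd_matrix(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-class SSD of sorted x[i..j] inclusive."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    s = cs[j + 1] - cs[i]
    s2 = cs2[j + 1] - cs2[i]
    with np.errstate(invalid="ignore"):
        cost = s2 - s**2 / cnt
    return np.where(j >= i, np.maximum(cost, 0.0), np.inf)


def jenks_breaks(values, k: int) -> list[float]:
    """Optimal k-class natural breaks (upper bounds, ascending).

    Exact DP: D[m][j] = min over split s of D[m-1][s-1] + SSD(s..j).
    Updating only on strictly smaller cost makes the reconstruction
    deterministic and prefers smaller upper bounds on ties.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(x)):
        raise McprError("values must be finite")
    n_distinct = len(np.unique(x))
    if k < 1:
        raise McprError("k must be >= 1")
    if k > n_distinct:
        raise McprError(f"k={k} exceeds the {n_distinct} distinct values")
    n = len(x)
    cost = _class_ssd_matrix(x)
    D = np.full((k + 1, n), np.inf)
    split = np.zeros((k + 1, n), dtype=int)
    D[1, :] = cost[0, :]
    for m in range(2, k + 1):
        for j in range(m - 1, n):
            for s in range(m - 1, j + 1):
                c = D[m - 1, s - 1] + cost[s, j]
                if c < D[m, j]:
                    D[m, j] = c
                    split[m, j] = s
    # reconstruct class upper bounds
    bounds = []
    j = n - 1
    for m in range(k, 0, -1):
        bounds.append(float(x[j]))
        j = split[m, j] - 1
    return bounds[::-1]


def _assign(values: np.ndarray, breaks: list[float]) -> np.ndarray:
    """Class index 1..k by first break >= value (top class absorbs above)."""
    idx = np.searchsorted(np.asarray(breaks), values, side="left") + 1
    return np.minimum(idx, len(breaks))


def total_ssd(values: np.ndarray) -> float:
    v = np.asarray(values, float)
    return float(np.sum((v - v.mean()) ** 2))


def goodness_of_variance_fit(values, breaks) -> float:
    """GVF = 1 - (within-class SSD / total SSD), in [0, 1]."""
    v = np.asarray(values, float)
    tss = total_ssd(v)
    if tss == 0:
        return 1.0
    cls = _assign(v, breaks)
    wss = sum(total_ssd(v[cls == c]) for c in np.unique(cls))
    return 1.0 - wss / tss


class JenksNaturalBreaks(BaseEstimator):
    """Natural-breaks classifier with a scikit-learn surface.

    ``fit`` learns the break points on a 1-D value array; ``predict``
    assigns class labels 1..k by the learned upper bounds.  Fitted
    attributes: ``breaks_``, ``labels_``, ``gvf_``.
    """

    def __init__(self, n_classes: int = 5):
        self.n_classes = n_classes

    def fit(self, X, y=None):
        v = np.ravel(np.asarray(X, float))
        self.breaks_ = jenks_breaks(v, self.n_classes)
        self.labels_ = _assign(v, self.breaks_)
        self.gvf_ = goodness_of_variance_fit(v, self.breaks_)
        return self

    def predict(self, X):
        return _assign(np.ravel(np.asarray(X, float)), self.breaks_)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class JenksResult:
    k: int
    breaks: list[float]          # ascending upper bounds of the valued classes
    assignments: dict            # district_id -> class 1..k
    gvf: float
    n_no_data: int = 0


def classify_districts(district_values: pd.Series, k: int = 5) -> JenksResult:
    """Five-class district choropleth with a reserved bottom class.

    Missing and zero-valued districts go to class 1; the remaining positive
    values are Jenks-classified into the upper classes (2..k when enough
    distinct values exist; with fewer distinct values the occupied classes
    stack down from class k, so a single valued district lands in the top
    class).  The top class's upper bound equals the data maximum.
    """
    s = pd.Series(district_values, dtype=float)
    if s.notna().sum() == 0:
        raise McprError("all districts missing")
    no_data = s.isna() | (s == 0)
    pos = s[~no_data]
    assignments = {did: 1 for did in s.index[no_data]}
    if len(pos) == 0:
        return JenksResult(k=k, breaks=[], assignments=assignments, gvf=1.0,
                           n_no_data=int(no_data.sum()))
    if not no_data.any() and len(np.unique(pos)) >= k:
        breaks = jenks_breaks(pos.to_numpy(), k)
        offset = 0
    else:
        n_cls = min(k - 1, len(np.unique(pos)))
        breaks = jenks_breaks(pos.to_numpy(), n_cls)
        offset = k - n_cls
    cls = _assign(pos.to_numpy(), breaks) + offset
    assignments.update(dict(zip(pos.index, (int(c) for c in cls))))
    gvf = goodness_of_variance_fit(pos.to_numpy(), breaks)
    return JenksResult(k=k, breaks=breaks, assignments=assignments, gvf=gvf,
                       n_no_data=int(no_data.sum()))
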