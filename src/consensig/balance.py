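"""ADASYN oversampling of the minority class.

Adaptive synthetic sampling puts more synthetic points near the class
boundary: each minority sample gets a share of the synthetic budget
proportional to the fraction of majority samples among its k nearest
neighbours, and each synthetic point is a random convex combination of
the sample and one of its k nearest *minority* neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class BalancedSet:
    X: np.ndarray  # (n_original + n_synthetic, n_features)
    y: np.ndarray
    origin: np.ndarray  # "original" / "synthetic" per row

    @property
    def n_synthetic(self) -> int:
        return int(np.sum(self.origin == "synthetic"))


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to `total` (ties: lowest index).

    Plain per-point rounding of r̂_i * G can miss G by up to half the
    minority size, which would leave the classes visibly unbalanced; the
    largest-remainder rule keeps every g_i within 1 of round(r̂_i * G)
    while making the totals exact.
    """
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def adasyn(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    beta: float = 1.0,
    seed: Optional[int] = None,
) -> BalancedSet:
    """Balance a two-class sample by adaptive synthetic minority oversampling.

    Generates ``G = round(beta * (m_majority - m_minority))`` synthetic
    minority points.  Point ``x_i`` receives ``g_i = round(r̂_i * G)`` of
    them, where ``r_i`` is the majority fraction among its ``k`` nearest
    neighbours in the full sample (normalised to ``r̂``; uniform fallback
    when no minority point has majority neighbours).  Each synthetic point
    is ``x_i + λ (x_z − x_i)`` with ``λ ~ U(0,1)`` and ``x_z`` drawn from
    the ``k`` nearest minority neighbours of ``x_i`` (any other minority
    point if it has none).  Euclidean metric; deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ADASYN requires exactly two classes in y")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    m_min, m_maj = counts.min(), counts.max()
    if m_min < 2:
        raise ValueError("minority class needs at least 2 samples to interpolate")

    origin = np.array(["original"] * len(y))
    G = int(round(beta * (m_maj - m_min)))
    if G <= 0:
        return BalancedSet(X.copy(), y.copy(), origin)

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    Xmin = X[min_idx]

    # majority fraction among k nearest neighbours in the full set
    k_full = min(k, len(y) - 1)
    nn_all = NearestNeighbors(n_neighbors=k_full + 1).fit(X)
    _, ind = nn_all.kneighbors(Xmin)
    neigh = ind[:, 1:]  # drop self
    r = np.array([(y[row] == majority).mean() for row in neigh])
    if r.sum() == 0:
        r_hat = np.full(m_min, 1.0 / m_min)
    else:
        r_hat = r / r.sum()
    g = _largest_remainder(r_hat * G, G)

    # k nearest minority neighbours of each minority point
    k_min = min(k, m_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Xmin)
    _, ind_min = nn_min.kneighbors(Xmin)
    min_neigh = ind_min[:, 1:]

    synth: list[np.ndarray] = []
    for i in np.flatnonzero(g > 0):
        for _ in range(g[i]):
            z = min_neigh[i][rng.integers(0, min_neigh.shape[1])]
            lam = rng.uniform()
            synth.append(Xmin[i] + lam * (Xmin[z] - Xmin[i]))
    if not synth:
        return BalancedSet(X.copy(), y.copy(), origin)
    Xs = np.vstack(synth)
    return BalancedSet(
        np.vstack([X, Xs]),
        np.concatenate([y, np.full(len(Xs), minority, dtype=y.dtype)]),
        np.concatenate([origin, np.array(["synthetic"] * len(Xs))]),
    )
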