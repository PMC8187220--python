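"""Dataset splitting and sampling: random, farthest-point, structure-based, k-fold.

Distances are always Euclidean distances between descriptor vectors, never
raw coordinates.  All randomness flows through ``numpy.random.default_rng``
(PCG64), recorded so splits are reproducible across platforms.  Deterministic
tie-breaks: the lowest index wins.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .data import SplitIndices

__all__ = ["random_split", "fps_order", "sbs_order", "kfold_splits"]


def random_split(
    n: int,
    fractions: Mapping[str, float] | None = None,
    counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SplitIndices:
    """Uniform split without replacement into named groups.

    By default 80%:20% training:test.  Fractional sizes are rounded to
    nearest; any requested sizes exceeding ``n`` raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if counts is None:
        fractions = dict(fractions or {"training": 0.8, "test": 0.2})
        if sum(fractions.values()) > 1 + 1e-12:
            raise ValueError("fractions sum exceeds 1")
        counts = {}
        names = list(fractions)
        for name in names[:-1]:
            counts[name] = int(round(fractions[name] * n))
        # last group absorbs rounding so a full partition stays a partition
        if abs(sum(fractions.values()) - 1) < 1e-12:
            counts[names[-1]] = n - sum(counts.values())
        else:
            counts[names[-1]] = int(round(fractions[names[-1]] * n))
    total = sum(counts.values())
    if total > n:
        raise ValueError(f"requested {total} points but only {n} available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups: dict[str, np.ndarray] = {}
    start = 0
    for name, c in counts.items():
        groups[name] = np.sort(perm[start : start + c])
        start += c
    split = SplitIndices(groups)
    split.validate_disjoint()
    return split


def _pairwise_sq(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def fps_order(x_vectors: np.ndarray) -> np.ndarray:
    """Greedy farthest-point ordering of descriptor vectors.

    The first two indices are the globally most distant pair; each subsequent
    index maximizes the minimum distance to everything already selected, so
    any prefix of the returned ordering is itself an FPS sample.
    """
    x = np.atleast_2d(np.asarray(x_vectors, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("FPS needs at least 2 points")
    d2 = _pairwise_sq(x)
    # most distant pair; ties resolved toward the lexicographically first (i, j)
    flat = np.argmax(d2)
    i, j = divmod(int(flat), n)
    first, second = min(i, j), max(i, j)
    order = [first, second]
    min_d2 = np.minimum(d2[first], d2[second])
    selected = np.zeros(n, dtype=bool)
    selected[[first, second]] = True
    for _ in range(n - 2):
        masked = np.where(selected, -np.inf, min_d2)
        nxt = int(np.argmax(masked))  # argmax returns the lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        min_d2 = np.minimum(min_d2, d2[nxt])
    return np.array(order, dtype=int)


def _greedy_from_seed(d2: np.ndarray, members: np.ndarray, seed_pos: int) -> list[int]:
    """FPS-style greedy ordering restricted to ``members``, starting at seed_pos
    (position within members)."""
    m = len(members)
    sub = d2[np.ix_(members, members)]
    order = [seed_pos]
    min_d2 = sub[seed_pos].copy()
    chosen = np.zeros(m, dtype=bool)
    chosen[seed_pos] = True
    for _ in range(m - 1):
        masked = np.where(chosen, -np.inf, min_d2)
        nxt = int(np.argmax(masked))
        order.append(nxt)
        chosen[nxt] = True
        min_d2 = np.minimum(min_d2, sub[nxt])
    return [int(members[i]) for i in order]


def sbs_order(x_vectors: np.ndarray, eq_index: int, n_slices: int = 5) -> np.ndarray:
    """Structure-based sampling order: distance-to-equilibrium slicing + greedy FPS.

    Points are sorted by Euclidean distance to the equilibrium descriptor and
    partitioned into ``n_slices`` contiguous, near-equal regions of increasing
    deformation.  A greedy max-min ordering is built within each slice — the
    slice containing the equilibrium point is seeded with it, the others with
    their point nearest to equilibrium — and slices are interleaved
    proportionally to their sizes, so any prefix draws from all deformation
    regions.  Fully deterministic.
    """
    x = np.atleast_2d(np.asarray(x_vectors, dtype=float))
    n = x.shape[0]
    if not 0 <= eq_index < n:
        raise ValueError("eq_index out of range")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if n_slices > n:
        raise ValueError("more slices than points")
    dist_eq = np.linalg.norm(x - x[eq_index], axis=1)
    by_dist = np.argsort(dist_eq, kind="stable")
    slices = np.array_split(by_dist, n_slices)
    d2 = _pairwise_sq(x)
    per_slice_orders: list[list[int]] = []
    for s, members in enumerate(slices):
        members = np.asarray(members)
        if eq_index in members:
            seed_pos = int(np.where(members == eq_index)[0][0])
        else:
            seed_pos = int(np.argmin(dist_eq[members]))
        per_slice_orders.append(_greedy_from_seed(d2, members, seed_pos))
    # proportional interleave: always take from the slice with the largest quota deficit
    sizes = np.array([len(o) for o in per_slice_orders], dtype=float)
    taken = np.zeros(len(per_slice_orders))
    cursors = [0] * len(per_slice_orders)
    merged: list[int] = []
    for m in range(n):
        deficit = (m + 1) * sizes / n - taken
        deficit[[c >= len(o) for c, o in zip(cursors, per_slice_orders)]] = -np.inf
        s = int(np.argmax(deficit))
        merged.append(per_slice_orders[s][cursors[s]])
        cursors[s] += 1
        taken[s] += 1
    return np.array(merged, dtype=int)


def kfold_splits(n: int, k: int, seed: int = 0) -> list[SplitIndices]:
    """k-fold cross-validation splits: fold sizes differ by at most one and
    every index validates exactly once across folds (k = n is leave-one-out)."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, fold in enumerate(folds):
        train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        out.append(SplitIndices({"training": train, "validation": np.sort(fold)}))
    return out
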