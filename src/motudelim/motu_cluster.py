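"""Furthest-neighbor (complete linkage) MOTU clustering and threshold sweeps.

Sequences are agglomerated by repeatedly merging the two clusters with the
smallest complete-linkage (maximum pairwise) distance while that distance
does not exceed the threshold (inclusive). Complete linkage is inversion-
free, so the merge heights are non-decreasing and the partition at a lower
threshold always refines the partition at a higher one; a sweep therefore
replays a single merge sequence, cut at each grid point.

Ties between candidate merges are broken deterministically: the pair whose
smallest member index (input order) is lowest wins, then the other
cluster's smallest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from motudelim.distances import DistanceMatrix

__all__ = ["MotuPartition", "SweepCurve", "Plateau", "cluster_at", "sweep", "find_plateaus"]


@dataclass
class MotuPartition:
    """Assignment of every sequence to a MOTU."""

    threshold: float | None
    method: str  # furthest_neighbor | abgd | ptp
    assignment: dict[str, str]
    n_motus: int

    def __post_init__(self) -> None:
        assert self.n_motus == len(set(self.assignment.values()))

    def motus(self) -> dict[str, list[str]]:
        """MOTU id -> member sample ids (input order preserved)."""
        out: dict[str, list[str]] = {}
        for sid, motu in self.assignment.items():
            out.setdefault(motu, []).append(sid)
        return out


@dataclass(frozen=True)
class SweepCurve:
    """MOTU count per threshold over a grid (thresholds in percent)."""

    grid: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class Plateau:
    """A maximal run of constant MOTU count along the sweep grid (percent units)."""

    start: float
    end: float
    count: int
    length: int


def _complete_linkage_merges(values: np.ndarray) -> list[tuple[float, int, int]]:
    """Full complete-linkage merge sequence with the deterministic tie-break.

    Returns ``(height, a, b)`` triples where a and b are representative
    indices (the cluster's smallest member index); heights are
    non-decreasing. Cached per matrix by the callers.
    """
    n = values.shape[0]
    if np.isnan(values).any():
        raise ValueError("distance matrix contains undefined entries")
    C = values.astype(float).copy()
    np.fill_diagonal(C, np.inf)
    active = np.ones(n, dtype=bool)
    minmem = np.arange(n)  # smallest member index of the cluster rooted at slot i
    merges: list[tuple[float, int, int]] = []
    for _ in range(n - 1):
        sub = np.where(active)[0]
        block = C[np.ix_(sub, sub)]
        h = block.min()
        ai, aj = np.where(block == h)
        best = None
        for x, y in zip(ai, aj):
            if x >= y:
                continue
            a, b = sub[x], sub[y]
            key = tuple(sorted((minmem[a], minmem[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merges.append((float(h), int(min(minmem[a], minmem[b])), int(max(minmem[a], minmem[b]))))
        # Lance-Williams update for complete linkage: d(new, k) = max(d(a,k), d(b,k))
        C[a, :] = np.maximum(C[a, :], C[b, :])
        C[:, a] = C[a, :]
        C[a, a] = np.inf
        active[b] = False
        minmem[a] = min(minmem[a], minmem[b])
    return merges


def _merges_of(dm: DistanceMatrix) -> list[tuple[float, int, int]]:
    if not hasattr(dm, "_cl_merges"):
        dm._cl_merges = _complete_linkage_merges(dm.values)
    return dm._cl_merges


def _cut(dm: DistanceMatrix, threshold: float) -> tuple[dict[str, str], int]:
    parent = list(range(dm.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h, a, b in _merges_of(dm):
        if h > threshold:
            break
        ra, rb = find(a), find(b)
        # root at the smaller index so MOTU ids follow first appearance
        parent[max(ra, rb)] = min(ra, rb)
    roots_seen: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for i, sid in enumerate(dm.ids):
        r = find(i)
        if r not in roots_seen:
            roots_seen[r] = f"MOTU_{len(roots_seen) + 1:04d}"
        assignment[sid] = roots_seen[r]
    return assignment, len(roots_seen)


def cluster_at(dm: DistanceMatrix, threshold: float) -> MotuPartition:
    """Furthest-neighbor partition at ``threshold`` (proportion, inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    assignment, k = _cut(dm, threshold)
    return MotuPartition(threshold=threshold, method="furthest_neighbor",
                         assignment=assignment, n_motus=k)


def sweep(
    dm: DistanceMatrix,
    grid_start: float = 0.0,
    grid_end: float = 8.0,
    step: float = 0.1,
) -> SweepCurve:
    """MOTU count at each threshold of a percent-unit grid (inclusive ends)."""
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.round(np.arange(grid_start, grid_end + step / 2, step), 10)
    counts = np.array([_cut(dm, t / 100.0)[1] for t in grid], dtype=int)
    assert (np.diff(counts) <= 0).all(), "MOTU count must be non-increasing in threshold"
    return SweepCurve(grid=grid, counts=counts)


def find_plateaus(curve: SweepCurve, min_length: int = 3) -> list[Plateau]:
    """Maximal constant-count runs of at least ``min_length`` grid steps."""
    if len(curve.grid) == 0:
        raise ValueError("empty sweep curve")
    out: list[Plateau] = []
    start = 0
    for i in range(1, len(curve.counts) + 1):
        if i == len(curve.counts) or curve.counts[i] != curve.counts[start]:
            length = i - start
            if length >= min_length:
                out.append(
                    Plateau(start=float(curve.grid[start]), end=float(curve.grid[i - 1]),
                            count=int(curve.counts[start]), length=length)
                )
            start = i
    return out
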