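import numpy as np
import pytest

from nucalign import LandmarkCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def generic_cloud(rng):
    """A small named cloud in general position."""
    pts = rng.uniform(-10, 10, size=(12, 3))
    names = tuple(f"c{i:02d}" for i in range(12))
    return LandmarkCloud(points=pts, names=names, source_id="generic")


def brute_force_gabriel(points: np.ndarray) -> set[tuple[int, int]]:
    """O(n^3) all-pairs/all-witness Gabriel oracle (strict open-ball test)."""
    n = len(points)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            d2 = np.dot(points[i] - points[j], points[i] - points[j])
            blocked = any(
                np.dot(points[i] - points[w], points[i] - points[w])
                + np.dot(points[j] - points[w], points[j] - points[w]) < d2
                for w in range(n) if w not in (i, j))
            if not blocked:
                edges.add((i, j))
    return edges


def brute_force_lap(cost: np.ndarray) -> float:
    """Exhaustive minimum-cost injection of the smaller side into the larger."""
    from itertools import permutations
    n, m = cost.shape
    best = np.inf
    if n <= m:
        for perm in permutations(range(m), n):
            c = sum(cost[i, p] for i, p in enumerate(perm))
            best = min(best, c)
    else:
        for perm in permutations(range(n), m):
            c = sum(cost[p, j] for j, p in enumerate(perm))
            best = min(best, c)
    return best
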