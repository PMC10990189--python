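import numpy as np
import pytest

import worklife as wl


@pytest.fixture(scope="session")
def small_bundle():
    """Shared 400-person default synthetic panel."""
    return wl.generate_bundle(400, seed=17)


@pytest.fixture(scope="session")
def small_distances(small_bundle):
    panel = small_bundle.sequences.fill_gaps()
    cm = wl.trate_costs(wl.estimate_transition_rates(panel))
    return panel, cm, wl.pairwise_distances(panel, cm)


def om_oracle(a, b, indel, sub):
    """Independent recursive-memo optimal-matching aligner.

    ``sub`` is a mapping (tok_a, tok_b) -> cost.  Used as the oracle for
    the dynamic-programming implementation; shares no code with it.
    """
    from functools import lru_cache

    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == len(a):
            return (len(b) - j) * indel
        if j == len(b):
            return (len(a) - i) * indel
        return min(
            d(i + 1, j) + indel,
            d(i, j + 1) + indel,
            d(i + 1, j + 1) + sub[(a[i], b[j])],
        )

    return d(0, 0)


def enumerate_edit_costs(a, b, indel, sub):
    """Exhaustive enumeration over all monotone alignments (tiny inputs)."""
    a, b = tuple(a), tuple(b)

    def rec(i, j):
        if i == len(a) and j == len(b):
            yield 0.0
            return
        if i < len(a):
            for c in rec(i + 1, j):
                yield c + indel
        if j < len(b):
            for c in rec(i, j + 1):
                yield c + indel
        if i < len(a) and j < len(b):
            for c in rec(i + 1, j + 1):
                yield c + sub[(a[i], b[j])]

    return min(rec(0, 0))


def naive_ward_merges(points):
    """Greedy O(n^3) Ward agglomeration from coordinates.

    At each step merges the pair of clusters whose union minimizes the
    increase in within-cluster sum of squares.  Returns the list of
    (frozenset_a, frozenset_b, height) merges with Ward.D2-scale heights
    ``sqrt(2 * delta_SSE)``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    clusters = {i: frozenset([i]) for i in range(len(points))}
    merges = []
    next_key = len(points)

    def sse(members):
        xs = points[sorted(members)]
        return float(((xs - xs.mean(axis=0)) ** 2).sum())

    while len(clusters) > 1:
        best = None
        for ka in sorted(clusters):
            for kb in sorted(clusters):
                if kb <= ka:
                    continue
                u = clusters[ka] | clusters[kb]
                inc = sse(u) - sse(clusters[ka]) - sse(clusters[kb])
                if best is None or inc < best[0] - 1e-12:
                    best = (inc, ka, kb)
        inc, ka, kb = best
        merged = clusters.pop(ka) | clusters.pop(kb)
        merges.append((merged, np.sqrt(2 * inc)))
        clusters[next_key] = merged
        next_key += 1
    return merges
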