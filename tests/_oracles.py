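"""Independent oracles used by the tests.

These deliberately re-derive quantities by brute force (grid scans, direct
recursions, exhaustive agglomeration) without calling the code paths they
check.
"""

from __future__ import annotations

import numpy as np

_BASIC = {"Amino": None, "K": "K", "R": "R", "H": "H"}
_ACIDIC = {"Carboxyl": None, "D": "D", "E": "E", "C": "C", "Y": "Y"}


def charge_at(sequence: str, ph: np.ndarray, pks: dict[str, float]) -> np.ndarray:
    """Direct two-sum Henderson-Hasselbalch evaluation (termwise, no vectorized
    grouping tricks shared with the implementation)."""
    ph = np.asarray(ph, dtype=float)
    total = np.zeros_like(ph)
    groups = ["Amino", "Carboxyl"]
    for c in sequence:
        if c in "KRH":
            groups.append(c)
        elif c in "DECY":
            groups.append(c)
    for g in groups:
        pk = pks[g]
        if g in _BASIC:
            total = total + 1.0 / (1.0 + 10.0 ** (ph - pk))
        else:
            total = total - 1.0 / (1.0 + 10.0 ** (pk - ph))
    return total


def grid_scan_pi(sequence: str, pks: dict[str, float], step: float = 1e-4) -> float:
    """pI as the grid pH with the smallest |net charge|."""
    grid = np.arange(step, 14.0, step)
    q = charge_at(sequence, grid, pks)
    return float(grid[np.argmin(np.abs(q))])


def exponential_smooth_recursion(x, d: float) -> list[float]:
    """Plain-python s1 = x1; s_t = (1-d) x_t + d s_{t-1}."""
    out = [float(x[0])]
    for v in x[1:]:
        out.append((1.0 - d) * float(v) + d * out[-1])
    return out


def brute_force_average_linkage(D: np.ndarray, labels: list[str]
                                ) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration: repeatedly merge the pair of clusters with the
    smallest mean pairwise dissimilarity; ties by smallest sorted label pair."""
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                d = np.mean([D[idx[x], idx[y]] for x in ca for y in cb])
                key = (d, tuple(sorted(ca | cb)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        ca, cb = clusters[a], clusters[b]
        merges.append((ca, cb, float(d)))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(ca | cb)
    return merges


def brute_force_motif_count(sequence: str, unit_len: int, matcher) -> int:
    """Non-overlapping left-to-right count by position-by-position scanning."""
    count = 0
    i = 0
    while i + unit_len <= len(sequence):
        if matcher(sequence[i:i + unit_len]):
            count += 1
            i += unit_len
        else:
            i += 1
    return count
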