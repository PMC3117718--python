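"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by slower, simpler routes than the
implementation: an unbanded full dynamic-programming co-start aligner, a
Warshall-style reachability clustering, and an O(n²) prefix scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _full_dp(s: np.ndarray, t: np.ndarray, match: int, mismatch: int, gap: int) -> int:
    """Unbanded co-start alignment score: anchored at (0, 0), consumes all
    of the shorter sequence ``s`` and ends anywhere in ``t``."""
    m, n = len(s), len(t)
    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        prev[j] = gap * j
    for i in range(1, m + 1):
        cur[0] = gap * i
        for j in range(1, n + 1):
            sub = match if s[i - 1] == t[j - 1] else mismatch
            best = prev[j - 1] + sub
            if prev[j] + gap > best:
                best = prev[j] + gap
            if cur[j - 1] + gap > best:
                best = cur[j - 1] + gap
            cur[j] = best
        prev, cur = cur, prev
    best = prev[0]
    for j in range(1, n + 1):
        if prev[j] > best:
            best = prev[j]
    return best


_ENC = np.zeros(128, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENC[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def costart_score(a: str, b: str, match: int = 1, mismatch: int = -2, gap: int = -3) -> int:
    s, t = (a, b) if len(a) <= len(b) else (b, a)
    return int(_full_dp(encode(s), encode(t), match, mismatch, gap))


def brute_force_clusters(
    reads: list[tuple[str, str]],
    score_threshold: int = 100,
    length_diff_max: int = 70,
    aggressive: bool = False,
) -> set[frozenset[str]]:
    """All-pairs full-DP clustering under the duplicate edge criteria,
    components found by boolean-matrix transitive closure."""
    n = len(reads)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ida, sa = reads[i]
            idb, sb = reads[j]
            if not aggressive and abs(len(sa) - len(sb)) >= length_diff_max:
                continue
            if costart_score(sa, sb) > score_threshold:
                adj[i, j] = adj[j, i] = True
    reach = adj.copy()
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    seen: set[int] = set()
    clusters = set()
    for i in range(n):
        if i in seen:
            continue
        comp = set(np.flatnonzero(reach[i]))
        seen |= comp
        clusters.add(frozenset(reads[k][0] for k in comp))
    return clusters


def brute_force_prefix_pairs(reads: list[tuple[str, str]], k: int) -> set[tuple[str, str]]:
    """O(n²) scan for pairs sharing their first k bases."""
    pairs = set()
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            ida, sa = reads[i]
            idb, sb = reads[j]
            if len(sa) >= k and len(sb) >= k and sa[:k] == sb[:k]:
                pairs.add((min(ida, idb), max(ida, idb)))
    return pairs
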