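"""Paired-end linker detection and read splitting.

A 454 paired-end read is the concatenation end1 + linker + end2 produced
by sequencing across the junction of a circularised fragment.  Locating
the linker inside the read defines the mate pair; a missing, truncated or
badly placed linker makes the read unusable as a pair but often still
usable as a single read.

Linker occurrences are found with a Smith-Waterman local alignment
(match +1, mismatch −2, gap −3 per base) of each linker against the read,
on both strands.  A hit is *full* when it spans the entire linker with at
most ``full_mismatch_max`` mismatches+gaps, *partial* otherwise; hits
covering less than ``partial_min_completeness`` of the linker are ignored
as noise.

The decision tree over the surviving hits:

==== =========================================== =================
case situation                                   action
==== =========================================== =================
a    no linker                                   keep whole single
b    two or more linker hits                     discard
c    one partial hit within ``end_margin``       clip linker, keep
     of either read end                          longer flank
d    one partial hit, internal                   discard
e    one full hit, both flanks >= min_end_len    emit mate pair
f    one full hit, neither flank long enough     discard
g    one full hit, exactly one flank long enough keep that flank
==== =========================================== =================
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .io_formats import Read

__all__ = [
    "Linker",
    "LinkerMatch",
    "PairendConfig",
    "Action",
    "PairendDecision",
    "find_linker_matches",
    "classify_pairend",
    "split_pairend",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Linker:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("linker sequence must be non-empty")


@dataclass(frozen=True)
class LinkerMatch:
    """A located (possibly partial) linker occurrence inside a read."""

    linker_id: str
    start: int
    end: int  # half-open on the read
    strand: str  # '+' or '-'
    matches: int
    mismatches: int
    gapped_bases: int
    completeness: float  # matched linker span / linker length
    score: int


@dataclass
class PairendConfig:
    """Thresholds of the linker decision tree (all exposed as CLI flags)."""

    min_end_len: int = 50
    full_mismatch_max: int = 2
    partial_min_completeness: float = 0.5
    end_margin: int = 5

    def __post_init__(self) -> None:
        if min(self.min_end_len, self.full_mismatch_max, self.end_margin) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.partial_min_completeness <= 1:
            raise ValueError("partial_min_completeness must be in (0, 1]")


class Action(Enum):
    SINGLE_WHOLE = "single_whole"
    DISCARD = "discard"
    SINGLE_CLIPPED = "single_clipped"
    PAIR = "pair"


@dataclass
class PairendDecision:
    case_label: str  # one of a-g
    action: Action
    clip_interval: Optional[tuple[int, int]] = None  # region kept (clipped single)
    pair_intervals: Optional[tuple[tuple[int, int], tuple[int, int]]] = None


_MATCH, _MISMATCH, _GAP = 1, -2, -3


def _smith_waterman(query: str, target: str) -> Optional[tuple[int, int, int, int, int, int, int, int]]:
    """Best local alignment of query inside target.

    Returns (score, q_start, q_end, t_start, t_end, matches, mismatches,
    gapped_bases) or None if no positive-scoring alignment exists.
    Masked target positions ('#') never match.
    """
    lq, lt = len(query), len(target)
    h = [[0] * (lt + 1) for _ in range(lq + 1)]
    ptr = [[0] * (lt + 1) for _ in range(lq + 1)]  # 1 diag, 2 up, 3 left
    best, bi, bj = 0, 0, 0
    for i in range(1, lq + 1):
        qi = query[i - 1]
        hi, hp, pi = h[i], h[i - 1], ptr[i]
        for j in range(1, lt + 1):
            sub = _MATCH if qi == target[j - 1] else _MISMATCH
            s, op = hp[j - 1] + sub, 1
            u = hp[j] + _GAP
            if u > s:
                s, op = u, 2
            left = hi[j - 1] + _GAP
            if left > s:
                s, op = left, 3
            if s <= 0:
                s, op = 0, 0
            hi[j] = s
            pi[j] = op
            if s > best:
                best, bi, bj = s, i, j
    if best <= 0:
        return None
    i, j = bi, bj
    matches = mismatches = gaps = 0
    while ptr[i][j]:
        op = ptr[i][j]
        if op == 1:
            if query[i - 1] == target[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif op == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return best, i, bi, j, bj, matches, mismatches, gaps


def find_linker_matches(
    r: Read, linkers: list[Linker], cfg: PairendConfig | None = None
) -> list[LinkerMatch]:
    """All non-overlapping linker occurrences in ``r``, both strands.

    Each linker is searched iteratively: the best local hit is taken, its
    read interval masked, and the search repeated until no hit reaches
    ``partial_min_completeness``.  Candidate hits from all linkers and
    strands are then merged greedily by score (ties to the leftmost
    start) into a non-overlapping set, returned sorted by read position.
    """
    cfg = cfg or PairendConfig()
    candidates: list[LinkerMatch] = []
    for linker in linkers:
        for strand, lseq in (("+", linker.seq), ("-", revcomp(linker.seq))):
            masked = list(r.seq)
            while True:
                hit = _smith_waterman(lseq, "".join(masked))
                if hit is None:
                    break
                score, q0, q1, t0, t1, mat, mis, gaps = hit
                completeness = (q1 - q0) / len(linker.seq)
                if completeness < cfg.partial_min_completeness:
                    break
                candidates.append(
                    LinkerMatch(linker.id, t0, t1, strand, mat, mis, gaps,
                                completeness, score)
                )
                for k in range(t0, t1):
                    masked[k] = "#"
    candidates.sort(key=lambda m: (-m.score, m.start))
    chosen: list[LinkerMatch] = []
    for m in candidates:
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: m.start)
    return chosen


def _is_full(m: LinkerMatch, cfg: PairendConfig) -> bool:
    return m.completeness >= 1.0 and (m.mismatches + m.gapped_bases) <= cfg.full_mismatch_max


def classify_pairend(
    r: Read, matches: list[LinkerMatch], cfg: PairendConfig | None = None
) -> PairendDecision:
    """Apply the 7-case linker decision tree to one read."""
    cfg = cfg or PairendConfig()
    n = len(r)
    for m in matches:
        if not (0 <= m.start < m.end <= n):
            raise ValueError(
                f"match [{m.start}, {m.end}) does not lie on read {r.id!r} "
                f"of length {n}"
            )
    if not matches:
        return PairendDecision("a", Action.SINGLE_WHOLE)
    if len(matches) >= 2:
        return PairendDecision("b", Action.DISCARD)
    m = matches[0]
    left = (0, m.start)  # flank before the linker
    right = (m.end, n)
    left_len, right_len = m.start, n - m.end
    if not _is_full(m, cfg):
        near_start = m.start <= cfg.end_margin
        near_end = right_len <= cfg.end_margin
        if near_start or near_end:
            # keep the longer linker-free remainder; tie goes left
            keep = left if left_len >= right_len else right
            return PairendDecision("c", Action.SINGLE_CLIPPED, clip_interval=keep)
        return PairendDecision("d", Action.DISCARD)
    left_ok = left_len >= cfg.min_end_len
    right_ok = right_len >= cfg.min_end_len
    if left_ok and right_ok:
        return PairendDecision("e", Action.PAIR, pair_intervals=(left, right))
    if left_ok or right_ok:
        keep = left if left_ok else right
        return PairendDecision("g", Action.SINGLE_CLIPPED, clip_interval=keep)
    return PairendDecision("f", Action.DISCARD)


def _slice(r: Read, iv: tuple[int, int], new_id: str) -> Read:
    s, e = iv
    return Read(
        new_id,
        r.seq[s:e],
        None if r.qual is None else r.qual[s:e],
        origin=r.origin,
    )


def split_pairend(r: Read, d: PairendDecision) -> list[Read]:
    """Materialise a decision: 0 (discard), 1 (single) or 2 (pair) reads.

    Pair halves are named ``id/1`` (left of the linker in read
    orientation) and ``id/2``; qualities are sliced in parallel.
    """
    if d.action is Action.DISCARD:
        return []
    if d.action is Action.SINGLE_WHOLE:
        return [r]
    if d.action is Action.SINGLE_CLIPPED:
        assert d.clip_interval is not None
        return [_slice(r, d.clip_interval, r.id)]
    assert d.pair_intervals is not None
    left, right = d.pair_intervals
    return [_slice(r, left, r.id + "/1"), _slice(r, right, r.id + "/2")]
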