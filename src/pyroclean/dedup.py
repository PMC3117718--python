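"""Artificial-duplicate detection for pyrosequencing reads.

The 454 platform can emit several reads from one DNA fragment.  Such
artificial duplicates start at the same genomic position on the same
strand and are near-identical, differing only by homopolymer indels,
substitutions, and end truncations.  Detection therefore compares read
*starts*: two reads are similar when an alignment anchored at the first
base of both scores above a threshold.

The all-vs-self comparison is seeded by shared forward-strand prefix
k-mers (reads whose first ``seed_k`` bases are identical), then scored
with a banded dynamic-programming extension anchored at offset 0 of both
reads and running to the end of the shorter one.  An edge joins two reads
when the score exceeds ``score_threshold`` (strictly) and — unless
``aggressive`` — their length difference is strictly below
``length_diff_max``.  Connected components of the resulting graph are
duplication clusters; only the longest member of each is kept.

Forward-only seeding makes the same-strand requirement structural:
reverse-complement pairs are never joined.  A consequence of the default
``score_threshold=100`` with unit match reward is that reads shorter than
101 bases can never be flagged as duplicates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import Read, ReadSet

__all__ = [
    "DedupConfig",
    "AlignmentHit",
    "DuplicationCluster",
    "DuplicationProfile",
    "find_candidate_pairs",
    "score_co_start_alignment",
    "build_duplicate_graph",
    "extract_clusters",
    "deduplicate",
    "duplication_profile",
]

_NEG = -(10**9)


@dataclass
class DedupConfig:
    """Parameters of the duplicate-removal stage.

    ``score_threshold`` (default 100) and ``length_diff_max`` (default 70
    bases) are both strict bounds.  Scoring weights +1 / −2 / −3-per-gapped-base
    approximate megablast defaults so that a score of ~100 corresponds to
    roughly 100 matching bases.
    """

    score_threshold: int = 100
    length_diff_max: int = 70
    aggressive: bool = False
    seed_k: int = 16
    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_penalty: int = -3
    band: int = 8

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.length_diff_max < 0:
            raise ValueError("length_diff_max must be non-negative")
        if self.seed_k < 8:
            raise ValueError("seed_k must be at least 8")


@dataclass(frozen=True)
class AlignmentHit:
    """A scored co-start comparison between two reads."""

    id_a: str
    id_b: str
    score: int
    aligned_len: int
    mismatches: int
    gaps: int
    co_start: bool = True
    same_strand: bool = True


@dataclass
class DuplicationCluster:
    """A connected component of the duplicate graph."""

    member_ids: frozenset[str]
    representative_id: str

    def __len__(self) -> int:
        return len(self.member_ids)


def find_candidate_pairs(rs: ReadSet, cfg: DedupConfig) -> set[tuple[str, str]]:
    """All unordered pairs of distinct reads sharing their first ``seed_k`` bases.

    Reads shorter than ``seed_k`` can never be candidates.  The result is a
    superset of every pair that a co-start, same-strand alignment with no
    differences in the first ``seed_k`` bases would produce.
    """
    buckets: dict[str, list[str]] = defaultdict(list)
    for r in rs:
        if len(r) < cfg.seed_k:
            continue
        buckets[r.seq[: cfg.seed_k]].append(r.id)
    pairs: set[tuple[str, str]] = set()
    for ids in buckets.values():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                pairs.add((a, b) if a <= b else (b, a))
    return pairs


def _banded_costart(
    s: str, t: str, band: int, match: int, mismatch: int, gap: int
) -> tuple[int, int, int, int]:
    """Banded global-prefix alignment of s (shorter) against a prefix of t.

    Anchored at (0, 0); the alignment consumes all of ``s`` and may end at
    any position of ``t`` within the band.  Cells outside the band
    ``|j - i| <= band`` are unreachable; paths needing them are truncated
    there, which only matters for duplicates differing by many indels.

    Returns (score, aligned_len, mismatches, gapped_bases).
    """
    m, n = len(s), len(t)
    width = 2 * band + 1
    # score[i][k] with j = i + k - band
    score = [[_NEG] * width for _ in range(m + 1)]
    ptr = [[0] * width for _ in range(m + 1)]  # 1=diag 2=up(del in t) 3=left(ins)
    score[0][band] = 0
    for k in range(band + 1, width):
        j = k - band
        if j > n:
            break
        score[0][k] = gap * j
        ptr[0][k] = 3
    for i in range(1, m + 1):
        si = s[i - 1]
        row, prow = score[i], score[i - 1]
        prow_ptr = ptr[i]
        for k in range(width):
            j = i + k - band
            if j < 0 or j > n:
                continue
            best, op = _NEG, 0
            if j >= 1 and prow[k] != _NEG:  # diagonal: consume s[i-1], t[j-1]
                d = prow[k] + (match if si == t[j - 1] else mismatch)
                if d > best:
                    best, op = d, 1
            if k + 1 < width and prow[k + 1] != _NEG:  # up: consume s[i-1] only
                d = prow[k + 1] + gap
                if d > best:
                    best, op = d, 2
            if k >= 1 and row[k - 1] != _NEG and j >= 1:  # left: consume t[j-1] only
                d = row[k - 1] + gap
                if d > best:
                    best, op = d, 3
            if op:
                row[k] = best
                prow_ptr[k] = op
    # end anywhere in the last row (end of the shorter read)
    best_k = max(range(width), key=lambda k: score[m][k])
    best = score[m][best_k]
    # traceback for match/mismatch/gap accounting
    i, k = m, best_k
    matches = mismatches = gaps = aligned = 0
    while i > 0 or k != band:
        op = ptr[i][k]
        if op == 0:
            break
        aligned += 1
        if op == 1:
            j = i + k - band
            if s[i - 1] == t[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
        elif op == 2:
            gaps += 1
            i -= 1
            k += 1
        else:
            gaps += 1
            k -= 1
    return best, aligned, mismatches, gaps


def score_co_start_alignment(a: Read, b: Read, cfg: DedupConfig) -> AlignmentHit:
    """Score the alignment of ``a`` and ``b`` anchored at the first base of both.

    The extension runs to the end of the shorter read; the score is
    ``matches*match_reward + mismatches*mismatch_penalty +
    gapped_bases*gap_penalty``.  Co-start and same-strand hold by
    construction (forward-only comparison).
    """
    if a.id == b.id:
        raise ValueError("cannot align a read with itself")
    s, t = (a.seq, b.seq) if len(a) <= len(b) else (b.seq, a.seq)
    score, aligned, mism, gaps = _banded_costart(
        s, t, cfg.band, cfg.match_reward, cfg.mismatch_penalty, cfg.gap_penalty
    )
    return AlignmentHit(a.id, b.id, score, aligned, mism, gaps)


def build_duplicate_graph(
    hits: list[AlignmentHit], rs: ReadSet, cfg: DedupConfig
) -> list[tuple[str, str]]:
    """Edges of the duplicate graph.

    An edge joins a hit's reads iff the hit is co-start and same-strand,
    its score is strictly above ``score_threshold``, and (unless
    ``aggressive``) the length difference is strictly below
    ``length_diff_max``.
    """
    edges = []
    for h in hits:
        if not (h.co_start and h.same_strand):
            continue
        if h.score <= cfg.score_threshold:
            continue
        if not cfg.aggressive:
            if abs(len(rs[h.id_a]) - len(rs[h.id_b])) >= cfg.length_diff_max:
                continue
        edges.append((h.id_a, h.id_b))
    return edges


def extract_clusters(
    edges: list[tuple[str, str]], rs: ReadSet
) -> list[DuplicationCluster]:
    """Connected components over ALL reads; edge-less reads form singletons.

    The representative is the longest member; ties break to the
    lexicographically smallest id.  Clusters are ordered by the first
    appearance of any member in the input, so output is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(r.id for r in rs)
    g.add_edges_from(edges)
    order = {r.id: i for i, r in enumerate(rs)}
    clusters = []
    for comp in nx.connected_components(g):
        rep = min(comp, key=lambda i: (-len(rs[i]), i))
        clusters.append(DuplicationCluster(frozenset(comp), rep))
    clusters.sort(key=lambda c: min(order[i] for i in c.member_ids))
    return clusters


def deduplicate(
    rs: ReadSet, cfg: DedupConfig | None = None
) -> tuple[ReadSet, list[tuple[str, str]], list[DuplicationCluster]]:
    """Remove artificial duplicates, keeping one representative per cluster.

    Returns ``(kept, removed, clusters)`` where ``kept`` preserves the
    original input order, ``removed`` lists ``(read_id, representative_id)``
    for every non-representative, and clusters partition the input.
    """
    cfg = cfg or DedupConfig()
    pairs = find_candidate_pairs(rs, cfg)
    hits = [score_co_start_alignment(rs[a], rs[b], cfg) for a, b in sorted(pairs)]
    edges = build_duplicate_graph(hits, rs, cfg)
    clusters = extract_clusters(edges, rs)
    keep_ids = {c.representative_id for c in clusters}
    rep_of = {m: c.representative_id for c in clusters for m in c.member_ids}
    kept = ReadSet([r for r in rs if r.id in keep_ids], rs.format_of_origin)
    removed = [(r.id, rep_of[r.id]) for r in rs if r.id not in keep_ids]
    return kept, removed, clusters


@dataclass
class DuplicationProfile:
    """Cluster-size histogram plus the two replication-rate summaries."""

    histogram: dict[int, int]
    dup_membership_rate: float
    removal_rate: float
    total_reads: int = field(default=0)

    @property
    def max_cluster_size(self) -> int:
        return max(self.histogram, default=0)


def duplication_profile(clusters: list[DuplicationCluster]) -> DuplicationProfile:
    """Histogram of cluster sizes and duplication-rate summaries.

    ``dup_membership_rate`` is the fraction of reads sitting in clusters of
    size >= 2; ``removal_rate`` is the fraction of reads discarded when one
    representative is kept per cluster, ``(N - #clusters) / N``.
    """
    hist: dict[int, int] = defaultdict(int)
    for c in clusters:
        hist[len(c)] += 1
    total = sum(size * cnt for size, cnt in hist.items())
    in_dup = sum(size * cnt for size, cnt in hist.items() if size >= 2)
    membership = in_dup / total if total else 0.0
    removal = (total - len(clusters)) / total if total else 0.0
    return DuplicationProfile(dict(sorted(hist.items())), membership, removal, total)
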