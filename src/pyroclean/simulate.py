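"""Synthetic genomes and shotgun reads for duplicate-removal studies.

The random-fragmentation null model: reads of fixed length are drawn with
uniform start positions from both strands of a genome.  Two reads drawn
from the same (start, strand) cell are then exact copies — the baseline
level of "duplication" that a random library produces by chance, governed
by the birthday problem over M = 2·(L − read_len + 1) cells.  Comparing an
observed duplication profile to this null separates platform-induced
artificial duplicates from coincidental co-starting fragments.

A uniform random genome stands in for a real bacterial genome: the null
depends only on length, and a synthetic sequence avoids the repeat-family
artifacts (rRNA operons, IS elements) a real genome would add.

Error models: per-base substitutions at ``error_rate``, and ±1 indels per
homopolymer run at ``homopolymer_indel_rate`` — the dominant 454 error
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dedup import DedupConfig, DuplicationProfile, deduplicate
from .io_formats import Read, ReadSet
from .pairend import Linker, revcomp

__all__ = [
    "SimConfig",
    "ReadTruth",
    "random_genome",
    "simulate_shotgun_reads",
    "inject_duplicates",
    "replication_experiment",
    "ReplicationResult",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions of the simulation.

    Defaults reproduce a full Titanium-scale run: 671,856 reads of 500 bp
    from a 4.6 Mb genome (the size of E. coli K12), error-free.
    """

    genome_len: int = 4_600_000
    n_reads: int = 671_856
    read_len: int = 500
    seed: int = 0
    error_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    linker: Optional[Linker] = None

    def __post_init__(self) -> None:
        if self.read_len >= self.genome_len:
            raise ValueError("read_len must be smaller than genome_len")
        if self.n_reads < 1:
            raise ValueError("n_reads must be at least 1")


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth of one simulated read: genomic start and strand."""

    start: int
    strand: str  # '+' or '-'


def random_genome(cfg: SimConfig) -> str:
    """Seeded uniform i.i.d. genome of ``genome_len`` bases."""
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, 4, size=cfg.genome_len, dtype=np.uint8)
    return _BASES[idx].tobytes().decode("ascii")


def _apply_errors(seq: str, rng: np.random.Generator, cfg: SimConfig) -> str:
    if cfg.error_rate > 0:
        chars = list(seq)
        for i in np.flatnonzero(rng.random(len(chars)) < cfg.error_rate):
            chars[i] = "ACGT"[rng.integers(0, 4)]
            # may redraw the original base; that's a no-op error, as in life
        seq = "".join(chars)
    if cfg.homopolymer_indel_rate > 0:
        seq = perturb_homopolymers(seq, cfg.homopolymer_indel_rate, rng)
    return seq


def _homopolymer_runs(seq: str, start: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of one base in seq[start:], as (run_start, run_end)."""
    runs = []
    i = start
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def perturb_homopolymers(
    seq: str, rate: float, rng: np.random.Generator, protect_prefix: int = 0
) -> str:
    """Apply ±1-base indels to homopolymer runs, each with probability ``rate``.

    Runs beginning before ``protect_prefix`` are left untouched, and
    single-base runs are never shortened to nothing.
    """
    out = []
    for i, j in _homopolymer_runs(seq):
        run = seq[i:j]
        if i >= protect_prefix and rng.random() < rate:
            if rng.random() < 0.5 and len(run) > 1:
                run = run[:-1]
            else:
                run = run + run[0]
        out.append(run)
    return "".join(out)


def simulate_shotgun_reads(
    genome: str, cfg: SimConfig
) -> tuple[ReadSet, list[ReadTruth]]:
    """Draw ``n_reads`` reads of ``read_len`` bases, uniform start and strand.

    Minus-strand reads are reverse-complemented.  Returns the reads (ids
    ``sim_0`` ...) and the per-read (start, strand) ground truth.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_pos = len(genome) - cfg.read_len + 1
    starts = rng.integers(0, n_pos, size=cfg.n_reads)
    strands = rng.integers(0, 2, size=cfg.n_reads)
    rs = ReadSet(format_of_origin="fastq")
    truth = []
    for i in range(cfg.n_reads):
        s = int(starts[i])
        frag = genome[s : s + cfg.read_len]
        if strands[i]:
            frag = revcomp(frag)
        frag = _apply_errors(frag, rng, cfg)
        rs.append(Read(f"sim_{i}", frag, None))
        truth.append(ReadTruth(s, "-" if strands[i] else "+"))
    return rs, truth


def inject_duplicates(
    rs: ReadSet,
    n_clusters: int,
    sizes: Sequence[int],
    cfg: SimConfig,
    truncation_max: int = 0,
    protect_prefix: int = 0,
) -> tuple[ReadSet, list[set[str]]]:
    """Append perturbed copies of existing reads, forming known duplicate clusters.

    The first ``n_clusters`` entries of ``sizes`` give each cluster's total
    size; the template is an existing read, and size−1 copies are appended
    with 454-style perturbations (per-base substitutions at
    ``cfg.error_rate``, ±1 homopolymer indels at
    ``cfg.homopolymer_indel_rate``, and a uniform end truncation of up to
    ``truncation_max`` bases).  Positions before ``protect_prefix`` are
    exempt from perturbation.  Returns the enlarged read set and the truth
    clusters (sets of read ids, singletons not listed).
    """
    sizes = list(sizes)[:n_clusters]
    if len(sizes) < n_clusters:
        raise ValueError("fewer sizes than requested clusters")
    if n_clusters > len(rs):
        raise ValueError(f"cannot pick {n_clusters} templates from {len(rs)} reads")
    rng = np.random.default_rng(cfg.seed + 2)
    templates = rng.choice(len(rs.reads), size=n_clusters, replace=False)
    out = ReadSet(list(rs.reads), rs.format_of_origin)
    truth = []
    for c, (t_idx, size) in enumerate(zip(templates, sizes)):
        if size < 1:
            raise ValueError("cluster sizes must be >= 1")
        template = rs.reads[int(t_idx)]
        cluster = {template.id}
        for k in range(size - 1):
            seq = template.seq
            if truncation_max > 0:
                cut = int(rng.integers(0, truncation_max + 1))
                if cut:
                    seq = seq[:-cut]
            if cfg.error_rate > 0:
                chars = list(seq)
                for i in np.flatnonzero(rng.random(len(chars)) < cfg.error_rate):
                    if i >= protect_prefix:
                        chars[i] = "ACGT"[rng.integers(0, 4)]
                seq = "".join(chars)
            if cfg.homopolymer_indel_rate > 0:
                seq = perturb_homopolymers(
                    seq, cfg.homopolymer_indel_rate, rng, protect_prefix
                )
            dup = Read(f"{template.id}_dup{c}_{k}", seq, None)
            out.append(dup)
            cluster.add(dup.id)
        truth.append(cluster)
    return out, truth


@dataclass
class ReplicationResult:
    """Outcome of one random-fragmentation replication experiment."""

    dup_membership_rate: float
    removal_rate: float
    max_cluster_size: int
    histogram: dict[int, int]
    n_reads: int
    expected_membership_rate: float = field(default=0.0)
    verified_subsample: int = field(default=0)


def _hash_profile(starts: np.ndarray, strands: np.ndarray) -> DuplicationProfile:
    keys = starts.astype(np.int64) * 2 + strands
    _, counts = np.unique(keys, return_counts=True)
    sizes, freq = np.unique(counts, return_counts=True)
    hist = {int(s): int(f) for s, f in zip(sizes, freq)}
    n = int(counts.sum())
    in_dup = int(counts[counts >= 2].sum())
    return DuplicationProfile(hist, in_dup / n, (n - len(counts)) / n, n)


def replication_experiment(
    cfg: SimConfig, verify_subsample: int = 10_000
) -> ReplicationResult:
    """Measure chance duplication under random fragmentation.

    Draws ``n_reads`` error-free reads and clusters exact co-start copies.
    Because error-free reads from one (start, strand) cell are identical,
    clustering reduces to hashing the cells — the fast path used at full
    scale.  On a subsample of up to ``verify_subsample`` reads the fast
    path is checked against the alignment-based clustering; a discrepancy
    raises ``RuntimeError``.

    Also reports the birthday-problem expectation for the membership rate,
    1 − exp(−(n−1)/M) with M = 2·(genome_len − read_len + 1).
    """
    if cfg.error_rate or cfg.homopolymer_indel_rate:
        raise ValueError("the replication null model is defined for error-free reads")
    rng = np.random.default_rng(cfg.seed + 1)
    n_pos = cfg.genome_len - cfg.read_len + 1
    starts = rng.integers(0, n_pos, size=cfg.n_reads)
    strands = rng.integers(0, 2, size=cfg.n_reads)
    prof = _hash_profile(starts, strands)

    n_sub = min(verify_subsample, cfg.n_reads)
    if n_sub >= 2:
        genome = random_genome(cfg)
        sub = np.sort(
            np.random.default_rng(cfg.seed + 3).choice(
                cfg.n_reads, size=n_sub, replace=False
            )
        )
        rs = ReadSet()
        for i in sub:
            frag = genome[starts[i] : starts[i] + cfg.read_len]
            if strands[i]:
                frag = revcomp(frag)
            rs.append(Read(f"sim_{i}", frag, None))
        _, _, clusters = deduplicate(rs, DedupConfig())
        aligned = {frozenset(c.member_ids) for c in clusters}
        by_key: dict[int, set[str]] = {}
        for i in sub:
            by_key.setdefault(int(starts[i]) * 2 + int(strands[i]), set()).add(
                f"sim_{i}"
            )
        hashed = {frozenset(v) for v in by_key.values()}
        if aligned != hashed:
            raise RuntimeError(
                "hash fast path disagrees with alignment clustering on the "
                f"verification subsample ({len(aligned)} vs {len(hashed)} clusters)"
            )

    m_cells = 2 * n_pos
    expected = 1.0 - float(np.exp(-(cfg.n_reads - 1) / m_cells))
    return ReplicationResult(
        prof.dup_membership_rate,
        prof.removal_rate,
        prof.max_cluster_size,
        prof.histogram,
        cfg.n_reads,
        expected_membership_rate=expected,
        verified_subsample=n_sub,
    )
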