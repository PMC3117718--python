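"""Basic per-read filters: length, complexity, quality and N content.

Each filter is a pure keep/remove predicate on one read, except the
standard-deviation length filter whose mean and deviation are computed on
the pristine input set before any removal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from statistics import mean, pstdev

from .io_formats import Read, ReadSet

__all__ = [
    "FilterConfig",
    "filter_length_window",
    "filter_length_std",
    "complexity_score",
    "filter_complexity_full",
    "filter_complexity_window",
    "filter_quality",
    "filter_n_rate",
]

# DEFLATE's fixed header, subtracted so short reads are not penalised
_EMPTY_COMPRESSED = len(zlib.compress(b"", 9))


@dataclass
class FilterConfig:
    """Thresholds of the basic filters.

    Defaults are conservative conventions for 454-era data: reads between
    50 and 1000 bases, a ±2σ length window, 20% compression complexity on
    100-base windows stepped by 50, at least one base above Phred 20, and
    at most 2% undetermined bases.  The complexity default of 20 sits
    between simple repeats (homopolymers to tetramer repeats score < 8 at
    any read length) and uniform-random DNA (>= 35 for reads up to
    1000 bases; the per-base compressed size falls with length).
    """

    length_min: int = 50
    length_max: int = 1000
    length_std_k: float = 2.0
    complexity_threshold: float = 20.0
    complexity_window: int = 100
    complexity_step: int = 50
    quality_threshold: int = 20
    n_rate_max: float = 0.02

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min must not exceed length_max")
        for name in ("length_min", "length_std_k", "complexity_window",
                     "complexity_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_length_window(r: Read, cfg: FilterConfig) -> bool:
    """Keep iff length_min <= len <= length_max (both inclusive)."""
    return cfg.length_min <= len(r) <= cfg.length_max


def filter_length_std(rs: ReadSet, cfg: FilterConfig) -> tuple[ReadSet, list[str]]:
    """Keep reads within mean ± k·σ of the input length distribution.

    σ is the population standard deviation (÷N) over ALL input reads,
    fixed before any removal.  Fewer than two reads: no-op.
    """
    if len(rs) < 2:
        import logging
        logging.getLogger(__name__).warning(
            "length-std filter needs >= 2 reads; leaving input unchanged"
        )
        return rs, []
    lengths = [len(r) for r in rs]
    mu, sigma = mean(lengths), pstdev(lengths)
    lo, hi = mu - cfg.length_std_k * sigma, mu + cfg.length_std_k * sigma
    kept, removed = [], []
    for r in rs:
        (kept if lo <= len(r) <= hi else removed).append(r)
    return (
        ReadSet([r for r in kept], rs.format_of_origin),
        [r.id for r in removed],
    )


def complexity_score(s: str) -> float:
    """Compression-based complexity of ``s`` in percent.

    100 × (DEFLATE length at maximum compression, minus the empty-input
    codec overhead) ÷ sequence length.  Homopolymers score near 0; random
    DNA around 30-55 depending on length.
    """
    if not s:
        raise ValueError("complexity of an empty sequence is undefined")
    return 100.0 * (len(zlib.compress(s.encode(), 9)) - _EMPTY_COMPRESSED) / len(s)


def filter_complexity_full(r: Read, cfg: FilterConfig) -> bool:
    """Keep iff the whole-read complexity is strictly above the threshold."""
    return complexity_score(r.seq) > cfg.complexity_threshold


def _windows(s: str, width: int, step: int) -> list[str]:
    if len(s) <= width:
        return [s]
    out = []
    for start in range(0, len(s), step):
        w = s[start : start + width]
        if len(w) * 2 >= width:  # final short window only if >= width/2
            out.append(w)
    return out


def filter_complexity_window(r: Read, cfg: FilterConfig) -> bool:
    """Keep iff at least one sliding window exceeds the complexity threshold.

    Windows of ``complexity_window`` bases every ``complexity_step``; the
    final short window counts when at least half a window long; a read
    shorter than one window is a single whole-read window.
    """
    return any(
        complexity_score(w) > cfg.complexity_threshold
        for w in _windows(r.seq, cfg.complexity_window, cfg.complexity_step)
    )


def filter_quality(r: Read, cfg: FilterConfig) -> bool:
    """Keep iff at least one base quality is strictly above the threshold.

    Reads without qualities are kept with a warning.
    """
    if r.qual is None:
        import logging
        logging.getLogger(__name__).warning(
            "read %s has no quality values; quality filter skipped", r.id
        )
        return True
    return max(r.qual) > cfg.quality_threshold


def filter_n_rate(r: Read, cfg: FilterConfig) -> bool:
    """Keep iff the fraction of undetermined bases is at most ``n_rate_max``."""
    return r.seq.count("N") / len(r) <= cfg.n_rate_max
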