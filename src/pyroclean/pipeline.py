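"""Orchestration of the cleaning stages, output files and the log.

Stage order is fixed: paired-end splitting first (it rewrites the read
set), then length, undetermined bases, complexity, quality, and duplicate
removal.  A read is attributed to the FIRST stage that removes it, so the
per-reason counters sum to the input read count.

When paired-end splitting is enabled, later filters run on the derived
fragments (pair halves, clipped singles); if any fragment of a read fails
a filter, the whole read is attributed to that stage and none of its
fragments is written.  Surviving pair halves go to ``<prefix>_pairs``,
surviving singles to ``<prefix>_singles``; without paired-end mode all
kept reads go to ``<prefix>_clean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .dedup import DedupConfig, DuplicationProfile, deduplicate, duplication_profile
from .filters import (
    FilterConfig,
    filter_complexity_full,
    filter_complexity_window,
    filter_length_std,
    filter_length_window,
    filter_n_rate,
    filter_quality,
)
from .io_formats import Read, ReadSet, load_reads, write_reads
from .pairend import Action, Linker, PairendConfig, classify_pairend, find_linker_matches, split_pairend

__all__ = [
    "PipelineOptions",
    "CleaningReport",
    "run_pipeline",
    "write_log",
    "parse_log_footer",
    "plot_duplication_profile",
]

REMOVAL_ORDER = ["linker", "length", "ns", "complexity", "quality", "duplicate"]


@dataclass
class PipelineOptions:
    """Which stages run, and with what thresholds."""

    pairend: bool = False
    linkers: list[Linker] = field(default_factory=list)
    pairend_cfg: PairendConfig = field(default_factory=PairendConfig)
    length_mode: Optional[str] = None  # None | "win" | "std"
    clean_ns: bool = False
    complexity_mode: Optional[str] = None  # None | "full" | "win"
    clean_quality: bool = False
    dedup: bool = False
    dedup_cfg: DedupConfig = field(default_factory=DedupConfig)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    out_format: str = "fastq"

    def __post_init__(self) -> None:
        if self.length_mode not in (None, "win", "std"):
            raise ValueError(f"unknown length mode {self.length_mode!r}")
        if self.complexity_mode not in (None, "full", "win"):
            raise ValueError(f"unknown complexity mode {self.complexity_mode!r}")
        if self.pairend and not self.linkers:
            raise ValueError("paired-end cleaning requires at least one linker")

    @property
    def any_stage(self) -> bool:
        return bool(
            self.pairend or self.length_mode or self.clean_ns
            or self.complexity_mode or self.clean_quality or self.dedup
        )


@dataclass
class CleaningReport:
    """Per-read fates, per-reason counters, and the duplication profile."""

    records: list[tuple[str, str, str]]  # (id, fate, detail), input order
    counters: dict[str, int]
    n_input: int
    n_written: int
    profile: Optional[DuplicationProfile] = None
    output_files: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - sum(self.counters.values())


class _Group:
    """One input read and the fragments derived from it."""

    __slots__ = ("orig_id", "fate", "detail", "fragments", "pool")

    def __init__(self, orig_id: str):
        self.orig_id = orig_id
        self.fate = "kept"
        self.detail = ""
        self.fragments: list[Read] = []
        self.pool = "plain"  # plain | pair | single

    @property
    def alive(self) -> bool:
        return not self.fate.startswith("removed")


def _remove(group: _Group, reason: str, detail: str = "") -> None:
    group.fate = f"removed:{reason}"
    group.detail = detail
    group.fragments = []


def run_pipeline(
    in_path: str | Path, out_prefix: str | Path, opts: PipelineOptions
) -> CleaningReport:
    """Run the enabled cleaning stages on ``in_path``; write outputs and return the report."""
    if not opts.any_stage:
        raise ValueError("no cleaning stage enabled")
    rs = load_reads(in_path)
    out_prefix = Path(out_prefix)
    cfg = opts.filter_cfg

    groups: list[_Group] = []
    for r in rs:
        g = _Group(r.id)
        g.fragments = [r]
        groups.append(g)

    if opts.pairend:
        for g in groups:
            (r,) = g.fragments
            matches = find_linker_matches(r, opts.linkers, opts.pairend_cfg)
            d = classify_pairend(r, matches, opts.pairend_cfg)
            frags = split_pairend(r, d)
            if d.action is Action.DISCARD:
                _remove(g, "linker", f"case={d.case_label}")
            else:
                g.fragments = frags
                if d.action is Action.PAIR:
                    g.pool = "pair"
                    g.fate = "split:pair"
                    g.detail = f"case={d.case_label}"
                elif d.action is Action.SINGLE_CLIPPED:
                    g.pool = "single"
                    g.fate = "split:single"
                    g.detail = f"case={d.case_label}"
                else:
                    g.pool = "single"

    if opts.length_mode == "win":
        for g in groups:
            if g.alive and not all(filter_length_window(f, cfg) for f in g.fragments):
                _remove(g, "length", "window")
    elif opts.length_mode == "std":
        pool = ReadSet(
            [f for g in groups if g.alive for f in g.fragments]
        )
        _, removed_ids = filter_length_std(pool, cfg)
        removed_set = set(removed_ids)
        for g in groups:
            if g.alive and any(f.id in removed_set for f in g.fragments):
                _remove(g, "length", "std")

    per_read = [
        ("ns", opts.clean_ns, filter_n_rate),
        ("complexity", opts.complexity_mode == "full", filter_complexity_full),
        ("complexity", opts.complexity_mode == "win", filter_complexity_window),
        ("quality", opts.clean_quality, filter_quality),
    ]
    for reason, enabled, pred in per_read:
        if not enabled:
            continue
        for g in groups:
            if g.alive and not all(pred(f, cfg) for f in g.fragments):
                _remove(g, reason, "")

    profile = None
    if opts.dedup:
        pool = ReadSet([f for g in groups if g.alive for f in g.fragments])
        _, removed, clusters = deduplicate(pool, opts.dedup_cfg)
        profile = duplication_profile(clusters)
        rep_of = dict(removed)
        for g in groups:
            if not g.alive:
                continue
            dup = [f.id for f in g.fragments if f.id in rep_of]
            if dup:
                _remove(g, "duplicate", f"kept={rep_of[dup[0]]}")

    # output files
    pairs = ReadSet()
    singles = ReadSet()
    for g in groups:
        if not g.alive:
            continue
        target = pairs if g.pool == "pair" else singles
        for f in g.fragments:
            target.append(f)
    out_files = []
    ext = opts.out_format
    if opts.pairend:
        for name, s in (("pairs", pairs), ("singles", singles)):
            p = Path(f"{out_prefix}_{name}.{ext}")
            write_reads(s, p, ext) if len(s) else p.write_text("")
            out_files.append(str(p))
    else:
        p = Path(f"{out_prefix}_clean.{ext}")
        write_reads(singles, p, ext) if len(singles) else p.write_text("")
        out_files.append(str(p))

    counters = {r: 0 for r in REMOVAL_ORDER}
    for g in groups:
        if not g.alive:
            counters[g.fate.split(":", 1)[1]] += 1
    counters = {k: v for k, v in counters.items() if v}
    n_written = len(pairs) + len(singles)
    return CleaningReport(
        [(g.orig_id, g.fate, g.detail) for g in groups],
        counters,
        len(rs),
        n_written,
        profile,
        out_files,
    )


def write_log(report: CleaningReport, path: str | Path, timestamp: bool = False) -> None:
    """Tab-separated per-read log plus a summary/histogram footer."""
    lines = []
    if timestamp:
        lines.append(f"# generated\t{datetime.now(timezone.utc).isoformat()}")
    lines.append("# id\tfate\tdetail")
    for rid, fate, detail in report.records:
        lines.append(f"{rid}\t{fate}\t{detail}")
    lines.append(f"# input\t{report.n_input}")
    lines.append(f"# written\t{report.n_written}")
    lines.append(f"# kept\t{report.n_kept}")
    for reason in REMOVAL_ORDER:
        if reason in report.counters:
            lines.append(f"# removed\t{reason}\t{report.counters[reason]}")
    if report.profile is not None:
        for size, count in sorted(report.profile.histogram.items()):
            lines.append(f"# cluster_size\t{size}\t{count}")
        lines.append(
            f"# dup_membership_rate\t{report.profile.dup_membership_rate:.6f}"
        )
        lines.append(f"# removal_rate\t{report.profile.removal_rate:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_log_footer(path: str | Path) -> dict:
    """Parse the summary block back out of a log file."""
    out: dict = {"removed": {}, "histogram": {}}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("# "):
            continue
        parts = line[2:].split("\t")
        if parts[0] in ("input", "written", "kept"):
            out[parts[0]] = int(parts[1])
        elif parts[0] == "removed":
            out["removed"][parts[1]] = int(parts[2])
        elif parts[0] == "cluster_size":
            out["histogram"][int(parts[1])] = int(parts[2])
        elif parts[0] in ("dup_membership_rate", "removal_rate"):
            out[parts[0]] = float(parts[1])
    return out


def plot_duplication_profile(profile: DuplicationProfile, path: str | Path) -> None:
    """Bar plot of the cluster-size histogram (sizes >= 2)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = [s for s in sorted(profile.histogram) if s >= 2]
    counts = [profile.histogram[s] for s in sizes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(sizes, counts, color="#4878a8")
    ax.set_xlabel("duplication cluster size")
    ax.set_ylabel("number of clusters")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
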