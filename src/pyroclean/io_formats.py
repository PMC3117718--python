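"""Reading and writing of sequencing-read files.

Supported inputs are FASTQ (Sanger / Phred+33), FASTA with an optional
``.qual`` sidecar of space-separated Phred integers (the legacy 454
convention), and SFF v1 flowgram files (read-only).  All records are
materialised as :class:`Read` objects inside a :class:`ReadSet` whose
iteration order equals file order — downstream tie-breaking depends on it.

SFF clip points (``clip_qual_*`` and ``clip_adapter_*``, 1-based and
inclusive in the format) are converted on ingest to a single 0-based
half-open interval: ``left = max(left clips, 1) - 1`` and ``right`` the
minimum of the positive right clips (defaulting to the number of bases).
The stored sequence and qualities are the clipped region; flow values are
parsed by the underlying reader but discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "ReadSet",
    "ReadIngestError",
    "load_reads",
    "write_reads",
]

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class ReadIngestError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class Read:
    """One sequencing read.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`ReadSet`.
    seq : str
        Uppercase sequence over ``{A, C, G, T, N}``.
    qual : list of int, optional
        Phred-scaled qualities (0-93), one per base.
    clip : (int, int), optional
        0-based half-open interval of the usable region in the raw SFF
        bases this read was cut from.
    origin : (str, int), optional
        Source file and record index.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    clip: Optional[tuple[int, int]] = None
    origin: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.qual)} quality values for "
                f"{len(self.seq)} bases"
            )
        if self.clip is not None and not self.clip[0] < self.clip[1]:
            raise ValueError(f"read {self.id!r}: empty clip interval {self.clip}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    """Ordered collection of reads with unique ids."""

    reads: list[Read] = field(default_factory=list)
    format_of_origin: Optional[str] = None

    def __post_init__(self) -> None:
        self._by_id: dict[str, Read] = {}
        for r in self.reads:
            if r.id in self._by_id:
                raise ReadIngestError(f"duplicate read id {r.id!r}")
            self._by_id[r.id] = r

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __getitem__(self, read_id: str) -> Read:
        return self._by_id[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._by_id

    def append(self, read: Read) -> None:
        if read.id in self._by_id:
            raise ReadIngestError(f"duplicate read id {read.id!r}")
        self.reads.append(read)
        self._by_id[read.id] = read


def _sanitize_seq(read_id: str, raw: str) -> str:
    seq = raw.upper()
    bad = _NON_ACGTN.findall(seq)
    if bad:
        logger.warning(
            "read %s: %d non-ACGTN character(s) mapped to N (%s)",
            read_id, len(bad), ",".join(sorted(set(bad))),
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def detect_format(path: str | Path) -> str:
    """Detect fastq/fasta/sff from magic bytes / first character."""
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head == b".sff":
        return "sff"
    if head.startswith(b"@"):
        return "fastq"
    if head.startswith(b">"):
        return "fasta"
    raise ReadIngestError(f"{path}: cannot detect format from leading bytes {head!r}")


def _sff_clip(record: SeqRecord) -> tuple[int, int]:
    # Biopython reports SFF clip points already shifted to 0-based slice
    # coordinates (raw 1-based lefts minus one); 0 on the right means unset.
    ann = record.annotations
    left = max(ann["clip_qual_left"], ann["clip_adapter_left"], 0)
    rights = [r for r in (ann["clip_qual_right"], ann["clip_adapter_right"]) if r > 0]
    right = min(rights) if rights else len(record.seq)
    return left, right


def _load_sff(path: Path) -> ReadSet:
    rs = ReadSet(format_of_origin="sff")
    try:
        records = list(SeqIO.parse(str(path), "sff"))
    except ValueError as exc:
        raise ReadIngestError(f"{path}: not a readable SFF v1 file ({exc})") from exc
    for idx, rec in enumerate(records):
        left, right = _sff_clip(rec)
        if not left < right:
            raise ReadIngestError(
                f"{path}: read {rec.id!r} has an empty clipped region "
                f"[{left}, {right})"
            )
        seq = _sanitize_seq(rec.id, str(rec.seq)[left:right])
        qual = list(rec.letter_annotations["phred_quality"][left:right])
        rs.append(Read(rec.id, seq, qual, clip=(left, right), origin=(str(path), idx)))
    return rs


def _load_fastq(path: Path) -> ReadSet:
    rs = ReadSet(format_of_origin="fastq")
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = _sanitize_seq(rec.id, str(rec.seq))
            qual = list(rec.letter_annotations["phred_quality"])
            rs.append(Read(rec.id, seq, qual, origin=(str(path), idx)))
    except ValueError as exc:
        raise ReadIngestError(f"{path}: malformed FASTQ ({exc})") from exc
    return rs


def _load_fasta(path: Path) -> ReadSet:
    quals: dict[str, list[int]] = {}
    qual_path = path.with_suffix(".qual")
    if qual_path.exists():
        for rec in SeqIO.parse(str(qual_path), "qual"):
            quals[rec.id] = list(rec.letter_annotations["phred_quality"])
    rs = ReadSet(format_of_origin="fasta")
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = _sanitize_seq(rec.id, str(rec.seq))
        qual = quals.get(rec.id)
        if qual is not None and len(qual) != len(seq):
            raise ReadIngestError(
                f"{qual_path}: read {rec.id!r} has {len(qual)} quality values "
                f"for {len(seq)} bases"
            )
        rs.append(Read(rec.id, seq, qual, origin=(str(path), idx)))
    return rs


def load_reads(path: str | Path, format: str = "auto") -> ReadSet:
    """Load reads from ``path``.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"auto", "fastq", "fasta", "sff"}
        With ``auto``, SFF is recognised by its ``.sff`` magic bytes,
        then ``@`` selects FASTQ and ``>`` FASTA.

    Returns
    -------
    ReadSet
        Reads in file order.  Duplicate ids, FASTQ length mismatches and
        non-v1 SFF files raise :class:`ReadIngestError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return ReadSet(format_of_origin=None if format == "auto" else format)
    if format == "auto":
        format = detect_format(path)
    if format == "sff":
        return _load_sff(path)
    if format == "fastq":
        return _load_fastq(path)
    if format == "fasta":
        return _load_fasta(path)
    raise ValueError(f"unknown format {format!r}")


def write_reads(rs: ReadSet, path: str | Path, format: str = "fastq") -> int:
    """Write ``rs`` to ``path`` as FASTQ or FASTA; returns records written.

    FASTQ output requires qualities on every read (use ``fasta`` for
    quality-less sets).  The FASTQ round trip is the identity on
    (id, seq, qual).
    """
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported output format {format!r} (use fastq or fasta)")
    if format == "fastq":
        missing = [r.id for r in rs if r.qual is None]
        if missing:
            raise ValueError(
                f"{len(missing)} read(s) lack quality values (first: "
                f"{missing[0]!r}); cannot write fastq — use fasta"
            )
    records = []
    for r in rs:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        if format == "fastq":
            rec.letter_annotations["phred_quality"] = list(r.qual)  # type: ignore[arg-type]
        records.append(rec)
    return SeqIO.write(records, str(path), format)
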