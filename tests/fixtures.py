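"""Programmatic pipeline fixtures shared by the unit and acceptance tests."""

from __future__ import annotations

import numpy as np

from pyroclean import Read, ReadSet, write_reads

from conftest import random_dna

# expected per-reason removals for the accounting fixture below
ACCOUNTING_EXPECTED = {"length": 2, "ns": 1, "complexity": 1, "quality": 2,
                       "duplicate": 2}


def make_accounting_fixture(path, seed: int = 42) -> ReadSet:
    """A 20-read FASTQ where each doomed read violates exactly one filter.

    2 out-of-window lengths, 1 N-rich read, 1 homopolymer, 2 reads with no
    base above Phred 20, and 3 identical copies of one template (2 of
    which are surplus duplicates); the remaining 11 reads are clean and
    mutually unrelated.  Expected: 12 kept, ACCOUNTING_EXPECTED counters.
    """
    rng = np.random.default_rng(seed)
    q30 = lambda n: [30] * n
    reads = [
        Read("short_1", random_dna(rng, 30), q30(30)),
        Read("long_1", random_dna(rng, 1200), q30(1200)),
        Read("nrich_1", "".join(
            "N" if i % 10 == 0 else s
            for i, s in enumerate(random_dna(rng, 300))
        ), q30(300)),
        Read("homopol_1", "A" * 300, q30(300)),
        Read("lowq_1", random_dna(rng, 300), [5] * 300),
        Read("lowq_2", random_dna(rng, 300), [5] * 300),
    ]
    template = random_dna(rng, 300)
    reads += [Read(f"dup_{k}", template, q30(300)) for k in range(3)]
    reads += [Read(f"clean_{k}", random_dna(rng, 300), q30(300)) for k in range(11)]
    rs = ReadSet(reads)
    write_reads(rs, path, "fastq")
    return rs
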