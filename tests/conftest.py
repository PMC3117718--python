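"""Shared fixtures: a byte-level SFF writer and sequence helpers.

The SFF writer builds 454 SFF v1 files directly with ``struct`` so the
package's reader is checked against an independent byte-level encoding of
the format, not against its own output.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

SFF_MAGIC = 0x2E736666

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _pad8(chunk: bytes) -> bytes:
    rem = len(chunk) % 8
    return chunk + b"\x00" * ((8 - rem) % 8)


def write_sff(
    path: str | Path,
    reads: list[dict],
    n_flows: int = 400,
    key: str = "TCAG",
    version: int = 1,
    flowgram_format: int = 1,
) -> None:
    """Write an SFF v1 file from scratch.

    Each read dict needs ``name`` and ``bases``; optional keys: ``quals``
    (defaults to 30s), ``clip_qual_left/right`` and
    ``clip_adapter_left/right`` (1-based inclusive, 0 = not set).
    """
    flow_chars = ("TACG" * n_flows)[:n_flows].encode()
    head = struct.pack(
        ">IIQIIHHHB",
        SFF_MAGIC,
        version,
        0,  # index offset
        0,  # index length
        len(reads),
        0,  # header_length placeholder, fixed below
        len(key),
        n_flows,
        flowgram_format,
    )
    body = head + flow_chars + key.encode()
    header_length = (len(body) + 7) // 8 * 8
    body = struct.pack(
        ">IIQIIHHHB", SFF_MAGIC, version, 0, 0, len(reads),
        header_length, len(key), n_flows, flowgram_format,
    ) + flow_chars + key.encode()
    out = bytearray(_pad8(body))
    for rd in reads:
        name = rd["name"].encode()
        bases = rd["bases"]
        nb = len(bases)
        quals = rd.get("quals", [30] * nb)
        assert len(quals) == nb
        rh_fixed = struct.pack(
            ">HHIHHHH",
            0,  # read_header_length placeholder
            len(name),
            nb,
            rd.get("clip_qual_left", 0),
            rd.get("clip_qual_right", 0),
            rd.get("clip_adapter_left", 0),
            rd.get("clip_adapter_right", 0),
        )
        rh_len = (len(rh_fixed) + len(name) + 7) // 8 * 8
        rh = struct.pack(
            ">HHIHHHH", rh_len, len(name), nb,
            rd.get("clip_qual_left", 0), rd.get("clip_qual_right", 0),
            rd.get("clip_adapter_left", 0), rd.get("clip_adapter_right", 0),
        ) + name
        out += _pad8(rh)
        flows = struct.pack(f">{n_flows}H", *([100] * n_flows))
        flow_index = bytes([1] * nb)
        data = flows + flow_index + bases.encode() + bytes(quals)
        out += _pad8(data)
    Path(path).write_bytes(bytes(out))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def sff_writer(tmp_path):
    def _write(reads, **kw):
        p = tmp_path / "fixture.sff"
        write_sff(p, reads, **kw)
        return p

    return _write
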