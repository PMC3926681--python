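from __future__ import annotations

import numpy as np
import pytest

from satmap.readqc import ReadRecord

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20140201)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def tile_reads(seq: str, read_len: int = 100, step: int = 10, depth: int = 1) -> list[str]:
    """Error-free reads tiling a sequence end to end at roughly read_len/step x."""
    reads = []
    for _ in range(depth):
        reads.extend(
            seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)
        )
        reads.append(seq[-read_len:])  # make sure the tail is covered
    return reads


def read(seq: str, quals=None, read_id: str = "r1", mate: str = "forward") -> ReadRecord:
    if quals is None:
        quals = [40] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord(read_id, mate, seq, list(quals))
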