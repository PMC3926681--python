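"""Quality processing of paired-end RNA-Seq reads.

Raw read pairs are cleaned in three fixed steps — terminal quality trimming
at a minimum phred score, removal of reads shorter than a length floor, and
removal of reads still containing ambiguous 'N' bases — and then classified
into *paired* reads (both mates survive) and *orphan* reads (exactly one
mate survives).  Only the clean paired pool feeds assembly; it can be
partitioned into nested, seeded base-count quanta (e.g. 1, 3, 5 ... Gb) for
incremental sub-assembly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from . import seqio

Mate = Literal["forward", "reverse"]


@dataclass
class ReadRecord:
    """A single sequencing read with per-base phred qualities."""

    read_id: str
    mate: Mate
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.mate not in ("forward", "reverse"):
            raise ValueError(f"read {self.read_id!r}: invalid mate {self.mate!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QualityPolicy:
    """Cleaning thresholds: terminal trim quality, length floor, N rejection."""

    min_phred: int = 20
    min_length_bp: int = 30
    reject_n: bool = True

    def __post_init__(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass
class ReadPairPool:
    """Clean reads split into surviving pairs and orphans, with tallies.

    Base tallies for clean/paired/orphan categories are post-trimming;
    raw tallies are pre-trimming, so ``clean_bases < raw_bases`` even when
    no read is rejected outright.
    """

    paired: list[tuple[ReadRecord, ReadRecord]] = field(default_factory=list)
    orphans: list[ReadRecord] = field(default_factory=list)
    raw_reads: int = 0
    clean_reads: int = 0
    paired_reads: int = 0
    orphan_reads: int = 0
    raw_bases: int = 0
    clean_bases: int = 0
    paired_bases: int = 0
    orphan_bases: int = 0

    @property
    def rejected_reads(self) -> int:
        return self.raw_reads - self.clean_reads

    def validate(self) -> None:
        if self.clean_reads != self.paired_reads + self.orphan_reads:
            raise AssertionError("clean_reads != paired_reads + orphan_reads")
        if self.paired_reads % 2:
            raise AssertionError("paired_reads must be even")
        if self.paired_reads != 2 * len(self.paired):
            raise AssertionError("paired_reads inconsistent with member records")
        if self.paired_bases != sum(len(f) + len(r) for f, r in self.paired):
            raise AssertionError("paired_bases inconsistent with member records")
        if self.orphan_bases != sum(len(o) for o in self.orphans):
            raise AssertionError("orphan_bases inconsistent with member records")

    def summary_rows(self) -> list[dict]:
        """Cleaning-report rows (category, read count, base count, % of raw)."""
        rows = []
        for name, nreads, nbases in (
            ("Raw reads", self.raw_reads, self.raw_bases),
            ("Clean reads", self.clean_reads, self.clean_bases),
            ("Paired reads", self.paired_reads, self.paired_bases),
            ("Orphan reads (single end)", self.orphan_reads, self.orphan_bases),
        ):
            rows.append(
                {
                    "category": name,
                    "reads": nreads,
                    "bases": nbases,
                    "reads_pct_of_raw": percent_of(nreads, self.raw_reads),
                    "bases_pct_of_raw": percent_of(nbases, self.raw_bases),
                }
            )
        return rows


def percent_of(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


@dataclass(frozen=True)
class QuantumSchedule:
    """Strictly increasing target base counts (nt) for incremental quanta."""

    targets: tuple[int, ...]

    def __post_init__(self) -> None:
        targets = tuple(int(t) for t in self.targets)
        object.__setattr__(self, "targets", targets)
        if not targets:
            raise ValueError("schedule must contain at least one target")
        if any(t <= 0 for t in targets):
            raise ValueError("targets must be positive base counts")
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("targets must be strictly increasing")


def trim_read(read: ReadRecord, policy: QualityPolicy) -> Optional[ReadRecord]:
    """Symmetrically end-trim a read; return None if it fails the policy.

    Bases are removed from either end while the terminal base is below
    ``min_phred``; interior low-quality bases are retained.  The trimmed
    read is rejected when shorter than ``min_length_bp`` or, if
    ``reject_n``, when an 'N' remains after trimming.
    """
    lo, hi = 0, len(read.sequence)
    quals = read.qualities
    while lo < hi and quals[lo] < policy.min_phred:
        lo += 1
    while hi > lo and quals[hi - 1] < policy.min_phred:
        hi -= 1
    if hi - lo < policy.min_length_bp:
        return None
    seq = read.sequence[lo:hi]
    if policy.reject_n and "N" in seq:
        return None
    if lo == 0 and hi == len(read.sequence):
        return read
    return ReadRecord(read.read_id, read.mate, seq, quals[lo:hi])


def clean_library(
    raw_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    policy: QualityPolicy = QualityPolicy(),
) -> ReadPairPool:
    """Clean raw pairs and classify survivors into paired/orphan sets."""
    pool = ReadPairPool()
    seen_ids: set[str] = set()
    for fwd, rev in raw_pairs:
        if fwd.read_id in seen_ids:
            raise ValueError(f"duplicate read_id {fwd.read_id!r} in input")
        seen_ids.add(fwd.read_id)
        pool.raw_reads += 2
        pool.raw_bases += len(fwd) + len(rev)
        tf = trim_read(fwd, policy)
        tr = trim_read(rev, policy)
        if tf is not None and tr is not None:
            pool.paired.append((tf, tr))
            pool.paired_reads += 2
            pool.paired_bases += len(tf) + len(tr)
        elif tf is not None or tr is not None:
            surv = tf if tf is not None else tr
            pool.orphans.append(surv)
            pool.orphan_reads += 1
            pool.orphan_bases += len(surv)
    pool.clean_reads = pool.paired_reads + pool.orphan_reads
    pool.clean_bases = pool.paired_bases + pool.orphan_bases
    pool.validate()
    return pool


def partition_quanta(
    pool: ReadPairPool, schedule: QuantumSchedule, seed: int
) -> list[list[tuple[ReadRecord, ReadRecord]]]:
    """Shuffle pairs once (seeded), then cut nested prefix quanta.

    Each quantum is the shortest shuffled prefix of whole pairs whose summed
    base count (both mates) reaches its target, so smaller quanta are exact
    prefixes of larger ones and pairs are never split.
    """
    if not pool.paired:
        raise ValueError("pool has no paired reads to partition")
    last = schedule.targets[-1]
    if last > pool.paired_bases:
        raise ValueError(
            f"target {last} nt exceeds available paired bases "
            f"{pool.paired_bases} nt (short by {last - pool.paired_bases} nt)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool.paired))
    shuffled = [pool.paired[i] for i in order]
    sizes = np.cumsum([len(f) + len(r) for f, r in shuffled])
    quanta = []
    for target in schedule.targets:
        n_pairs = int(np.searchsorted(sizes, target, side="left")) + 1
        quanta.append(shuffled[:n_pairs])
    return quanta


def length_histogram(
    reads: Iterable[ReadRecord | int], bin_edges: Sequence[int]
) -> np.ndarray:
    """Count read lengths into half-open bins [e0,e1), [e1,e2) ...

    Every read must fall inside the binning range; each is counted exactly
    once, so the counts sum to the number of reads.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing, >= 2 edges")
    lengths = [r if isinstance(r, int) else len(r) for r in reads]
    counts = np.zeros(len(edges) - 1, dtype=int)
    for length in lengths:
        if length < edges[0] or length >= edges[-1]:
            raise ValueError(f"read length {length} outside bins [{edges[0]}, {edges[-1]})")
        counts[np.searchsorted(edges, length, side="right") - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# file-level convenience wrappers


def read_paired_fastq(fq1, fq2) -> list[tuple[ReadRecord, ReadRecord]]:
    """Load two synchronized FASTQ files into read pairs.

    Mate suffixes ``/1``/``/2`` are stripped before pairing; forward and
    reverse files must list the same ids in the same order, without
    duplicates within a file.
    """

    def strip(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    pairs = []
    seen: set[str] = set()
    it1, it2 = seqio.parse_fastq(fq1), seqio.parse_fastq(fq2)
    for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
        rid1, rid2 = strip(id1), strip(id2)
        if rid1 != rid2:
            raise ValueError(f"mate ids out of sync: {id1!r} vs {id2!r}")
        if rid1 in seen:
            raise ValueError(f"duplicate read_id {rid1!r} in mate file")
        seen.add(rid1)
        pairs.append(
            (
                ReadRecord(rid1, "forward", seq1, list(q1)),
                ReadRecord(rid2, "reverse", seq2, list(q2)),
            )
        )
    return pairs


def write_pool(pool: ReadPairPool, out_prefix: str) -> dict[str, str]:
    """Write cleaned pairs, orphans and the cleaning report; return paths."""
    import pandas as pd

    p1 = f"{out_prefix}_clean_1.fastq"
    p2 = f"{out_prefix}_clean_2.fastq"
    po = f"{out_prefix}_orphans.fastq"
    pr = f"{out_prefix}_cleaning_report.tsv"
    seqio.write_fastq(
        ((f.read_id + "/1", f.sequence, f.qualities) for f, _ in pool.paired), p1
    )
    seqio.write_fastq(
        ((r.read_id + "/2", r.sequence, r.qualities) for _, r in pool.paired), p2
    )
    suffix = {"forward": "/1", "reverse": "/2"}
    seqio.write_fastq(
        ((o.read_id + suffix[o.mate], o.sequence, o.qualities) for o in pool.orphans), po
    )
    pd.DataFrame(pool.summary_rows()).to_csv(pr, sep="\t", index=False)
    return {"clean_1": p1, "clean_2": p2, "orphans": po, "report": pr}
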