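"""Synthetic transcriptomes and paired-end read simulation.

The generator emulates the statistical structure the saturation
methodology assumes: a transcriptome with log-normal transcript lengths,
log-normal expression weights spanning several orders of magnitude (the
wide dynamic range of plant tissues), an optional tissue-restricted
fraction at near-zero abundance, and 2 x 100 nt paired-end reads drawn
from ~200 bp fragments with position-dependent phred qualities and a
substitution-only error model.  Everything is deterministic per seed so
pipeline runs are byte-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import seqio
from .assembler import AssemblyParams, assemble_internal
from .metrics import assembly_stats, sweep_result
from .readqc import (
    QualityPolicy,
    QuantumSchedule,
    ReadRecord,
    clean_library,
    partition_quanta,
)
from .saturation import SaturationMatrix, build_matrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticTranscriptomeSpec:
    n_transcripts: int = 500
    length_median_bp: int = 500
    length_sigma: float = 0.45
    expression_orders: float = 4.0  # dynamic range, orders of magnitude
    tissue_specific_fraction: float = 0.1
    tissue_specific_weight_factor: float = 1e-6
    gc_fraction: float = 0.43
    min_length_bp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        if not (0.0 <= self.tissue_specific_fraction <= 1.0):
            raise ValueError("tissue_specific_fraction must be in [0, 1]")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.min_length_bp < 200:
            raise ValueError("transcripts must be >= 200 bp (fragment size)")
        if self.length_median_bp < self.min_length_bp:
            raise ValueError("length_median_bp below the minimum length floor")


@dataclass(frozen=True)
class ReadSimSpec:
    read_length: int = 100
    fragment_mean: int = 200
    fragment_sd: int = 20
    per_base_error_rate: float = 0.005
    quality_profile: Optional[tuple[float, ...]] = None  # position -> mean phred
    quality_sd: float = 4.0
    n_base_rate: float = 1e-4  # ambiguous-base calls, written as 'N'
    target_bases: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if not (0.0 <= self.per_base_error_rate <= 0.1):
            raise ValueError("per_base_error_rate must be in [0, 0.1]")
        if self.target_bases < 2 * self.read_length:
            raise ValueError("target_bases below a single read pair")

    def profile(self) -> np.ndarray:
        if self.quality_profile is not None:
            prof = np.asarray(self.quality_profile, dtype=float)
            if len(prof) != self.read_length:
                raise ValueError("quality_profile length != read_length")
            return prof
        # default Illumina-like decay from Q38 at the 5' end to Q26 at the 3'
        return np.linspace(38.0, 26.0, self.read_length)


@dataclass
class Transcriptome:
    records: list[tuple[str, str]]
    weights: np.ndarray  # normalized abundance weights, sum 1
    spec: SyntheticTranscriptomeSpec

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for _, s in self.records])

    def to_fasta(self, path) -> None:
        seqio.write_fasta(self.records, path)

    def abundance_rows(self) -> list[dict]:
        return [
            {"transcript_id": tid, "length_bp": len(seq), "weight": float(w)}
            for (tid, seq), w in zip(self.records, self.weights)
        ]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode("ascii")


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = seqio.revcomp(seq)
    n = len(seq)
    return {
        min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)
    }


def gen_transcriptome(spec: SyntheticTranscriptomeSpec) -> Transcriptome:
    """Deterministically sample a synthetic transcriptome.

    Transcript sequences are drawn i.i.d. at the requested GC content and
    re-drawn on (rare) canonical 31-mer collisions so no two transcripts
    share a 31-mer — each transcript is then assembly-separable.  Abundance
    weights are log-normal, scaled so the expected max/min ratio spans
    ``expression_orders`` orders of magnitude, and normalized to sum 1.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.maximum(
        rng.lognormal(math.log(spec.length_median_bp), spec.length_sigma, spec.n_transcripts),
        spec.min_length_bp,
    ).astype(int)

    seen_kmers: set[str] = set()
    records: list[tuple[str, str]] = []
    for i, length in enumerate(lengths):
        for _attempt in range(50):
            seq = _random_sequence(rng, int(length), spec.gc_fraction)
            kmers = _canonical_kmers(seq, 31)
            if not (kmers & seen_kmers):
                seen_kmers |= kmers
                break
        else:
            raise RuntimeError("could not draw a 31-mer-disjoint transcript")
        records.append((f"txp{i + 1:05d}", seq))

    n = spec.n_transcripts
    if n > 1:
        # span `expression_orders` decades between the expected extremes
        sigma = math.log(10.0 ** spec.expression_orders) / (2.0 * math.sqrt(2.0 * math.log(n)))
    else:
        sigma = 0.0
    weights = rng.lognormal(0.0, sigma, n)
    n_restricted = int(round(spec.tissue_specific_fraction * n))
    if n_restricted and n > 1:
        restricted = rng.choice(n, size=n_restricted, replace=False)
        weights[restricted] *= spec.tissue_specific_weight_factor
    weights /= weights.sum()
    return Transcriptome(records=records, weights=weights, spec=spec)


def simulate_reads(
    transcriptome: Transcriptome, spec: ReadSimSpec
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Simulate paired-end reads until ``target_bases`` is reached.

    Fragments are drawn from transcripts with probability proportional to
    abundance weight x length; the two mates are the fragment ends, the
    reverse mate complemented.  Substitution errors occur at
    ``per_base_error_rate``; qualities are normal draws around the
    positional profile; rare ambiguous calls become 'N' at quality 2.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = transcriptome.lengths
    probs = transcriptome.weights * lengths
    probs = probs / probs.sum()
    n_pairs = math.ceil(spec.target_bases / (2 * spec.read_length))
    choices = rng.choice(len(lengths), size=n_pairs, p=probs)
    profile = spec.profile()
    rl = spec.read_length
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    for i, t_idx in enumerate(choices):
        tid, seq = transcriptome.records[t_idx]
        tlen = lengths[t_idx]
        frag_len = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
        frag_len = max(rl, min(int(tlen), frag_len))
        start = int(rng.integers(0, tlen - frag_len + 1))
        fragment = seq[start : start + frag_len]
        fwd_seq = fragment[:rl]
        rev_seq = seqio.revcomp(fragment)[:rl]
        rid = f"sim{i + 1:08d}"
        fwd = _mutate(rng, fwd_seq, spec, profile)
        rev = _mutate(rng, rev_seq, spec, profile)
        pairs.append(
            (
                ReadRecord(rid, "forward", fwd[0], fwd[1]),
                ReadRecord(rid, "reverse", rev[0], rev[1]),
            )
        )
    return pairs


def _mutate(
    rng: np.random.Generator, seq: str, spec: ReadSimSpec, profile: np.ndarray
) -> tuple[str, list[int]]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    quals = np.clip(np.rint(rng.normal(profile[:n], spec.quality_sd)), 2, 40).astype(int)
    if spec.per_base_error_rate > 0:
        err = rng.random(n) < spec.per_base_error_rate
        if err.any():
            # substitute with a different base: shift by 1..3 in ACGT order
            lut = np.full(256, 0, dtype=np.uint8)
            for j, c in enumerate(b"ACGT"):
                lut[c] = j
            shifts = rng.integers(1, 4, size=int(err.sum()))
            codes = (lut[arr[err]] + shifts) % 4
            arr[err] = _BASES[codes]
    if spec.n_base_rate > 0:
        amb = rng.random(n) < spec.n_base_rate
        if amb.any():
            arr[amb] = ord("N")
            quals[amb] = 2
    return arr.tobytes().decode("ascii"), quals.tolist()


def write_paired_fastq(pairs, prefix: str) -> tuple[str, str]:
    p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    seqio.write_fastq(((f.read_id + "/1", f.sequence, f.qualities) for f, _ in pairs), p1)
    seqio.write_fastq(((r.read_id + "/2", r.sequence, r.qualities) for _, r in pairs), p2)
    return p1, p2


@dataclass
class SaturationStudy:
    """All artifacts of one end-to-end synthetic saturation run."""

    transcriptome: Transcriptome
    pool_stats: dict
    quantum_bases: list[int]
    stats: list  # AssemblyStats per (datasize, k) cell
    sweeps: dict  # datasize_bases -> KmerSweepResult
    full_label: tuple[int, int]
    matrix: SaturationMatrix


def synthetic_saturation_study(
    t_spec: SyntheticTranscriptomeSpec,
    r_spec: ReadSimSpec,
    schedule_targets: Sequence[int],
    k_values: Sequence[int],
    policy: QualityPolicy = QualityPolicy(),
    assembly_params: AssemblyParams = AssemblyParams(),
    e_threshold: float = 1.0e-5,
    partition_seed: Optional[int] = None,
    sim_margin: float = 1.15,
    progress: Optional[Callable[[str], None]] = None,
) -> SaturationStudy:
    """Run clean -> partition -> sweep -> map -> matrix end to end.

    Reads are simulated once with enough margin over the largest quantum to
    survive quality filtering, cleaned, partitioned into nested quanta, and
    each (quantum, k) cell is assembled and mapped against the full
    transcriptome assembly (the optimized — or, if non-peaked, boundary-best
    — assembly of the largest quantum).
    """

    def log(msg: str) -> None:
        if progress:
            progress(msg)

    schedule = QuantumSchedule(tuple(schedule_targets))
    need = int(schedule.targets[-1] * sim_margin)
    r_spec = replace(r_spec, target_bases=max(r_spec.target_bases, need))
    log(f"simulating {r_spec.target_bases} bases from {t_spec.n_transcripts} transcripts")
    transcriptome = gen_transcriptome(t_spec)
    raw_pairs = simulate_reads(transcriptome, r_spec)
    pool = clean_library(raw_pairs, policy)
    quanta = partition_quanta(
        pool, schedule, seed=r_spec.seed if partition_seed is None else partition_seed
    )

    assemblies = {}
    all_stats = []
    sweeps = {}
    for target, quantum in zip(schedule.targets, quanta):
        seqs = [s for f, r in quantum for s in (f.sequence, r.sequence)]
        per_k = []
        for k in k_values:
            log(f"assembling {target} nt at k={k} ({len(seqs)} reads)")
            asm = assemble_internal(
                seqs, replace(assembly_params, k=k), label=(target, k)
            )
            assemblies[(target, k)] = asm
            st = assembly_stats(asm)
            per_k.append(st)
            all_stats.append(st)
        sweeps[target] = sweep_result(target, per_k)

    top = schedule.targets[-1]
    top_sweep = sweeps[top]
    full_k = top_sweep.optimized_k if top_sweep.peaked else top_sweep.boundary_k
    full_assembly = assemblies[(top, full_k)]
    log(f"mapping saturation matrix against full assembly ({top}, k={full_k})")
    matrix = build_matrix(assemblies, full_assembly, e_threshold, sweeps=sweeps)
    return SaturationStudy(
        transcriptome=transcriptome,
        pool_stats={
            "raw_reads": pool.raw_reads,
            "clean_reads": pool.clean_reads,
            "paired_reads": pool.paired_reads,
            "orphan_reads": pool.orphan_reads,
            "paired_bases": pool.paired_bases,
        },
        quantum_bases=list(schedule.targets),
        stats=all_stats,
        sweeps=sweeps,
        full_label=(top, full_k),
        matrix=matrix,
    )
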