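"""Minimal de Bruijn unitig assembler and external-assembler adapter.

The internal assembler builds the canonical k-mer graph (a k-mer and its
reverse complement are one node — appropriate for unstranded RNA-Seq
libraries), drops k-mers seen fewer than ``min_kmer_count`` times to
suppress sequencing errors, compresses maximal unbranched paths into
unitigs, and emits unitigs at least ``min_transcript_bp`` long as
transcripts.  It is a deterministic, desk-scale transcripts-from-reads
stage: no tip/bubble removal, no isoform resolution, no scaffolding.  The
adapter hook runs a real assembler executable instead and parses its FASTA.

k must be odd (odd k rules out reverse-complement-palindromic k-mers, so
the canonical representation is well defined).
"""
from __future__ import annotations

import shlex
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import read_fasta, revcomp, write_fasta


class AdapterError(RuntimeError):
    """External assembler failed or produced unparseable output."""


@dataclass(frozen=True)
class AssemblyParams:
    k: int = 25
    min_transcript_bp: int = 100
    min_kmer_count: int = 2

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if self.min_transcript_bp < 1:
            raise ValueError("min_transcript_bp must be >= 1")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass
class Assembly:
    """Transcript set for one (datasize, k) cell."""

    transcripts: list[tuple[str, str]]
    label: Optional[tuple[int, int]] = None  # (datasize_bases, k)

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript ids in assembly")

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.transcripts]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    def to_fasta(self, path) -> None:
        write_fasta(self.transcripts, path)

    @classmethod
    def from_fasta(cls, path, label=None) -> "Assembly":
        return cls(read_fasta(path), label=label)


# ---------------------------------------------------------------------------
# k-mer machinery

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(_BASES)}


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        rc = (rc << two) | ((tmp & three) ^ three)
        tmp >>= two
    return rc


def _canonical_codes_numpy(seqs: Sequence[str], k: int) -> np.ndarray:
    """Canonical k-mer codes of all valid k-windows (k <= 31, 2-bit packed)."""
    joined = "\x00".join(seqs)
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    bits = _LUT[arr]
    invalid = bits == 255
    bits = np.where(invalid, 0, bits).astype(np.uint64)
    n = len(bits) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = np.cumsum(invalid)
    ok = (bad[k - 1 :] - np.concatenate(([0], bad[: -k]))) == 0
    codes = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        codes = (codes << two) | bits[j : j + n]
    codes = codes[ok]
    return np.minimum(codes, _revcomp_codes(codes, k))


def _canonical_codes_python(seqs: Iterable[str], k: int) -> Counter:
    """Rolling-code canonical k-mer counter for arbitrary k (python ints)."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    counts: Counter = Counter()
    for seq in seqs:
        fwd = rc = 0
        run = 0
        for ch in seq:
            b = _CODE.get(ch)
            if b is None:
                run = 0
                fwd = rc = 0
                continue
            fwd = ((fwd << 2) | b) & mask
            rc = (rc >> 2) | ((3 - b) << shift)
            run += 1
            if run >= k:
                counts[min(fwd, rc)] += 1
    return counts


def count_solid_kmers(seqs: Sequence[str], k: int, min_count: int) -> set[int]:
    """Canonical k-mers occurring at least ``min_count`` times."""
    if k <= 31:
        codes = _canonical_codes_numpy(seqs, k)
        if codes.size == 0:
            return set()
        uniq, counts = np.unique(codes, return_counts=True)
        return set(int(c) for c in uniq[counts >= min_count])
    counter = _canonical_codes_python(seqs, k)
    return {code for code, n in counter.items() if n >= min_count}


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((code & 3) ^ 3)
        code >>= 2
    return rc


def _build_unitigs(solid: set[int], k: int) -> list[str]:
    """Compress maximal unbranched paths of the canonical graph to unitigs."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)

    def successors(f: int, r: int):
        out = []
        for b in range(4):
            nf = ((f << 2) | b) & mask
            nr = (r >> 2) | ((3 - b) << shift)
            if (nf if nf <= nr else nr) in solid:
                out.append((b, nf, nr))
        return out

    def n_predecessors(f: int, r: int) -> int:
        n = 0
        for b in range(4):
            pf = (f >> 2) | (b << shift)
            pr = ((r << 2) | (3 - b)) & mask
            if (pf if pf <= pr else pr) in solid:
                n += 1
        return n

    visited: set[int] = set()
    unitigs: list[str] = []

    def extend_right(f: int, r: int) -> list[str]:
        bases = []
        while True:
            succ = successors(f, r)
            if len(succ) != 1:
                break
            b, nf, nr = succ[0]
            canon = nf if nf <= nr else nr
            if canon in visited or canon not in solid:
                break
            if n_predecessors(nf, nr) != 1:
                break
            visited.add(canon)
            bases.append(_BASES[b])
            f, r = nf, nr
        return bases

    for start in sorted(solid):
        if start in visited:
            continue
        visited.add(start)
        f = start
        r = _rc_code(start, k)
        right = extend_right(f, r)
        left = extend_right(r, f)  # walking the reverse strand rightward
        seq = revcomp("".join(left)) + _decode(start, k) + "".join(right)
        rc = revcomp(seq)
        unitigs.append(seq if seq <= rc else rc)
    return unitigs


def assemble_internal(reads: Iterable, params: AssemblyParams, label=None) -> Assembly:
    """Assemble reads into unitig transcripts at one k-mer size."""
    seqs = _as_sequences(reads)
    if not seqs:
        raise ValueError("no reads to assemble")
    if params.k > max(len(s) for s in seqs):
        raise ValueError(f"k={params.k} exceeds the longest read length")
    solid = count_solid_kmers(seqs, params.k, params.min_kmer_count)
    unitigs = _build_unitigs(solid, params.k)
    unitigs = [u for u in unitigs if len(u) >= params.min_transcript_bp]
    unitigs.sort(key=lambda s: (-len(s), s))
    transcripts = [(f"tig{i + 1:06d}", seq) for i, seq in enumerate(unitigs)]
    return Assembly(transcripts, label=label)


def assemble_external(reads: Iterable, params: AssemblyParams, adapter_config: dict, label=None) -> Assembly:
    """Run an external assembler command and parse its FASTA output.

    ``adapter_config['command']`` is a shell-free template with ``{reads}``,
    ``{out}`` and ``{k}`` placeholders; the command must write transcripts
    in FASTA to ``{out}``.  The same minimum-transcript-length filter as the
    internal assembler is applied to the parsed records.
    """
    template = adapter_config.get("command")
    if not template:
        raise AdapterError("adapter_config must name a 'command' template")
    seqs = _as_sequences(reads)
    with tempfile.TemporaryDirectory(prefix="satmap_adapter_") as tmp:
        reads_fa = Path(tmp) / "reads.fasta"
        out_fa = Path(tmp) / "transcripts.fasta"
        write_fasta(((f"read{i}", s) for i, s in enumerate(seqs)), reads_fa)
        cmd = [
            part.format(reads=str(reads_fa), out=str(out_fa), k=params.k)
            for part in shlex.split(template)
        ]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except FileNotFoundError as exc:
            raise AdapterError(f"adapter executable not found: {cmd[0]!r}") from exc
        if proc.returncode != 0:
            raise AdapterError(
                f"adapter exited {proc.returncode}; stderr: {proc.stderr.strip()}"
            )
        if not out_fa.exists():
            raise AdapterError(f"adapter produced no output at {out_fa}")
        try:
            records = read_fasta(out_fa)
        except Exception as exc:  # pragma: no cover - parser detail
            raise AdapterError(f"unparseable adapter output: {exc}") from exc
    records = [(tid, seq) for tid, seq in records if len(seq) >= params.min_transcript_bp]
    return Assembly(records, label=label)


def sweep_kmers(
    reads: Iterable,
    k_values: Sequence[int],
    params: AssemblyParams = AssemblyParams(),
    engine: str = "internal",
    adapter_config: Optional[dict] = None,
    datasize_bases: Optional[int] = None,
) -> list[Assembly]:
    """One assembly per k, all from the same read input, in k_values order."""
    if not k_values:
        raise ValueError("k_values must be non-empty")
    seqs = _as_sequences(reads)
    assemblies = []
    for k in k_values:
        p = replace(params, k=k)
        label = (datasize_bases, k) if datasize_bases is not None else None
        if engine == "internal":
            assemblies.append(assemble_internal(seqs, p, label=label))
        elif engine == "external":
            assemblies.append(assemble_external(seqs, p, adapter_config or {}, label=label))
        else:
            raise ValueError(f"unknown engine {engine!r}")
    return assemblies


def _as_sequences(reads: Iterable) -> list[str]:
    """Accept plain strings, ReadRecords, or (fwd, rev) ReadRecord pairs."""
    seqs: list[str] = []
    for item in reads:
        if isinstance(item, str):
            seqs.append(item)
        elif isinstance(item, tuple) and len(item) == 2 and hasattr(item[0], "sequence"):
            seqs.append(item[0].sequence)
            seqs.append(item[1].sequence)
        elif hasattr(item, "sequence"):
            seqs.append(item.sequence)
        else:
            raise TypeError(f"cannot interpret read input of type {type(item)!r}")
    return seqs
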