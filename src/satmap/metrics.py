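"""Assembly statistics: N50, per-cell stats tables, optimized-k detection.

N50 is the length of the shortest transcript such that transcripts of equal
or greater length sum to at least half the total assembly length.  Across a
k-mer sweep at one read depth, the N50-vs-k series typically rises and
falls; the k at the interior global maximum is the *optimized k-mer* and
the N50 there the *optimized N50*.  A series whose maximum sits on the
boundary of the swept range (commonly at shallow depth) is *non-peaked*:
no optimum is declared and only the boundary maximum is reported
informationally.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .assembler import Assembly


@dataclass(frozen=True)
class AssemblyStats:
    datasize_bases: int
    k: int
    n_transcripts: int
    n50_bp: int
    total_bp: int


@dataclass
class KmerSweepResult:
    """N50-vs-k series for one datasize, with the detected optimum if any."""

    datasize_bases: int
    series: list[tuple[int, AssemblyStats]]
    optimized_k: Optional[int]
    optimized_n50_bp: Optional[int]
    peaked: bool
    # boundary maximum, reported informationally when the series is non-peaked
    boundary_k: Optional[int] = None
    boundary_n50_bp: Optional[int] = None


def n50(lengths: Iterable[int]) -> int:
    """N50 of a multiset of transcript lengths.

    Returns the largest length L such that the sum of all lengths >= L is at
    least half the total length.  Empty input is an error, not zero.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("N50 of an empty length multiset is undefined")
    half = sum(lens) / 2.0
    acc = 0
    for length in lens:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def find_optimized_kmer(
    series: Sequence[tuple[int, int]],
) -> tuple[Optional[int], Optional[int], bool]:
    """Locate the interior N50 maximum of an ordered (k, n50) series.

    Returns ``(optimized_k, optimized_n50, peaked)``.  The global maximum is
    taken with ties broken toward smaller k; ``peaked`` is True iff it falls
    strictly inside the k range.  For a non-peaked series the optimized
    fields are None (use the raw series for the boundary maximum).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 (k, n50) points")
    ks = [k for k, _ in series]
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("k values must be strictly increasing")
    values = [v for _, v in series]
    best = max(values)
    idx = values.index(best)  # first occurrence == smallest k on ties
    peaked = 0 < idx < len(series) - 1
    if peaked:
        return ks[idx], best, True
    return None, None, False


def assembly_stats(assembly: Assembly) -> AssemblyStats:
    if assembly.label is None:
        raise ValueError("assembly must carry a (datasize, k) label")
    datasize, k = assembly.label
    lengths = assembly.lengths
    return AssemblyStats(
        datasize_bases=datasize,
        k=k,
        n_transcripts=len(lengths),
        n50_bp=n50(lengths) if lengths else 0,
        total_bp=sum(lengths),
    )


def sweep_result(
    datasize_bases: int, stats: Sequence[AssemblyStats]
) -> KmerSweepResult:
    """Build a KmerSweepResult from per-k stats of one datasize."""
    ordered = sorted(stats, key=lambda s: s.k)
    series = [(s.k, s) for s in ordered]
    opt_k, opt_n50, peaked = find_optimized_kmer([(s.k, s.n50_bp) for s in ordered])
    boundary = max(ordered, key=lambda s: s.n50_bp) if not peaked else None
    return KmerSweepResult(
        datasize_bases=datasize_bases,
        series=series,
        optimized_k=opt_k,
        optimized_n50_bp=opt_n50,
        peaked=peaked,
        boundary_k=boundary.k if boundary else None,
        boundary_n50_bp=boundary.n50_bp if boundary else None,
    )


def stats_table(stats: Iterable[AssemblyStats]) -> pd.DataFrame:
    """Long-form grid of assembly stats, sorted by (datasize, k)."""
    rows = list(stats)
    labels = [(s.datasize_bases, s.k) for s in rows]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate (datasize, k) labels in stats")
    df = pd.DataFrame([s.__dict__ for s in rows])
    return df.sort_values(["datasize_bases", "k"]).reset_index(drop=True)


def render_sweep_grid(df: pd.DataFrame) -> str:
    """Wide TSV: k rows x datasize column pairs (N50, transcript count)."""
    pivot_n50 = df.pivot(index="k", columns="datasize_bases", values="n50_bp")
    pivot_cnt = df.pivot(index="k", columns="datasize_bases", values="n_transcripts")
    out = ["k\t" + "\t".join(f"{d}_n50\t{d}_transcripts" for d in pivot_n50.columns)]
    for k in pivot_n50.index:
        cells = []
        for d in pivot_n50.columns:
            cells.append(f"{pivot_n50.at[k, d]}\t{pivot_cnt.at[k, d]}")
        out.append(f"{k}\t" + "\t".join(cells))
    return "\n".join(out) + "\n"
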