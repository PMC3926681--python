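"""Seed-and-extend alignment with BLAST-like match rules.

Serial transcript mapping, ORF coverage screening, core-gene completeness
and transcript-to-scaffold coverage all share one engine: exact seed words
select candidate subjects, candidates are aligned with a gapped local
(Smith-Waterman) aligner, and per query only the top hit — highest bit
score, then lowest e-value, then lexicographically smallest subject id —
is retained if its e-value passes the threshold.  Bit scores and e-values
follow the Karlin-Altschul extreme-value formula

    bits = (lambda * S - ln K) / ln 2,    E = m * n * 2 ** (-bits)

with m the query length and n the summed subject length.  Both query
strands are searched (assembled transcripts have arbitrary orientation).

The alignment engine is Bio.Align.PairwiseAligner; the scoring defaults
are megablast-like (+1/-2, gap open 5, gap extend 2), with the matching
gapped Karlin parameters.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .assembler import Assembly
from .seqio import revcomp

# gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
_PROTEIN_LAMBDA = 0.267
_PROTEIN_K = 0.041

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide local-alignment scoring and e-value statistics.

    ``gap_open`` and ``gap_extend`` are positive costs: a gap of length g
    costs ``gap_open + g * gap_extend`` (BLAST convention).
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    karlin_lambda: float = 1.28
    karlin_K: float = 0.46
    search_space_bases: Optional[int] = None

    def __post_init__(self) -> None:
        if self.karlin_lambda <= 0:
            raise ValueError("karlin_lambda must be > 0 (degenerate scheme)")
        if self.match_reward <= 0 or self.mismatch_penalty >= 0:
            raise ValueError("match_reward must be > 0 and mismatch_penalty < 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs are given as non-negative magnitudes")


@dataclass
class MappingHit:
    query_id: str
    subject_id: str
    bit_score: float
    e_value: float
    percent_identity: float
    aligned_query_span: tuple[int, int]  # half-open on the query
    query_coverage_pct: float
    raw_score: float = 0.0
    alignment_length: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage_pct <= 100.0):
            raise ValueError("query_coverage_pct outside [0, 100]")
        if self.e_value <= 0:
            raise ValueError("e_value must be > 0")


def _nt_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match_reward
    aligner.mismatch_score = scheme.mismatch_penalty
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0  # open 11 + first extend 1
    aligner.extend_gap_score = -1.0
    return aligner


def karlin_stats(
    raw_score: float, m: int, n: int, lam: float, K: float
) -> tuple[float, float]:
    """(bit score, e-value) for a raw alignment score in an m x n search."""
    bits = (lam * raw_score - math.log(K)) / math.log(2.0)
    e_value = m * n * math.pow(2.0, -min(bits, 4000.0))
    return bits, max(e_value, 1e-300)


@dataclass
class _AlignmentSummary:
    score: float
    matches: int
    columns: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


def _summarize(alignment, target: str, query: str) -> _AlignmentSummary:
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    block_total = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        block_total += te - ts
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    gap_cols = (q_end - q_start - block_total) + (s_end - s_start - block_total)
    return _AlignmentSummary(
        score=float(alignment.score),
        matches=matches,
        columns=block_total + gap_cols,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


class SubjectIndex:
    """Exact seed-word index over subject sequences (forward strand)."""

    def __init__(self, subjects: Sequence[tuple[str, str]], word_size: int = 11):
        if not subjects:
            raise ValueError("subject set must be non-empty")
        self.subjects = list(subjects)
        self.word_size = word_size
        self.total_bases = sum(len(s) for _, s in self.subjects)
        self._index: dict[str, set[int]] = {}
        for idx, (_, seq) in enumerate(self.subjects):
            for i in range(len(seq) - word_size + 1):
                self._index.setdefault(seq[i : i + word_size], set()).add(idx)

    def candidates(self, query_seq: str, max_candidates: int) -> list[int]:
        """Subject indices ranked by number of shared distinct seed words."""
        counts: Counter = Counter()
        w = self.word_size
        for i in range(len(query_seq) - w + 1):
            hit = self._index.get(query_seq[i : i + w])
            if hit:
                for sidx in hit:
                    counts[sidx] += 1
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
        return ranked[:max_candidates]


def as_records(obj) -> list[tuple[str, str]]:
    """Normalize an Assembly or iterable of (id, seq) into a record list."""
    if isinstance(obj, Assembly):
        return list(obj.transcripts)
    return [(str(rid), str(seq).upper()) for rid, seq in obj]


def _better(a: Optional[MappingHit], b: MappingHit) -> MappingHit:
    if a is None:
        return b
    key_a = (-a.bit_score, a.e_value, a.subject_id)
    key_b = (-b.bit_score, b.e_value, b.subject_id)
    return b if key_b < key_a else a


def map_nucleotide(
    queries,
    subjects,
    e_threshold: float = 1.0e-5,
    scheme: Optional[ScoringScheme] = None,
    word_size: int = 11,
    max_candidates: int = 20,
    index: Optional[SubjectIndex] = None,
) -> list[MappingHit]:
    """Top nucleotide hit per query against a subject set.

    Seed-and-extend: subjects sharing at least one exact ``word_size``-mer
    with the query (either strand) are aligned locally; the best-scoring
    hit per query is kept if its e-value passes ``e_threshold``.
    """
    scheme = scheme or ScoringScheme()
    query_records = as_records(queries)
    if index is None:
        index = SubjectIndex(as_records(subjects), word_size)
    aligner = _nt_aligner(scheme)
    n_bases = scheme.search_space_bases or index.total_bases
    hits: list[MappingHit] = []
    for qid, qseq in query_records:
        best: Optional[MappingHit] = None
        qlen = len(qseq)
        for strand, oriented in (("+", qseq), ("-", revcomp(qseq))):
            for sidx in index.candidates(oriented, max_candidates):
                sid, sseq = index.subjects[sidx]
                alignments = aligner.align(sseq, oriented)
                if alignments.score <= 0:
                    continue
                summ = _summarize(alignments[0], sseq, oriented)
                bits, e_value = karlin_stats(
                    summ.score, qlen, n_bases, scheme.karlin_lambda, scheme.karlin_K
                )
                q_start, q_end = summ.q_start, summ.q_end
                if strand == "-":
                    q_start, q_end = qlen - summ.q_end, qlen - summ.q_start
                hit = MappingHit(
                    query_id=qid,
                    subject_id=sid,
                    bit_score=bits,
                    e_value=e_value,
                    percent_identity=100.0 * summ.matches / summ.columns,
                    aligned_query_span=(q_start, q_end),
                    query_coverage_pct=100.0 * (q_end - q_start) / qlen,
                    raw_score=summ.score,
                    alignment_length=summ.columns,
                    strand=strand,
                )
                best = _better(best, hit)
        if best is not None and best.e_value <= e_threshold:
            hits.append(best)
    return hits


def saturation_count(
    sub_assembly,
    full_assembly,
    e_threshold: float = 1.0e-5,
    index: Optional[SubjectIndex] = None,
    **kwargs,
) -> tuple[int, float]:
    """Distinct full-assembly transcripts top-hit by sub-assembly queries.

    Returns ``(n_mapped, pct_of_full)`` where the percentage is relative to
    the full assembly's transcript count — the transcript-representation
    measure of the mapping saturation test.
    """
    full_records = as_records(full_assembly)
    if not full_records:
        raise ValueError("full assembly must be non-empty")
    sub_records = as_records(sub_assembly)
    if not sub_records:
        return 0, 0.0
    hits = map_nucleotide(sub_records, full_records, e_threshold, index=index, **kwargs)
    mapped = {h.subject_id for h in hits}
    return len(mapped), 100.0 * len(mapped) / len(full_records)


@dataclass
class OrfScreenSummary:
    n_queries: int
    n_with_hits: int
    n_with_cov_ge_threshold: int
    pct_of_hits: float  # percentage among queries with hits
    coverage_threshold_pct: float
    hits: list[MappingHit] = field(default_factory=list)


def orf_coverage_screen(
    orfs,
    transcripts,
    coverage_threshold_pct: float = 70.0,
    e_threshold: float = 1.0e-5,
    **kwargs,
) -> OrfScreenSummary:
    """Screen reference ORFs (queries) against transcripts for coverage.

    Per ORF the best hit is retained; coverage is the aligned query span as
    a percentage of ORF length.  The summary percentage is computed among
    ORFs that have any hit.
    """
    orf_records = as_records(orfs)
    hits = map_nucleotide(orf_records, transcripts, e_threshold, **kwargs)
    n_pass = sum(h.query_coverage_pct >= coverage_threshold_pct for h in hits)
    return OrfScreenSummary(
        n_queries=len(orf_records),
        n_with_hits=len(hits),
        n_with_cov_ge_threshold=n_pass,
        pct_of_hits=100.0 * n_pass / len(hits) if hits else 0.0,
        coverage_threshold_pct=coverage_threshold_pct,
        hits=hits,
    )


def six_frame_translations(seq: str) -> list[str]:
    """Conceptual translations of all six reading frames (stops as '*')."""
    frames = []
    for oriented in (seq, revcomp(seq)):
        for off in range(3):
            codons = oriented[off : off + 3 * ((len(oriented) - off) // 3)]
            if len(codons) >= 3:
                frames.append(str(Seq(codons).translate()))
    return frames


def ceg_completeness(
    transcripts,
    core_proteins,
    e_threshold: float = 1.0e-10,
    word_size: int = 4,
    min_frame_aa: int = 15,
) -> int:
    """Count core proteins detected by translated transcript alignment.

    Each transcript is translated in all six frames; frames are aligned to
    the core-protein panel with BLOSUM62.  A core protein is detected when
    at least one frame alignment reaches e-value <= ``e_threshold``.
    """
    protein_records = as_records(core_proteins)
    for pid, pseq in protein_records:
        bad = set(pseq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"protein {pid!r} has invalid residues {sorted(bad)}")
    transcript_records = as_records(transcripts)
    if not transcript_records or not protein_records:
        return 0
    word_index: dict[str, set[int]] = {}
    for idx, (_, pseq) in enumerate(protein_records):
        for i in range(len(pseq) - word_size + 1):
            word_index.setdefault(pseq[i : i + word_size], set()).add(idx)
    aligner = _protein_aligner()
    n_aa = sum(len(p) for _, p in protein_records)
    detected: set[int] = set()
    for _, tseq in transcript_records:
        if len(detected) == len(protein_records):
            break
        for frame in six_frame_translations(tseq):
            if len(frame) < min_frame_aa:
                continue
            cands: set[int] = set()
            for i in range(len(frame) - word_size + 1):
                cands |= word_index.get(frame[i : i + word_size], set())
            for pidx in sorted(cands - detected):
                alignments = aligner.align(protein_records[pidx][1], frame)
                if alignments.score <= 0:
                    continue
                _, e_value = karlin_stats(
                    alignments.score, len(frame), n_aa, _PROTEIN_LAMBDA, _PROTEIN_K
                )
                if e_value <= e_threshold:
                    detected.add(pidx)
    return len(detected)


SCAFFOLD_COVERAGE_BINS = tuple(f"{lo}-{lo + 10}" for lo in range(10, 100, 10))


def _intron_tolerant_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    # Gaps that skip scaffold bases (introns) extend at near-zero cost; gaps
    # in the scaffold relative to the transcript stay at the normal cost.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match_reward
    aligner.mismatch_score = scheme.mismatch_penalty
    aligner.open_insertion_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_insertion_score = -scheme.gap_extend
    aligner.open_deletion_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_deletion_score = -0.1
    return aligner


@dataclass
class ScaffoldCoverageResult:
    n_queries: int
    n_mapped: int
    bin_labels: tuple[str, ...]
    bin_counts: list[int]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.bin_labels, self.bin_counts))


def scaffold_coverage_histogram(
    transcripts,
    scaffolds,
    min_score_frac: float = 0.10,
    scheme: Optional[ScoringScheme] = None,
    word_size: int = 13,
    max_candidates: int = 8,
) -> ScaffoldCoverageResult:
    """Bin transcript-to-scaffold query coverage into ten 10% categories.

    Per transcript the best intron-tolerant local alignment to any scaffold
    is retained if its raw score reaches ``min_score_frac`` of the maximal
    attainable score (a full-length perfect match).  Query coverage of the
    retained alignment is binned into [10,20) ... [90,100]; transcripts
    with no qualifying alignment are excluded from the mapped total.
    """
    scheme = scheme or ScoringScheme()
    transcript_records = as_records(transcripts)
    index = SubjectIndex(as_records(scaffolds), word_size)
    aligner = _intron_tolerant_aligner(scheme)
    counts = [0] * len(SCAFFOLD_COVERAGE_BINS)
    n_mapped = 0
    for _, tseq in transcript_records:
        best: Optional[tuple[float, float]] = None  # (score, coverage)
        for oriented in (tseq, revcomp(tseq)):
            for sidx in index.candidates(oriented, max_candidates):
                _, sseq = index.subjects[sidx]
                alignments = aligner.align(sseq, oriented)
                if alignments.score <= 0:
                    continue
                summ = _summarize(alignments[0], sseq, oriented)
                coverage = 100.0 * (summ.q_end - summ.q_start) / len(tseq)
                if best is None or summ.score > best[0]:
                    best = (summ.score, coverage)
        if best is None:
            continue
        score, coverage = best
        if score < min_score_frac * scheme.match_reward * len(tseq):
            continue
        if coverage < 10.0:
            continue
        n_mapped += 1
        counts[min(int(coverage // 10), 9) - 1] += 1
    return ScaffoldCoverageResult(
        n_queries=len(transcript_records),
        n_mapped=n_mapped,
        bin_labels=SCAFFOLD_COVERAGE_BINS,
        bin_counts=counts,
    )


def hits_to_table(hits: Iterable[MappingHit]):
    """BLAST outfmt-6-like table of hits (pandas DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "percent_identity": h.percent_identity,
                "alignment_length": h.alignment_length,
                "e_value": h.e_value,
                "bit_score": h.bit_score,
                "query_coverage_pct": h.query_coverage_pct,
                "strand": h.strand,
            }
            for h in hits
        ]
    )
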