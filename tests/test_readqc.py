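from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq, read
from satmap.pipeline import _round2
from satmap.readqc import (
    QualityPolicy,
    QuantumSchedule,
    ReadRecord,
    clean_library,
    length_histogram,
    partition_quanta,
    percent_of,
    trim_read,
)

POLICY = QualityPolicy()


class TestTrimRead:
    def test_high_quality_read_unchanged(self, rng):
        r = read(random_seq(rng, 100), 40)
        assert trim_read(r, POLICY) is r

    def test_long_low_quality_tail_rejected(self, rng):
        # end-trimming removes the 75-base Q10 tail, leaving 25 nt < 30 bp
        quals = [40] * 25 + [10] * 75
        r = read(random_seq(rng, 100), quals)
        assert trim_read(r, POLICY) is None

    def test_read_with_interior_n_rejected(self, rng):
        seq = random_seq(rng, 50)
        seq = seq[:25] + "N" + seq[26:]
        assert trim_read(read(seq, 40), POLICY) is None

    def test_n_tolerated_when_policy_allows(self, rng):
        seq = random_seq(rng, 50)[:25] + "N" + random_seq(rng, 24)
        kept = trim_read(read(seq, 40), QualityPolicy(reject_n=False))
        assert kept is not None and len(kept) == 50

    def test_symmetric_trim_keeps_interior_low_quality(self, rng):
        # low-quality bases at both ends are removed, an interior one is kept
        quals = [5] * 3 + [40] * 20 + [5] + [40] * 20 + [5] * 4
        r = read(random_seq(rng, 48), quals)
        trimmed = trim_read(r, POLICY)
        assert len(trimmed) == 41
        assert trimmed.qualities[0] >= 20 and trimmed.qualities[-1] >= 20
        assert 5 in trimmed.qualities

    def test_trim_is_idempotent(self, rng):
        quals = list(rng.integers(2, 41, 100))
        r = read(random_seq(rng, 100), quals)
        once = trim_read(r, POLICY)
        if once is not None:
            again = trim_read(once, POLICY)
            assert again is not None
            assert again.sequence == once.sequence
            assert again.qualities == once.qualities

    def test_mismatched_lengths_is_input_error(self):
        with pytest.raises(ValueError, match="quality length"):
            ReadRecord("r1", "forward", "ACGT", [40, 40, 40])


class TestCleanLibrary:
    def _pair(self, rng, rid, fail_fwd=False, fail_rev=False):
        def one(mate, fail):
            seq = random_seq(rng, 100)
            if fail:
                seq = seq[:50] + "N" + seq[51:]
            return ReadRecord(rid, mate, seq, [40] * 100)

        return one("forward", fail_fwd), one("reverse", fail_rev)

    def test_empty_input_all_zero(self):
        pool = clean_library([])
        assert pool.raw_reads == pool.clean_reads == pool.paired_reads == 0
        assert pool.orphan_reads == pool.raw_bases == 0

    def test_enumerated_survivors(self, rng):
        pairs = [self._pair(rng, f"p{i}") for i in range(7)]
        pairs += [self._pair(rng, "p7", fail_rev=True), self._pair(rng, "p8", fail_fwd=True)]
        pairs += [self._pair(rng, "p9", fail_fwd=True, fail_rev=True)]
        pool = clean_library(pairs)
        assert pool.raw_reads == 20
        assert pool.paired_reads == 14
        assert pool.orphan_reads == 2
        assert pool.clean_reads == 16
        assert pool.rejected_reads == 4
        assert pool.orphans[0].mate == "forward"  # the surviving mate of p7

    def test_duplicate_read_id_is_error(self, rng):
        pairs = [self._pair(rng, "dup"), self._pair(rng, "dup")]
        with pytest.raises(ValueError, match="duplicate"):
            clean_library(pairs)

    def test_reference_paired_percentage_formats_as_96_13(self):
        # bark library tallies: paired reads as % of raw
        assert _round2(percent_of(163_316_702, 169_887_626)) == "96.13"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 45), st.integers(0, 45)), max_size=25))
    def test_conservation_invariants(self, qual_pairs):
        rng = np.random.default_rng(42)
        pairs = []
        for i, (qf, qr) in enumerate(qual_pairs):
            pairs.append(
                (
                    read(random_seq(rng, 60), qf, f"h{i}", "forward"),
                    read(random_seq(rng, 60), qr, f"h{i}", "reverse"),
                )
            )
        pool = clean_library(pairs)
        assert pool.raw_reads == pool.clean_reads + pool.rejected_reads
        assert pool.clean_reads == pool.paired_reads + pool.orphan_reads
        assert pool.paired_reads % 2 == 0
        pool.validate()


class TestPartitionQuanta:
    def _pool(self, rng, n_pairs=5, length=100):
        pairs = [
            (
                read(random_seq(rng, length), 40, f"p{i}", "forward"),
                read(random_seq(rng, length), 40, f"p{i}", "reverse"),
            )
            for i in range(n_pairs)
        ]
        return clean_library(pairs)

    def test_prefix_sum_cut_points(self, rng):
        pool = self._pool(rng)  # 5 pairs x 200 nt = 1000 nt
        quanta = partition_quanta(pool, QuantumSchedule((400, 1000)), seed=0)
        assert [len(q) for q in quanta] == [2, 5]

    def test_full_schedule_returns_whole_pool(self, rng):
        pool = self._pool(rng)
        (quantum,) = partition_quanta(pool, QuantumSchedule((1000,)), seed=3)
        assert len(quantum) == 5

    def test_subsets_are_nested_prefixes(self, rng):
        pool = self._pool(rng, n_pairs=40)
        quanta = partition_quanta(pool, QuantumSchedule((1000, 3000, 8000)), seed=9)
        ids = [[f.read_id for f, _ in q] for q in quanta]
        assert ids[0] == ids[1][: len(ids[0])]
        assert ids[1] == ids[2][: len(ids[1])]

    def test_same_seed_is_deterministic(self, rng):
        pool = self._pool(rng, n_pairs=20)
        a = partition_quanta(pool, QuantumSchedule((1500, 4000)), seed=11)
        b = partition_quanta(pool, QuantumSchedule((1500, 4000)), seed=11)
        assert [[f.read_id for f, _ in q] for q in a] == [
            [f.read_id for f, _ in q] for q in b
        ]

    def test_excessive_target_names_shortfall(self, rng):
        pool = self._pool(rng)
        with pytest.raises(ValueError, match="short by 500"):
            partition_quanta(pool, QuantumSchedule((1500,)), seed=0)

    def test_schedule_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            QuantumSchedule((100, 100))


class TestLengthHistogram:
    def test_empty_input_all_zero(self):
        assert length_histogram([], [30, 100, 101]).tolist() == [0, 0]

    def test_hand_binning(self):
        counts = length_histogram([30, 99, 100], [30, 100, 101])
        assert counts.tolist() == [2, 1]
        assert counts.sum() == 3

    def test_out_of_range_read_is_error(self):
        with pytest.raises(ValueError, match="outside bins"):
            length_histogram([101], [30, 100, 101])

    def test_high_quality_library_peaks_at_full_length(self, rng):
        from satmap.simdata import ReadSimSpec, SyntheticTranscriptomeSpec, gen_transcriptome, simulate_reads

        tr = gen_transcriptome(SyntheticTranscriptomeSpec(n_transcripts=30, seed=1))
        pairs = simulate_reads(tr, ReadSimSpec(target_bases=200_000, seed=1))
        pool = clean_library(pairs)
        reads = [r for pair in pool.paired for r in pair]
        counts = length_histogram(reads, list(range(30, 102)))
        assert counts[-1] > 0.5 * counts.sum()  # bin [100, 101): full-length reads
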