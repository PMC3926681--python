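from __future__ import annotations

import pytest

from conftest import mutate, random_seq
from oracles import smith_waterman_score
from satmap.mapper import (
    ScoringScheme,
    ceg_completeness,
    map_nucleotide,
    orf_coverage_screen,
    saturation_count,
    scaffold_coverage_histogram,
    six_frame_translations,
)
from satmap.seqio import revcomp

# amino acid -> one codon, for back-translating test proteins
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AAS = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


class TestMapNucleotide:
    def test_identical_query_is_perfect_top_hit(self, rng):
        s = random_seq(rng, 400)
        (hit,) = map_nucleotide([("q", s)], [("a", s), ("b", random_seq(rng, 400))])
        assert hit.subject_id == "a"
        assert hit.percent_identity == 100.0
        assert hit.query_coverage_pct == 100.0
        assert hit.e_value < 1e-50

    def test_no_shared_seed_word_no_hit(self, rng):
        hits = map_nucleotide([("q", "AT" * 100)], [("s", "GC" * 100)])
        assert hits == []

    def test_reverse_strand_query_is_found(self, rng):
        s = random_seq(rng, 300)
        (hit,) = map_nucleotide([("q", revcomp(s))], [("s", s)])
        assert hit.strand == "-"
        assert hit.query_coverage_pct == 100.0

    def test_scattered_mismatches_agree_with_dp_oracle(self, rng):
        subject = random_seq(rng, 800)
        q = list(subject[200:500])
        for p in rng.choice(300, 10, replace=False):
            q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
        q = "".join(q)
        (hit,) = map_nucleotide([("q", q)], [("s", subject)])
        assert hit.raw_score == smith_waterman_score(subject, q)
        assert 95.0 < hit.percent_identity < 98.0

    def test_top_hit_score_matches_oracle_on_random_related_pairs(self, rng):
        for _ in range(15):
            subject = random_seq(rng, int(rng.integers(80, 400)))
            lo = int(rng.integers(0, len(subject) // 2))
            hi = int(rng.integers(lo + 40, len(subject) + 1))
            query = mutate(rng, subject[lo:hi], 0.05)
            hits = map_nucleotide([("q", query)], [("s", subject)], e_threshold=1e3)
            oracle = max(
                smith_waterman_score(subject, query),
                smith_waterman_score(subject, revcomp(query)),
            )
            assert hits and hits[0].raw_score == oracle

    def test_degenerate_scheme_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            ScoringScheme(karlin_lambda=0.0)

    def test_empty_subject_set_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            map_nucleotide([("q", random_seq(rng, 100))], [])


class TestSaturationCount:
    def test_self_mapping_is_exactly_100(self, rng):
        full = [(f"t{i}", random_seq(rng, 250)) for i in range(20)]
        assert saturation_count(full, full) == (20, 100.0)

    def test_empty_sub_assembly_is_zero(self, rng):
        full = [(f"t{i}", random_seq(rng, 250)) for i in range(5)]
        assert saturation_count([], full) == (0, 0.0)

    def test_exact_copies_enumerate(self, rng):
        full = [(f"t{i}", random_seq(rng, 300)) for i in range(50)]
        sub = [(f"q{i}", full[i][1]) for i in range(40)]
        assert saturation_count(sub, full) == (40, 80.0)

    def test_monotone_in_sub_assembly(self, rng):
        full = [(f"t{i}", random_seq(rng, 300)) for i in range(30)]
        sub = [(f"q{i}", full[i][1]) for i in range(30)]
        previous = 0
        for cut in (5, 10, 20, 30):
            n_mapped, _ = saturation_count(sub[:cut], full)
            assert n_mapped >= previous
            previous = n_mapped


class TestOrfCoverageScreen:
    def test_contained_orf_passes_at_full_coverage(self, rng):
        t = random_seq(rng, 900)
        orf = t[200:600]
        summary = orf_coverage_screen([("orf1", orf)], [("t1", t)])
        assert summary.n_with_hits == 1
        assert summary.n_with_cov_ge_threshold == 1
        assert summary.hits[0].query_coverage_pct == 100.0

    def test_partial_match_counted_but_fails_screen(self, rng):
        orf = random_seq(rng, 300)
        transcript = orf[:180] + random_seq(rng, 400)  # 60% of the ORF present
        summary = orf_coverage_screen([("orf1", orf)], [("t1", transcript)])
        assert summary.n_with_hits == 1
        assert summary.n_with_cov_ge_threshold == 0

    def test_summary_percentage_is_among_hits(self, rng):
        transcripts = [("t1", random_seq(rng, 800))]
        orfs = [
            ("full", transcripts[0][1][100:500]),
            ("partial", transcripts[0][1][500:650] + random_seq(rng, 250)),
            ("absent", random_seq(rng, 400)),
        ]
        summary = orf_coverage_screen(orfs, transcripts)
        assert summary.n_queries == 3
        assert summary.n_with_hits == 2
        assert summary.pct_of_hits == 50.0


class TestCegCompleteness:
    def test_back_translated_protein_detected(self, rng):
        protein = "".join(_AAS[i] for i in rng.integers(0, 20, 150))
        assert ceg_completeness([("t1", back_translate(protein))], [("p1", protein)]) == 1

    def test_empty_transcript_set_detects_nothing(self, rng):
        assert ceg_completeness([], [("p1", "MKV" * 40)]) == 0

    def test_corrupted_panel_counts_encoded_subset(self, rng):
        proteins = [
            (f"p{i}", "".join(_AAS[j] for j in rng.integers(0, 20, 120)))
            for i in range(20)
        ]
        transcripts = [
            (f"t{i}", mutate(rng, back_translate(p), 0.05))
            for i, (_, p) in enumerate(proteins[:15])
        ]
        assert ceg_completeness(transcripts, proteins) == 15

    def test_invalid_residues_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid residues"):
            ceg_completeness([("t1", random_seq(rng, 120))], [("p1", "MKV123")])

    def test_six_frames_cover_both_strands(self):
        frames = six_frame_translations("ATGAAAGTT" * 10)
        assert len(frames) == 6
        assert any(f.startswith("MKV") for f in frames)


class TestScaffoldCoverage:
    def test_embedded_and_half_embedded_binning(self, rng):
        scaffold = random_seq(rng, 6000)
        transcripts = []
        for i in range(7):  # fully embedded
            start = 100 + i * 700
            transcripts.append((f"full{i}", scaffold[start : start + 400]))
        for i in range(3):  # half embedded: 50% scaffold, 50% foreign
            start = 5000 + i * 300
            transcripts.append(
                (f"half{i}", scaffold[start : start + 200] + random_seq(rng, 200))
            )
        res = scaffold_coverage_histogram(transcripts, [("sc", scaffold)])
        assert res.n_mapped == 10
        assert res.as_dict()["90-100"] == 7
        assert res.as_dict()["50-60"] == 3
        assert sum(res.bin_counts) == res.n_mapped

    def test_unrelated_transcript_excluded(self, rng):
        res = scaffold_coverage_histogram(
            [("t", random_seq(rng, 300))], [("sc", random_seq(rng, 2000))]
        )
        assert res.n_mapped == 0

    def test_intron_in_scaffold_is_bridged(self, rng):
        scaffold = random_seq(rng, 3000)
        spliced = scaffold[100:350] + scaffold[700:950]  # 350 nt "intron" skipped
        res = scaffold_coverage_histogram([("t", spliced)], [("sc", scaffold)])
        assert res.as_dict()["90-100"] == 1
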