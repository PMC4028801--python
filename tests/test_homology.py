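"""Translated search engine: frames, alignment scores, E-values, pooling."""

import math

import numpy as np
import pytest

from groupii import _jtt
from groupii.fixtures import reverse_translate
from groupii.homology import (
    DEFAULT_SCHEME,
    HSP,
    local_align,
    pool_hits,
    six_frame_translate,
    translated_search,
)

from .oracles import brute_force_sw, sweep_union

AA = list(_jtt.AA_ORDER)


def random_protein(rng, n):
    return "".join(rng.choice(AA, size=n, p=_jtt.FREQUENCIES))


class TestSixFrames:
    def test_code_table_identity(self):
        frames = six_frame_translate("ATGGCT")
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
        assert fwd0.protein == "MA"

    def test_reverse_frames_equal_forward_frames_of_revcomp(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dna = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 200))))
            rc = dna[::-1].translate(str.maketrans("ACGT", "TGCA"))
            rev = {f.frame: f.protein for f in six_frame_translate(dna) if f.strand == "-"}
            fwd_rc = {f.frame: f.protein for f in six_frame_translate(rc) if f.strand == "+"}
            assert rev == fwd_rc

    def test_frames_jointly_cover_all_but_frame_ends(self):
        rng = np.random.default_rng(4)
        dna = "".join(rng.choice(list("ACGT"), size=300))
        for f in six_frame_translate(dna):
            dropped = (300 - f.frame) % 3 + f.frame
            assert dropped <= 2 + f.frame  # at most 2 nt lost per frame end
            assert 3 * len(f.protein) + (300 - f.frame) % 3 == 300 - f.frame


class TestLocalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        rng = np.random.default_rng(7)
        p = random_protein(rng, 30)
        aln = local_align(p, p)
        expected = sum(DEFAULT_SCHEME.matrix[c, c] for c in p)
        assert aln.score == expected
        assert all(q is not None and s is not None for q, s in aln.aligned_pairs)

    def test_matches_brute_force_dp_on_random_pairs(self):
        rng = np.random.default_rng(8)
        matrix = DEFAULT_SCHEME.matrix
        for _ in range(100):
            q = random_protein(rng, int(rng.integers(5, 31)))
            s = random_protein(rng, int(rng.integers(5, 31)))
            expected = brute_force_sw(
                q, s, matrix, DEFAULT_SCHEME.gap_open, DEFAULT_SCHEME.gap_extend
            )
            aln = local_align(q, s)
            got = aln.score if aln else 0
            assert got == expected

    def test_score_is_symmetric_for_symmetric_matrix(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            q = random_protein(rng, 25)
            s = random_protein(rng, 25)
            a = local_align(q, s)
            b = local_align(s, q)
            assert (a.score if a else 0) == (b.score if b else 0)


class TestTranslatedSearch:
    def test_planted_orf_is_top_hit_with_significant_evalue(self):
        rng = np.random.default_rng(10)
        protein = random_protein(rng, 200)
        orf = reverse_translate(protein, rng)
        dna = (
            "".join(rng.choice(list("ACGT"), size=500))
            + orf
            + "".join(rng.choice(list("ACGT"), size=400))
        )
        hsps = translated_search(protein, dna)
        assert hsps, "planted ORF not found"
        top = hsps[0]
        assert top.evalue <= 1e-20
        assert top.strand == "+"
        s, e = top.subject_interval
        assert s >= 498 and e <= 500 + len(orf) + 2
        assert not top.has_internal_stop

    def test_shuffled_queries_find_nothing(self):
        rng = np.random.default_rng(12)
        protein = list(random_protein(rng, 150))
        dna = "".join(rng.choice(list("ACGT"), size=1500))
        hits = 0
        for _ in range(100):
            rng.shuffle(protein)
            if translated_search("".join(protein), dna):
                hits += 1
        assert hits <= 5  # >=95% of shuffles yield no HSP at the cutoff

    def test_evalue_strictly_decreasing_in_score(self):
        evs = [DEFAULT_SCHEME.evalue(s, 200, 1000) for s in range(50, 400, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_karlin_altschul_tail_calibration(self):
        # P(bit >= s) for shuffled subjects should track m*n*2^-s within a
        # factor of 3 (the NCBI-style bit score already folds in K)
        rng = np.random.default_rng(42)
        m, n, trials = 60, 200, 200
        query = random_protein(rng, m)
        subject = list(random_protein(rng, n))
        bits = []
        for _ in range(trials):
            rng.shuffle(subject)
            aln = local_align(query, "".join(subject))
            bits.append(DEFAULT_SCHEME.bit_score(aln.score if aln else 0))
        bits = np.array(bits)
        for q in (0.5, 0.25, 0.1):
            s = float(np.quantile(bits, 1 - q))
            empirical = float((bits >= s).mean())
            expected = min(1.0, m * n * 2.0 ** (-s))
            assert expected / 3 <= empirical <= expected * 3


def _hsp(acc, start, end, strand="+", query="q", ev=1e-30):
    return HSP(
        query_id=query,
        subject_accession=acc,
        subject_interval=(start, end),
        strand=strand,
        frame=0,
        raw_score=300,
        bit_score=120.0,
        evalue=ev,
    )


class TestPooling:
    def test_overlapping_hits_merge_to_union(self):
        loci = pool_hits(
            [_hsp("X", 100, 1300, query="q1"), _hsp("X", 150, 1350, query="q2")]
        )
        assert len(loci) == 1
        assert loci[0].interval == (100, 1350)
        assert loci[0].supporting_queries == ["q1", "q2"]

    def test_opposite_strands_stay_separate(self):
        loci = pool_hits([_hsp("X", 100, 400, "+"), _hsp("X", 100, 400, "-")])
        assert len(loci) == 2

    def test_bookended_intervals_do_not_merge(self):
        loci = pool_hits([_hsp("X", 100, 400), _hsp("X", 400, 700)])
        assert len(loci) == 2

    def test_chained_overlaps_match_sweep_line_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            intervals = []
            for _ in range(int(rng.integers(1, 12))):
                s = int(rng.integers(0, 5000))
                intervals.append((s, s + int(rng.integers(10, 1500))))
            loci = pool_hits([_hsp("X", s, e) for s, e in intervals])
            assert [l.interval for l in loci] == sweep_union(intervals)

    def test_pooling_is_a_partition_refinement(self):
        rng = np.random.default_rng(14)
        hsps = []
        for _ in range(40):
            s = int(rng.integers(0, 3000))
            hsps.append(_hsp("X", s, s + int(rng.integers(10, 900))))
        loci = pool_hits(hsps)
        for h in hsps:
            containing = [
                l
                for l in loci
                if l.interval[0] <= h.subject_interval[0]
                and h.subject_interval[1] <= l.interval[1]
            ]
            assert len(containing) == 1
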