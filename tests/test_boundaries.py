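"""Boundary profiles, dual-scorer scanning, and boundary resolution."""

import numpy as np
import pytest

from groupii.boundaries import (
    BoundaryBin,
    BoundaryCandidate,
    BoundaryCall,
    IntronStatus,
    Side,
    _profile_scan,
    build_profile,
    generate_intron,
    resolve_boundaries,
    scan_boundaries,
    tier_for,
)
from groupii.fixtures import CLASS_C_FIVE, IUPAC, sample_consensus

from .conftest import truth_window_positions, window_for


def _training(consensus, n=40, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    return [sample_consensus(consensus, rng, noise) for _ in range(n)]


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBuildProfile:
    def test_identical_training_puts_argmax_on_observed_bases(self):
        prof = build_profile(["GTGCG"] * 10, "X", Side.FIVE_PRIME, n_calibration=50)
        assert prof.consensus() == "GTGCG"

    def test_class_c_consensus_is_columnwise_argmax(self):
        prof = build_profile(
            _training(CLASS_C_FIVE), "C", Side.FIVE_PRIME, n_calibration=50
        )
        got = prof.consensus()
        for i, c in enumerate(CLASS_C_FIVE):
            allowed = IUPAC[c]
            if len(allowed) == 1:
                assert got[i] == c
            else:
                assert got[i] in allowed

    def test_entropy_decreases_with_conservation(self):
        loose = build_profile(
            _training("GTGCGATCGA", noise=0.35), "X", Side.FIVE_PRIME, n_calibration=50
        )
        tight = build_profile(
            _training("GTGCGATCGA", noise=0.02), "X", Side.FIVE_PRIME, n_calibration=50
        )
        assert tight.column_entropy().mean() < loose.column_entropy().mean()

    def test_ragged_training_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["ACGT", "ACG"], "X", Side.FIVE_PRIME)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["ACGT"], "X", Side.FIVE_PRIME)


def test_forward_scorer_dominates_viterbi_everywhere():
    # sum over paths >= best path, in odds space, at every offset
    rng = np.random.default_rng(1)
    prof = build_profile(_training("GTGCGATCGATCGGA"), "X", Side.FIVE_PRIME,
                         n_calibration=50)
    for _ in range(5):
        window = _random_dna(rng, 300)
        va, vb = _profile_scan(prof.log_odds, np.array(
            [{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in window]
        ))
        assert (vb >= va - 1e-9).all()


@pytest.fixture(scope="module")
def profile():
    return build_profile(_training("GTGCGATCGATCGGAATCG"), "X", Side.FIVE_PRIME)


class TestScan:

    def test_planted_motif_found_at_exact_position(self, profile):
        rng = np.random.default_rng(2)
        motif = sample_consensus("GTGCGATCGATCGGAATCG", rng)
        window = _random_dna(rng, 400) + motif + _random_dna(rng, 300)
        call = scan_boundaries(window, profile, profile)
        assert call.candidates_5
        assert call.candidates_5[0].window_position == 400
        assert call.candidates_5[0].tier == "high"

    def test_translation_equivariance(self, profile):
        rng = np.random.default_rng(3)
        motif = sample_consensus("GTGCGATCGATCGGAATCG", rng)
        pad = _random_dna(rng, 200)
        w1 = motif + pad
        w2 = _random_dna(rng, 7) + motif + pad[:-7]
        c1 = scan_boundaries(w1, profile, profile).candidates_5[0]
        c2 = scan_boundaries(w2, profile, profile).candidates_5[0]
        assert c2.window_position - c1.window_position == 7

    def test_random_windows_have_no_confident_boundary(self, profile):
        rng = np.random.default_rng(4)
        confident = 0
        for _ in range(100):
            call = scan_boundaries(_random_dna(rng, 120), profile, profile)
            if any(
                c.tier in ("high", "medium")
                for c in call.candidates_5 + call.candidates_3
            ):
                confident += 1
        assert confident <= 5

    def test_window_shorter_than_profile_bins_none(self, profile):
        call = scan_boundaries("ACGT", profile, profile)
        assert call.bin is BoundaryBin.NONE
        assert call.tier is None


def test_tier_is_monotone_in_score():
    order = {None: 0, "low": 1, "medium": 2, "high": 3}
    zs = np.linspace(0, 10, 200)
    tiers = [order[tier_for(float(z))] for z in zs]
    assert tiers == sorted(tiers)


def _cand(side, pos, z=8.0, tier="high"):
    return BoundaryCandidate(
        side=side, window_position=pos, score_a=z, score_b=z - 0.5, tier=tier
    )


def _call(c5, c3):
    if c5 and c3:
        b = BoundaryBin.BOTH
    elif c5:
        b = BoundaryBin.FIVE_ONLY
    elif c3:
        b = BoundaryBin.THREE_ONLY
    else:
        b = BoundaryBin.NONE
    return BoundaryCall(bin=b, tier="high", candidates_5=c5, candidates_3=c3)


class TestResolve:
    def test_unique_pair_resolves_with_correct_length(self):
        call = _call(
            [_cand(Side.FIVE_PRIME, 2100)], [_cand(Side.THREE_PRIME, 4600)]
        )
        res = resolve_boundaries(call, (2400, 4300))
        assert res.status is IntronStatus.HAVE_BOUNDARIES
        assert (res.start_5, res.end_3) == (2100, 4600)
        assert res.end_3 - res.start_5 + 1 == 2501

    def test_two_high_five_prime_candidates_are_ambiguous(self):
        call = _call(
            [_cand(Side.FIVE_PRIME, 2100), _cand(Side.FIVE_PRIME, 1500)],
            [_cand(Side.THREE_PRIME, 4600)],
        )
        res = resolve_boundaries(call, (2400, 4300))
        assert res.status is IntronStatus.AMBIGUOUS
        assert "multiple_5" in res.reasons

    def test_wrong_order_is_ambiguous(self):
        call = _call(
            [_cand(Side.FIVE_PRIME, 4700)], [_cand(Side.THREE_PRIME, 2100)]
        )
        res = resolve_boundaries(call, (4800, 4900))
        assert res.status is IntronStatus.AMBIGUOUS

    def test_short_span_violates_length_bounds(self):
        call = _call(
            [_cand(Side.FIVE_PRIME, 2100)], [_cand(Side.THREE_PRIME, 2250)]
        )
        res = resolve_boundaries(call, (2130, 2220))
        assert res.status is IntronStatus.AMBIGUOUS
        assert "length_out_of_bounds" in res.reasons

    def test_submaximal_fallback_admits_single_best_medium(self):
        call = _call(
            [_cand(Side.FIVE_PRIME, 2100)],
            [
                _cand(Side.THREE_PRIME, 4600, z=4.5, tier="medium"),
                _cand(Side.THREE_PRIME, 5200, z=3.0, tier="low"),
            ],
        )
        strict = resolve_boundaries(call, (2400, 4300))
        assert strict.status is IntronStatus.AMBIGUOUS
        relaxed = resolve_boundaries(call, (2400, 4300), admit_single_submaximal=True)
        assert relaxed.status is IntronStatus.HAVE_BOUNDARIES
        assert relaxed.end_3 == 4600


class TestGenerate:
    def test_emitted_intron_matches_planted_motifs(self, small_world, bundle_=None):
        spec, bundle, records, truth = small_world
        by_acc = {r.accession: r for r in records}
        row = next(r for r in truth.rows if r.kind == "intron")
        window = window_for(row, by_acc)
        p5 = bundle.profiles[row.class_label]["five_prime"]
        p3 = bundle.profiles[row.class_label]["three_prime"]
        call = scan_boundaries(window, p5, p3)
        res = resolve_boundaries(call, window.hit_interval_window)
        assert res.status is IntronStatus.HAVE_BOUNDARIES
        generate_intron(window, res)
        assert res.intron_seq == window.window_seq[res.start_5 : res.end_3 + 1]
        assert res.intron_seq.startswith("GT")
        w5, w3 = truth_window_positions(row, window)
        assert (res.start_5, res.end_3) == (w5, w3)
        assert len(res.exon_context_5) == 20 and len(res.exon_context_3) == 20

    def test_class_c_intron_has_generic_consensus_termini(self, corpus):
        records, truth = corpus
        row = next(
            r for r in truth.rows if r.kind == "intron" and r.class_label == "C"
        )
        rec = {r.accession: r for r in records}[row.accession]
        s, e = row.intron_interval
        intron = rec.sequence[s:e]
        if row.strand == "-":
            from groupii.seqio import revcomp

            intron = revcomp(intron)
        assert intron.startswith("GT")
        assert intron.endswith("AT")

    def test_generate_requires_resolved_boundaries(self):
        res = resolve_boundaries(_call([], []), (100, 200))
        with pytest.raises(ValueError):
            generate_intron("ACGT" * 300, res)
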