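"""ML distances, identity grouping, and prototype selection."""

import numpy as np
import pytest

from groupii import _jtt
from groupii.redundancy import (
    DEFAULT_DISTANCE_THRESHOLD,
    DistanceMatrix,
    IdentityGroup,
    align_orf_region,
    distance_matrix,
    group_by_threshold,
    ml_distance,
    select_prototypes,
)

from .oracles import bfs_components, grid_jtt_distance

AA = list(_jtt.AA_ORDER)


def random_protein(rng, n):
    return "".join(rng.choice(AA, size=n, p=_jtt.FREQUENCIES))


def substitute(protein, k, rng):
    p = list(protein)
    for i in rng.choice(len(p), size=k, replace=False):
        p[i] = _jtt.AA_ORDER.replace(p[i], "")[rng.integers(19)]
    return "".join(p)


class TestMLDistance:
    def test_identical_sequences_have_zero_distance(self):
        p = random_protein(np.random.default_rng(0), 200)
        assert ml_distance(p, p) == 0.0

    def test_twenty_subs_in_400_is_near_ninety_five_percent_identity(self):
        rng = np.random.default_rng(1)
        a = random_protein(rng, 400)
        b = substitute(a, 20, rng)
        d = ml_distance(a, b)
        assert abs(d - 0.052) <= 0.01
        assert d < DEFAULT_DISTANCE_THRESHOLD

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(80, 160))
            a = random_protein(rng, n)
            b = substitute(a, int(rng.integers(2, n // 4)), rng)
            assert abs(ml_distance(a, b) - grid_jtt_distance(a, b)) < 1e-3

    def test_distance_monotone_under_nested_differences(self):
        rng = np.random.default_rng(3)
        a = random_protein(rng, 300)
        b = list(a)
        prev = 0.0
        positions = rng.choice(300, size=25, replace=False)
        for i in positions:
            b[i] = _jtt.AA_ORDER.replace(b[i], "")[rng.integers(19)]
            d = ml_distance(a, "".join(b))
            assert d >= prev - 1e-9
            prev = d

    def test_gap_columns_excluded_pairwise(self):
        assert ml_distance("AC-DE", "ACWDE") == ml_distance("ACDE", "ACDE")

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError):
            ml_distance("---", "AAA")


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        p = random_protein(np.random.default_rng(4), 150)
        aligned = align_orf_region([("a", p), ("b", p)])
        assert aligned == [("a", p), ("b", p)]

    def test_planted_pair_identity_matches_hamming_oracle(self):
        rng = np.random.default_rng(5)
        a = random_protein(rng, 400)
        b = substitute(a, 20, rng)
        aligned = align_orf_region([("a", a), ("b", b)])
        cols = list(zip(aligned[0][1], aligned[1][1]))
        ident = sum(1 for x, y in cols if x == y and x != "-") / len(cols)
        assert abs(ident - 0.95) <= 0.01

    def test_singleton_short_circuits(self):
        assert align_orf_region([("only", "MKV")]) == [("only", "MKV")]


class TestGrouping:
    def test_pair_at_95_identity_groups_together(self):
        rng = np.random.default_rng(6)
        a = random_protein(rng, 400)
        b = substitute(a, 20, rng)
        dm = distance_matrix([("a", a), ("b", b)])
        groups = group_by_threshold(dm)
        assert len(groups) == 1 and groups[0].member_ids == ["a", "b"]

    def test_single_linkage_chains_transitively(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0.05, 0.12], [0.05, 0, 0.05], [0.12, 0.05, 0]])
        groups = group_by_threshold(DistanceMatrix(ids, d), threshold=0.061)
        assert len(groups) == 1
        assert groups[0].member_ids == ["a", "b", "c"]

    def test_all_distant_pairs_stay_singletons(self):
        ids = ["a", "b", "c"]
        d = np.full((3, 3), 0.3)
        np.fill_diagonal(d, 0.0)
        groups = group_by_threshold(DistanceMatrix(ids, d))
        assert [g.member_ids for g in groups] == [["a"], ["b"], ["c"]]

    def test_matches_brute_force_components_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            ids = [f"s{i}" for i in range(n)]
            d = rng.uniform(0, 0.15, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            groups = group_by_threshold(DistanceMatrix(ids, d), threshold=0.061)
            assert [g.member_ids for g in groups] == bfs_components(ids, d, 0.061)

    def test_groups_partition_the_candidate_set(self):
        rng = np.random.default_rng(8)
        n = 15
        ids = [f"s{i}" for i in range(n)]
        d = rng.uniform(0, 0.12, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        groups = group_by_threshold(DistanceMatrix(ids, d))
        members = [m for g in groups for m in g.member_ids]
        assert sorted(members) == sorted(ids)
        assert len(members) == len(set(members))


class TestPrototypes:
    def _group(self, members):
        return IdentityGroup(group_id="g0", class_label="ML", member_ids=members)

    def test_single_species_group_gets_one_prototype(self):
        g = self._group(["a", "b", "c", "d"])
        protos = select_prototypes(
            g, species={m: "Synthetica x" for m in g.member_ids},
            lengths={"a": 10, "b": 30, "c": 20, "d": 30},
        )
        assert protos == [("b", "Synthetica x")]  # longest, tie broken by id

    def test_each_species_in_a_group_gets_a_prototype(self):
        g = self._group(["a", "b", "c", "d", "e"])
        species = {"a": "X", "b": "X", "c": "Y", "d": "Y", "e": "X"}
        protos = select_prototypes(g, species, lengths={m: 1 for m in g.member_ids})
        assert len(protos) == 2
        assert {sp for _, sp in protos} == {"X", "Y"}

    def test_singleton_is_its_own_prototype(self):
        g = self._group(["solo"])
        assert select_prototypes(g, {"solo": "X"}) == [("solo", "X")]
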