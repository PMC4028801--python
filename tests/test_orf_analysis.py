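"""Domain inventory, ORF intactness, and IEP start assignment."""

import itertools

import numpy as np
import pytest

from groupii.fixtures import reverse_translate
from groupii.orf_analysis import (
    DomainCategory,
    OrfIssue,
    ReferenceIEP,
    assign_iep,
    candidate_region,
    categorize_counts,
    domain_inventory,
    orf_intactness,
    pick_reference,
    sd_motif_score,
)

from .conftest import window_for


@pytest.fixture(scope="module")
def world(small_world):
    spec, bundle, records, truth = small_world
    by_acc = {r.accession: r for r in records}
    return bundle, by_acc, truth


def _class_ref(bundle, label):
    if label in bundle.class_refs:
        return bundle.class_refs[label]
    return bundle.class_refs["CL1"]


def test_category_mapping_is_total_and_exclusive():
    # exhaustive truth table over (has zero count, has >1 count)
    for zero, extra in itertools.product([False, True], repeat=2):
        counts = {"0": 1, "1": 0 if zero else 1, "X": 2 if extra else 1}
        got = categorize_counts(counts)
        expected = {
            (False, False): DomainCategory.NORMAL,
            (True, False): DomainCategory.MISSING,
            (False, True): DomainCategory.EXTRA,
            (True, True): DomainCategory.MISSING_AND_EXTRA,
        }[(zero, extra)]
        assert got is expected


def test_reference_against_itself_is_normal(world):
    bundle, _, _ = world
    ref = next(iter(bundle.class_refs.values()))
    window = reverse_translate(ref.protein, np.random.default_rng(0)) + "TAA"
    inv = domain_inventory(window, ref)
    assert inv.category is DomainCategory.NORMAL
    assert all(c == 1 for c in inv.counts.values())


def test_truncated_intron_is_missing_late_domains(world):
    bundle, by_acc, truth = world
    row = next(r for r in truth.rows if r.kind == "truncated")
    ref = _class_ref(bundle, row.class_label)
    inv = domain_inventory(window_for(row, by_acc), ref)
    assert inv.category is DomainCategory.MISSING
    assert inv.counts["X"] == 0 and inv.counts["7"] == 0
    assert inv.counts["0"] == 1


def test_twintron_has_duplicated_domains(world):
    bundle, by_acc, truth = world
    row = next(r for r in truth.rows if r.kind == "twintron")
    ref = _class_ref(bundle, row.class_label)
    inv = domain_inventory(window_for(row, by_acc), ref)
    assert inv.category in (DomainCategory.EXTRA, DomainCategory.MISSING_AND_EXTRA)
    assert any(c > 1 for c in inv.counts.values())


def test_removing_a_proxy_segment_never_raises_its_count(world):
    bundle, by_acc, truth = world
    row = next(r for r in truth.rows if r.kind == "intron")
    ref = _class_ref(bundle, row.class_label)
    window = window_for(row, by_acc)
    before = domain_inventory(window, ref).counts["5"]
    # cut out the window segment around the domain-5 proxy
    hsps_start = window.hit_interval_window[0]
    cut_at = hsps_start + 3 * ref.proxy_positions["5"]
    mutated = window.window_seq[: cut_at - 30] + window.window_seq[cut_at + 30 :]
    after = domain_inventory(mutated, ref).counts["5"]
    assert after <= before


class TestIntactness:
    def test_planted_intron_is_intact_single_hsp(self, world):
        bundle, by_acc, truth = world
        row = next(r for r in truth.rows if r.kind == "intron")
        rel = bundle.curated[0]
        status = orf_intactness(window_for(row, by_acc), rel.protein, rel.region)
        assert status.intact and status.hsp_count == 1

    def test_frameshift_splits_into_multiple_hsps(self, world):
        bundle, by_acc, truth = world
        row = next(r for r in truth.rows if r.kind == "frameshifted")
        rel = min(
            bundle.curated, key=lambda c: 0 if c.class_label == row.class_label else 1
        )
        status = orf_intactness(window_for(row, by_acc), rel.protein, rel.region)
        assert not status.intact
        assert OrfIssue.MULTIPLE_HSPS in status.issues
        assert status.hsp_count >= 2

    def test_premature_stop_is_detected(self, world):
        bundle, by_acc, truth = world
        row = next(r for r in truth.rows if r.kind == "premature_stop")
        rel = min(
            bundle.curated, key=lambda c: 0 if c.class_label == row.class_label else 1
        )
        status = orf_intactness(window_for(row, by_acc), rel.protein, rel.region)
        assert not status.intact
        assert OrfIssue.PREMATURE_STOP in status.issues


class TestStartAssignment:
    def test_exact_copy_recovers_identical_start_and_protein(self):
        rng = np.random.default_rng(31)
        protein = "M" + "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=250)
        )
        orf = reverse_translate(protein, rng) + "TAA"
        window = (
            "".join(rng.choice(list("ACGT"), size=300))
            + "AGGAGG"
            + "TTCCTAC"
            + orf
            + "".join(rng.choice(list("ACGT"), size=200))
        )
        iep = assign_iep(window, protein, "ATG")
        assert iep is not None
        assert iep.protein == protein
        assert iep.start_codon == "ATG"
        assert iep.start_pos_window == 313

    def test_sd_led_atg_beats_closer_sdless_gtg(self):
        # hand-scored: the AGGAGG PWM contributes ~10.6 bits to the ATG,
        # far above the <=2.5 combined distance/codon advantages of the GTG
        rng = np.random.default_rng(32)
        protein = "M" + "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200)
        )
        body = reverse_translate(protein, rng)[3:] + "TAA"
        # layout: [pad][AGGAGG][8 nt][ATG][12 nt shifted GTG frame]...body
        window = (
            "".join(rng.choice(list("ACGT"), size=120))
            + "AGGAGG" + "ACTCCTTC"  # SD + 8 nt spacer
            + "ATG" + "CACGTTCAAGTA" + "GTG"
            + body
            + "".join(rng.choice(list("ACGT"), size=60))
        )
        atg_pos = 120 + 6 + 8
        gtg_pos = atg_pos + 15
        assert window[atg_pos : atg_pos + 3] == "ATG"
        assert window[gtg_pos : gtg_pos + 3] == "GTG"
        assert sd_motif_score(window, atg_pos) > 10
        assert sd_motif_score(window, gtg_pos) == 0
        # relative aligns its start at the GTG (its protein body begins there)
        relative = "M" + str(
            __import__("Bio.Seq", fromlist=["Seq"]).Seq(window[gtg_pos + 3 :]).translate(table=11)
        ).split("*")[0]
        iep = assign_iep(window, relative, "GTG")
        assert iep is not None
        assert iep.start_pos_window == atg_pos
        assert iep.start_codon == "ATG"

    def test_start_aligned_into_missing_flank_gives_null(self):
        rng = np.random.default_rng(33)
        protein = "M" + "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=250)
        )
        orf = reverse_translate(protein, rng)
        window = orf[120:] + "TAA" + "".join(rng.choice(list("ACGT"), size=100))
        assert assign_iep(window, protein, "ATG") is None


def test_cl_candidates_pick_the_better_subclass_reference(world):
    bundle, by_acc, truth = world
    row = next(r for r in truth.rows if r.kind == "intron" and r.class_label == "CL")
    ref = pick_reference(
        list(bundle.class_refs.values()), "CL", window_for(row, by_acc)
    )
    assert ref.class_label in ("CL1", "CL2")


def test_candidate_region_maps_reference_span(world):
    bundle, _, truth = world
    ref = next(iter(bundle.class_refs.values()))
    region = candidate_region(ref.protein, ref)
    assert region == ref.region
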