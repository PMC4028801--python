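import pytest

from groupii.fixtures import FixtureSpec, make_reference_bundle, plant_genome
from groupii.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def default_spec():
    """The default study conditions: 8 classes, 45 full introns (40
    singletons + two identity clusters), 25 decoys."""
    return FixtureSpec(seed=2013)


@pytest.fixture(scope="session")
def bundle(default_spec):
    return make_reference_bundle(default_spec)


@pytest.fixture(scope="session")
def corpus(default_spec, bundle):
    return plant_genome(default_spec, bundle)


@pytest.fixture(scope="session")
def full_run(corpus, bundle, tmp_path_factory):
    """One end-to-end pipeline run over the default corpus, with storage
    trees on disk; shared by the pipeline and acceptance tests."""
    records, truth = corpus
    workdir = tmp_path_factory.mktemp("run_a")
    state = run_all(records, bundle, PipelineConfig(), workdir=workdir)
    return state, truth, workdir


@pytest.fixture(scope="session")
def small_world():
    """A two-class corpus with one decoy of each kind, for unit tests that
    need realistic planted elements without the full suite's cost."""
    spec = FixtureSpec(
        seed=7,
        n_classes=2,
        introns_per_class=2,
        decoys={
            "truncated": 1,
            "frameshifted": 1,
            "premature_stop": 1,
            "non_gii_rt": 1,
            "twintron": 1,
        },
        identity_clusters=[(2, 0.95)],
    )
    bundle = make_reference_bundle(spec)
    records, truth = plant_genome(spec, bundle)
    return spec, bundle, records, truth


def window_for(truth_row, records_by_acc, flank=3000):
    """Candidate-style window around a planted element's ORF."""
    from groupii.seqio import extract_window

    return extract_window(
        records_by_acc[truth_row.accession],
        truth_row.orf_interval,
        truth_row.strand,
        flank_nt=flank,
    )


def truth_window_positions(truth_row, window):
    """Planted 5'/3' boundary positions in window coordinates."""
    s, e = truth_row.intron_interval
    if truth_row.strand == "+":
        return window.to_window(s), window.to_window(e - 1)
    return window.to_window(e - 1), window.to_window(s)
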