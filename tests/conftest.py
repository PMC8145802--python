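import pytest

from isoquantbench import (
    SimulationConfig,
    build_two_condition_truth,
    make_toy_fixture,
    simulate_sample,
    spliced_sequence,
)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def toy():
    """Default toy fixture: 20 genes, <=4 isoforms, planted ambiguity."""
    return make_toy_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def toy_truth(toy):
    return build_two_condition_truth(toy.truth_config, toy.annotation)


@pytest.fixture(scope="session")
def transcript_seqs(toy):
    return {
        tx: spliced_sequence(model, toy.genome)
        for tx, model in toy.annotation.transcripts.items()
    }


@pytest.fixture(scope="session")
def idealized_bundle(toy, toy_truth):
    config = SimulationConfig.idealized(seed=FIXTURE_SEED)
    return simulate_sample(
        toy.annotation, toy.genome, toy_truth.truth.sample_counts("A1"), config, "A1"
    )


@pytest.fixture(scope="session")
def idealized_alignments(idealized_bundle, transcript_seqs):
    from isoquantbench import exact_match_align

    config = SimulationConfig.idealized(seed=FIXTURE_SEED)
    aligned, unaligned = exact_match_align(
        idealized_bundle.pairs, transcript_seqs, config.frag_min, config.frag_max
    )
    return aligned, unaligned
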