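"""Build a toy genome, generate two-condition truth, and simulate reads.

Prints the per-sample fragment totals and shows that the simulator emits
exactly one read pair per true fragment, with every read's source transcript
recorded in the origin log.
"""
from isoquantbench import (
    SimulationConfig,
    build_two_condition_truth,
    make_toy_fixture,
    simulate_sample,
)

fixture = make_toy_fixture(seed=7)
print(f"toy genome: {len(fixture.genome.chrom_names)} chromosomes, "
      f"{len(fixture.annotation)} transcripts in {len(fixture.annotation.genes)} genes")

result = build_two_condition_truth(fixture.truth_config, fixture.annotation)
print("label breakdown:", result.labels.value_counts().to_dict())

config = SimulationConfig.idealized(seed=7)
bundle = simulate_sample(
    fixture.annotation, fixture.genome, result.truth.sample_counts("A1"), config, "A1"
)
truth_total = result.truth.sample_counts("A1").sum()
print(f"sample A1: truth total {truth_total} fragments -> {len(bundle.pairs)} read pairs")
print("first origin-log rows (read_id, transcript, fragment start/length):")
print(bundle.origin.head(3).to_string(index=False))
# Every pair is one true fragment; the origin log is the ground truth that
# downstream quantifier benchmarking is scored against.
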