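"""How sequencing depth affects the estimate.

Downsampling only the post-treatment sample (databases at full depth) leaves
the estimate unbiased even at very shallow depth; downsampling the donor and
patient samples *before* database construction removes genome regions from
the databases and degrades the estimate — sequence the sources deeply, the
post samples can be shallow.
"""

from magtrack.simulate import SyntheticCohortParams, make_bundle, run_downsampling_experiment

bundle = make_bundle(SyntheticCohortParams(
    n_genomes=2, genome_length=25_000, read_length=100, n_reads=20_000, seed=8))

for side in ("post_only", "sources_only"):
    table = run_downsampling_experiment(
        bundle, depths=[20_000, 5_000, 1_000, 500], side=side, f=0.5, seed=8)
    print(f"\n{side}:")
    print("  depth  estimate  abs_error")
    for _, row in table.iterrows():
        print(f"{row.depth:7d}  {row.estimate:8.4f}  {row.absolute_error:9.4f}")
# post_only errors stay ~0 at all depths; sources_only errors grow sharply
# once source coverage gaps leave donor content out of the database.
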