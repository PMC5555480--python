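"""Simulate an Illumina-like paired-end library and verify its properties.

The pair count comes from the coverage formula ceil(L * C / (2 * read_len));
the placement log records every fragment's true origin, so the empirical
substitution rate and depth can be measured without any alignment step.
"""

from tebench import FixtureSpec, LibraryParams, compute_pair_count, make_toy_reference
from tebench.read_sim import empirical_error_rate, mean_depth, simulate_read_pairs

genome, *_ = make_toy_reference(FixtureSpec(chrom_len=100_000, seed=5))
genome_len = sum(len(c) for c in genome)

params = LibraryParams(read_len=101, insert_mean=300, insert_sd=42,
                       error_rate=0.01, coverage=100, seed=1)
n_pairs = compute_pair_count(genome_len, params)
print(f"{genome_len:,} bp genome at {params.coverage:.0f}x -> {n_pairs:,} read pairs")

batch = simulate_read_pairs(genome, params, n_pairs=n_pairs)
print(f"emitted {batch.total_bases:,} bases; "
      f"mean depth = {mean_depth(genome_len, batch):.2f}x (target {params.coverage:.0f}x)")
print(f"empirical substitution rate = {100 * empirical_error_rate(genome, batch):.3f}% "
      f"(configured {100 * params.error_rate:.0f}%)")
print(f"fraction of minus-strand fragments = {batch.placements.strand.mean():.3f} "
      "(expected ~0.5)")
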