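"""Positional views of caller behaviour: metaplots, TSD lengths, tRNA regions.

A TSD-anchored metaplot shows mean prediction coverage by distance from the
true insertion point (1.0 at the TSD = perfect in every sample). The TSD
length histogram exposes systematic over/under-calling of the duplication.
The tRNA-region table counts calls within 1000 bp upstream / 500 bp
downstream of tRNA starts, next to the closed-form random expectation.
"""

import numpy as np

from tebench import (
    FixtureSpec,
    MockCallerProfile,
    expected_random_proportion,
    generate_truth_set,
    make_mock_predictions,
    make_toy_reference,
    trna_region_table,
    tsd_length_histogram,
    tsd_profile,
)

genome, trnas, library, _, _ = make_toy_reference(
    FixtureSpec(chrom_len=400_000, n_trna=20, n_reference_copies=0, seed=11)
)
chrom_lengths = {c.name: len(c) for c in genome}
truths = generate_truth_set(chrom_lengths, trnas, list(library))

# a TEMP-like caller: exact positions but over-calls the TSD by 3 bp
caller = MockCallerProfile(method="overcaller", tsd_bias=3)
preds = make_mock_predictions(truths, caller, seed=9)
flat = [p for v in preds.values() for p in v]

prof = tsd_profile(preds, truths, flank=10, label="overcaller")
peak = prof.values.max()
covered = int((prof.values == peak).sum())
print(f"TSD metaplot: height {peak:.2f} over the {covered} TSD positions; the"
      " 3-bp over-call extends 3' of the TSD (halved after strand averaging)")

hist = tsd_length_histogram(flat)
for fam in sorted(hist):
    print(f"  {fam}: predicted TSD lengths {dict(hist[fam])}")

table = trna_region_table(flat, trnas)
print("\ntRNA-region enrichment (all true insertions target tRNA regions):")
print(table.to_string(index=False))

exp = expected_random_proportion(len(trnas), 1500, sum(chrom_lengths.values()))
print(f"\nexpected in-region fraction under uniform random placement: {exp:.3f}")
print("100% observed vs ~8% expected at random demonstrates tRNA targeting.")
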