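"""Score mock TE callers against insertion truth at every accuracy threshold.

Two simulated callers: a split-read-like one that hits the exact TSD with
90% sensitivity, and a read-pair-like one whose calls jitter around the true
site (sd 50 bp) and that emits one random false positive per sample. The
summary mirrors the standard per-method table: mean nonreference calls per
sample and the fraction of samples called correctly at the exact TSD and at
100/300/500-bp windows. Concordance counts how the methods' correct calls
overlap per sample (Venn regions).
"""

from tebench import (
    ConcordanceConfig,
    FixtureSpec,
    MockCallerProfile,
    concordance_sets,
    generate_truth_set,
    make_mock_predictions,
    make_toy_reference,
    score_sample_set,
)

genome, trnas, library, _, _ = make_toy_reference(
    FixtureSpec(chrom_len=400_000, n_trna=250, n_reference_copies=0, seed=11)
)
chrom_lengths = {c.name: len(c) for c in genome}
truths = generate_truth_set(chrom_lengths, trnas, list(library))
print(f"{len(truths)} single-insertion samples\n")

callers = {
    "splitread": MockCallerProfile(method="splitread", p_detect=0.9),
    "readpair": MockCallerProfile(method="readpair", p_detect=0.9,
                                  pos_error_sd=50.0, fp_rate=1.0, evidence="rp"),
}
by_method = {
    name: make_mock_predictions(truths, prof, seed=3, chrom_lengths=chrom_lengths)
    for name, prof in callers.items()
}

for name, preds in by_method.items():
    summary, _ = score_sample_set(preds, truths, method=name)
    cols = ["mean_nonreference", "correct_exact", "correct_100", "correct_300", "correct_500"]
    print(summary[cols].round(3).to_string(), "\n")

print("A correct_exact near 0.9 means the caller recovered the exact 5-bp TSD")
print("in ~90% of samples; jittered callers only catch up at wider windows.\n")

config = ConcordanceConfig({"splitread": 0, "readpair": 100})
counts = concordance_sets(by_method, truths, config)
for key in sorted(counts, key=lambda k: (len(k), sorted(k))):
    label = " + ".join(sorted(key)) if key else "neither"
    print(f"  {label:25s} {counts[key]:4d} samples")
print(f"  total {sum(counts.values())} (= sample count)")
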