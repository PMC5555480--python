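"""Build a synthetic universe and a batch of single-TE-insertion genomes.

Each sample genome carries one Ty-family element spliced in upstream of a
tRNA gene, flanked by a 5-bp target site duplication (TSD). The truth record
keeps the TSD in reference coordinates — that interval is what callers are
scored against.
"""

from tebench import FixtureSpec, generate_sample_set, make_toy_reference

spec = FixtureSpec(n_chroms=1, chrom_len=100_000, n_trna=8, n_families=4, seed=7)
genome, trnas, library, te_annotation, hierarchy = make_toy_reference(spec)
print(f"fixture: {len(genome)} chromosome(s), {len(trnas)} tRNA genes, "
      f"{len(library)} TE families, {len(te_annotation)} reference TE copies")

samples = generate_sample_set(genome, trnas, library)
print(f"{len(samples)} single-insertion samples "
      f"(= 2 orientations x {len(trnas)} tRNAs)")

modified, truth = samples[0]
te_len = len(library[truth.family])
ref_len, mod_len = len(genome[0]), len(modified[0])
print(f"\nsample {truth.sample_id}: {truth.family} on strand {truth.te_strand}, "
      f"TSD at {truth.tsd.chrom}:{truth.tsd.start}-{truth.tsd.end}")
print(f"genome grew by {mod_len - ref_len} bp = {te_len} bp TE + "
      f"{len(truth.tsd)} bp duplicated target site")

b = truth.tsd.end
print(f"flank 5' of TE: {modified[0].seq[b - 5:b]}  "
      f"flank 3' of TE: {modified[0].seq[b + te_len:b + te_len + 5]}  (identical: "
      f"{modified[0].seq[b - 5:b] == modified[0].seq[b + te_len:b + te_len + 5]})")
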