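# tebench

A benchmark toolkit for transposable-element (TE) insertion callers in
short-read resequencing data, built around the biology of the budding-yeast
Ty retrotransposons.

## The problem

Active yeast TE families (*Ty1*–*Ty4*) integrate upstream of
RNA-polymerase-III-transcribed tRNA genes and leave a 5-bp target site
duplication (TSD) — a direct repeat of host sequence flanking the new copy.
Software that detects nonreference TE insertions from whole-genome
sequencing varies enormously in positional accuracy, sensitivity and
false-positive behaviour, and each tool reports results in its own format.
Comparing them needs three things this package provides:

1. **Truth sets with realistic biology.** `genome_sim` builds one synthetic
   genome per (tRNA gene, TE orientation): the TSD window is placed at a
   family-specific upstream offset from the tRNA transcription start
   (200–195 bp for *Ty1*/*Ty2*/*Ty4*, 17–12 bp for *Ty3*, in tRNA
   orientation), and the canonical TE sequence is spliced in between two
   copies of the 5-bp target site:

   ```
   modified = ref[:b] + TE + ref[a:]        with TSD = ref[a:b), |TSD| = 5
   ```

   so the modified genome length is `L + |TE| + 5` and the element is
   flanked by identical 5-mers. `read_sim` then simulates paired-end reads
   (101-bp reads, 300 ± 42 bp inserts, 1% substitution error, 100×
   coverage by default), with the pair count from
   `n = ⌈L·C / (2·ℓ)⌉` and a placement log recording every fragment's true
   origin.

2. **A common output language.** `standardize` defines a BED6 scheme whose
   name column is `<family>_<category>_<sample>_<method>_<evidence>`
   (category `non-reference`/`reference`; evidence `sr` = split-read,
   `rp` = read-pair, `nonab` = reference TE asserted with no evidence of
   absence), plus within-method redundancy removal and partitioning of
   calls made on augmented TE "chromosomes".

3. **Evaluation the way the field reads it.** `evaluate` scores a
   prediction as correct at the *exact* threshold when it equals the true
   TSD interval, and at a window *w* when any part of it falls within *w*
   bp of the TSD (family must match; orientation never does). It also
   filters recurrent false positives (identical nonreference calls across
   multiple single-insertion samples), and counts per-sample cross-method
   concordance (Venn regions). `profiles` adds TSD-anchored and
   tRNA-anchored metaplots, TSD-length histograms, tRNA-region enrichment
   tables with the closed-form random expectation
   `n_tRNA × 1500 / L_genome`, and bedGraph export.

Everything runs on fully synthetic universes from `fixtures`
(genome + tRNA annotation + TE library + reference TE copies + hierarchy,
all from one seed), and mock callers with configurable sensitivity,
positional jitter, TSD-length bias and false-positive rate stand in for
real detectors, so the evaluation machinery is testable end to end with no
downloads.

## Worked example

```bash
python examples/simulate_insertions.py
```

prints

```
fixture: 1 chromosome(s), 8 tRNA genes, 4 TE families, 4 reference TE copies
16 single-insertion samples (= 2 orientations x 8 tRNAs)

sample tRNA-1.Ty1.plus: Ty1 on strand +, TSD at chr1:2000-2005
genome grew by 505 bp = 500 bp TE + 5 bp duplicated target site
flank 5' of TE: ATCAC  flank 3' of TE: ATCAC  (identical: True)
```

— one sample per tRNA and orientation; the insertion grew the genome by the
element plus the duplicated 5-bp target site, and the flanks on both sides
of the element are the same 5-mer (the TSD), which is exactly the interval
callers are scored against. The other examples cover read simulation
(`simulate_reads.py`), threshold scoring and concordance of two mock
callers (`evaluate_mock_callers.py`), and positional profiles
(`positional_profiles.py`).

A thin CLI mirrors the library for shell pipelines:

```bash
te-bench fixtures --out fx --seed 3
te-bench simulate-genomes --reference fx/reference.fasta \
    --trna-gff fx/trna.gff --te-library fx/te_library.fasta --out sim
te-bench simulate-reads --genome sim/tRNA-1.Ty1.plus.fasta --out-prefix reads/s1
te-bench mock-call --manifest sim/manifest.tsv --reference fx/reference.fasta \
    --out calls --p-detect 0.9
te-bench evaluate --manifest sim/manifest.tsv --predictions calls --out eval
te-bench profile  --manifest sim/manifest.tsv --predictions calls --out prof
```

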