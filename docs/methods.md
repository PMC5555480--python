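# Methods

## Insertion model

Each synthetic sample carries exactly one nonreference TE insertion,
targeted the way active yeast Ty elements target tRNA genes. For a tRNA
gene with transcription start `tss` (the first transcribed base: interval
start on the plus strand, `end − 1` on the minus strand), the 5-bp target
site duplication (TSD) occupies the bases whose upstream distance from
`tss` lies in `(d_min, d_max]`, measured in tRNA orientation:

| family class | d_max | d_min | TSD interval (plus-strand tRNA) |
|---|---|---|---|
| Ty1 / Ty2 / Ty4 | 200 | 195 | `[tss − 200, tss − 195)` |
| Ty3 | 17 | 12 | `[tss − 17, tss − 12)` |

Minus-strand tRNAs mirror this: `[tss + d_min + 1, tss + d_max + 1)`. A
described inclusive upstream range such as "200–195 bp" spans six bases;
one endpoint must be dropped to leave a 5-bp window, and we retain the
distal endpoint, so the farthest TSD base sits exactly `d_max` bp upstream.
This choice is what the upstream-offset checks measure.

The element is spliced in as `ref[:b] + TE' + ref[a:]` for TSD `[a, b)`,
where `TE'` is the canonical family sequence or its reverse complement.
The host 5-mer `ref[a:b]` therefore flanks the element on both sides — the
biological signature of a staggered-cut insertion — and the modified genome
length is `L + |TE| + 5`. TE orientation is a genome-strand property,
independent of the tRNA strand; batches are generated for both orientations
(family assignment cycles through the family list in tRNA order and
restarts for each orientation batch, so both batches place the same family
at a given tRNA). tRNAs whose TSD window would cross a contig edge are
skipped with a logged warning. Genome construction involves no randomness.

## Read simulator

A deliberately minimal paired-end model, sufficient for benchmarks whose
claims concern the *evaluation* machinery:

* pair count `n = ⌈L·C / (2·ℓ)⌉` (exact integer arithmetic when coverage is
  integral), so mean emitted depth lies in `[C, C + 2ℓ/L)`;
* chromosome chosen length-weighted; fragment start uniform; fragment
  length `round(Normal(μ=300, σ=42))` truncated to `[2ℓ, chrom length]`;
  fragments never span chromosome junctions;
* fragment strand fair-coin; read 1 is the fragment's 5′ ℓ bases, read 2
  the reverse complement of its 3′ end (ℓ = 101 by default);
* each base substituted independently with probability `e` (default 0.01)
  to a uniformly chosen different base; `N` is never substituted; no
  indels; constant quality symbol `I`;
* fully deterministic per seed (single `numpy` generator), byte-identical
  FASTQ on repeat runs.

The "±42 bp" insert parameter is interpreted as the standard deviation of
the insert-size distribution. A placement log records every pair's true
origin, so the empirical substitution rate and depth are measured directly
against the source genome with no alignment step.

## Standardized predictions

One record per call in BED6, 0-based half-open (all internal coordinates
are 0-based half-open; only the GFF reader/writer converts, `start − 1` on
input). The name column grammar is
`<family>_<category>_<sample>_<method>_<evidence>` with category literal
`non-reference` or `reference` and evidence `sr` / `rp` / `nonab`
(`nonab` is only legal on reference calls). The underscore delimiter is a
syntax choice of this package; components containing it are sanitized to
hyphens with a logged substitution, and generated sample ids use dots.
An optional single `track name="<sample>_<method>" ...` header line makes
merged files browser-loadable.

Redundancy removal operates within one method only, on the key
(chrom, start, end, family, category) — strand and evidence are excluded;
when split-read and read-pair duplicates coexist, the split-read record is
kept as the more informative class. No cross-method deduplication is ever
performed, since cross-method agreement is itself a quantity of interest.
Calls landing on augmented TE "chromosomes" are partitioned into a separate
bucket rather than silently dropped.

## Evaluation

`match_prediction` defines correctness: at the *exact* threshold the
predicted interval must equal the true TSD; at a numeric window `w` the
prediction must intersect `[tsd.start − w, tsd.end + w)` (clipped at zero)
by at least one base. The family must match (both sides resolved through
the instance→family hierarchy) for threshold scoring; orientation is never
consulted. The implementation is cross-checked in the test suite against a
brute-force per-base membership oracle on 10⁴ randomized cases.

Per-sample summary statistics report both the capped mean (fraction of
samples with ≥ 1 correct prediction, the headline `correct_<w>` columns)
and the uncapped mean match count (`matches_<w>`): with multiple
predictions near one truth the two diverge, and whether published summary
tables cap is not derivable, so both are emitted. Correctness is
non-decreasing in `w` by construction; the suite asserts this for every
mock-caller profile.

The recurrent-site filter exploits the single-insertion design: each truth
site belongs to one sample, so an identical nonreference call (same method,
interval, family) in ≥ 2 distinct samples (`min_samples` configurable) is a
systematic artifact and is removed and reported. Concordance analysis is
family- and orientation-agnostic with per-method windows (0 bp = TSD
overlap for split-read-class callers, wider for read-pair-class callers);
Venn-region counts over all method subsets, including the empty set, total
the sample count.

## Profiles

Metaplots accumulate prediction coverage around anchors, flip contributions
left-right for minus-strand anchors (tRNA mode) or minus-orientation sample
batches (TSD mode) so upstream always plots left, and divide by the number
of anchor/prediction pairs. Indicator mode caps each pair's per-position
contribution at 1 (so single-insertion profiles are bounded by 1);
multiplicity mode counts every covering prediction. Positions outside the
chromosome contribute nothing and the denominator is unchanged.

The tRNA region is the half-open window `[tss − 1000, tss + 500)` in tRNA
orientation (length exactly 1500 bp, mirrored on minus-strand genes). A
prediction overlapping any region counts once in `in_region` regardless of
how many regions it touches; totals are raw per-family counts with no
dedup, so the `total` column conserves input multiplicity. The random
expectation `n_anchors × window_len / genome_len` assumes non-overlapping
windows and is returned as a *fraction* (0.037 for 299 × 1500 bp windows in
a 12,162,995-bp genome — note that quantity is sometimes quoted with a
percent sign attached to the fraction itself); it is clamped to 1 with a
warning when windows tile more than the genome.

bedGraph is the native track export (run-length merged, zero runs included
so round trips are exact); binary bigWig conversion is left to the external
UCSC tool.

## Synthetic universes and mock callers

`make_toy_reference` generates uniform-random chromosome sequence, tRNA
genes of 72 bp with alternating strands placed ≥ 1500 bp apart and ≥ 2200
bp from contig edges (so insertion and evaluation windows never collide and
no tRNA is edge-skipped), a TE library of uniform-random 500-bp canonical
sequences, and reference TE copies planted mid-gap by overwriting genome
sequence (so extracted instances re-align exactly). With
`similar_family_pair` (default on) the first two families share identical
60-bp terminal repeats and differ internally — the LTR-sharing situation
that makes family assignment genuinely confusable. Defaults (1 chromosome,
100 kb, 8 tRNAs, 4 families) keep the full pipeline under a second; the
test suite scales to 250–299 tRNAs where sample-count or statistical
contracts require it.

What the generator deliberately does *not* emulate: real yeast base
composition and repeat structure, full-length (~6 kb) Ty elements, solo
LTRs, nested or multi-insertion genomes, chromatin-guided targeting.
Passing tests therefore demonstrate the correctness of the simulation,
standardization and evaluation machinery — not the performance of any real
caller on real data.

Mock callers consume truth manifests, not reads (read-level detection is
the job of the external tools under study; the machinery here is
caller-agnostic). Per truth they detect with probability `p_detect`
(optionally per family), shift the call by a constant directional bias plus
rounded `Normal(0, sd)` jitter, stretch or shrink the predicted TSD by
`tsd_bias` (minimum length 1), draw the called family from a confusion row,
and add `Poisson(fp_rate)` false calls at uniform random loci. Every
parameter is recoverable from the evaluation outputs, and the suite checks
recovery at 99% Monte-Carlo intervals on 500-sample batches
(`p_detect ∈ {0.3, 0.9}`, `fp_rate ∈ {0, 1}`, `tsd_bias ∈ {−2, 0, +3}`,
jitter sd ∈ {0, 50} bp).

## Numerical and degenerate-input choices

* Ceiling pair count: doubling coverage can undershoot double the pairs by
  at most one.
* Chromosomes shorter than one pair footprint are skipped with a warning;
  an all-short genome is an error.
* Duplicate-key hierarchy rows collapse when identical, error when
  conflicting; family lookup falls through to the key itself so canonical
  names resolve with or without a hierarchy.
* Window matching clips the truth window at coordinate 0; predictions are
  assumed within chromosome bounds, making right-edge clipping a no-op.
* Dedup is order-stable on first occurrence and idempotent.
* Profile anchors must share one length; mixed anchor lengths are an error
  rather than a silent resample.

## Reported problem sizes

The acceptance script uses a 100-kb fixture for read-simulator statistics
(100,000 pairs for the error-rate estimate; the formula-derived 49,505
pairs for the depth check) and a 460-kb, 299-tRNA fixture for the
batch-size count; these sizes make every check exact or place it well
inside 3 standard errors while keeping the whole script under a minute.
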