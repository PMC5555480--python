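"""Positional profiling of TE predictions.

Three views of where a caller puts its calls:

* metaplots — mean per-position prediction coverage around a set of anchors
  (the true TSDs of a simulated batch, or tRNA transcription starts),
  orientation-aware so upstream is always plotted left;
* TSD-length histograms — the distribution of predicted interval lengths
  for split-read callers, whose intervals are TSD calls;
* tRNA-region enrichment — the fraction of calls landing within 1000 bp
  upstream / 500 bp downstream of a tRNA start, against the closed-form
  expectation under uniform random placement.

Profiles export as TSV or bedGraph (for external bigWig conversion).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import logging

import numpy as np

from .formats import FeatureInterval, write_bedgraph, read_bedgraph  # noqa: F401 (re-export)
from .genome_sim import InsertionTruth, TrnaGene
from .standardize import StandardPrediction

logger = logging.getLogger(__name__)


@dataclass
class ProfileVector:
    """Mean prediction coverage by position relative to an anchor.

    offsets are oriented bp relative to the anchor start (negative =
    upstream); values are dimensionless mean coverage. In indicator mode on
    single-insertion batches a value of one at a position means every
    sample had a correct call covering it.
    """

    offsets: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tvalue\tseries\n")
            for o, v in zip(self.offsets, self.values):
                fh.write(f"{o}\t{float(v)!r}\t{self.label}\n")


def _oriented_window(anchor: FeatureInterval, flank_up: int, flank_down: int):
    """Genomic window covering flank_up upstream through flank_down
    downstream of the anchor, in anchor orientation."""
    if anchor.strand == "-":
        return anchor.start - flank_down, anchor.end + flank_up
    return anchor.start - flank_up, anchor.end + flank_down


def anchored_profile(
    pairs: Sequence[tuple[FeatureInterval, Sequence[StandardPrediction]]],
    flank_up: int,
    flank_down: int | None = None,
    mode: str = "indicator",
    negative_flip: bool = True,
    label: str = "",
    chrom_lengths: Mapping[str, int] | None = None,
) -> ProfileVector:
    """Mean prediction coverage around anchors.

    Each pair is (anchor interval, the predictions counted around it): for a
    TSD metaplot, one pair per sample (its truth TSD against its own calls);
    for a tRNA metaplot, one pair per tRNA gene against the pooled calls.
    The denominator is the number of pairs in both cases.

    mode "indicator": a position covered by >=1 prediction contributes 1 per
    pair; "multiplicity": each covering prediction contributes 1, so values
    can exceed one. Negative-strand anchors are flipped left-right (when
    negative_flip) so upstream is always at negative offsets. Positions
    outside the chromosome contribute nothing; the denominator is unchanged.
    """
    if mode not in {"indicator", "multiplicity"}:
        raise ValueError(f"invalid mode {mode!r}")
    if flank_down is None:
        flank_down = flank_up
    if not pairs:
        raise ValueError("no anchors supplied")
    anchor_lens = {len(a) for a, _ in pairs}
    if len(anchor_lens) != 1:
        raise ValueError("anchors must share one length")
    anchor_len = anchor_lens.pop()
    width = flank_up + anchor_len + flank_down

    total = np.zeros(width, dtype=float)
    for anchor, preds in pairs:
        win_start, win_end = _oriented_window(anchor, flank_up, flank_down)
        vec = np.zeros(width, dtype=float)
        for p in preds:
            iv = p.interval
            if iv.chrom != anchor.chrom:
                continue
            lo = max(iv.start, win_start)
            hi = min(iv.end, win_end)
            if chrom_lengths is not None:
                clen = chrom_lengths.get(anchor.chrom)
                if clen is not None:
                    hi = min(hi, clen)
                lo = max(lo, 0)
            if lo >= hi:
                continue
            if mode == "indicator":
                vec[lo - win_start : hi - win_start] = np.maximum(
                    vec[lo - win_start : hi - win_start], 1.0
                )
            else:
                vec[lo - win_start : hi - win_start] += 1.0
        if negative_flip and anchor.strand == "-":
            vec = vec[::-1]
        total += vec
    values = total / len(pairs)
    offsets = np.arange(-flank_up, anchor_len + flank_down)
    return ProfileVector(offsets=offsets, values=values, label=label)


def tsd_profile(
    predictions_by_sample: Mapping[str, Sequence[StandardPrediction]],
    truths: Sequence[InsertionTruth],
    flank: int,
    mode: str = "indicator",
    label: str = "",
) -> ProfileVector:
    """Metaplot centered on each sample's true TSD; minus-strand sample
    batches are mirrored so the TE's 5' side plots left."""
    pairs = []
    for t in truths:
        anchor = FeatureInterval(
            t.tsd.chrom, t.tsd.start, t.tsd.end, t.te_strand, t.sample_id
        )
        nonref = [
            p
            for p in predictions_by_sample.get(t.sample_id, [])
            if p.category == "nonreference"
        ]
        pairs.append((anchor, nonref))
    return anchored_profile(pairs, flank, flank, mode=mode, label=label)


def trna_profile(
    predictions: Sequence[StandardPrediction],
    trna_genes: Sequence[TrnaGene],
    upstream: int = 1000,
    downstream: int = 500,
    mode: str = "multiplicity",
    label: str = "",
) -> ProfileVector:
    """Metaplot of pooled predictions around tRNA transcription starts,
    orientation-aware (upstream left)."""
    pairs = []
    for g in trna_genes:
        anchor = FeatureInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.name)
        pairs.append((anchor, predictions))
    return anchored_profile(pairs, upstream, downstream - 1, mode=mode, label=label)


def tsd_length_histogram(
    predictions: Iterable[StandardPrediction],
    unique_sites_only: bool = True,
) -> dict[str, Counter]:
    """Predicted TSD-length counts per family (split-read calls: the
    interval *is* the TSD call).

    With unique_sites_only, identical (chrom, start, end, family) records
    across samples count once; calls at nearly the same locus but with a
    different length are distinct sites and count separately.
    """
    hist: dict[str, Counter] = {}
    seen: set[tuple] = set()
    for p in predictions:
        if unique_sites_only:
            key = (p.interval.chrom, p.interval.start, p.interval.end, p.family)
            if key in seen:
                continue
            seen.add(key)
        hist.setdefault(p.family, Counter())[len(p.interval)] += 1
    return hist


def trna_region(trna: TrnaGene, upstream: int = 1000, downstream: int = 500) -> FeatureInterval:
    """The [upstream, downstream) window around a tRNA transcription start,
    in genomic coordinates, mirrored for minus-strand genes. Length is
    always upstream + downstream."""
    tss = trna.tss
    if trna.strand == "+":
        return FeatureInterval(trna.chrom, tss - upstream, tss + downstream, "+", trna.name)
    return FeatureInterval(
        trna.chrom, tss - downstream + 1, tss + upstream + 1, "-", trna.name
    )


def trna_region_table(
    predictions: Sequence[StandardPrediction],
    trna_genes: Sequence[TrnaGene],
    upstream: int = 1000,
    downstream: int = 500,
):
    """Per-family counts of predictions falling in tRNA regions.

    A prediction is in-region if any part of it overlaps any tRNA window;
    it counts once regardless of how many windows it touches. Alleles
    recurring in several samples are deliberately counted independently
    (no dedup here). Returns a DataFrame (family, in_region, total, percent).
    """
    import pandas as pd

    regions = [trna_region(g, upstream, downstream) for g in trna_genes]
    rows: dict[str, list[int]] = {}
    for p in predictions:
        fam = rows.setdefault(p.family, [0, 0])
        fam[1] += 1
        if any(p.interval.overlaps(r) for r in regions):
            fam[0] += 1
    table = pd.DataFrame(
        [
            {
                "family": fam,
                "in_region": c[0],
                "total": c[1],
                "percent": 100.0 * c[0] / c[1] if c[1] else 0.0,
            }
            for fam, c in sorted(rows.items())
        ]
    )
    return table


def expected_random_proportion(n_anchors: int, window_len: int, genome_len: int) -> float:
    """Expected fraction of uniformly placed insertions landing in anchor
    windows: n_anchors * window_len / genome_len (windows assumed
    non-overlapping). Clamped to 1 with a warning if the windows tile more
    than the genome."""
    if n_anchors <= 0 or window_len <= 0 or genome_len <= 0:
        raise ValueError("all arguments must be positive")
    frac = n_anchors * window_len / genome_len
    if frac > 1:
        logger.warning("window tiling exceeds genome; clamping expectation to 1")
        return 1.0
    return frac


def profile_to_bedgraph(profile: ProfileVector, path, chrom: str | None = None) -> None:
    """Export a profile as bedGraph on a pseudo-chromosome (offsets shifted
    to start at zero), suitable for wigToBigWig conversion."""
    name = chrom or (profile.label or "profile")
    write_bedgraph({name: profile.values}, path)


def plot_profile(profile: ProfileVector, path, title: str = "") -> None:
    """Minimal matplotlib rendering of a metaplot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.offsets, profile.values, lw=1.2, label=profile.label or None)
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("mean prediction coverage")
    if title:
        ax.set_title(title)
    if profile.label:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
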