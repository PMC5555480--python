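"""Scoring of TE predictions against single-insertion truth.

A nonreference prediction is correct at the "exact" threshold when its
interval equals the true TSD exactly (and the right family is called), and
at a numeric window w when any part of it falls within w bp of the TSD —
the permissive bedtools-window definition of a true positive. Orientation
is never consulted. Per-sample correctness feeds summary tables (means
across samples, split by insertion strand), a recurrent-site filter for
batch-level false positives, and family-agnostic cross-method concordance
(Venn) counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import HierarchyMap
from .genome_sim import InsertionTruth
from .standardize import StandardPrediction

logger = logging.getLogger(__name__)

#: exact TSD, then windows of increasing permissiveness
DEFAULT_WINDOWS: tuple = ("exact", 100, 300, 500)


@dataclass(frozen=True)
class ThresholdConfig:
    windows: tuple = DEFAULT_WINDOWS
    family_required: bool = True  # concordance analysis sets this False

    def __post_init__(self) -> None:
        for w in self.windows:
            if w != "exact" and (not isinstance(w, int) or w <= 0):
                raise ValueError(f"invalid window {w!r}")


def match_prediction(
    prediction: StandardPrediction,
    truth: InsertionTruth,
    window,
    family_required: bool = True,
    hierarchy: HierarchyMap | None = None,
) -> bool:
    """Is this prediction correct for this truth at the given threshold?

    window "exact": interval equality with the TSD. Numeric w: >=1 bp
    intersection with [tsd.start - w, tsd.end + w), clipped at zero.
    Strand is never consulted. Families are resolved through the hierarchy
    (instance name -> canonical family) on both sides when given.
    """
    iv, tsd = prediction.interval, truth.tsd
    if iv.chrom != tsd.chrom:
        return False
    if family_required:
        pf, tf = prediction.family, truth.family
        if hierarchy is not None:
            pf, tf = hierarchy.family_of(pf), hierarchy.family_of(tf)
        if pf != tf:
            return False
    if window == "exact":
        return iv.start == tsd.start and iv.end == tsd.end
    lo = max(0, tsd.start - window)
    hi = tsd.end + window
    return iv.start < hi and lo < iv.end


@dataclass
class SampleScore:
    """Per-sample detail: raw counts plus match counts per window."""

    sample_id: str
    method: str
    te_strand: str
    n_reference: int
    n_nonreference: int
    matches: dict  # window -> number of matching predictions (uncapped)


def score_sample_set(
    per_sample_predictions: Mapping[str, Sequence[StandardPrediction]],
    truths: Sequence[InsertionTruth],
    thresholds: ThresholdConfig = ThresholdConfig(),
    hierarchy: HierarchyMap | None = None,
    method: str | None = None,
) -> tuple[pd.DataFrame, list[SampleScore]]:
    """Score one method's predictions over a single-insertion sample batch.

    Returns a summary DataFrame indexed by (method, te_strand) with the mean
    reference count, mean nonreference count, and — per window — the mean
    number of samples with at least one correct prediction ("correct_<w>",
    the headline, capped at one per sample) alongside the uncapped mean
    match count ("matches_<w>"); plus the per-sample detail records.

    Samples missing from per_sample_predictions count as zero predictions.
    """
    if method is None:
        methods = {p.method for v in per_sample_predictions.values() for p in v}
        if len(methods) > 1:
            raise ValueError(
                f"multiple methods in one scoring batch: {sorted(methods)}; "
                "score each method separately or pass method="
            )
        method = methods.pop() if methods else "unknown"
    details: list[SampleScore] = []
    for truth in truths:
        preds = per_sample_predictions.get(truth.sample_id, [])
        if truth.sample_id not in per_sample_predictions:
            logger.warning("no predictions for sample %s; scored as empty", truth.sample_id)
        nonref = [p for p in preds if p.category == "nonreference"]
        ref = [p for p in preds if p.category == "reference"]
        m = method
        matches = {
            w: sum(
                match_prediction(p, truth, w, thresholds.family_required, hierarchy)
                for p in nonref
            )
            for w in thresholds.windows
        }
        details.append(
            SampleScore(truth.sample_id, m, truth.te_strand, len(ref), len(nonref), matches)
        )

    rows = []
    for d in details:
        row = {
            "method": d.method,
            "te_strand": d.te_strand,
            "n_reference": d.n_reference,
            "n_nonreference": d.n_nonreference,
        }
        for w in thresholds.windows:
            row[f"correct_{w}"] = min(d.matches[w], 1)
            row[f"matches_{w}"] = d.matches[w]
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = df.groupby(["method", "te_strand"]).mean(numeric_only=True)
    summary = summary.rename(
        columns={"n_reference": "mean_reference", "n_nonreference": "mean_nonreference"}
    )
    return summary, details


def recurrent_site_filter(
    all_samples_predictions: Iterable[StandardPrediction],
    min_samples: int = 2,
) -> tuple[list[StandardPrediction], list[tuple]]:
    """Remove nonreference calls recurring across samples of a
    single-insertion batch.

    Each truth site is unique to one sample, so an identical nonreference
    call seen in >= min_samples distinct samples marks a systematic false
    positive. Grouping key: (method, chrom, start, end, family). Reference
    predictions pass through untouched.
    """
    preds = list(all_samples_predictions)
    samples_at: dict[tuple, set[str]] = {}
    for p in preds:
        if p.category != "nonreference":
            continue
        key = (p.method, p.interval.chrom, p.interval.start, p.interval.end, p.family)
        samples_at.setdefault(key, set()).add(p.sample_id)
    flagged = {k for k, s in samples_at.items() if len(s) >= min_samples}
    kept = []
    for p in preds:
        key = (p.method, p.interval.chrom, p.interval.start, p.interval.end, p.family)
        if p.category == "nonreference" and key in flagged:
            continue
        kept.append(p)
    flagged_sites = sorted(
        (k + (len(samples_at[k]),) for k in flagged), key=lambda t: t[:4]
    )
    return kept, flagged_sites


@dataclass(frozen=True)
class ConcordanceConfig:
    """Per-method correctness window for concordance analysis.

    Split-read-class methods use direct TSD overlap (0 bp); read-pair
    methods with lower positional resolution get wider windows (e.g. 100 bp
    for RetroSeq-class, 500 bp for TE-locate-class callers).
    """

    window_by_method: Mapping[str, int] = field(default_factory=dict)

    def window_for(self, method: str) -> int:
        if method not in self.window_by_method:
            raise ValueError(f"no concordance window configured for {method!r}")
        w = self.window_by_method[method]
        if w < 0:
            raise ValueError(f"negative window for {method!r}")
        return w


def concordance_sets(
    per_sample_predictions_by_method: Mapping[str, Mapping[str, Sequence[StandardPrediction]]],
    truths: Sequence[InsertionTruth],
    config: ConcordanceConfig,
) -> dict[frozenset, int]:
    """Venn-region counts: for every subset of methods, the number of samples
    in which exactly those methods called the insertion correctly.

    Correctness is family-agnostic and orientation-agnostic; window 0 means
    the prediction must overlap the TSD itself. The empty frozenset holds
    the "no method" count; all regions total the number of samples.
    """
    methods = list(per_sample_predictions_by_method)
    counts: dict[frozenset, int] = {}
    for truth in truths:
        correct = set()
        for m in methods:
            w = config.window_for(m)
            preds = per_sample_predictions_by_method[m].get(truth.sample_id, [])
            nonref = (p for p in preds if p.category == "nonreference")
            if w == 0:
                hit = any(
                    p.interval.chrom == truth.tsd.chrom
                    and p.interval.start < truth.tsd.end
                    and truth.tsd.start < p.interval.end
                    for p in nonref
                )
            else:
                hit = any(
                    match_prediction(p, truth, w, family_required=False)
                    for p in nonref
                )
            if hit:
                correct.add(m)
        key = frozenset(correct)
        counts[key] = counts.get(key, 0) + 1
    return counts


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t")


def write_detail_tsv(details: Sequence[SampleScore], path) -> None:
    rows = []
    for d in details:
        row = {
            "sample_id": d.sample_id,
            "method": d.method,
            "te_strand": d.te_strand,
            "n_reference": d.n_reference,
            "n_nonreference": d.n_nonreference,
        }
        row.update({f"matches_{w}": v for w, v in d.matches.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_venn_tsv(counts: Mapping[frozenset, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("methods\tn_samples\n")
        for key in sorted(counts, key=lambda k: (len(k), sorted(k))):
            label = "+".join(sorted(key)) if key else "(none)"
            fh.write(f"{label}\t{counts[key]}\n")
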