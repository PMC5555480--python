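"""Standardized BED6 prediction scheme and within-method postprocessing.

Every caller's output is reduced to one record per predicted TE with a
structured name column `<family>_<category>_<sample>_<method>_<evidence>`,
where category is "non-reference" or "reference" and evidence is "sr"
(split-read), "rp" (read-pair) or "nonab" (reference TE asserted present
because no evidence of absence was found). Redundancy removal happens only
within one method's results; cross-method redundancy is deliberately kept
so method concordance can be measured downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .formats import FeatureInterval, HierarchyMap

logger = logging.getLogger(__name__)

CATEGORIES = ("nonreference", "reference")
EVIDENCE_CODES = ("sr", "rp", "nonab")

_DELIM = "_"
_CATEGORY_LITERALS = {"nonreference": "non-reference", "reference": "reference"}
_CATEGORY_FROM_LITERAL = {v: k for k, v in _CATEGORY_LITERALS.items()}


@dataclass(frozen=True)
class StandardPrediction:
    """One standardized TE call."""

    interval: FeatureInterval
    family: str
    category: str  # "nonreference" | "reference"
    sample_id: str
    method: str
    evidence: str  # "sr" | "rp" | "nonab"
    score: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        if self.evidence not in EVIDENCE_CODES:
            raise ValueError(f"invalid evidence {self.evidence!r}")
        if self.evidence == "nonab" and self.category != "reference":
            raise ValueError('evidence "nonab" requires category "reference"')


def _sanitize(component: str) -> str:
    if _DELIM in component:
        clean = component.replace(_DELIM, "-")
        logger.warning("name component %r contains %r; using %r", component, _DELIM, clean)
        return clean
    return component


def make_name(family: str, category: str, sample_id: str, method: str, evidence: str) -> str:
    """Compose the BED name column. Components containing the delimiter are
    sanitized (underscore -> hyphen) with a logged substitution."""
    if category not in CATEGORIES:
        raise ValueError(f"invalid category {category!r}")
    if evidence not in EVIDENCE_CODES:
        raise ValueError(f"invalid evidence {evidence!r}")
    parts = [
        _sanitize(family),
        _CATEGORY_LITERALS[category],
        _sanitize(sample_id),
        _sanitize(method),
        evidence,
    ]
    return _DELIM.join(parts)


def parse_name(name: str) -> tuple[str, str, str, str, str]:
    """Invert make_name: -> (family, category, sample_id, method, evidence)."""
    parts = name.split(_DELIM)
    if len(parts) != 5:
        raise ValueError(f"cannot parse prediction name {name!r}: expected 5 fields")
    family, cat_literal, sample_id, method, evidence = parts
    if cat_literal not in _CATEGORY_FROM_LITERAL:
        raise ValueError(f"unknown category literal {cat_literal!r} in {name!r}")
    if evidence not in EVIDENCE_CODES:
        raise ValueError(f"unknown evidence code {evidence!r} in {name!r}")
    return family, _CATEGORY_FROM_LITERAL[cat_literal], sample_id, method, evidence


_EVIDENCE_RANK = {"sr": 0, "rp": 1, "nonab": 2}


def deduplicate_within_method(
    predictions: Sequence[StandardPrediction],
) -> list[StandardPrediction]:
    """Collapse records identical on (chrom, start, end, family, category).

    All records must share one method. Order-stable on first occurrence;
    when duplicates differ only in evidence, split-read ("sr") is kept as
    the more informative class.
    """
    methods = {p.method for p in predictions}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in one dedup batch: {sorted(methods)}")
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, p in enumerate(predictions):
        key = (p.interval.chrom, p.interval.start, p.interval.end, p.family, p.category)
        if key not in best:
            best[key] = i
            order.append(key)
        elif _EVIDENCE_RANK[p.evidence] < _EVIDENCE_RANK[predictions[best[key]].evidence]:
            best[key] = i
    return [predictions[best[k]] for k in order]


def partition_augmented(
    predictions: Iterable[StandardPrediction],
    augmented_chrom_names: set[str] | Sequence[str],
) -> tuple[list[StandardPrediction], list[StandardPrediction]]:
    """Split calls on real chromosomes from calls on the TE "chromosomes"
    added by reference augmentation (the non-ref_chromosome_results bucket)."""
    aug = set(augmented_chrom_names)
    main, on_aug = [], []
    for p in predictions:
        (on_aug if p.interval.chrom in aug else main).append(p)
    return main, on_aug


def annotate_reference_strand(
    predictions: Sequence[StandardPrediction],
    reference_annotation: Sequence[FeatureInterval],
) -> list[StandardPrediction]:
    """Fill in the strand of strand-less reference calls from the reference
    TE annotation, when an identically positioned annotated copy exists."""
    by_pos = {
        (f.chrom, f.start, f.end): f.strand
        for f in reference_annotation
        if f.strand in {"+", "-"}
    }
    out = []
    for p in predictions:
        if p.category == "reference" and p.interval.strand == ".":
            key = (p.interval.chrom, p.interval.start, p.interval.end)
            strand = by_pos.get(key)
            if strand is not None:
                out.append(replace(p, interval=replace(p.interval, strand=strand)))
                continue
            logger.debug("no positional match for reference call at %s", key)
        out.append(p)
    return out


def resolve_families(
    predictions: Sequence[StandardPrediction], hierarchy: HierarchyMap
) -> list[StandardPrediction]:
    """Map instance-named predictions to canonical families."""
    return [
        replace(p, family=hierarchy.family_of(p.family))
        if hierarchy.family_of(p.family) != p.family
        else p
        for p in predictions
    ]
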