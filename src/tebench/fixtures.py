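"""Self-contained synthetic test universes and mock callers.

Everything the benchmark needs — a genome, tRNA gene annotation, canonical
TE library, planted reference TE copies, hierarchy — is generated from a
seed, so the full pipeline runs with no downloads. Mock callers are test
doubles for real TE detectors: they read truth manifests (not reads) and
emit standardized predictions with configurable detection probability,
positional jitter, TSD-length bias, directional shift, false-positive rate
and family confusion, each emulating a behaviour class observed in real
split-read and read-pair callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats import FeatureInterval, GenomeSequence, HierarchyMap, reverse_complement
from .genome_sim import DEFAULT_OFFSET_RULES, InsertionTruth, TrnaGene
from .standardize import StandardPrediction

_TRNA_LEN = 72          # typical tRNA gene length
_LTR_LEN = 60           # shared terminal repeat for the similar family pair
_MIN_SPACING = 1500     # keeps insertion/evaluation windows disjoint
_EDGE_MARGIN = 2200     # tRNAs never close enough to an edge to be skipped


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic test universe."""

    n_chroms: int = 1
    chrom_len: int = 100_000
    n_trna: int = 8
    n_families: int = 4
    te_len: int = 500
    n_reference_copies: int = 4
    similar_family_pair: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_trna < 1 or self.n_chroms < 1:
            raise ValueError("counts must be positive")
        if self.similar_family_pair and self.n_families < 2:
            raise ValueError("similar_family_pair needs >= 2 families")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_te_library(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, str]:
    """Random canonical family sequences; optionally the first two families
    share identical terminal repeats (an LTR-like pair differing only in
    their internal region, the classic source of family confusion)."""
    families = [f"Ty{i + 1}" for i in range(spec.n_families)]
    library = {f: _random_seq(rng, spec.te_len) for f in families}
    if spec.similar_family_pair:
        ltr = _random_seq(rng, _LTR_LEN)
        for f in families[:2]:
            inner = library[f][_LTR_LEN:-_LTR_LEN]
            library[f] = ltr + inner + ltr
    return library


def make_toy_reference(
    spec: FixtureSpec,
) -> tuple[
    list[GenomeSequence],
    list[TrnaGene],
    dict[str, str],
    list[FeatureInterval],
    HierarchyMap,
]:
    """Build (genome, tRNA genes, TE library, reference TE annotation,
    hierarchy), deterministically for a fixed seed.

    tRNA loci are spaced so insertion and evaluation windows never collide;
    strands alternate. Reference TE copies are planted (sequence overwritten
    in place) in the inter-tRNA gaps, far from any insertion window, and
    annotated with instance names that the hierarchy maps to families.
    """
    rng = np.random.default_rng(spec.seed)
    library = make_te_library(spec, rng)
    families = list(library)

    # distribute tRNAs across chromosomes as evenly as possible
    per_chrom = [spec.n_trna // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_trna % spec.n_chroms):
        per_chrom[i] += 1

    genome: list[GenomeSequence] = []
    trna_genes: list[TrnaGene] = []
    te_annotation: list[FeatureInterval] = []
    hierarchy: dict[str, str] = {}
    copies_left = spec.n_reference_copies
    copy_idx = 0
    trna_idx = 0

    for ci in range(spec.n_chroms):
        name = f"chr{ci + 1}"
        seq = list(_random_seq(rng, spec.chrom_len))
        n_here = per_chrom[ci]
        usable = spec.chrom_len - 2 * _EDGE_MARGIN
        if n_here and usable < n_here * _MIN_SPACING:
            raise ValueError(
                f"infeasible packing: {n_here} tRNAs need "
                f">= {n_here * _MIN_SPACING + 2 * _EDGE_MARGIN} bp, "
                f"chrom_len is {spec.chrom_len}"
            )
        step = usable // n_here if n_here else 0
        gap_sites: list[int] = []
        for k in range(n_here):
            start = _EDGE_MARGIN + k * step
            strand = "+" if trna_idx % 2 == 0 else "-"
            trna_genes.append(
                TrnaGene(
                    FeatureInterval(
                        name, start, start + _TRNA_LEN, strand, f"tRNA-{trna_idx + 1}"
                    )
                )
            )
            # a planting site midway through this tRNA's gap, clear of the
            # upstream insertion window on either neighbour
            gap_sites.append(start + _TRNA_LEN + (step - _TRNA_LEN) // 2)
            trna_idx += 1

        # plant reference TE copies into gap midpoints
        for site in gap_sites:
            if copies_left == 0:
                break
            family = families[copy_idx % len(families)]
            te_seq = library[family]
            if site + len(te_seq) + 700 > spec.chrom_len:
                continue
            strand = "+" if copy_idx % 2 == 0 else "-"
            planted = te_seq if strand == "+" else reverse_complement(te_seq)
            seq[site : site + len(planted)] = planted
            instance = f"{family}-{copy_idx + 1}"
            te_annotation.append(
                FeatureInterval(name, site, site + len(planted), strand, instance)
            )
            hierarchy[instance] = family
            copy_idx += 1
            copies_left -= 1

        genome.append(GenomeSequence(name, "".join(seq)))

    if copies_left:
        raise ValueError(
            f"infeasible packing: {copies_left} reference TE copies did not fit"
        )
    return genome, trna_genes, library, te_annotation, HierarchyMap(hierarchy)


@dataclass(frozen=True)
class MockCallerProfile:
    """Behaviour of a simulated TE caller, scored per truth record.

    p_detect        detection probability (scalar, or per-family mapping)
    pos_error_sd    positional jitter, Normal(0, sd) rounded to bp; 0 = exact
    tsd_bias        bp added to the predicted TSD length (negative =
                    under-calls the TSD, positive = over-calls; min length 1)
    directional_shift  constant bp added to the predicted start (a 3' bias
                    when positive on the plus strand)
    fp_rate         Poisson mean of false calls per sample, uniform loci
    family_confusion  per-family row of probabilities over called families;
                    rows must sum to 1; default = always the true family
    evidence        "sr" (split-read: intervals are TSD calls) or "rp"
    """

    method: str = "mock"
    p_detect: float | Mapping[str, float] = 1.0
    pos_error_sd: float = 0.0
    tsd_bias: int = 0
    directional_shift: int = 0
    fp_rate: float = 0.0
    family_confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    evidence: str = "sr"

    def detect_p(self, family: str) -> float:
        p = self.p_detect[family] if isinstance(self.p_detect, Mapping) else self.p_detect
        if not 0 <= p <= 1:
            raise ValueError(f"p_detect out of [0,1] for {family!r}")
        return p

    def confusion_row(self, family: str) -> tuple[list[str], list[float]]:
        row = self.family_confusion.get(family)
        if row is None:
            return [family], [1.0]
        fams, probs = list(row), list(row.values())
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"confusion row for {family!r} does not sum to 1")
        return fams, probs


def make_mock_predictions(
    truths: Sequence[InsertionTruth],
    profile: MockCallerProfile,
    seed: int,
    chrom_lengths: Mapping[str, int] | None = None,
    fp_family_pool: Sequence[str] | None = None,
) -> dict[str, list[StandardPrediction]]:
    """Simulate one caller over a truth set -> per-sample predictions.

    Deterministic per seed. False positives need chrom_lengths to place
    uniform random loci (and draw their family from fp_family_pool, default:
    the families seen in truths).
    """
    rng = np.random.default_rng(seed)
    if profile.fp_rate > 0 and chrom_lengths is None:
        raise ValueError("fp_rate > 0 requires chrom_lengths")
    if fp_family_pool is None:
        fp_family_pool = sorted({t.family for t in truths})
    chroms = sorted(chrom_lengths) if chrom_lengths else []
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float) if chroms else None

    out: dict[str, list[StandardPrediction]] = {}
    for t in truths:
        preds: list[StandardPrediction] = []
        if rng.random() < profile.detect_p(t.family):
            shift = profile.directional_shift
            if profile.pos_error_sd > 0:
                shift += int(np.rint(rng.normal(0.0, profile.pos_error_sd)))
            length = max(1, len(t.tsd) + profile.tsd_bias)
            start = max(0, t.tsd.start + shift)
            fams, probs = profile.confusion_row(t.family)
            called = fams[rng.choice(len(fams), p=probs)]
            preds.append(
                StandardPrediction(
                    interval=FeatureInterval(t.tsd.chrom, start, start + length, "."),
                    family=called,
                    category="nonreference",
                    sample_id=t.sample_id,
                    method=profile.method,
                    evidence=profile.evidence,
                )
            )
        n_fp = rng.poisson(profile.fp_rate) if profile.fp_rate > 0 else 0
        for _ in range(n_fp):
            ci = rng.choice(len(chroms), p=lens / lens.sum())
            length = max(1, 5 + profile.tsd_bias)
            pos = int(rng.integers(0, chrom_lengths[chroms[ci]] - length))
            preds.append(
                StandardPrediction(
                    interval=FeatureInterval(chroms[ci], pos, pos + length, "."),
                    family=fp_family_pool[rng.integers(0, len(fp_family_pool))],
                    category="nonreference",
                    sample_id=t.sample_id,
                    method=profile.method,
                    evidence=profile.evidence,
                )
            )
        out[t.sample_id] = preds
    return out
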