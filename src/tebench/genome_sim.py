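"""Synthetic genomes carrying single TE insertions at tRNA-targeted sites.

Active yeast Ty families integrate upstream of RNA-polymerase-III-transcribed
tRNA genes and leave a 5-bp target site duplication (TSD). This module
constructs one modified genome per (tRNA, TE strand) combination: the TSD
window is placed at a family-specific upstream offset from the tRNA
transcription start (200-195 bp for Ty1/Ty2/Ty4-class elements, 17-12 bp for
Ty3-class), the canonical TE sequence is spliced in between two copies of
the TSD, and the truth record keeps the TSD interval in *reference*
coordinates so callers can be scored against it.

The module is fully deterministic: no randomness enters genome construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import cycle
from typing import Iterable, Sequence

from .formats import FeatureInterval, GenomeSequence, reverse_complement

logger = logging.getLogger(__name__)

TSD_LEN = 5  # all active S. cerevisiae TEs duplicate 5 bp on insertion


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA gene with an orientation-aware transcription start (tss)."""

    interval: FeatureInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("tRNA gene must be stranded")

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class OffsetRule:
    """Family-specific TSD placement: the TSD occupies the bases whose
    upstream distance from the tRNA tss lies in (d_min, d_max]."""

    family: str
    d_max: int
    d_min: int
    tsd_len: int = TSD_LEN

    def __post_init__(self) -> None:
        if self.tsd_len < 1:
            raise ValueError("tsd_len must be >= 1")
        if self.d_max - self.d_min != self.tsd_len:
            raise ValueError(
                f"{self.family}: d_max - d_min must equal tsd_len "
                f"({self.d_max} - {self.d_min} != {self.tsd_len})"
            )


#: Ty1/Ty2/Ty4 target the first ~200 bp upstream of tRNA genes; Ty3 targets
#: the Pol III transcription-initiation region ~17 bp upstream.
DEFAULT_OFFSET_RULES: dict[str, OffsetRule] = {
    "Ty1": OffsetRule("Ty1", d_max=200, d_min=195),
    "Ty2": OffsetRule("Ty2", d_max=200, d_min=195),
    "Ty3": OffsetRule("Ty3", d_max=17, d_min=12),
    "Ty4": OffsetRule("Ty4", d_max=200, d_min=195),
}


@dataclass(frozen=True)
class InsertionTruth:
    """One synthetic insertion, with the TSD in reference coordinates."""

    sample_id: str
    family: str
    te_strand: str  # genome strand of the inserted TE, independent of tRNA strand
    tsd: FeatureInterval
    trna_name: str


def tsd_interval_for(trna: TrnaGene, rule: OffsetRule) -> FeatureInterval:
    """TSD window at upstream distances (d_min, d_max] in tRNA orientation.

    Plus-strand tRNA: upstream is leftward, [tss - d_max, tss - d_min).
    Minus-strand tRNA: upstream is rightward, [tss + d_min + 1, tss + d_max + 1).
    """
    tss = trna.tss
    if trna.strand == "+":
        start, end = tss - rule.d_max, tss - rule.d_min
    else:
        start, end = tss + rule.d_min + 1, tss + rule.d_max + 1
    return FeatureInterval(trna.chrom, start, end, ".", trna.name)


def plan_insertion_sites(
    trna_genes: Sequence[TrnaGene],
    families_cycle: Sequence[str],
    offset_rules: dict[str, OffsetRule] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[tuple[TrnaGene, str, FeatureInterval]]:
    """Assign one family per tRNA by cycling through families in tRNA order,
    and compute each TSD window.

    tRNAs whose window would cross a chromosome edge are skipped with a
    warning (requires chrom_lengths to check the right edge).
    """
    rules = offset_rules if offset_rules is not None else DEFAULT_OFFSET_RULES
    missing = [f for f in families_cycle if f not in rules]
    if missing:
        raise ValueError(f"no offset rule for families: {missing}")
    plan: list[tuple[TrnaGene, str, FeatureInterval]] = []
    fam_iter = cycle(families_cycle)
    for trna in trna_genes:
        family = next(fam_iter)
        rule = rules[family]
        tss = trna.tss
        if trna.strand == "+":
            start, end = tss - rule.d_max, tss - rule.d_min
        else:
            start, end = tss + rule.d_min + 1, tss + rule.d_max + 1
        if start < 0 or (
            chrom_lengths is not None and end > chrom_lengths.get(trna.chrom, end)
        ):
            logger.warning(
                "skipping tRNA %s: TSD window [%d,%d) crosses a chromosome edge",
                trna.name, start, end,
            )
            continue
        plan.append((trna, family, tsd_interval_for(trna, rule)))
    return plan


def make_single_insertion_genome(
    reference: Sequence[GenomeSequence],
    plan_entry: tuple[TrnaGene, str, FeatureInterval],
    canonical_te_seq: str,
    te_strand: str,
    sample_id: str | None = None,
) -> tuple[list[GenomeSequence], InsertionTruth]:
    """Splice one TE into the reference, duplicating the TSD.

    With TSD [a, b) on chromosome c, the modified chromosome is
    ``ref[:b] + TE' + ref[a:]`` where TE' is the canonical sequence
    (te_strand "+") or its reverse complement (te_strand "-"). The 5-bp
    host sequence ref[a:b] therefore flanks the element on both sides.
    """
    if te_strand not in {"+", "-"}:
        raise ValueError(f"invalid te_strand {te_strand!r}")
    if not canonical_te_seq:
        raise ValueError("canonical TE sequence is empty")
    trna, family, tsd = plan_entry
    te = canonical_te_seq.upper()
    if te_strand == "-":
        te = reverse_complement(te)
    out: list[GenomeSequence] = []
    found = False
    for chrom in reference:
        if chrom.name != tsd.chrom:
            out.append(chrom)
            continue
        if tsd.end > len(chrom.seq):
            raise ValueError(
                f"TSD interval [{tsd.start},{tsd.end}) out of bounds on "
                f"{chrom.name} (len {len(chrom.seq)})"
            )
        modified = chrom.seq[: tsd.end] + te + chrom.seq[tsd.start:]
        out.append(GenomeSequence(chrom.name, modified))
        found = True
    if not found:
        raise ValueError(f"chromosome {tsd.chrom!r} not in reference")
    if sample_id is None:
        sample_id = f"{trna.name}.{family}.{'plus' if te_strand == '+' else 'minus'}"
    truth = InsertionTruth(
        sample_id=sample_id,
        family=family,
        te_strand=te_strand,
        tsd=tsd,
        trna_name=trna.name,
    )
    return out, truth


def generate_sample_set(
    reference: Sequence[GenomeSequence],
    trna_genes: Sequence[TrnaGene],
    canonical_tes: dict[str, str],
    offset_rules: dict[str, OffsetRule] | None = None,
    families_cycle: Sequence[str] | None = None,
) -> list[tuple[list[GenomeSequence], InsertionTruth]]:
    """One single-insertion sample per (tRNA, TE genome strand).

    Family alternation restarts for each strand batch, so the plus- and
    minus-strand batches place the same family at the same tRNA. With n
    usable tRNAs this yields 2n samples.
    """
    if not trna_genes:
        raise ValueError("no tRNA genes supplied")
    if families_cycle is None:
        families_cycle = list(canonical_tes)
    chrom_lengths = {c.name: len(c.seq) for c in reference}
    plan = plan_insertion_sites(
        trna_genes, families_cycle, offset_rules, chrom_lengths
    )
    samples = []
    for te_strand in ("+", "-"):
        for entry in plan:
            _trna, family, _tsd = entry
            samples.append(
                make_single_insertion_genome(
                    reference, entry, canonical_tes[family], te_strand
                )
            )
    return samples


def generate_truth_set(
    chrom_lengths: dict[str, int],
    trna_genes: Sequence[TrnaGene],
    families_cycle: Sequence[str],
    offset_rules: dict[str, OffsetRule] | None = None,
) -> list[InsertionTruth]:
    """The truth records of generate_sample_set without constructing the
    modified genome sequences — for scoring pipelines that only need the
    TSD coordinates (mock callers, profile oracles)."""
    plan = plan_insertion_sites(trna_genes, families_cycle, offset_rules, chrom_lengths)
    truths = []
    for te_strand in ("+", "-"):
        for trna, family, tsd in plan:
            sid = f"{trna.name}.{family}.{'plus' if te_strand == '+' else 'minus'}"
            truths.append(
                InsertionTruth(
                    sample_id=sid,
                    family=family,
                    te_strand=te_strand,
                    tsd=tsd,
                    trna_name=trna.name,
                )
            )
    return truths


def extract_te_instances(
    reference: Sequence[GenomeSequence],
    te_annotation: Iterable[FeatureInterval],
) -> list[GenomeSequence]:
    """Pull annotated reference TE copies out of the genome sequence.

    Minus-strand instances are reverse-complemented so every returned
    sequence reads in element orientation.
    """
    by_name = {c.name: c for c in reference}
    out = []
    for feat in te_annotation:
        chrom = by_name.get(feat.chrom)
        if chrom is None:
            raise ValueError(f"unknown chromosome {feat.chrom!r}")
        if feat.end > len(chrom.seq):
            raise ValueError(
                f"annotation {feat.name!r} out of bounds on {feat.chrom}"
            )
        seq = chrom.seq[feat.start : feat.end]
        if feat.strand == "-":
            seq = reverse_complement(seq)
        out.append(GenomeSequence(feat.name or f"{feat.chrom}:{feat.start}-{feat.end}", seq))
    return out


def augment_reference(
    reference: Sequence[GenomeSequence],
    canonical_tes: dict[str, str] | None = None,
    reference_te_instances: Sequence[GenomeSequence] | None = None,
    mode: str = "canonical",
) -> tuple[list[GenomeSequence], list[FeatureInterval]]:
    """Append TE sequences as extra "chromosomes" plus a matching annotation.

    mode selects canonical family sequences, extracted reference instances,
    or both. Each added chromosome gets an annotation record spanning it
    entirely, for appending to the reference TE annotation. Name collisions
    with existing chromosomes are disambiguated with a numeric suffix.
    """
    if mode not in {"canonical", "extracted", "both"}:
        raise ValueError(f"invalid mode {mode!r}")
    additions: list[GenomeSequence] = []
    if mode in ("canonical", "both"):
        if canonical_tes is None:
            raise ValueError("mode requires canonical_tes")
        additions.extend(GenomeSequence(n, s) for n, s in canonical_tes.items())
    if mode in ("extracted", "both"):
        if reference_te_instances is None:
            raise ValueError("mode requires reference_te_instances")
        additions.extend(reference_te_instances)

    taken = {c.name for c in reference}
    genome = list(reference)
    annotation: list[FeatureInterval] = []
    for add in additions:
        name = add.name
        if name in taken:
            i = 2
            while f"{name}_{i}" in taken:
                i += 1
            logger.warning("chromosome name collision: %r renamed %r", name, f"{name}_{i}")
            name = f"{name}_{i}"
        taken.add(name)
        genome.append(GenomeSequence(name, add.seq))
        annotation.append(FeatureInterval(name, 0, len(add.seq), "+", name))
    return genome, annotation


# ---------------------------------------------------------------------------
# Manifests

def write_truth_manifest(truths: Iterable[InsertionTruth], path) -> None:
    """Truth manifest as BED6: TSD interval, family in the name column,
    strand column carrying the TE genome strand."""
    with open(path, "w") as fh:
        for t in sorted(truths, key=lambda t: (t.tsd.chrom, t.tsd.start, t.sample_id)):
            fh.write(
                f"{t.tsd.chrom}\t{t.tsd.start}\t{t.tsd.end}"
                f"\t{t.family}_{t.sample_id}\t0\t{t.te_strand}\n"
            )


def write_run_manifest(truths: Iterable[InsertionTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttrna\tfamily\tte_strand\tchrom\ttsd_start\ttsd_end\n")
        for t in truths:
            fh.write(
                f"{t.sample_id}\t{t.trna_name}\t{t.family}\t{t.te_strand}"
                f"\t{t.tsd.chrom}\t{t.tsd.start}\t{t.tsd.end}\n"
            )
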