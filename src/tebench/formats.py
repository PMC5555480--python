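"""File-format I/O and coordinate conventions.

All coordinates are 0-based half-open internally; conversion to and from
1-based (GFF) or 0-based (BED) conventions happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.name!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic interval, 0-based half-open, with strand and a name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) for {self.name!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "FeatureInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class HierarchyMap:
    """Mapping from reference TE instance names to canonical family names.

    Lookup falls through to the key itself, so canonical family names
    resolve to themselves whether or not they appear as instances.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def family_of(self, name: str) -> str:
        return self.mapping.get(name, name)

    @property
    def families(self) -> set[str]:
        return set(self.mapping.values())

    def __contains__(self, name: str) -> bool:
        return name in self.mapping


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file; sequences are uppercased.

    Record order is preserved. Raises FormatError on empty records or
    duplicate names.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty FASTA record {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(GenomeSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[GenomeSequence], path: str | Path, line_width: int = 70
) -> None:
    """Write records as wrapped FASTA. Deterministic byte output."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF (1-based, inclusive) -> internal 0-based half-open

def _gff_feature_name(attributes: str) -> str:
    """Extract ID or Name from a GFF attribute column (first match).

    Handles both GFF3 `key=value;` and GTF-like `key "value";` styles.
    """
    for part in attributes.replace('"', "").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
        else:
            key, _, value = part.partition(" ")
        if key.strip() in ("ID", "Name"):
            return value.strip()
    return ""


def read_gff_features(
    path: str | Path, feature_filter: str | None = None
) -> list[FeatureInterval]:
    """Read GFF features, converting 1-based inclusive to 0-based half-open.

    feature_filter restricts to rows whose type column (column 3) matches.
    """
    features: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}:{lineno}: expected >=8 GFF columns")
            chrom, _source, ftype, start_s, end_s, _score, strand = cols[:7]
            if feature_filter is not None and ftype != feature_filter:
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )
            name = _gff_feature_name(cols[8]) if len(cols) > 8 else ""
            features.append(
                FeatureInterval(chrom, start - 1, end, strand, name)
            )
    return features


def write_gff_features(
    features: Iterable[FeatureInterval],
    path: str | Path,
    source: str = "tebench",
    feature_type: str = "feature",
) -> None:
    """Write features as 1-based inclusive GFF rows."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f"ID={f.name}" if f.name else "."
            fh.write(
                f"{f.chrom}\t{source}\t{feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Hierarchy TSV

def read_hierarchy(path: str | Path) -> HierarchyMap:
    """Read the two-column instance -> family hierarchy file.

    Duplicate identical rows collapse; conflicting duplicates are an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-delimited columns, got {len(cols)}"
                )
            instance, family = cols
            if not instance or not family:
                raise FormatError(f"{path}:{lineno}: empty field")
            if instance in mapping and mapping[instance] != family:
                raise FormatError(
                    f"{path}:{lineno}: instance {instance!r} maps to both "
                    f"{mapping[instance]!r} and {family!r}"
                )
            mapping[instance] = family
    return HierarchyMap(mapping)


def write_hierarchy(hierarchy: HierarchyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for instance, family in hierarchy.mapping.items():
            fh.write(f"{instance}\t{family}\n")


# ---------------------------------------------------------------------------
# Standardized BED6

def write_standard_bed(
    predictions,
    path: str | Path,
    sample: str | None = None,
    method: str | None = None,
    with_header: bool = False,
) -> None:
    """Write standardized predictions as 0-based half-open BED6.

    Records are sorted by (chrom, start, end). The optional single track
    header carries the sample and method so genome browsers can label
    merged result files.
    """
    from .standardize import make_name  # local import: avoid cycle

    preds = sorted(
        predictions, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        if with_header:
            sample = sample if sample is not None else (
                preds[0].sample_id if preds else "sample"
            )
            method = method if method is not None else (
                preds[0].method if preds else "method"
            )
            fh.write(
                f'track name="{sample}_{method}" description="{sample} {method}"\n'
            )
        for p in preds:
            name = make_name(
                p.family, p.category, p.sample_id, p.method, p.evidence
            )
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{name}\t{p.score}\t{p.interval.strand}\n"
            )


def read_standard_bed(path: str | Path):
    """Read a standardized BED6 file back into StandardPrediction records.

    A leading `track` header line is skipped if present.
    """
    from .standardize import StandardPrediction, parse_name

    predictions = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            if idx == 0 and line.startswith("track"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}: record {idx}: expected 6 BED columns")
            chrom, start_s, end_s, name, score_s, strand = cols
            try:
                family, category, sample_id, method, evidence = parse_name(name)
            except ValueError as exc:
                raise FormatError(f"{path}: record {idx}: {exc}") from exc
            predictions.append(
                StandardPrediction(
                    interval=FeatureInterval(
                        chrom, int(start_s), int(end_s), strand
                    ),
                    family=family,
                    category=category,
                    sample_id=sample_id,
                    method=method,
                    evidence=evidence,
                    score=int(score_s),
                )
            )
    return predictions


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(coverage: dict[str, "object"], path: str | Path) -> None:
    """Write per-chromosome value vectors as bedGraph, merging equal runs.

    Zero-valued runs are written too, so a round-trip reconstructs the
    full vector. Values are written as repr'd floats (ints stay short).
    """
    import numpy as np

    with open(path, "w") as fh:
        for chrom, values in coverage.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or len(arr) == 0:
                raise ValueError(f"coverage for {chrom!r} must be a nonempty vector")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"coverage for {chrom!r} contains non-finite values")
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = float(arr[s])
                v_str = f"{int(v)}" if v == int(v) else repr(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{v_str}\n")


def read_bedgraph(path: str | Path) -> dict[str, "object"]:
    """Read a bedGraph file back into dense per-chromosome vectors."""
    import numpy as np

    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            spans.setdefault(chrom, []).append((int(s), int(e), float(v)))
    out = {}
    for chrom, runs in spans.items():
        length = max(e for _, e, _ in runs)
        arr = np.zeros(length, dtype=float)
        for s, e, v in runs:
            arr[s:e] = v
        out[chrom] = arr
    return out
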