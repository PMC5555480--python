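"""Paired-end short-read simulation (a wgsim-equivalent for this benchmark).

Fragments are placed uniformly over the genome (chromosomes chosen
length-weighted), fragment length is Normal(insert_mean, insert_sd) rounded
and truncated, and each read base is substituted independently with the
given error probability. Only substitutions are modelled; qualities are a
constant symbol. Every pair's true origin is recorded in a placement log so
empirical error and depth can be measured without alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import GenomeSequence

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_QUAL = "I"  # constant Phred symbol


@dataclass(frozen=True)
class LibraryParams:
    """Sequencing-library parameters.

    Defaults mirror a typical Illumina resequencing design: 101-bp reads,
    300-bp inserts with 42-bp standard deviation, 1% per-base substitution
    error, 100-fold target coverage.
    """

    read_len: int = 101
    insert_mean: int = 300
    insert_sd: float = 42.0
    error_rate: float = 0.01
    coverage: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class PlacementLog:
    """True origin of every simulated pair (parallel arrays)."""

    chrom: np.ndarray      # chromosome index into `chrom_names`
    start: np.ndarray      # fragment start, 0-based
    frag_len: np.ndarray
    strand: np.ndarray     # True = fragment taken from the minus strand
    chrom_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.start)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pair\tchrom\tfrag_start\tfrag_end\tstrand\n")
            for i in range(len(self)):
                fh.write(
                    f"{i}\t{self.chrom_names[self.chrom[i]]}\t{self.start[i]}"
                    f"\t{self.start[i] + self.frag_len[i]}"
                    f"\t{'-' if self.strand[i] else '+'}\n"
                )


@dataclass
class ReadPairBatch:
    """Simulated read pairs as uint8 base matrices plus their placement log.

    reads1/reads2 are (n_pairs, read_len) arrays of ASCII base codes.
    """

    reads1: np.ndarray
    reads2: np.ndarray
    placements: PlacementLog
    read_len: int

    @property
    def n_pairs(self) -> int:
        return self.reads1.shape[0]

    @property
    def total_bases(self) -> int:
        return self.reads1.size + self.reads2.size

    def read_name(self, i: int) -> str:
        p = self.placements
        strand = "-" if p.strand[i] else "+"
        return f"sim_{p.chrom_names[p.chrom[i]]}_{p.start[i]}_{strand}_{i}"

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        qual = _QUAL * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                name = self.read_name(i)
                f1.write(
                    f"@{name}/1\n{self.reads1[i].tobytes().decode()}\n+\n{qual}\n"
                )
                f2.write(
                    f"@{name}/2\n{self.reads2[i].tobytes().decode()}\n+\n{qual}\n"
                )


def compute_pair_count(genome_len: int, params: LibraryParams) -> int:
    """Pairs needed for the target mean depth: ceil(L * cov / (2 * read_len))."""
    if genome_len < 2 * params.read_len:
        raise ValueError("genome shorter than one read-pair footprint")
    cov = params.coverage
    if float(cov).is_integer():
        # exact integer ceiling division, immune to float rounding
        num = genome_len * int(cov)
        return -(-num // (2 * params.read_len))
    import math

    return math.ceil(genome_len * cov / (2 * params.read_len))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[a] = b


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[mat[:, ::-1]]


def _inject_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability error_rate,
    choosing uniformly among the three other {A,C,G,T} bases. N is left as N."""
    if error_rate == 0:
        return mat
    # map ASCII -> 0..3 (A,C,G,T); anything else (N) -> 4
    code = np.full(256, 4, dtype=np.uint8)
    for k, b in enumerate(b"ACGT"):
        code[b] = k
    c = code[mat]
    hit = rng.random(mat.shape) < error_rate
    hit &= c < 4
    offsets = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    new_c = (c + offsets) % 4
    out = mat.copy()
    out[hit] = _BASES[new_c[hit]]
    return out


def simulate_read_pairs(
    genome: Sequence[GenomeSequence],
    params: LibraryParams,
    n_pairs: int | None = None,
) -> ReadPairBatch:
    """Simulate paired-end reads; deterministic for a given seed.

    Read 1 is the 5' read_len bases of the fragment; read 2 is the reverse
    complement of its 3' end. Fragment strand is chosen fairly, so read
    orientation is symmetric. Fragments never span chromosome junctions;
    fragment lengths are truncated to [2*read_len, chromosome length].
    """
    rl = params.read_len
    usable = [c for c in genome if len(c.seq) >= 2 * rl]
    for c in genome:
        if len(c.seq) < 2 * rl:
            logger.warning("chromosome %s shorter than a pair footprint; skipped", c.name)
    if not usable:
        raise ValueError("no chromosome long enough for a read pair")

    lengths = np.array([len(c.seq) for c in usable], dtype=np.int64)
    genome_len = int(lengths.sum())
    if n_pairs is None:
        n_pairs = compute_pair_count(genome_len, params)

    rng = np.random.default_rng(params.seed)

    chrom_idx = rng.choice(len(usable), size=n_pairs, p=lengths / genome_len)
    frag_len = np.rint(
        rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)
    ).astype(np.int64)
    frag_len = np.maximum(frag_len, 2 * rl)
    frag_len = np.minimum(frag_len, lengths[chrom_idx])
    max_start = lengths[chrom_idx] - frag_len
    starts = (rng.random(n_pairs) * (max_start + 1)).astype(np.int64)
    minus = rng.random(n_pairs) < 0.5

    encoded = [_encode(c.seq) for c in usable]
    offs = np.arange(rl)
    left = np.empty((n_pairs, rl), dtype=np.uint8)
    right = np.empty((n_pairs, rl), dtype=np.uint8)
    for ci, arr in enumerate(encoded):
        sel = chrom_idx == ci
        if not sel.any():
            continue
        s = starts[sel]
        f = frag_len[sel]
        left[sel] = arr[s[:, None] + offs]
        right[sel] = arr[(s + f - rl)[:, None] + offs]

    # plus-strand fragment: read1 = left fwd, read2 = revcomp(right)
    # minus-strand fragment: read1 = revcomp(right), read2 = left fwd
    reads1 = np.where(minus[:, None], _revcomp_rows(right), left)
    reads2 = np.where(minus[:, None], left, _revcomp_rows(right))

    reads1 = _inject_errors(reads1, params.error_rate, rng)
    reads2 = _inject_errors(reads2, params.error_rate, rng)

    placements = PlacementLog(
        chrom=chrom_idx,
        start=starts,
        frag_len=frag_len,
        strand=minus,
        chrom_names=[c.name for c in usable],
    )
    return ReadPairBatch(reads1=reads1, reads2=reads2, placements=placements, read_len=rl)


def empirical_error_rate(genome: Sequence[GenomeSequence], batch: ReadPairBatch) -> float:
    """Fraction of read bases differing from their true source base,
    recomputed from the placement log (no alignment needed)."""
    by_name = {c.name: _encode(c.seq) for c in genome}
    rl = batch.read_len
    offs = np.arange(rl)
    p = batch.placements
    mismatches = 0
    for ci, name in enumerate(p.chrom_names):
        arr = by_name[name]
        sel = p.chrom == ci
        if not sel.any():
            continue
        s = p.start[sel]
        f = p.frag_len[sel]
        minus = p.strand[sel]
        left = arr[s[:, None] + offs]
        right = arr[(s + f - rl)[:, None] + offs]
        true1 = np.where(minus[:, None], _revcomp_rows(right), left)
        true2 = np.where(minus[:, None], left, _revcomp_rows(right))
        mismatches += int((batch.reads1[sel] != true1).sum())
        mismatches += int((batch.reads2[sel] != true2).sum())
    return mismatches / batch.total_bases


def mean_depth(genome_len: int, batch: ReadPairBatch) -> float:
    """Total emitted read bases divided by genome length."""
    return batch.total_bases / genome_len
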