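"""Genomic intervals, sequence extraction, controls and cluster partitioning.

Binding clusters arrive as BED intervals on a reference genome; the models
downstream consume RNA sequences.  This module bridges the two: it reads and
writes BED/FASTA, pulls out stranded RNA sequences, samples length-matched
negative controls from 3'UTR transcripts, and partitions two cluster sets
(e.g. HuR vs TTP) into exclusive and common subsets.

Coordinates are BED-style throughout: 0-based, half-open, stranded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "TranscriptAnnotation",
    "PartitionResult",
    "LengthSummary",
    "BedParseError",
    "SequenceExtractionError",
    "ControlGenerationError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "extract_sequences",
    "generate_controls",
    "partition_clusters",
    "summarize_lengths",
    "read_labeled_fasta",
    "write_labeled_fasta",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class BedParseError(ValueError):
    """A BED line could not be parsed into a valid interval."""


class SequenceExtractionError(KeyError):
    """An interval refers to a missing chromosome or lies out of range."""


class ControlGenerationError(ValueError):
    """No eligible transcript can host a length-matched control."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic region in 0-based half-open (BED) coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """>=1 bp overlap on the same chromosome (and strand if ``stranded``)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class SequenceRecord:
    """An RNA sequence with identifier, class label and optional domain tag.

    ``label`` is ``"positive"`` or ``"negative"``; ``domain`` is ``"HuR"``,
    ``"TTP"`` or ``None`` (used by the feature-augmentation machinery).
    """

    id: str
    seq: str
    label: str = "positive"
    domain: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"record {self.id!r}: bad label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptAnnotation:
    """A set of 3'UTR transcript intervals, indexed by identifier."""

    intervals: list[GenomicInterval]
    index: dict[str, GenomicInterval] = field(init=False)

    def __post_init__(self):
        self.index = {}
        for iv in self.intervals:
            if iv.name in self.index:
                raise ValueError(f"duplicate transcript identifier {iv.name!r}")
            self.index[iv.name] = iv

    @classmethod
    def from_bed(cls, path) -> "TranscriptAnnotation":
        return cls(read_bed(path))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class PartitionResult:
    """Clusters split into A-only, B-only and common (overlapping) subsets."""

    a_only: list[GenomicInterval]
    b_only: list[GenomicInterval]
    common: list[GenomicInterval]


class LengthSummary(tuple):
    """(count, min, mean, max) of sequence lengths; mean rounded to integer."""

    def __new__(cls, count, min_, mean, max_):
        return super().__new__(cls, (count, min_, mean, max_))

    count = property(lambda self: self[0])
    min = property(lambda self: self[1])
    mean = property(lambda self: self[2])
    max = property(lambda self: self[3])


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into a list of intervals.

    A missing strand column defaults to "+"; a missing name column is
    auto-generated as ``chrom:start-end``.  Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}, line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals, path) -> None:
    """Write intervals as 6-column BED (score column fixed to 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{name: uppercase sequence}``.

    Headers are truncated at the first whitespace.  Duplicate headers and
    empty files are errors.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_sequences(
    genome: dict[str, str],
    intervals,
    label: str = "positive",
    domain: str | None = None,
) -> list[SequenceRecord]:
    """Extract stranded RNA sequences for intervals from a genome mapping.

    Minus-strand intervals are reverse-complemented before the DNA T -> RNA U
    mapping.  The record id is the interval name.
    """
    records = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise SequenceExtractionError(
                f"interval {iv.name}: chromosome {iv.chrom!r} not in genome"
            )
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise SequenceExtractionError(
                f"interval {iv.name}: [{iv.start},{iv.end}) exceeds "
                f"{iv.chrom} length {len(chrom_seq)}"
            )
        seq = chrom_seq[iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        records.append(SequenceRecord(iv.name, _to_rna(seq), label, domain))
    return records


def _interval_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def generate_controls(
    positives,
    annotation: TranscriptAnnotation,
    genome: dict[str, str],
    seed: int,
    label: str = "negative",
    domain: str | None = None,
) -> list[SequenceRecord]:
    """Sample one length-matched negative per positive from 3'UTR transcripts.

    For each positive, a transcript is chosen uniformly at random among those
    long enough and free of overlap with any positive cluster, then a start
    position uniformly among valid placements.  Deterministic given ``seed``.

    ``positives`` may be :class:`GenomicInterval` objects (their coordinates
    then exclude overlapping transcripts) or :class:`SequenceRecord` objects
    (only their lengths are used; the annotation is assumed disjoint from the
    positive set).
    """
    pos_intervals = [p for p in positives if isinstance(p, GenomicInterval)]
    lengths = [p.length if isinstance(p, GenomicInterval) else len(p) for p in positives]
    pos_trees = _interval_trees(pos_intervals)

    def clean(tx: GenomicInterval) -> bool:
        tree = pos_trees.get(tx.chrom)
        return tree is None or not tree.overlap(tx.start, tx.end)

    eligible = [tx for tx in annotation.intervals if clean(tx)]
    eligible_lengths = np.array([tx.length for tx in eligible])

    rng = np.random.default_rng(seed)
    controls = []
    for i, length in enumerate(lengths):
        ok = np.flatnonzero(eligible_lengths >= length)
        if ok.size == 0:
            raise ControlGenerationError(
                f"no positive-free transcript of length >= {length} "
                f"available for control {i}"
            )
        tx = eligible[int(rng.choice(ok))]
        offset = int(rng.integers(0, tx.length - length + 1))
        iv = GenomicInterval(
            tx.chrom, tx.start + offset, tx.start + offset + length,
            f"ctrl_{i}", tx.strand,
        )
        rec = extract_sequences(genome, [iv], label=label, domain=domain)[0]
        controls.append(rec)
    return controls


def partition_clusters(set_a, set_b, stranded: bool = True) -> PartitionResult:
    """Partition two cluster sets into A-only, B-only and common subsets.

    A cluster of A overlapping (>=1 bp, same chromosome and strand) any
    cluster of B is assigned to ``common``, represented by the A interval;
    the overlapping B clusters are consumed.  The remainders populate
    ``a_only`` and ``b_only``.
    """
    b_trees = _interval_trees(set_b)
    consumed: set[int] = set()
    a_only, common = [], []
    for a in set_a:
        tree = b_trees.get(a.chrom)
        hits = []
        if tree is not None:
            for hit in tree.overlap(a.start, a.end):
                b = hit.data
                if stranded and b.strand != a.strand:
                    continue
                hits.append(b)
        if hits:
            common.append(a)
            consumed.update(id(b) for b in hits)
        else:
            a_only.append(a)
    b_only = [b for b in set_b if id(b) not in consumed]
    return PartitionResult(a_only=a_only, b_only=b_only, common=common)


def summarize_lengths(records) -> LengthSummary:
    """Count / min / integer-rounded mean / max of record lengths."""
    lengths = [len(r) for r in records]
    if not lengths:
        raise ValueError("cannot summarize an empty record list")
    mean = int(np.floor(sum(lengths) / len(lengths) + 0.5))
    return LengthSummary(len(lengths), min(lengths), mean, max(lengths))


_HEADER_RE = re.compile(r"\|label=(positive|negative)(?:\|domain=(\w+))?")


def write_labeled_fasta(records, path) -> None:
    """Serialize labeled records as FASTA: ``>id|label=positive|domain=HuR``."""
    with open(path, "w") as fh:
        for rec in records:
            domain = rec.domain if rec.domain is not None else "none"
            fh.write(f">{rec.id}|label={rec.label}|domain={domain}\n{rec.seq}\n")


def read_labeled_fasta(path) -> list[SequenceRecord]:
    """Read FASTA written by :func:`write_labeled_fasta`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        m = _HEADER_RE.search(header)
        if m is None:
            raise ValueError(f"header {header!r} lacks a |label=... field")
        domain = m.group(2)
        if domain in (None, "none"):
            domain = None
        rec_id = header.split("|", 1)[0]
        records.append(
            SequenceRecord(rec_id, _to_rna(str(rec.seq)), m.group(1), domain)
        )
    if not records:
        raise ValueError(f"no records found in {path}")
    return records
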