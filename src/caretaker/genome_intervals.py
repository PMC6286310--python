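"""Genomic interval arithmetic, sequence-change parsing and binned gene density.

Coordinates are 1-based inclusive throughout (FlyBase ``arm:start..end``
dialect); conversion to 0-based half-open BED happens only at the I/O
boundary via :func:`to_bed` / :func:`from_bed`.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import AnnotationError, CoordinateError, InputError, IntervalParseError

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "GenomeAnnotation",
    "DensityProfile",
    "SequenceChange",
    "interval_length_kb",
    "parse_flybase_interval",
    "parse_sequence_change",
    "net_length_change",
    "is_frameshift",
    "gene_midpoint",
    "bin_gene_density",
    "intragenic_percentage",
    "to_bed",
    "from_bed",
    "write_bed",
    "read_bed",
    "write_flybase_tsv",
    "write_density_csv",
]

_DNA = frozenset("ACGT")

_INTERVAL_RE = re.compile(r"^\s*(?P<arm>[^\s:]+):(?P<start>\d+)\.\.(?P<end>\d+)(?:\s+\S+)?\s*$")
_CHANGE_RE = re.compile(r"^\s*(?P<ref>[A-Za-z]+)\s*>\s*(?P<alt>[A-Za-z]+)\s*$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive coordinate span on a named chromosome arm."""

    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"coordinates must be >= 1, got {self.arm}:{self.start}..{self.end}"
            )
        if self.start > self.end:
            raise CoordinateError(
                f"start > end in {self.arm}:{self.start}..{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.arm}:{self.start}..{self.end}"


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    is_hrpg: bool = False


@dataclass
class GenomeAnnotation:
    """Gene records plus arm lengths; the input to density computations."""

    genes: list[GeneRecord] = field(default_factory=list)
    arm_length_bp: dict[str, int] = field(default_factory=dict)
    intergenic: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)

    def genes_on_arm(self, arm: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.interval.arm == arm]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_hrpg(self) -> int:
        return sum(1 for g in self.genes if g.is_hrpg)


@dataclass
class DensityProfile:
    """Per-arm gene counts in consecutive fixed-width bins from position 1."""

    arm: str
    bin_size_bp: int
    counts: list[int]

    @property
    def n_genes(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SequenceChange:
    """A REF > ALT substitution/indel at a 1-based position on an arm."""

    arm: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for label, seq in (("ref", self.ref), ("alt", self.alt)):
            if not seq:
                raise IntervalParseError(f"{label} allele is empty")
            bad = set(seq) - _DNA
            if bad:
                raise IntervalParseError(
                    f"non-DNA characters {sorted(bad)} in {label} allele {seq!r}"
                )
        if self.ref == self.alt:
            raise IntervalParseError(f"ref == alt ({self.ref!r}): not a change")
        if self.position < 1:
            raise IntervalParseError(f"position must be >= 1, got {self.position}")


def interval_length_kb(interval: GenomicInterval, decimals: int = 2) -> float:
    """Inclusive span length in kbp, rounded half-up to ``decimals`` places."""
    if decimals < 0:
        raise InputError("decimals must be >= 0")
    kb = Decimal(interval.length_bp) / Decimal(1000)
    quantum = Decimal(1).scaleb(-decimals)
    return float(kb.quantize(quantum, rounding=ROUND_HALF_UP))


def parse_flybase_interval(text: str) -> GenomicInterval:
    """Parse ``arm:start..end`` text, tolerating a trailing release tag."""
    m = _INTERVAL_RE.match(text)
    if m is None:
        raise IntervalParseError(f"cannot parse interval from {text!r}")
    return GenomicInterval(m["arm"], int(m["start"]), int(m["end"]))


def parse_sequence_change(text: str, arm: str, position: int) -> SequenceChange:
    """Parse a ``REF > ALT`` string; alleles are uppercased."""
    m = _CHANGE_RE.match(text)
    if m is None:
        raise IntervalParseError(f"cannot parse sequence change from {text!r}")
    return SequenceChange(arm=arm, position=position,
                          ref=m["ref"].upper(), alt=m["alt"].upper())


def net_length_change(change: SequenceChange) -> int:
    """Net inserted (+) or deleted (-) base pairs: len(alt) - len(ref)."""
    return len(change.alt) - len(change.ref)


def is_frameshift(change: SequenceChange) -> bool:
    """True iff the net length change is not a multiple of 3."""
    return net_length_change(change) % 3 != 0


def gene_midpoint(gene: GeneRecord) -> float:
    """Midpoint (start + end) / 2, kept as an exact real (halves allowed)."""
    iv = gene.interval
    return (iv.start + iv.end) / 2.0


def bin_gene_density(
    annotation: GenomeAnnotation, bin_size_bp: int = 40_000
) -> list[DensityProfile]:
    """Count gene midpoints per fixed-width bin on every arm.

    A gene falls in bin ``floor((midpoint - 1) / bin_size)`` so position 1
    maps to bin 0 and a midpoint exactly on a bin boundary belongs to the
    lower bin.  The number of bins is ``ceil(arm_length / bin_size)``.
    """
    if bin_size_bp < 1:
        raise InputError(f"bin_size_bp must be >= 1, got {bin_size_bp}")
    profiles: list[DensityProfile] = []
    for arm in sorted(annotation.arm_length_bp):
        arm_len = annotation.arm_length_bp[arm]
        if arm_len < 1:
            raise AnnotationError(f"arm {arm!r} has non-positive length {arm_len}")
        n_bins = math.ceil(arm_len / bin_size_bp)
        counts = [0] * n_bins
        for g in annotation.genes_on_arm(arm):
            if g.interval.end > arm_len:
                raise AnnotationError(
                    f"gene {g.gene_id} ({g.interval}) extends beyond arm "
                    f"{arm!r} length {arm_len}"
                )
            idx = math.floor((gene_midpoint(g) - 1) / bin_size_bp)
            counts[idx] += 1
        profiles.append(DensityProfile(arm=arm, bin_size_bp=bin_size_bp, counts=counts))
    known = set(annotation.arm_length_bp)
    for g in annotation.genes:
        if g.interval.arm not in known:
            raise AnnotationError(f"gene {g.gene_id} on unknown arm {g.interval.arm!r}")
    return profiles


def intragenic_percentage(
    genome_size_bp: int, intergenic: Sequence[GenomicInterval]
) -> float:
    """Percent of the genome not covered by the given intergenic intervals.

    Computed as the complement of the summed intergenic span:
    ``100 * (genome_size - sum(lengths)) / genome_size``.
    """
    if genome_size_bp < 1:
        raise InputError(f"genome_size_bp must be >= 1, got {genome_size_bp}")
    by_arm: dict[str, list[GenomicInterval]] = {}
    for iv in intergenic:
        by_arm.setdefault(iv.arm, []).append(iv)
    for arm, ivs in by_arm.items():
        ivs.sort()
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise InputError(f"overlapping intergenic intervals {a} and {b}")
    total = sum(iv.length_bp for iv in intergenic)
    if total > genome_size_bp:
        raise InputError(
            f"intergenic total {total} bp exceeds genome size {genome_size_bp} bp"
        )
    return 100.0 * (genome_size_bp - total) / genome_size_bp


# --- BED boundary (0-based half-open) -------------------------------------

def to_bed(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert to a (chrom, start, end) BED triple (0-based half-open)."""
    return (interval.arm, interval.start - 1, interval.end)


def from_bed(record: tuple[str, int, int]) -> GenomicInterval:
    """Convert a BED (chrom, start, end) triple back to a 1-based interval."""
    chrom, start, end = record
    if int(start) < 0:
        raise IntervalParseError(f"negative BED start {start}")
    if int(end) <= int(start):
        raise IntervalParseError(f"BED end {end} must exceed start {start}")
    return GenomicInterval(str(chrom), int(start) + 1, int(end))


def write_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as BED: chrom, start, end, gene_id, score (1 = hRPG)."""
    with open(path, "w", newline="") as fh:
        for g in annotation.genes:
            chrom, start, end = to_bed(g.interval)
            fh.write(f"{chrom}\t{start}\t{end}\t{g.gene_id}\t{int(g.is_hrpg)}\n")


def read_bed(path: str | Path,
             arm_length_bp: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read genes written by :func:`write_bed`.

    When ``arm_length_bp`` is omitted each arm length is inferred as the
    maximum gene end seen on that arm.
    """
    genes: list[GeneRecord] = []
    inferred: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalParseError(f"{path}:{line_no}: fewer than 3 BED columns")
            iv = from_bed((parts[0], int(parts[1]), int(parts[2])))
            gene_id = parts[3] if len(parts) > 3 else f"bed{line_no:06d}"
            is_hrpg = len(parts) > 4 and parts[4] not in ("0", ".", "")
            genes.append(GeneRecord(gene_id=gene_id, interval=iv, is_hrpg=is_hrpg))
            inferred[iv.arm] = max(inferred.get(iv.arm, 0), iv.end)
    arms = dict(arm_length_bp) if arm_length_bp is not None else inferred
    return GenomeAnnotation(genes=genes, arm_length_bp=arms)


def write_flybase_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as TSV with 1-based inclusive ``arm:start..end`` locations."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "location", "is_hrpg"])
        for g in annotation.genes:
            writer.writerow([g.gene_id, str(g.interval), int(g.is_hrpg)])


def write_density_csv(profiles: Iterable[DensityProfile], path: str | Path) -> None:
    """Write density profiles as CSV: arm, bin_start_bp (1-based), count."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["arm", "bin_start_bp", "count"])
        for p in profiles:
            for i, c in enumerate(p.counts):
                writer.writerow([p.arm, i * p.bin_size_bp + 1, c])
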