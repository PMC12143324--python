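"""Typed data model for genomic tracks.

All in-memory coordinates are 0-based, half-open ``[start, end)``.  Dialects
that are 1-based inclusive on disk (GFF/GTF, VCF, methylC, GWAS/eQTL tab) are
converted at the I/O boundary and converted back on write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNSTRANDED = "."

    @classmethod
    def parse(cls, s: str) -> "Strand":
        if s in ("+", "-"):
            return cls(s)
        return cls.UNSTRANDED


@dataclass(frozen=True)
class GenomeAssembly:
    """Named assembly: an ordered list of (chromosome, length in bp)."""

    name: str
    chromosomes: tuple  # of (chrom_name, length)

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for c, ln in self.chromosomes:
            if not (isinstance(ln, (int, np.integer)) and ln >= 1):
                raise ValueError(f"chromosome {c!r} has non-positive length {ln!r}")

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    def resolve_chrom(self, chrom: str) -> Optional[str]:
        """Resolve a chromosome name against the assembly.

        Tolerates a missing/extra ``chr`` prefix ("1" vs "chr1"); anything
        beyond that is unresolvable and returns None.
        """
        lengths = self.lengths
        if chrom in lengths:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in lengths:
            return alt
        return None

    def length_of(self, chrom: str) -> int:
        resolved = self.resolve_chrom(chrom)
        if resolved is None:
            raise KeyError(f"unknown chromosome {chrom!r} in assembly {self.name!r}")
        return self.lengths[resolved]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def padded(self, left: int, right: int, chrom_length: Optional[int] = None) -> "GenomicInterval":
        start = max(0, self.start - left)
        end = self.end + right
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end, self.strand)


# ---------------------------------------------------------------------------
# Track record variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalPoint:
    """One step of a piecewise-constant signal (bedGraph/bigWig interval)."""

    interval: GenomicInterval
    value: float

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple  # of GenomicInterval
    cds: tuple = ()


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    interval: GenomicInterval
    transcripts: tuple = ()

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based position of the first REF base
    ref: str
    alts: tuple
    variant_id: str = "."
    info: tuple = ()  # of (key, value) pairs, hashable

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + max(1, len(self.ref)))

    @property
    def start(self):
        return self.pos

    @property
    def end(self):
        return self.pos + max(1, len(self.ref))


_METH_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class MethylationRecord:
    chrom: str
    pos: int  # 0-based
    strand: Strand
    context: str
    level: float
    coverage: int

    def __post_init__(self):
        if self.context not in _METH_CONTEXTS:
            raise ValueError(f"methylation context {self.context!r} not in {_METH_CONTEXTS}")
        if not (0.0 <= self.level <= 1.0):
            raise ValueError(f"methylation level {self.level} outside [0, 1]")
        if self.coverage < 0:
            raise ValueError("negative methylation coverage")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, self.strand)

    @property
    def start(self):
        return self.pos

    @property
    def end(self):
        return self.pos + 1


@dataclass(frozen=True)
class InteractionRecord:
    """A pairwise link between two genomic anchors (longrange/biginteract)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float = 0.0
    name: str = "."

    @property
    def chrom(self):
        return self.anchor1.chrom

    @property
    def start(self):
        return self.anchor1.start

    @property
    def end(self):
        return self.anchor1.end


@dataclass(frozen=True)
class AssociationRecord:
    """A GWAS / eQTL association point."""

    chrom: str
    pos: int  # 0-based
    score: float
    p_value: float
    label: str
    group: str

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)

    @property
    def start(self):
        return self.pos

    @property
    def end(self):
        return self.pos + 1


TrackRecord = Union[
    SignalPoint, GeneModel, Variant, MethylationRecord, InteractionRecord, AssociationRecord
]


@dataclass
class ContactTile:
    """Dense sub-matrix of a Hi-C contact map at one bin size."""

    chrom_a: str
    chrom_b: str
    bin_size: int
    origin_a: int
    origin_b: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("contact matrix must be 2-D")
        if np.any(self.matrix < 0):
            raise ValueError("contact counts must be non-negative")


class TrackKind(str, enum.Enum):
    SIGNAL = "signal"
    FEATURE = "feature"
    GENE = "gene"
    VARIANT = "variant"
    METHYLATION = "methylation"
    INTERACTION = "interaction"
    ASSOCIATION = "association"
    CONTACT = "contact"


@dataclass
class TrackHandle:
    """Opened track: parsed records plus a region-query index."""

    track_id: str
    kind: TrackKind
    format: str
    path: str
    assembly: GenomeAssembly
    index: "object" = None  # genome.index.TrackIndex
    group: Optional[str] = None
    extra: dict = field(default_factory=dict)  # e.g. contact matrices

    @property
    def record_count(self) -> int:
        return 0 if self.index is None else self.index.record_count
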