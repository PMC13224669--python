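"""Core genomic data model shared by every module.

All coordinates are 0-based half-open; conversion from the 1-based
inclusive conventions of VCF and GTF happens only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class Genotype(str, Enum):
    """Diploid genotype of one sample for one variant allele."""

    HOMREF = "HOMREF"
    HET = "HET"
    HOM = "HOM"
    MISSING = "MISSING"


#: alternate-allele dose contributed by each genotype to an AF numerator
ALT_DOSE = {Genotype.HOMREF: 0, Genotype.HET: 1, Genotype.HOM: 2}

#: ordering used when merging genotype calls for the same sample
_GT_RANK = {Genotype.MISSING: 0, Genotype.HOMREF: 1, Genotype.HET: 2, Genotype.HOM: 3}


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    ``end == start`` is permitted and denotes a zero-width anchor point
    (used for insertions); all interval-type records require end > start.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_point(self) -> bool:
        return self.end == self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp shared; a zero-width anchor overlaps an interval containing it."""
        if self.chrom != other.chrom:
            return False
        if self.is_point:
            return other.start <= self.start < other.end
        if other.is_point:
            return self.start <= other.start < self.end
        return self.overlap_len(other) > 0

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class SVRecord:
    """One structural variant with per-sample genotypes.

    For DEL/DUP/INV the interval spans the rearranged segment and
    ``svlen`` equals its length.  For INS the interval is a zero-width
    anchor at the insertion point and ``svlen`` is the inserted length.
    """

    id: str
    svtype: SVType
    interval: GenomicInterval
    svlen: int
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    source: str = ""
    qc_flags: set[str] = field(default_factory=set)
    background_af: Optional[float] = None

    def __post_init__(self) -> None:
        self.svtype = SVType(self.svtype)
        if self.svlen <= 0:
            raise ValueError(f"{self.id}: svlen must be positive, got {self.svlen}")
        if self.svtype is not SVType.INS and self.svlen != self.interval.length:
            raise ValueError(
                f"{self.id}: svlen {self.svlen} != interval length "
                f"{self.interval.length} for {self.svtype.value}"
            )
        self.genotypes = {s: Genotype(g) for s, g in self.genotypes.items()}
        if self.background_af is not None and not 0.0 <= self.background_af <= 1.0:
            raise ValueError(f"{self.id}: background_af outside [0,1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def carriers(self) -> list[str]:
        """Samples with a confident non-reference genotype."""
        return [
            s
            for s, g in self.genotypes.items()
            if g in (Genotype.HET, Genotype.HOM)
        ]

    @property
    def carrier_count(self) -> int:
        return len(self.carriers())


@dataclass(frozen=True)
class PointVariant:
    """A point variant (e.g. a stop-gain SNV) carried by one sample."""

    chrom: str
    pos: int
    consequence: str = "stop_gain"
    sample: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be non-negative")


def classify_gt_tuple(alleles: tuple, alt_index: int = 1) -> Genotype:
    """Map a VCF GT allele tuple to a :class:`Genotype` for one ALT allele.

    Half-calls such as ``./1`` are MISSING (conservative AF denominator).
    """
    if alleles is None or len(alleles) == 0 or any(a is None for a in alleles):
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt >= 2:
        return Genotype.HOM
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOMREF


def merge_genotypes(
    calls: list[Mapping[str, Genotype]], samples: list[str]
) -> dict[str, Genotype]:
    """Combine per-record genotype maps; the strongest call per sample wins."""
    out: dict[str, Genotype] = {}
    for s in samples:
        best = Genotype.MISSING
        seen = False
        for gmap in calls:
            if s in gmap:
                seen = True
                if _GT_RANK[gmap[s]] > _GT_RANK[best]:
                    best = gmap[s]
        if not seen:
            best = Genotype.HOMREF  # absent from every member call = reference
        out[s] = best
    return out
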