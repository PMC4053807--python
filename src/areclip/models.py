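"""Core domain types shared across the package.

Coordinates are genomic, 0-based, half-open everywhere in memory; readers of
1-based formats (GTF, 1-based closed CSV dialects) convert on ingest.
Sequences are stored in the RNA alphabet (A, C, G, U), strand-resolved, i.e.
written 5'→3' in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

REGIONS = ("utr3", "utr5", "cds", "intron", "unannotated")

#: precedence used when a site overlaps segments of several types and the
#: majority-overlap criterion ties
REGION_PRECEDENCE = ("utr3", "utr5", "cds", "intron")

_DNA_TO_RNA = str.maketrans("TtAaCcGgUu", "UUAACCGGUU")


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to the uppercase RNA alphabet."""
    out = seq.translate(_DNA_TO_RNA)
    bad = set(out) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return out


_RC = str.maketrans("ACGUN", "UGCAN")


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Segment:
    """One transcript segment (genomic interval) with a region label."""

    region: str
    start: int  # genomic, 0-based
    end: int    # genomic, half-open
    sequence: Optional[str] = None  # RNA, transcript orientation

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment interval [{self.start}, {self.end})")
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError("segment sequence length does not match interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A gene's single transcript: ordered segments 5'UTR, CDS (with
    interleaved introns), 3'UTR.

    ``segments`` are ordered in transcript (5'→3') orientation; for a minus
    strand gene this means decreasing genomic coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    segments: tuple[Segment, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.segments:
            raise ValueError("transcript must have at least one segment")

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> int:
        return max(s.end for s in self.segments)

    @property
    def span(self) -> int:
        return self.end - self.start

    def segments_of(self, region: str) -> list[Segment]:
        return [s for s in self.segments if s.region == region]

    @property
    def utr3_length(self) -> int:
        return sum(s.length for s in self.segments_of("utr3"))

    @property
    def utr3(self) -> Optional[Segment]:
        segs = self.segments_of("utr3")
        return segs[0] if segs else None

    def utr3_sequence(self) -> Optional[str]:
        segs = self.segments_of("utr3")
        if not segs or any(s.sequence is None for s in segs):
            return None
        return "".join(s.sequence for s in segs)


@dataclass
class BindingSite:
    """One PARalyzer-style cluster (binding site).

    ``t2c_read_count`` counts reads carrying at least one T-to-C conversion,
    ``other_conv_read_count`` reads whose conversions are all non-T-to-C.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_count: int = 0
    t2c_read_count: int = 0
    other_conv_read_count: int = 0
    sequence: Optional[str] = None
    gene_id: Optional[str] = None
    region: str = "unannotated"
    name: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"site start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if min(self.read_count, self.t2c_read_count, self.other_conv_read_count) < 0:
            raise ValueError("negative read counts")
        if self.t2c_read_count + self.other_conv_read_count > self.read_count:
            raise ValueError("conversion read counts exceed total read count")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.sequence is not None:
            self.sequence = to_rna(self.sequence)
            if len(self.sequence) != self.length:
                raise ValueError("site sequence length does not match interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def with_annotation(self, gene_id: Optional[str], region: str) -> "BindingSite":
        return replace(self, gene_id=gene_id, region=region)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene reduction: site counts by region, 3'UTR length, expression."""

    gene_id: str
    n_sites_utr3: int = 0
    n_sites_utr5: int = 0
    n_sites_cds: int = 0
    n_sites_intron: int = 0
    utr3_length: int = 0
    log2fc: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def n_sites_total(self) -> int:
        return (self.n_sites_utr3 + self.n_sites_utr5
                + self.n_sites_cds + self.n_sites_intron)

    @property
    def region_category(self) -> str:
        others = self.n_sites_utr5 + self.n_sites_cds
        if self.n_sites_utr3 > 0 and self.n_sites_intron == 0 and others == 0:
            return "utr3_only"
        if self.n_sites_intron > 0 and self.n_sites_utr3 == 0 and others == 0:
            return "intron_only"
        if self.n_sites_utr3 > 0 and self.n_sites_intron > 0:
            return "both"
        return "other"


def group_by_gene(sites: Iterable[BindingSite]) -> dict[str, list[BindingSite]]:
    out: dict[str, list[BindingSite]] = {}
    for s in sites:
        if s.gene_id is not None:
            out.setdefault(s.gene_id, []).append(s)
    return out
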