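"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 1-based inclusive (GTF-native); BED input is
converted at the boundary by :mod:`lncquarry.io`.  Strand is one of ``+``,
``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")

#: transcript/gene biotypes the pipeline distinguishes
BIOTYPE_PROTEIN_CODING = "protein_coding"
BIOTYPE_ANNOTATED_LNCRNA = "annotated_lncRNA"
BIOTYPE_UNKNOWN = "unknown"


class IntegrityError(ValueError):
    """An input object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a chromosome, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntegrityError(
                f"start must be >= 1 (got {self.start} on {self.chrom})")
        if self.end < self.start:
            raise IntegrityError(
                f"end < start ({self.chrom}:{self.start}-{self.end})")
        if self.strand not in VALID_STRANDS:
            raise IntegrityError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start) + 1

    def gap_to(self, other: "GenomicInterval") -> int:
        """Bases strictly between the two intervals (0 if they overlap or touch).

        Defined for intervals on the same chromosome as
        ``max(0, other.start - self.end - 1, self.start - other.end - 1)``.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on the same chromosome")
        return max(0, other.start - self.end - 1, self.start - other.end - 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass
class TranscriptModel:
    """An exon-structured transcript with optional spliced sequence.

    ``exons`` are sorted by start, non-overlapping, and share one
    chromosome and strand; the transcript interval is the exon span.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = BIOTYPE_UNKNOWN
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise IntegrityError(
                f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise IntegrityError(
                f"{self.transcript_id}: exons on multiple chromosomes {chroms}")
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise IntegrityError(
                f"{self.transcript_id}: conflicting exon strands {strands}")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise IntegrityError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start,
                               self.exons[-1].end, self.strand)

    @property
    def length(self) -> int:
        """Spliced length: the sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1,
                                       self.strand))
        return out

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((a.end + 1, b.start - 1)
                     for a, b in zip(self.exons, self.exons[1:]))

    @property
    def gc_content(self) -> float:
        """GC fraction of the spliced sequence (requires ``sequence``)."""
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: sequence not extracted")
        seq = self.sequence
        gc = seq.count("G") + seq.count("C")
        return gc / len(seq)


@dataclass(frozen=True)
class HitRecord:
    """One significant similarity-search hit (blast-tabular semantics)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bitscore < 0:
            raise IntegrityError("E-value and bitscore must be non-negative")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise IntegrityError("percent identity outside [0, 100]")


@dataclass
class GeneSet:
    """A named gene set (GO term, pathway, ...) for enrichment."""

    set_id: str
    description: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise IntegrityError(f"gene set {self.set_id} has no members")
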