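"""Coordinate-safe data model shared by every stage of the pipeline.

All internal coordinates are 1-based inclusive (GTF convention). BED input is
converted on read, never stored half-open. Exon chains are always ordered
5'->3' in *transcript* orientation, so on the minus strand genomic
coordinates strictly decrease along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "ExonChain",
    "TranscriptCall",
    "ReferenceSets",
    "OrfRecord",
    "UtrRecord",
    "MergedTranscript",
    "OrfParams",
    "MergeParams",
    "ClassifyParams",
    "ValidationParams",
    "LocusConfig",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval.

    ``strand == "."`` means strand-agnostic: it compares as compatible with
    either strand (refTSS / polyA-atlas records may omit strand).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start must be <= end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 1:
            raise ValueError(f"coordinates are 1-based, got start={self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def strand_compatible(self, other: "GenomicInterval") -> bool:
        return "." in (self.strand, other.strand) or self.strand == other.strand

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """>=1 bp of shared sequence; same strand when ``stranded``."""
        if self.chrom != other.chrom:
            return False
        if stranded and not self.strand_compatible(other):
            return False
        return max(self.start, other.start) <= min(self.end, other.end)

    def distance_to(self, pos: int) -> int:
        """bp distance from a point to the nearest edge; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return interval.length


@dataclass(frozen=True)
class ExonChain:
    """Ordered exons of one transcript, 5'->3' in transcript orientation."""

    exons: Tuple[GenomicInterval, ...]

    def __init__(self, exons: Iterable[GenomicInterval]):
        object.__setattr__(self, "exons", tuple(exons))
        self._validate()

    def _validate(self) -> None:
        if not self.exons:
            raise ValueError("exon chain must contain at least one exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError("all exons must share one chrom and strand")
        if self.strand not in "+-":
            raise ValueError("exon chain strand must be + or -")
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                if b.start <= a.end + 1:
                    raise ValueError(
                        f"exons must be ordered 5'->3' with >=1 bp introns: {a} then {b}"
                    )
            else:
                if b.end >= a.start - 1:
                    raise ValueError(
                        f"minus-strand exons must have strictly decreasing coordinates "
                        f"with >=1 bp introns: {a} then {b}"
                    )

    # -- basic geometry -------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """First-to-last-exon genomic span."""
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def five_prime(self) -> int:
        """Genomic position of the transcript 5' terminus."""
        e = self.exons[0]
        return e.start if self.strand == "+" else e.end

    @property
    def three_prime(self) -> int:
        e = self.exons[-1]
        return e.end if self.strand == "+" else e.start

    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Intron (donor->acceptor) intervals in transcript order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1, "+"))
            else:
                out.append(GenomicInterval(self.chrom, b.end + 1, a.start - 1, "-"))
        return tuple(out)

    # -- coordinate projection ------------------------------------------

    def genomic_position(self, tx_pos: int) -> int:
        """Map a 1-based transcript coordinate to its genomic position."""
        if not 1 <= tx_pos <= self.tx_length:
            raise ValueError(f"transcript position {tx_pos} outside 1..{self.tx_length}")
        offset = tx_pos - 1
        for e in self.exons:
            if offset < e.length:
                return e.start + offset if self.strand == "+" else e.end - offset
            offset -= e.length
        raise AssertionError("unreachable")

    def genomic_blocks(self, tx_start: int, tx_end: int) -> Tuple[GenomicInterval, ...]:
        """Project a transcript-coordinate range onto genomic blocks.

        Blocks are returned in transcript (5'->3') order and are maximal per
        exon, so they can be compared structurally between transcripts.
        """
        if tx_start > tx_end:
            raise ValueError("tx_start must be <= tx_end")
        if tx_start < 1 or tx_end > self.tx_length:
            raise ValueError("range outside transcript")
        blocks = []
        cursor = 1
        for e in self.exons:
            lo = max(tx_start, cursor)
            hi = min(tx_end, cursor + e.length - 1)
            if lo <= hi:
                off0, off1 = lo - cursor, hi - cursor
                if self.strand == "+":
                    blocks.append(
                        GenomicInterval(self.chrom, e.start + off0, e.start + off1, "+")
                    )
                else:
                    blocks.append(
                        GenomicInterval(self.chrom, e.end - off1, e.end - off0, "-")
                    )
            cursor += e.length
        return tuple(blocks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.exons)

    def __len__(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class TranscriptCall:
    """One per-sample isoform model as emitted by the upstream caller."""

    sample_id: str
    call_id: str
    gene_label: str
    exons: ExonChain
    caller_status: str = "other"  # Known / Novel / Genomic / other
    gene_status: str = "other"  # Known / Antisense / Intergenic / other
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"read_count must be >= 0, got {self.read_count}")


@dataclass
class ReferenceSets:
    """External evidence bundle: annotation models plus end/junction atlases."""

    annotation: Tuple[TranscriptCall, ...] = ()
    tss_peaks: frozenset = frozenset()
    pas_clusters: frozenset = frozenset()
    junctions: frozenset = frozenset()


# -- ORF / UTR records ----------------------------------------------------


@dataclass(frozen=True)
class OrfRecord:
    """A transcript's selected coding block.

    ``tx_start``/``tx_end`` are transcript-relative 1-based positions of the
    CDS *including* the stop codon; ``protein_length`` excludes the stop.
    """

    tx_start: int
    tx_end: int
    cds_blocks: Tuple[GenomicInterval, ...]
    protein_length: int
    protein_seq: str
    orf_id: Optional[str] = None

    def __post_init__(self) -> None:
        nt = self.tx_end - self.tx_start + 1
        if nt % 3 != 0:
            raise ValueError(f"CDS length {nt} not divisible by 3")
        if self.protein_length != nt // 3 - 1:
            raise ValueError("protein_length must equal codons - 1 (stop excluded)")
        if sum(b.length for b in self.cds_blocks) != nt:
            raise ValueError("cds_blocks total length must equal the CDS span")

    @property
    def block_key(self) -> Tuple[Tuple[str, int, int, str], ...]:
        """Hashable genomic CDS structure used for ORF distinctness."""
        return tuple((b.chrom, b.start, b.end, b.strand) for b in self.cds_blocks)

    def with_id(self, orf_id: str) -> "OrfRecord":
        return replace(self, orf_id=orf_id)


@dataclass(frozen=True)
class UtrRecord:
    """A 5' or 3' untranslated block set of one transcript.

    ``internal_boundaries`` are every genomic block edge except the distal
    transcript terminus; two UTRs are the "same" UTR when these match exactly
    and the distal ends are within the merge tolerance.
    """

    side: str  # "5" or "3"
    blocks: Tuple[GenomicInterval, ...]
    internal_boundaries: Tuple[int, ...]
    distal_end: Optional[int]

    def __post_init__(self) -> None:
        if self.side not in ("5", "3"):
            raise ValueError("side must be '5' or '3'")
        if self.blocks and self.distal_end is None:
            raise ValueError("non-empty UTR needs a distal end")

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    @property
    def cluster_key(self) -> Tuple:
        """Exact-match part of UTR identity (side + internal boundaries)."""
        return (self.side, self.internal_boundaries)


@dataclass(frozen=True)
class MergedTranscript:
    """Cross-sample equivalence class of transcript calls."""

    composite_id: str
    orf_id: str
    utr5_id: str
    utr3_id: str
    member_calls: Tuple[Tuple[str, str], ...]  # (sample_id, call_id)
    occurrence: int
    representative_exons: ExonChain
    representative_member: Optional[Tuple[str, str]] = None
    representative_orf: Optional[OrfRecord] = None
    nmd: bool = False

    def __post_init__(self) -> None:
        n_samples = len({s for s, _ in self.member_calls})
        if self.occurrence != n_samples or self.occurrence < 1:
            raise ValueError("occurrence must equal the number of distinct member samples")


# -- parameter blocks -----------------------------------------------------


@dataclass(frozen=True)
class OrfParams:
    start_codon: str = "ATG"
    stop_codons: Tuple[str, ...] = ("TAA", "TAG", "TGA")
    nmd_distance: int = 50
    longest_per_stop: bool = True

    def __post_init__(self) -> None:
        if self.nmd_distance <= 0:
            raise ValueError("nmd_distance must be > 0")


@dataclass(frozen=True)
class MergeParams:
    end_tolerance: int = 20
    min_occurrence: int = 3

    def __post_init__(self) -> None:
        if self.end_tolerance < 0:
            raise ValueError("end_tolerance must be >= 0")


@dataclass(frozen=True)
class ClassifyParams:
    coding_min_aa: int = 150
    tissue_fold: float = 2.0
    min_occurrence: int = 3

    def __post_init__(self) -> None:
        if min(self.coding_min_aa, self.tissue_fold, self.min_occurrence) <= 0:
            raise ValueError("all classification parameters must be positive")


@dataclass(frozen=True)
class ValidationParams:
    tss_tolerance: int = 50
    pas_tolerance: int = 50

    def __post_init__(self) -> None:
        if self.tss_tolerance < 0 or self.pas_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass(frozen=True)
class LocusConfig:
    """Target gene plus the readthrough partner locus on the same strand."""

    target_locus: GenomicInterval
    partner_locus: GenomicInterval
    target_gene_id: str
    readthrough_gene_id: str

    def __post_init__(self) -> None:
        if self.target_locus.chrom != self.partner_locus.chrom:
            raise ValueError("target and partner loci must share a chromosome")
        if self.target_locus.strand != self.partner_locus.strand:
            raise ValueError("target and partner loci must share a strand")
        if self.target_locus == self.partner_locus:
            raise ValueError("target and partner loci must differ")
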