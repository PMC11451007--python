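"""ORF prediction on spliced transcripts, UTR extraction and the NMD rule.

The model is deliberately simple and matches how long-read isoform studies
screen coding potential: scan the spliced sequence for ATG..stop open
reading frames, keep only the longest ORF per stop codon (nested starts
sharing a stop are redundant), then select the longest ORF per transcript.
The selected CDS is projected back through the exon chain to genomic blocks,
the flanking transcript regions become the 5'/3' UTRs, and a transcript is
called NMD-sensitive when its stop codon lies more than 50 nt upstream of
the most downstream exon-exon junction (the classic 50-nt rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .model import ExonChain, GenomicInterval, OrfParams, OrfRecord, UtrRecord

__all__ = [
    "OrfCandidate",
    "find_orfs",
    "select_orf",
    "extract_utrs",
    "predict_nmd",
    "assign_orf_ids",
    "decompose",
    "TranscriptDecomposition",
]


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate ORF in transcript coordinates, stop codon included."""

    tx_start: int
    tx_end: int

    @property
    def nt_length(self) -> int:
        return self.tx_end - self.tx_start + 1


def find_orfs(seq: str, params: OrfParams = OrfParams()) -> List[OrfCandidate]:
    """All in-frame ATG..stop ORFs of ``seq``, longest-per-stop.

    Every returned candidate runs from an ATG to the first in-frame stop
    codon downstream of it (inclusive). When ``params.longest_per_stop`` is
    set (the default) only the most upstream start is kept for each distinct
    stop position. ORFs without an in-frame stop before the transcript end
    are discarded. Codons containing N never match start or stop.
    """
    seq = seq.upper()
    start, stops = params.start_codon, set(params.stop_codons)
    out: List[OrfCandidate] = []
    for frame in range(3):
        open_starts: List[int] = []  # 0-based start positions awaiting a stop
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == start:
                open_starts.append(i)
            if codon in stops and open_starts:
                if params.longest_per_stop:
                    out.append(OrfCandidate(open_starts[0] + 1, i + 3))
                else:
                    out.extend(OrfCandidate(s + 1, i + 3) for s in open_starts)
                open_starts = []
    out.sort(key=lambda c: (c.tx_start, c.tx_end))
    return out


def select_orf(
    candidates: Sequence[OrfCandidate],
    chain: ExonChain,
    seq: str,
    params: OrfParams = OrfParams(),
) -> Optional[OrfRecord]:
    """Pick the single longest candidate and lift it to genomic blocks.

    Length ties break to the most 5' start so the choice is deterministic
    under input permutation. Returns ``None`` for transcripts without an ORF.
    """
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (-c.nt_length, c.tx_start))
    coding = seq[best.tx_start - 1 : best.tx_end - 3]
    protein = str(Seq(coding).translate())
    return OrfRecord(
        tx_start=best.tx_start,
        tx_end=best.tx_end,
        cds_blocks=chain.genomic_blocks(best.tx_start, best.tx_end),
        protein_length=len(protein),
        protein_seq=protein,
    )


def _edges(blocks: Sequence[GenomicInterval]) -> List[int]:
    out: List[int] = []
    for b in blocks:
        out.extend((b.start, b.end))
    return out


def _utr(side: str, chain: ExonChain, tx_lo: int, tx_hi: int) -> UtrRecord:
    if tx_lo > tx_hi:
        return UtrRecord(side=side, blocks=(), internal_boundaries=(), distal_end=None)
    blocks = chain.genomic_blocks(tx_lo, tx_hi)
    distal = chain.five_prime if side == "5" else chain.three_prime
    edges = _edges(blocks)
    edges.remove(distal)  # the distal terminus is tolerance-matched, not exact
    return UtrRecord(
        side=side,
        blocks=blocks,
        internal_boundaries=tuple(sorted(edges)),
        distal_end=distal,
    )


def extract_utrs(chain: ExonChain, orf: OrfRecord) -> Tuple[UtrRecord, UtrRecord]:
    """5' and 3' UTR block records flanking the selected CDS.

    Together with the CDS blocks the two UTRs tile the exon chain exactly.
    Either side may be empty (CDS starting at base 1 / stop at the 3' end).
    """
    utr5 = _utr("5", chain, 1, orf.tx_start - 1)
    utr3 = _utr("3", chain, orf.tx_end + 1, chain.tx_length)
    return utr5, utr3


def predict_nmd(chain: ExonChain, orf: OrfRecord, params: OrfParams = OrfParams()) -> bool:
    """50-nt rule: stop codon > ``nmd_distance`` nt upstream of the last junction.

    The distance is measured in spliced coordinates from the last base of
    the stop codon; single-exon transcripts can never be NMD-sensitive.
    """
    if chain.n_exons < 2:
        return False
    last_junction = chain.tx_length - chain.exons[-1].length
    return last_junction - orf.tx_end > params.nmd_distance


def assign_orf_ids(orfs: Sequence[OrfRecord], gene: str) -> Dict[Tuple, str]:
    """Length-rank IDs ``{gene}_{rank}_{len}aa`` over the distinct-ORF catalog.

    Distinctness is by genomic CDS block structure. Ranks follow descending
    protein length; ties break by 5'-most genomic CDS start, then by block
    structure, so the numbering is stable under input permutation.
    """
    distinct: Dict[Tuple, OrfRecord] = {}
    for o in orfs:
        distinct.setdefault(o.block_key, o)

    def sort_key(item):
        key, o = item
        first = o.cds_blocks[0]
        five_prime_pos = first.start if first.strand == "+" else -first.end
        return (-o.protein_length, five_prime_pos, key)

    ranked = sorted(distinct.items(), key=sort_key)
    return {key: f"{gene}_{rank}_{o.protein_length}aa" for rank, (key, o) in enumerate(ranked, 1)}


@dataclass(frozen=True)
class TranscriptDecomposition:
    """ORF/UTR/NMD decomposition of one exon chain."""

    chain: ExonChain
    orf: Optional[OrfRecord]
    utr5: UtrRecord
    utr3: UtrRecord
    nmd: bool


def decompose(chain: ExonChain, seq: str, params: OrfParams = OrfParams()) -> TranscriptDecomposition:
    """Run the full ORF -> UTR -> NMD cascade on one transcript.

    Transcripts without an ORF get pseudo-UTR records that carry the full
    splice structure: internal boundaries are every exon edge except the two
    termini, and each side keeps its own distal end. Downstream merging then
    reduces to "identical intron chain, both ends within tolerance", which is
    the natural identity for non-coding transcripts.
    """
    orf = select_orf(find_orfs(seq, params), chain, seq, params)
    if orf is None:
        edges = _edges(chain.exons)
        edges.remove(chain.five_prime)
        edges.remove(chain.three_prime)
        internal = tuple(sorted(edges))
        utr5 = UtrRecord("5", chain.exons, internal, chain.five_prime)
        utr3 = UtrRecord("3", chain.exons, internal, chain.three_prime)
        return TranscriptDecomposition(chain, None, utr5, utr3, False)
    utr5, utr3 = extract_utrs(chain, orf)
    return TranscriptDecomposition(chain, orf, utr5, utr3, predict_nmd(chain, orf, params))
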