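"""Orthogonal-evidence validation of merged transcripts.

Three evidence classes corroborate a transcript model: its 5' terminus
against TSS peak atlases (CAGE-style), its splice junctions against junction
databases (exact intron coordinates), and its 3' terminus against polyA-site
cluster atlases. End matches are tolerance-based (distance to the nearest
interval edge, 0 inside); junction matches are exact. A tissue-level
junction count matrix additionally yields detection rates and mean counts,
the statistic used to gauge how often readthrough-specific junctions appear
in short-read compendia. Finally, exact exon-identity screening and
isoform-unique tryptic peptides connect transcript models to multimapping
risk and to proteomic detectability.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd
from pyteomics import parser as _pyt_parser

from .model import ExonChain, GenomicInterval, MergedTranscript, ValidationParams
from .io import spliced_sequence

__all__ = [
    "validate_tss",
    "validate_junctions",
    "validate_pas",
    "junction_detection_rates",
    "exon_identity_screen",
    "unique_peptides",
    "TRYPSIN_RULE",
]

# cleave after K/R except before P; the spec'd digestion for uniqueness scans
TRYPSIN_RULE = r"(?<=[KR])(?!P)"


def _end_validated(
    pos: int, strand: str, chrom: str, intervals: Iterable[GenomicInterval], tolerance: int
) -> bool:
    probe = GenomicInterval(chrom, pos, pos, strand)
    return any(
        i.chrom == chrom and i.strand_compatible(probe) and i.distance_to(pos) <= tolerance
        for i in intervals
    )


def _validate_ends(
    merged: Sequence[MergedTranscript],
    intervals: Iterable[GenomicInterval],
    tolerance: int,
    end: str,
    label: str,
) -> Tuple[Dict[str, bool], float]:
    intervals = list(intervals)
    if not intervals:
        warnings.warn(f"empty {label} set: no transcript can be validated")
        return {m.composite_id: False for m in merged}, 0.0
    flags = {}
    for m in merged:
        chain = m.representative_exons
        pos = chain.five_prime if end == "5" else chain.three_prime
        flags[m.composite_id] = _end_validated(pos, chain.strand, chain.chrom, intervals, tolerance)
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, fraction


def validate_tss(
    merged: Sequence[MergedTranscript],
    tss_peaks: Iterable[GenomicInterval],
    params: ValidationParams = ValidationParams(),
) -> Tuple[Dict[str, bool], float]:
    """Per-transcript flag (5' end within tolerance of a same-strand peak)
    plus the validated fraction."""
    return _validate_ends(merged, tss_peaks, params.tss_tolerance, "5", "TSS peak")


def validate_pas(
    merged: Sequence[MergedTranscript],
    pas_clusters: Iterable[GenomicInterval],
    params: ValidationParams = ValidationParams(),
) -> Tuple[Dict[str, bool], float]:
    """Per-transcript flag (3' end within tolerance of a same-strand polyA
    cluster) plus the validated fraction."""
    return _validate_ends(merged, pas_clusters, params.pas_tolerance, "3", "polyA cluster")


def validate_junctions(
    merged: Sequence[MergedTranscript],
    junctions: Iterable[GenomicInterval],
) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Split the merged set's distinct introns into matched / unmatched.

    A junction matches only on exact donor/acceptor coordinates and strand;
    a 1-bp shift is a different junction.
    """
    reference = {(j.chrom, j.start, j.end, j.strand) for j in junctions}
    seen: Set[Tuple[str, int, int, str]] = set()
    matched, unmatched = [], []
    for m in merged:
        for intron in m.representative_exons.introns():
            key = (intron.chrom, intron.start, intron.end, intron.strand)
            if key in seen:
                continue
            seen.add(key)
            (matched if key in reference else unmatched).append(intron)
    return matched, unmatched


def junction_detection_rates(
    counts: pd.DataFrame, sample_tissue: Mapping[str, str]
) -> pd.DataFrame:
    """Per-(junction, tissue) detection rate and mean read count.

    Detection rate = fraction of the tissue's samples with count > 0; the
    mean includes zero-count samples. One row per junction and tissue, plus
    the global min/mean/max of the per-tissue means under tissue ``__all__``.
    """
    tissues = pd.Series({s: sample_tissue[s] for s in counts.columns})
    rows = []
    for junction, row in counts.iterrows():
        by_tissue = row.groupby(tissues)
        means = by_tissue.mean()
        for tissue, mean_count in means.items():
            group = by_tissue.get_group(tissue)
            rows.append(
                {
                    "junction": junction,
                    "tissue": tissue,
                    "n_samples": len(group),
                    "detection_rate": float((group > 0).mean()),
                    "mean_count": float(mean_count),
                }
            )
        rows.append(
            {
                "junction": junction,
                "tissue": "__all__",
                "n_samples": len(row),
                "detection_rate": float((row > 0).mean()),
                "mean_count": float(means.mean()),
                "min_tissue_mean": float(means.min()),
                "max_tissue_mean": float(means.max()),
            }
        )
    return pd.DataFrame(rows)


def exon_identity_screen(
    exons_a: Sequence[GenomicInterval],
    exons_b: Sequence[GenomicInterval],
    genome,
) -> List[Tuple[GenomicInterval, GenomicInterval]]:
    """All (a, b) exon pairs with byte-identical strand-aware sequences.

    Used to quantify how much of a locus is duplicated inside a readthrough
    gene (identical exons defeat unique short-read mapping).
    """

    def seq_of(e: GenomicInterval) -> str:
        return spliced_sequence(ExonChain([e]), genome)

    b_by_seq: Dict[str, List[GenomicInterval]] = {}
    for b in exons_b:
        b_by_seq.setdefault(seq_of(b), []).append(b)
    pairs = []
    for a in exons_a:
        for b in b_by_seq.get(seq_of(a), []):
            pairs.append((a, b))
    return pairs


def unique_peptides(
    isoform_protein: str,
    background_proteins: Sequence[str],
    min_length: int = 6,
    missed_cleavages: int = 0,
) -> List[str]:
    """Tryptic peptides of the isoform absent from every background protein.

    Digestion cleaves after K/R except before P with the given number of
    missed cleavages; peptides shorter than ``min_length`` are not
    informative for MS search and are dropped. Uniqueness is substring-based:
    a peptide contained anywhere in a background protein is discarded.
    """
    if not isoform_protein:
        raise ValueError("isoform protein sequence is empty")
    peptides = _pyt_parser.cleave(
        isoform_protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=min_length
    )
    unique = [p for p in peptides if not any(p in bg for bg in background_proteins)]
    # report in order of appearance within the isoform
    unique.sort(key=lambda p: (isoform_protein.find(p), p))
    return unique
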