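"""Readthrough disambiguation and gene-level quantification.

A readthrough (conjoined) gene splices exons of two adjacent loci together,
so a transcript overlapping *both* loci belongs to the readthrough gene and
must not inflate the target gene's counts. Assignment is by genomic span
overlap (>=1 bp, same strand) against the two configured loci.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .model import GenomicInterval, LocusConfig, TranscriptCall

__all__ = [
    "assign_to_locus",
    "filter_artifacts",
    "gene_length",
    "compute_tpm",
]

LABELS = ("target", "readthrough", "neither")


def _overlaps_locus(call: TranscriptCall, locus: GenomicInterval, exonic: bool) -> bool:
    if exonic:
        return any(e.overlaps(locus) for e in call.exons)
    return call.exons.span.overlaps(locus)


def assign_to_locus(
    transcripts: Iterable[TranscriptCall],
    cfg: LocusConfig,
    exonic_overlap: bool = False,
) -> List[Tuple[TranscriptCall, str]]:
    """Label each call ``target`` / ``readthrough`` / ``neither``.

    ``readthrough`` iff the transcript overlaps both loci; ``target`` iff it
    overlaps the target locus only. Overlap is measured on the first-to-last
    exon span by default (``exonic_overlap=True`` restricts it to exons).
    The three labels partition the input.
    """
    out = []
    for t in transcripts:
        hits_target = _overlaps_locus(t, cfg.target_locus, exonic_overlap)
        hits_partner = _overlaps_locus(t, cfg.partner_locus, exonic_overlap)
        if hits_target and hits_partner:
            label = "readthrough"
        elif hits_target:
            label = "target"
        else:
            label = "neither"
        out.append((t, label))
    return out


def filter_artifacts(transcripts: Iterable[TranscriptCall]) -> List[TranscriptCall]:
    """Drop caller artifacts before quantification.

    Removes transcripts labelled ``Genomic`` (unspliced genomic reads) and
    transcripts of genes labelled ``Antisense`` or ``Intergenic``; everything
    else, including unlabelled calls, is retained.
    """
    return [
        t
        for t in transcripts
        if t.caller_status != "Genomic" and t.gene_status not in ("Antisense", "Intergenic")
    ]


def gene_length(transcripts: Sequence[TranscriptCall]) -> float:
    """Gene length in kb = union of exonic bases over the gene's transcripts.

    This is the dataset-derived exonic length used as the RPK denominator,
    not the annotated genomic span.
    """
    if not transcripts:
        raise ValueError("gene_length needs at least one transcript")
    intervals = sorted(
        ((e.start, e.end) for t in transcripts for e in t.exons), key=lambda x: x[0]
    )
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total / 1000.0


def compute_tpm(
    gene_counts: Mapping[str, Mapping[str, float]],
    gene_lengths_kb: Mapping[str, float],
) -> pd.DataFrame:
    """Per-sample TPM from read counts and exonic gene lengths.

    ``gene_counts`` maps sample_id -> {gene_id: read_count}. For each sample:
    RPK = count / length_kb, scaling = sum(RPK) / 1e6, TPM = RPK / scaling,
    so TPMs sum to 1e6 within each sample. A sample whose total RPK is zero
    has no defined TPM and raises.
    """
    rows = []
    for sample, counts in gene_counts.items():
        rpk = {}
        for gene, count in counts.items():
            if gene not in gene_lengths_kb:
                raise KeyError(f"no length for gene {gene!r}")
            if gene_lengths_kb[gene] <= 0:
                raise ValueError(f"non-positive length for gene {gene!r}")
            rpk[gene] = count / gene_lengths_kb[gene]
        total = sum(rpk.values())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total RPK; TPM undefined")
        scaling = total / 1_000_000.0
        for gene, r in rpk.items():
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": gene,
                    "read_count": counts[gene],
                    "gene_length_kb": gene_lengths_kb[gene],
                    "rpk": r,
                    "tpm": r / scaling,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "read_count", "gene_length_kb", "rpk", "tpm"]
    )
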