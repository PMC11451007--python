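"""Usage statistics, novelty against a reference annotation, and the
eight-way transcript taxonomy.

Usage is compositional: within each sample the locus's transcript read
counts are renormalised to fractions, so "usage" answers *which isoform*
carries the locus's transcription, independently of expression depth.
Novelty is structural: an ORF is known when its genomic CDS blocks equal a
reference ORF's, a UTR when its internal boundaries match and its distal end
is within the merge tolerance of a reference UTR, and a transcript when all
three components match one reference model jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ClassifyParams, MergedTranscript, MergeParams, OrfParams, TranscriptCall
from .orfs import TranscriptDecomposition, decompose
from .io import spliced_sequence

__all__ = [
    "CATEGORIES",
    "usage",
    "median_usage",
    "orf_usage",
    "tissue_specific",
    "ReferenceStructures",
    "build_reference_structures",
    "NoveltyFlags",
    "novelty",
    "classify",
]

CATEGORIES = (
    "NMD_Known",
    "NMD_Novel",
    "Non_coding_Known",
    "Non_coding_Novel",
    "Coding_Known",
    "Novel_3/5UTR_only",
    "Novel_combination",
    "Novel_ORF_and_UTR",
    "Novel_ORF_only",
)


# -- usage ----------------------------------------------------------------


def usage(
    merged: Sequence[MergedTranscript],
    quant: Mapping[Tuple[str, str], int],
) -> pd.DataFrame:
    """Per-(transcript, sample) usage fractions.

    usage(t, s) = sum of t's member counts in s / total locus counts in s,
    the locus total being taken over every merged transcript supplied.
    Samples with zero locus counts are undefined (NaN). Rows are composite
    ids, columns sample ids; within a locus-positive sample the column sums
    to 1.
    """
    samples = sorted({s for s, _ in quant})
    counts = pd.DataFrame(0.0, index=[m.composite_id for m in merged], columns=samples)
    for m in merged:
        for sample, call in m.member_calls:
            counts.loc[m.composite_id, sample] += quant.get((sample, call), 0)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.div(totals.where(totals > 0), axis=1)
    return frac


def median_usage(transcript_id: str, usage_matrix: pd.DataFrame) -> float:
    """Median usage over the samples in which the transcript is detected.

    Detection means usage > 0; undefined samples are ignored. Raises if the
    transcript is never detected (the median does not exist).
    """
    row = usage_matrix.loc[transcript_id].dropna()
    detected = row[row > 0]
    if detected.empty:
        raise ValueError(f"{transcript_id!r} is not detected in any sample")
    return float(detected.median())


def orf_usage(
    usage_matrix: pd.DataFrame, orf_of_transcript: Mapping[str, str]
) -> pd.DataFrame:
    """Sum transcript usage per ORF within each sample.

    Rows are ORF ids; per sample the ORF usages sum to 1 wherever the locus
    is expressed (the mapping must cover every transcript row).
    """
    missing = [t for t in usage_matrix.index if t not in orf_of_transcript]
    if missing:
        raise KeyError(f"transcripts without an ORF assignment: {missing}")
    groups = pd.Series({t: orf_of_transcript[t] for t in usage_matrix.index})
    return usage_matrix.groupby(groups).sum(min_count=1)


def tissue_specific(
    usage_matrix: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    params: ClassifyParams = ClassifyParams(),
) -> Dict[str, Optional[str]]:
    """Flag transcripts whose usage is >= ``tissue_fold`` times higher in one
    tissue than in any other.

    The per-tissue summary is the mean usage over that tissue's
    locus-positive samples (undetected transcripts count as 0). A transcript
    expressed in a single tissue only is specific to it. With fewer than two
    tissues nothing can be compared and all flags are ``None``.
    """
    tissues = pd.Series({s: sample_tissue[s] for s in usage_matrix.columns})
    if tissues.nunique() < 2:
        warnings.warn("tissue specificity needs >=2 tissues; all transcripts unflagged")
        return {t: None for t in usage_matrix.index}
    means = usage_matrix.T.groupby(tissues).mean()  # tissue x transcript
    flags: Dict[str, Optional[str]] = {}
    for t in usage_matrix.index:
        col = means[t].dropna()
        top_tissue = col.idxmax()
        top = col[top_tissue]
        others = col.drop(top_tissue)
        if top > 0 and (others <= top / params.tissue_fold + 1e-12).all():
            flags[t] = str(top_tissue)
        else:
            flags[t] = None
    return flags


# -- novelty --------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceStructures:
    """Structural index of a reference annotation after ORF/UTR decomposition."""

    orf_keys: frozenset
    utr5: Tuple[Tuple[Tuple[int, ...], int], ...]  # (internal_boundaries, distal)
    utr3: Tuple[Tuple[Tuple[int, ...], int], ...]
    transcripts: Tuple[Tuple, ...]  # (orf_key | None, utr5 struct, utr3 struct)


def _utr_struct(utr) -> Optional[Tuple[Tuple[int, ...], int]]:
    if utr.is_empty:
        return None
    return (utr.internal_boundaries, utr.distal_end)


def build_reference_structures(
    reference: Sequence[TranscriptCall],
    genome,
    orf_params: OrfParams = OrfParams(),
) -> ReferenceStructures:
    """Run the reference models through the same ORF/UTR engine as the data."""
    orf_keys = set()
    utr5, utr3, txs = [], [], []
    for call in reference:
        d = decompose(call.exons, spliced_sequence(call.exons, genome), orf_params)
        okey = d.orf.block_key if d.orf is not None else None
        if okey is not None:
            orf_keys.add(okey)
        u5, u3 = _utr_struct(d.utr5), _utr_struct(d.utr3)
        if u5 is not None:
            utr5.append(u5)
        if u3 is not None:
            utr3.append(u3)
        txs.append((okey, u5, u3))
    return ReferenceStructures(
        orf_keys=frozenset(orf_keys),
        utr5=tuple(utr5),
        utr3=tuple(utr3),
        transcripts=tuple(txs),
    )


@dataclass(frozen=True)
class NoveltyFlags:
    orf_novel: bool
    utr5_novel: bool
    utr3_novel: bool
    transcript_novel: bool


def _utr_matches(query, refs, tolerance: int) -> bool:
    if query is None:
        return any(r is None for r in refs) or not refs
    internal, distal = query
    return any(
        r is not None and r[0] == internal and abs(r[1] - distal) <= tolerance for r in refs
    )


def novelty(
    decomposition: TranscriptDecomposition,
    reference: ReferenceStructures,
    merge_params: MergeParams = MergeParams(),
) -> NoveltyFlags:
    """Structural novelty of one transcript against the reference index.

    With an empty reference everything is novel (and a warning is issued
    once by the caller that built the empty index).
    """
    tol = merge_params.end_tolerance
    okey = decomposition.orf.block_key if decomposition.orf is not None else None
    u5, u3 = _utr_struct(decomposition.utr5), _utr_struct(decomposition.utr3)

    # a transcript without an ORF has no ORF to be novel (it is classified
    # through the non-coding branch)
    orf_known = True if okey is None else okey in reference.orf_keys
    utr5_known = _utr_matches(u5, reference.utr5, tol) if u5 is not None else True
    utr3_known = _utr_matches(u3, reference.utr3, tol) if u3 is not None else True

    tx_known = False
    for r_okey, r_u5, r_u3 in reference.transcripts:
        if r_okey != okey:
            continue
        if _utr_matches(u5, [r_u5], tol) and _utr_matches(u3, [r_u3], tol):
            tx_known = True
            break
    return NoveltyFlags(
        orf_novel=not orf_known,
        utr5_novel=not utr5_known,
        utr3_novel=not utr3_known,
        transcript_novel=not tx_known,
    )


# -- taxonomy -------------------------------------------------------------


def classify(
    nmd: bool,
    protein_length: Optional[int],
    flags: NoveltyFlags,
    params: ClassifyParams = ClassifyParams(),
) -> str:
    """Total decision cascade onto the eight-way taxonomy.

    Order matters: NMD trumps everything, then coding potential (< 150 aa or
    no ORF is non-coding), then whole-transcript novelty, then the ORF/UTR
    novelty combination for novel coding transcripts.
    """
    if nmd:
        return "NMD_Novel" if flags.transcript_novel else "NMD_Known"
    if protein_length is None or protein_length < params.coding_min_aa:
        return "Non_coding_Novel" if flags.transcript_novel else "Non_coding_Known"
    if not flags.transcript_novel:
        return "Coding_Known"
    any_utr_novel = flags.utr5_novel or flags.utr3_novel
    if not flags.orf_novel:
        return "Novel_3/5UTR_only" if any_utr_novel else "Novel_combination"
    return "Novel_ORF_and_UTR" if any_utr_novel else "Novel_ORF_only"
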