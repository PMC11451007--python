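"""End-to-end orchestration: assign -> filter -> quantify -> decompose ->
merge -> classify -> validate, with a file-based runner on top of an
in-memory analysis core.

The in-memory entry point is :func:`analyze`; :func:`run_all` wraps it with
format I/O and report emission for shell use. Stage outputs are plain
TSV/GTF so every step is independently diffable, and the summary records the
effective parameters plus counts entering and leaving each filter so the
analysis funnel is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import classify as clf
from . import locus as locus_mod
from . import merge as merge_mod
from . import validate as val_mod
from .io import spliced_sequence
from .model import (
    ClassifyParams,
    GenomicInterval,
    LocusConfig,
    MergedTranscript,
    MergeParams,
    OrfParams,
    TranscriptCall,
    ValidationParams,
)
from .orfs import assign_orf_ids, decompose

logger = logging.getLogger("isocollapse")

__all__ = ["PipelineParams", "LocusReport", "analyze", "run_all"]


@dataclass(frozen=True)
class PipelineParams:
    """All stage parameters with their standard defaults."""

    orf: OrfParams = OrfParams()
    merge: MergeParams = MergeParams()
    classify: ClassifyParams = ClassifyParams()
    validation: ValidationParams = ValidationParams()

    def as_dict(self) -> Dict[str, object]:
        return {
            "start_codon": self.orf.start_codon,
            "stop_codons": list(self.orf.stop_codons),
            "nmd_distance_nt": self.orf.nmd_distance,
            "end_tolerance_bp": self.merge.end_tolerance,
            "min_occurrence": self.merge.min_occurrence,
            "coding_min_aa": self.classify.coding_min_aa,
            "tissue_fold": self.classify.tissue_fold,
            "tss_tolerance_bp": self.validation.tss_tolerance,
            "pas_tolerance_bp": self.validation.pas_tolerance,
        }


@dataclass
class LocusReport:
    """Everything the pipeline computed for one locus."""

    params: PipelineParams
    locus: LocusConfig
    n_input_calls: int
    n_after_artifact_filter: int
    target_calls: List[TranscriptCall]
    readthrough_calls: List[TranscriptCall]
    neither_calls: List[TranscriptCall]
    gene_tpm: pd.DataFrame
    merged: List[MergedTranscript]
    valid: List[MergedTranscript]
    minor: List[MergedTranscript]
    usage_matrix: pd.DataFrame
    orf_of_transcript: Dict[str, str]
    orf_usage: pd.DataFrame
    categories: Dict[str, str]
    novelty: Dict[str, clf.NoveltyFlags]
    tissue_flags: Dict[str, Optional[str]]
    tss_flags: Dict[str, bool]
    tss_fraction: float
    pas_flags: Dict[str, bool]
    pas_fraction: float
    junctions_matched: List[GenomicInterval]
    junctions_unmatched: List[GenomicInterval]

    # -- derived summaries ---------------------------------------------

    def category_histogram(self) -> Dict[str, int]:
        hist = Counter(self.categories.values())
        return {c: hist.get(c, 0) for c in clf.CATEGORIES if hist.get(c, 0)}

    def n_novel(self) -> int:
        return sum(1 for f in self.novelty.values() if f.transcript_novel)

    def top_transcripts(self, n: int = 15) -> pd.DataFrame:
        rows = []
        for m in sorted(self.valid, key=lambda m: (-m.occurrence, m.composite_id))[:n]:
            rows.append(
                {
                    "composite_id": m.composite_id,
                    "occurrence": m.occurrence,
                    "median_usage": clf.median_usage(m.composite_id, self.usage_matrix),
                    "category": self.categories[m.composite_id],
                    "tissue_specific": self.tissue_flags.get(m.composite_id) or "",
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> Dict[str, object]:
        orf_ids = {self.orf_of_transcript[m.composite_id] for m in self.valid}
        orf_ids.discard(merge_mod.NO_ORF_ID)
        novel_orfs = {
            self.orf_of_transcript[m.composite_id]
            for m in self.valid
            if self.novelty[m.composite_id].orf_novel
            and self.orf_of_transcript[m.composite_id] != merge_mod.NO_ORF_ID
        }
        utr5 = {m.utr5_id for m in self.valid if m.utr5_id != "5UTR_0"}
        utr3 = {m.utr3_id for m in self.valid if m.utr3_id != "3UTR_0"}
        novel_u5 = {m.utr5_id for m in self.valid if self.novelty[m.composite_id].utr5_novel}
        novel_u3 = {m.utr3_id for m in self.valid if self.novelty[m.composite_id].utr3_novel}
        n_junctions = len(self.junctions_matched) + len(self.junctions_unmatched)
        return {
            "parameters": self.params.as_dict(),
            "n_input_calls": self.n_input_calls,
            "n_after_artifact_filter": self.n_after_artifact_filter,
            "n_target_calls": len(self.target_calls),
            "n_readthrough_calls": len(self.readthrough_calls),
            "n_merged": len(self.merged),
            "n_valid": len(self.valid),
            "n_minor": len(self.minor),
            "n_novel": self.n_novel(),
            "n_orfs": len(orf_ids),
            "n_novel_orfs": len(novel_orfs),
            "n_5utrs": len(utr5),
            "n_novel_5utrs": len(novel_u5 & utr5),
            "n_3utrs": len(utr3),
            "n_novel_3utrs": len(novel_u3 & utr3),
            "n_tissue_specific": sum(1 for v in self.tissue_flags.values() if v),
            "category_histogram": self.category_histogram(),
            "tss_validated_fraction": self.tss_fraction,
            "pas_validated_fraction": self.pas_fraction,
            "n_junctions": n_junctions,
            "n_junctions_matched": len(self.junctions_matched),
        }


def _gene_level_quant(
    labeled: Sequence[Tuple[TranscriptCall, str]], cfg: LocusConfig
) -> pd.DataFrame:
    """Per-sample gene TPMs after readthrough reassignment.

    Target- and readthrough-labeled transcripts are pooled under the two
    configured gene ids; "neither" transcripts keep their caller gene label
    and stay in the TPM denominator (the scaling is sample-wide).
    """
    gene_of: Dict[Tuple[TranscriptCall, str], str] = {}
    counts: Dict[str, Dict[str, float]] = defaultdict(lambda: defaultdict(float))
    by_gene: Dict[str, List[TranscriptCall]] = defaultdict(list)
    for call, label in labeled:
        if label == "target":
            gene = cfg.target_gene_id
        elif label == "readthrough":
            gene = cfg.readthrough_gene_id
        else:
            gene = call.gene_label
        counts[call.sample_id][gene] += call.read_count
        by_gene[gene].append(call)
    lengths = {g: locus_mod.gene_length(calls) for g, calls in by_gene.items()}
    return locus_mod.compute_tpm(counts, lengths)


def analyze(
    calls: Sequence[TranscriptCall],
    quant: Mapping[Tuple[str, str], int],
    sample_tissue: Mapping[str, str],
    genome,
    reference_calls: Sequence[TranscriptCall],
    cfg: LocusConfig,
    params: PipelineParams = PipelineParams(),
    tss_peaks: Sequence[GenomicInterval] = (),
    pas_clusters: Sequence[GenomicInterval] = (),
    junctions: Sequence[GenomicInterval] = (),
) -> LocusReport:
    """Run the full locus analysis in memory and return every stage result."""
    n_input = len(calls)
    retained = locus_mod.filter_artifacts(calls)
    logger.info("artifact filter: %d -> %d calls", n_input, len(retained))

    labeled = locus_mod.assign_to_locus(retained, cfg)
    target = [c for c, lab in labeled if lab == "target"]
    readthrough = [c for c, lab in labeled if lab == "readthrough"]
    neither = [c for c, lab in labeled if lab == "neither"]
    logger.info(
        "locus assignment: %d target, %d readthrough, %d neither",
        len(target), len(readthrough), len(neither),
    )

    gene_tpm = _gene_level_quant(labeled, cfg)

    # ORF/UTR decomposition of every target call
    annotated = [
        merge_mod.AnnotatedCall(call=c, decomposition=decompose(c.exons, spliced_sequence(c.exons, genome), params.orf))
        for c in target
    ]
    with_orf = [a for a in annotated if a.decomposition.orf is not None]
    orf_ids = assign_orf_ids([a.decomposition.orf for a in with_orf], cfg.target_gene_id)
    for a in annotated:
        if a.decomposition.orf is None:
            a.orf_id = merge_mod.NO_ORF_ID
        else:
            a.orf_id = orf_ids[a.decomposition.orf.block_key]
    merge_mod.annotate_utr_ids(annotated, params.merge)

    merged = merge_mod.merge_calls(annotated)
    valid, minor = merge_mod.filter_valid(merged, params.merge.min_occurrence)
    logger.info("merged %d calls into %d transcripts (%d valid)", len(annotated), len(merged), len(valid))

    usage_matrix = clf.usage(merged, quant)
    orf_of_transcript = {m.composite_id: m.orf_id for m in merged}
    orf_usage = clf.orf_usage(usage_matrix, orf_of_transcript)

    # novelty + taxonomy on the valid set
    reference = clf.build_reference_structures(reference_calls, genome, params.orf)
    if not reference_calls:
        logger.warning("empty reference annotation: every transcript will be novel")
    ac_by_member = {(a.call.sample_id, a.call.call_id): a for a in annotated}
    novelty_flags: Dict[str, clf.NoveltyFlags] = {}
    categories: Dict[str, str] = {}
    for m in valid:
        rep = ac_by_member[m.representative_member]
        flags = clf.novelty(rep.decomposition, reference, params.merge)
        novelty_flags[m.composite_id] = flags
        plen = rep.decomposition.orf.protein_length if rep.decomposition.orf else None
        categories[m.composite_id] = clf.classify(m.nmd, plen, flags, params.classify)

    valid_usage = usage_matrix.loc[[m.composite_id for m in valid]]
    tissue_flags = clf.tissue_specific(valid_usage, sample_tissue, params.classify)

    tss_flags, tss_fraction = val_mod.validate_tss(valid, tss_peaks, params.validation)
    pas_flags, pas_fraction = val_mod.validate_pas(valid, pas_clusters, params.validation)
    matched, unmatched = val_mod.validate_junctions(valid, junctions)

    return LocusReport(
        params=params,
        locus=cfg,
        n_input_calls=n_input,
        n_after_artifact_filter=len(retained),
        target_calls=target,
        readthrough_calls=readthrough,
        neither_calls=neither,
        gene_tpm=gene_tpm,
        merged=merged,
        valid=valid,
        minor=minor,
        usage_matrix=usage_matrix,
        orf_of_transcript=orf_of_transcript,
        orf_usage=orf_usage,
        categories=categories,
        novelty=novelty_flags,
        tissue_flags=tissue_flags,
        tss_flags=tss_flags,
        tss_fraction=tss_fraction,
        pas_flags=pas_flags,
        pas_fraction=pas_fraction,
        junctions_matched=matched,
        junctions_unmatched=unmatched,
    )


# ---------------------------------------------------------------------------
# file-based runner
# ---------------------------------------------------------------------------


def _parse_locus(spec: str) -> GenomicInterval:
    """Parse 'chr16:28474111-28495575:-' into an interval."""
    try:
        chrom, coords, strand = spec.rsplit(":", 2)
        start, end = coords.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start), int(end), strand)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse locus {spec!r}; expected chrom:start-end:strand") from exc


def run_all(config: Mapping[str, object], outdir: str) -> LocusReport:
    """Execute the pipeline from a configuration mapping and write reports.

    Expected keys: ``genome`` (FASTA), ``reference_gtf``, ``sample_gtfs``
    (list), ``sample_quants`` (list, aligned), ``samples_tsv`` (sample_id,
    tissue), ``target_locus`` / ``partner_locus`` (chrom:start-end:strand),
    ``target_gene`` / ``readthrough_gene``, optional ``tss_bed`` /
    ``pas_bed`` / ``junctions_tsv`` and a ``parameters`` block.
    """
    from pyfaidx import Fasta

    from .io import (
        read_bed_intervals,
        read_gtf,
        read_junction_table,
        read_quant,
        write_gtf,
    )

    os.makedirs(outdir, exist_ok=True)
    genome = Fasta(str(config["genome"]))
    reference_calls = read_gtf(config["reference_gtf"], dialect="reference")

    sample_meta = pd.read_csv(config["samples_tsv"], sep="\t")
    sample_tissue = dict(zip(sample_meta["sample_id"].astype(str), sample_meta["tissue"]))

    calls: List[TranscriptCall] = []
    quant: Dict[Tuple[str, str], int] = {}
    for gtf_path, quant_path in zip(config["sample_gtfs"], config["sample_quants"]):
        sample_quant = read_quant(quant_path)
        samples = {s for s, _ in sample_quant}
        if len(samples) != 1:
            raise ValueError(f"{quant_path} must contain exactly one sample")
        (sample,) = samples
        for call in read_gtf(gtf_path, dialect="caller", sample_id=sample):
            count = sample_quant.get((sample, call.call_id), 0)
            calls.append(
                TranscriptCall(
                    sample_id=sample,
                    call_id=call.call_id,
                    gene_label=call.gene_label,
                    exons=call.exons,
                    caller_status=call.caller_status,
                    gene_status=call.gene_status,
                    read_count=count,
                )
            )
        quant.update(sample_quant)

    cfg = LocusConfig(
        target_locus=_parse_locus(str(config["target_locus"])),
        partner_locus=_parse_locus(str(config["partner_locus"])),
        target_gene_id=str(config.get("target_gene", "target")),
        readthrough_gene_id=str(config.get("readthrough_gene", "readthrough")),
    )

    p = config.get("parameters", {})
    params = PipelineParams(
        orf=OrfParams(nmd_distance=int(p.get("nmd_distance_nt", 50))),
        merge=MergeParams(
            end_tolerance=int(p.get("end_tolerance_bp", 20)),
            min_occurrence=int(p.get("min_occurrence", 3)),
        ),
        classify=ClassifyParams(
            coding_min_aa=int(p.get("coding_min_aa", 150)),
            tissue_fold=float(p.get("tissue_fold", 2.0)),
        ),
        validation=ValidationParams(
            tss_tolerance=int(p.get("tss_tolerance_bp", 50)),
            pas_tolerance=int(p.get("pas_tolerance_bp", 50)),
        ),
    )

    tss = read_bed_intervals(config["tss_bed"], "tss") if config.get("tss_bed") else set()
    pas = read_bed_intervals(config["pas_bed"], "pas") if config.get("pas_bed") else set()
    junctions = (
        read_junction_table(config["junctions_tsv"])[0] if config.get("junctions_tsv") else set()
    )

    report = analyze(
        calls, quant, sample_tissue, genome, reference_calls, cfg, params,
        tss_peaks=sorted(tss), pas_clusters=sorted(pas), junctions=sorted(junctions),
    )
    write_report(report, outdir)
    return report


def write_report(report: LocusReport, outdir: str) -> None:
    """Emit the per-stage TSV/GTF/JSON bundle."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda f: os.path.join(outdir, f)  # noqa: E731
    from .io import write_gtf

    if report.valid:
        write_gtf(report.valid, join("merged_valid.gtf"))
    report.gene_tpm.to_csv(join("gene_tpm.tsv"), sep="\t", index=False)
    rows = []
    for m in report.valid:
        rows.append(
            {
                "composite_id": m.composite_id,
                "orf_id": m.orf_id,
                "utr5_id": m.utr5_id,
                "utr3_id": m.utr3_id,
                "occurrence": m.occurrence,
                "median_usage": clf.median_usage(m.composite_id, report.usage_matrix),
                "category": report.categories[m.composite_id],
                "novel": report.novelty[m.composite_id].transcript_novel,
                "tissue_specific": report.tissue_flags.get(m.composite_id) or "",
                "tss_validated": report.tss_flags[m.composite_id],
                "pas_validated": report.pas_flags[m.composite_id],
            }
        )
    pd.DataFrame(rows).to_csv(join("transcripts.tsv"), sep="\t", index=False)
    report.usage_matrix.to_csv(join("usage_matrix.tsv"), sep="\t")
    report.orf_usage.to_csv(join("orf_usage.tsv"), sep="\t")
    with open(join("summary.json"), "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
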