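"""Readers and writers for the standard formats the pipeline consumes.

GTF is parsed through :mod:`gffutils` (in-memory database) so attribute
handling follows the reference implementation of the format; BED and the
quantification/junction TSVs go through :mod:`pandas`; genome FASTA access
uses :mod:`pyfaidx`. Everything is converted into the 1-based inclusive
internal model at the boundary — no half-open coordinate ever escapes this
module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from .model import ExonChain, GenomicInterval, MergedTranscript, TranscriptCall
from .model import interval_length  # re-exported: spec'd as an io-level helper

__all__ = [
    "GtfDialect",
    "read_gtf",
    "write_gtf",
    "read_quant",
    "write_quant",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_junction_table",
    "write_junction_table",
    "spliced_sequence",
    "interval_length",
    "write_fasta",
]


@dataclass(frozen=True)
class GtfDialect:
    """Attribute keys carrying caller novelty labels.

    TALON-style defaults; for each status the first key present wins and
    unknown/absent labels map to ``"other"`` rather than erroring.
    """

    transcript_status_keys: Tuple[str, ...] = ("transcript_status", "transcript_novelty")
    gene_status_keys: Tuple[str, ...] = ("gene_status", "gene_novelty")


_CALLER = GtfDialect()
_REFERENCE = GtfDialect(transcript_status_keys=(), gene_status_keys=())

_TX_LABELS = {"known": "Known", "novel": "Novel", "genomic": "Genomic"}
_GENE_LABELS = {"known": "Known", "antisense": "Antisense", "intergenic": "Intergenic"}


def _normalise(raw: str, table: Mapping[str, str]) -> str:
    return table.get(raw.strip().lower(), "other")


def _status(attrs, keys: Sequence[str], table: Mapping[str, str]) -> str:
    for key in keys:
        if key in attrs:
            return _normalise(attrs[key][0], table)
    return "other"


def read_gtf(
    path: Union[str, os.PathLike],
    dialect: str = "caller",
    sample_id: str = "",
) -> List[TranscriptCall]:
    """Parse a GTF into :class:`TranscriptCall` records.

    Parameters
    ----------
    dialect
        ``"caller"`` reads TALON-style novelty attributes; ``"reference"``
        ignores them (every status becomes ``"other"``).
    sample_id
        Stamped onto every record (callers emit one GTF per sample).
    """
    if dialect not in ("caller", "reference"):
        raise ValueError("dialect must be 'caller' or 'reference'")
    keys = _CALLER if dialect == "caller" else _REFERENCE
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface file/line context
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    transcripts: Dict[str, dict] = {}
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        tid = feat.attributes["transcript_id"][0]
        transcripts[tid] = {
            "gene": feat.attributes.get("gene_id", ["unknown"])[0],
            "caller_status": _status(feat.attributes, keys.transcript_status_keys, _TX_LABELS),
            "gene_status": _status(feat.attributes, keys.gene_status_keys, _GENE_LABELS),
            "strand": feat.strand,
            "exons": [],
        }
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise ValueError(f"exon without transcript_id in {path} at {feat.seqid}:{feat.start}")
        tid = feat.attributes["transcript_id"][0]
        if tid not in transcripts:
            raise ValueError(f"exon references unknown transcript {tid!r} in {path}")
        transcripts[tid]["exons"].append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        )

    calls = []
    for tid, rec in transcripts.items():
        if not rec["exons"]:
            raise ValueError(f"transcript {tid!r} has no exons in {path}")
        exons = sorted(rec["exons"], key=lambda e: e.start, reverse=rec["strand"] == "-")
        calls.append(
            TranscriptCall(
                sample_id=sample_id,
                call_id=tid,
                gene_label=rec["gene"],
                exons=ExonChain(exons),
                caller_status=rec["caller_status"],
                gene_status=rec["gene_status"],
            )
        )
    return calls


def _gtf_attrs(pairs: Sequence[Tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(
    transcripts: Sequence[Union[TranscriptCall, MergedTranscript]],
    path: Union[str, os.PathLike],
    source: str = "isocollapse",
) -> None:
    """Write transcript + exon features, 1-based inclusive.

    Merged transcripts are written with their composite id as
    ``transcript_id`` and the representative member's exon chain.
    """
    if not transcripts:
        raise ValueError("refusing to write an empty GTF")
    lines = []
    for t in transcripts:
        if isinstance(t, MergedTranscript):
            chain, tid = t.representative_exons, t.composite_id
            attrs = [("gene_id", t.orf_id.split("_")[0]), ("transcript_id", tid),
                     ("occurrence", str(t.occurrence))]
        else:
            chain, tid = t.exons, t.call_id
            attrs = [
                ("gene_id", t.gene_label),
                ("transcript_id", tid),
                ("transcript_status", t.caller_status),
                ("gene_status", t.gene_status),
            ]
        span = chain.span
        lines.append(
            "\t".join(
                [span.chrom, source, "transcript", str(span.start), str(span.end),
                 ".", chain.strand, ".", _gtf_attrs(attrs)]
            )
        )
        for e in sorted(chain.exons, key=lambda x: x.start):
            lines.append(
                "\t".join(
                    [e.chrom, source, "exon", str(e.start), str(e.end),
                     ".", e.strand, ".", _gtf_attrs(attrs[:2])]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- quantification -------------------------------------------------------


def read_quant(path: Union[str, os.PathLike]) -> Dict[Tuple[str, str], int]:
    """Read a TSV of per-sample transcript read counts.

    Columns: ``sample_id``, ``transcript_id``, ``read_count``. Missing
    transcripts are simply absent from the mapping (never zero-filled).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "transcript_id": str})
    required = {"sample_id", "transcript_id", "read_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"quant TSV must have columns {sorted(required)}")
    if (df["read_count"] < 0).any():
        bad = df.loc[df["read_count"] < 0].iloc[0]
        raise ValueError(f"negative read count for {bad['transcript_id']}")
    if df.duplicated(["sample_id", "transcript_id"]).any():
        raise ValueError("duplicate (sample_id, transcript_id) rows in quant TSV")
    return {
        (r.sample_id, r.transcript_id): int(r.read_count)
        for r in df.itertuples(index=False)
    }


def write_quant(counts: Mapping[Tuple[str, str], int], path: Union[str, os.PathLike]) -> None:
    rows = [
        {"sample_id": s, "transcript_id": t, "read_count": c}
        for (s, t), c in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "transcript_id", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


# -- BED ------------------------------------------------------------------


def read_bed_intervals(path: Union[str, os.PathLike], kind: str = "tss") -> Set[GenomicInterval]:
    """Read BED3+ into 1-based inclusive intervals.

    BED is half-open 0-based: internal start = BED start + 1, end unchanged.
    Strand comes from column 6 when present, otherwise ``"."``.
    """
    if kind not in ("tss", "pas", "generic"):
        raise ValueError("kind must be 'tss', 'pas' or 'generic'")
    out: Set[GenomicInterval] = set()
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{n}: BED needs >=3 columns")
            chrom, b_start, b_end = parts[0], int(parts[1]), int(parts[2])
            if b_end <= b_start:
                raise ValueError(f"{path}:{n}: BED end must be > start")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.add(GenomicInterval(chrom, b_start + 1, b_end, strand))
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval], path: Union[str, os.PathLike], name: str = "."
) -> None:
    """Inverse of :func:`read_bed_intervals` (internal -> half-open 0-based)."""
    rows = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end, i.strand))
    with open(path, "w") as fh:
        for i in rows:
            fh.write(f"{i.chrom}\t{i.start - 1}\t{i.end}\t{name}\t0\t{i.strand}\n")


# -- junction tables ------------------------------------------------------


def read_junction_table(
    path: Union[str, os.PathLike],
) -> Tuple[Set[GenomicInterval], pd.DataFrame]:
    """Read an intron table: chrom, intron_start, intron_end, strand[, counts].

    Returns the deduplicated junction set plus a count matrix (one row per
    junction, one column per extra sample column; empty when absent).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "intron_start", "intron_end", "strand"]
    if not set(required).issubset(df.columns):
        raise ValueError(f"junction TSV must have columns {required}")
    junctions = {
        GenomicInterval(r.chrom, int(r.intron_start), int(r.intron_end), r.strand)
        for r in df.itertuples(index=False)
    }
    count_cols = [c for c in df.columns if c not in required]
    counts = df.set_index(required)[count_cols] if count_cols else pd.DataFrame()
    return junctions, counts


def write_junction_table(
    junctions: Iterable[GenomicInterval],
    path: Union[str, os.PathLike],
    counts: pd.DataFrame | None = None,
) -> None:
    rows = sorted(junctions, key=lambda j: (j.chrom, j.start, j.end))
    df = pd.DataFrame(
        {
            "chrom": [j.chrom for j in rows],
            "intron_start": [j.start for j in rows],
            "intron_end": [j.end for j in rows],
            "strand": [j.strand for j in rows],
        }
    )
    if counts is not None and not counts.empty:
        df = df.join(counts.reset_index(drop=True))
    df.to_csv(path, sep="\t", index=False)


# -- sequence -------------------------------------------------------------


def spliced_sequence(chain: ExonChain, genome: Union[Fasta, Mapping[str, str]]) -> str:
    """Spliced transcript sequence, 5'->3'.

    Minus-strand exons are reverse-complemented; the concatenation follows
    transcript order so the result reads like the mature RNA (as DNA).
    """
    if isinstance(genome, Fasta):
        contig_len = len(genome[chain.chrom])
        fetch = lambda s, e: str(genome[chain.chrom][s - 1 : e])  # noqa: E731
    else:
        contig = genome[chain.chrom]
        contig_len = len(contig)
        fetch = lambda s, e: contig[s - 1 : e]  # noqa: E731
    parts = []
    for e in chain.exons:
        if e.end > contig_len:
            raise ValueError(f"exon {e} beyond end of contig {chain.chrom} ({contig_len} bp)")
        seq = fetch(e.start, e.end).upper()
        if chain.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        parts.append(seq)
    return "".join(parts)


def write_fasta(sequences: Mapping[str, str], path: Union[str, os.PathLike], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
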