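"""Synthetic two-gene locus with complete ground truth.

The generator emulates the study design the pipeline targets: a target gene
on the minus strand, a partner gene downstream of it, a readthrough gene
splicing exons of both together, per-sample caller GTF + quantification
pairs with terminus jitter and caller novelty labels, and the three external
reference sets (TSS peaks, polyA clusters, junction table).

Construction principle
----------------------
Gene-body filler sequence is drawn from {A, C} only, and every ATG and TAA
in the locus is planted explicitly at a designed position. Because start and
stop codons require T/G, the codon landscape of every transcript is fully
determined by the construction tables below, and each truth transcript's
ORF, protein length, NMD status and category are derived by coordinate
arithmetic — never by running the ORF scanner. That keeps the generator an
independent oracle for the analysis modules.

The truth catalog contains ten valid target-gene transcripts covering every
archetype the taxonomy distinguishes: the canonical coding model, a long/
short 3'UTR pair, a distal 5'-exon UTR variant, an in-frame exon skip, an
alternative-start shorter product, a frameshift exon skip whose premature
stop satisfies the >50-nt NMD rule (known and novel variants), a short-ORF
non-coding pair, a retained last intron with a downstream stop, plus a
readthrough transcript spanning both loci and the partner gene model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Seq import Seq

from .model import (
    ExonChain,
    GenomicInterval,
    LocusConfig,
    TranscriptCall,
)

__all__ = [
    "SimConfig",
    "TruthTranscript",
    "TruthCatalog",
    "SimulatedSamples",
    "build_truth",
    "simulate_samples",
    "write_truth",
    "write_samples",
    "DEFAULT_USAGE",
]

CHROM = "chrS"
TARGET_GENE = "GENA"
PARTNER_GENE = "GENB"
READTHROUGH_GENE = "GENA-GENB-RT"

# ---------------------------------------------------------------------------
# Sense-local construction tables. Coordinates are 1-based on the "sense"
# axis, which runs 5'->3' in transcript orientation; the genome stores the
# reverse complement, so sense position p maps to genomic 9301 - p on the
# minus strand (pad 500, sense length 8800).
# ---------------------------------------------------------------------------

_PAD = 500
_SENSE_LEN = 8800

E0 = (701, 850)
E1 = (1201, 1400)
E2 = (1701, 1950)  # 100 nt UTR + 150 nt CDS
E3 = (2301, 2480)
E4 = (2781, 2930)
E5 = (3431, 3551)  # 121 nt: skipping it shifts the frame by 1
E6 = (3852, 3940)  # 89 nt
I6 = (3941, 4340)  # retained-intron archetype keeps this
E7 = (4341, 4573)  # 33 nt CDS (incl. stop) + 200 nt UTR
B1 = (7201, 7400)
B2 = (7701, 7900)
B3 = (8201, 8500)

# planted codons (sense coordinates of the first base)
ATG_CANONICAL = 1801
ATG_ALT = 2301  # first codon of E3, in the canonical frame
TAA_SKIP_FRAME = 3882  # E6 offset 31: in-frame only after skipping E5
ATG_SHORT = 3893  # E6 offset 42: canonical frame, 26-aa product
TAA_CANONICAL = 4371  # E7 offset 31
TAA_RETAINED = 4061  # I6 offset 121: canonical frame
ATG_PARTNER = 7301
TAA_PARTNER = 8261  # B3 offset 61

_PLANTS = {
    ATG_CANONICAL: "ATGC",  # trailing C avoids spurious TGA at +1
    ATG_ALT: "ATGC",
    ATG_SHORT: "ATGC",
    ATG_PARTNER: "ATGC",
    TAA_SKIP_FRAME: "TAA",
    TAA_CANONICAL: "TAA",
    TAA_RETAINED: "TAA",
    TAA_PARTNER: "TAA",
}

# designed per-tissue usage fractions for the ten valid target transcripts;
# columns sum to 1 per tissue. Ratios are kept either >= 3x (tissue-specific
# by the 2x rule, with margin) or <= ~1.6x (safely non-specific).
DEFAULT_USAGE: Dict[str, Dict[str, float]] = {
    "canonical":    {"brain": 0.42,  "heart": 0.40, "blood": 0.30},
    "long_3utr":    {"brain": 0.08,  "heart": 0.10, "blood": 0.12},
    "distal_5exon": {"brain": 0.05,  "heart": 0.05, "blood": 0.05},
    "skip_e4":      {"brain": 0.02,  "heart": 0.02, "blood": 0.03},
    "alt_start":    {"brain": 0.06,  "heart": 0.05, "blood": 0.04},
    "ptc_known":    {"brain": 0.03,  "heart": 0.09, "blood": 0.03},
    "ptc_novel":    {"brain": 0.015, "heart": 0.02, "blood": 0.015},
    "short_known":  {"brain": 0.09,  "heart": 0.03, "blood": 0.03},
    "short_novel":  {"brain": 0.02,  "heart": 0.02, "blood": 0.06},
    "retained_i6":  {"brain": 0.215, "heart": 0.22, "blood": 0.325},
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the synthetic locus.

    ``utr_jitter_bp`` is the maximum *spread* between two jittered copies of
    one distal end: per-sample offsets are uniform integers in
    [-j//2, +j//2], matching the tolerance dimension of the merge criterion.
    ``forced_jitter`` overrides the spread for named transcripts and draws
    only the two extremes, which guarantees a controlled tolerance violation
    when set above the merge tolerance.
    """

    seed: int = 0
    n_samples: int = 50
    tissues: Tuple[str, ...] = ("brain", "heart", "blood")
    utr_jitter_bp: int = 20
    dropout: float = 0.2
    count_depth: int = 5000
    usage_profile: Optional[Mapping[str, Mapping[str, float]]] = None
    forced_jitter: Mapping[str, int] = field(default_factory=dict)
    tss_coverage: float = 0.7
    pas_coverage: float = 0.7
    junction_coverage: float = 0.7
    peak_halfwidth: int = 5

    def profile(self) -> Mapping[str, Mapping[str, float]]:
        return self.usage_profile if self.usage_profile is not None else DEFAULT_USAGE

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.utr_jitter_bp < 0:
            raise ValueError("utr_jitter_bp must be >= 0")
        prof = self.profile()
        for tissue in self.tissues:
            total = sum(prof[name][tissue] for name in prof)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"usage fractions for {tissue!r} sum to {total}, not 1")


def _sense_to_genomic(s: int, e: int) -> GenomicInterval:
    g = _PAD + _SENSE_LEN + 1  # sense p -> genomic g - p
    return GenomicInterval(CHROM, g - e, g - s, "-")


def _chain(sense_exons: Sequence[Tuple[int, int]]) -> ExonChain:
    # sense order is transcript order; genomic coordinates decrease on '-'
    return ExonChain([_sense_to_genomic(s, e) for s, e in sense_exons])


@dataclass(frozen=True)
class TruthTranscript:
    name: str
    gene: str
    sense_exons: Tuple[Tuple[int, int], ...]
    in_reference: bool
    orf_name: Optional[str]
    protein_length: Optional[int]
    nmd: bool
    category: Optional[str]
    tissue_specific: Optional[str]
    cds_sense: Tuple[Tuple[int, int], ...] = ()

    @property
    def chain(self) -> ExonChain:
        return _chain(self.sense_exons)

    @property
    def five_prime_genomic(self) -> int:
        return self.chain.five_prime

    @property
    def three_prime_genomic(self) -> int:
        return self.chain.three_prime


def _cds_len(blocks: Sequence[Tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in blocks)


# CDS block tables (sense coordinates, stop codon included)
_CDS = {
    "orf_canonical": ((1801, 1950), E3, E4, E5, E6, (4341, 4373)),
    "orf_skip_e4": ((1801, 1950), E3, E5, E6, (4341, 4373)),
    "orf_alt_start": (E3, E4, E5, E6, (4341, 4373)),
    "orf_frameshift": ((1801, 1950), E3, E4, (3852, 3884)),
    "orf_short": ((3893, 3940), (4341, 4373)),
    "orf_retained": ((1801, 1950), E3, E4, E5, (3852, 4063)),
    "orf_partner": ((7301, 7400), B2, (8201, 8263)),
}

# length-rank ids over the six detected target-gene ORFs: ranks follow
# descending protein length, ties to the 5'-most genomic CDS start
_EXPECTED_ORF_ID = {
    "orf_retained": f"{TARGET_GENE}_1_270aa",
    "orf_canonical": f"{TARGET_GENE}_2_240aa",
    "orf_skip_e4": f"{TARGET_GENE}_3_190aa",
    "orf_alt_start": f"{TARGET_GENE}_4_190aa",
    "orf_frameshift": f"{TARGET_GENE}_5_170aa",
    "orf_short": f"{TARGET_GENE}_6_26aa",
}


def _truth_transcripts() -> List[TruthTranscript]:
    full = (E1, E2, E3, E4, E5, E6)

    def t(name, exons, ref, orf, nmd, category, specific):
        plen = _cds_len(_CDS[orf]) // 3 - 1 if orf else None
        return TruthTranscript(
            name=name,
            gene=TARGET_GENE,
            sense_exons=tuple(exons),
            in_reference=ref,
            orf_name=orf,
            protein_length=plen,
            nmd=nmd,
            category=category,
            tissue_specific=specific,
            cds_sense=_CDS[orf] if orf else (),
        )

    return [
        t("canonical", (*full, E7), True, "orf_canonical", False, "Coding_Known", None),
        t("long_3utr", (*full, (4341, 4973)), False, "orf_canonical", False,
          "Novel_combination", None),
        t("distal_5exon", (E0, *full, (4341, 4423)), False, "orf_canonical", False,
          "Novel_3/5UTR_only", None),
        t("skip_e4", (E1, E2, E3, E5, E6, E7), False, "orf_skip_e4", False,
          "Novel_ORF_only", None),
        t("alt_start", ((901, 1400), E3, E4, E5, E6, E7), False, "orf_alt_start", False,
          "Novel_ORF_and_UTR", None),
        t("ptc_known", ((601, 1400), E2, E3, E4, E6, (4341, 5373)), True,
          "orf_frameshift", True, "NMD_Known", "heart"),
        t("ptc_novel", ((301, 1400), E2, E3, E4, E6, (4341, 5773)), False,
          "orf_frameshift", True, "NMD_Novel", None),
        t("short_known", ((3792, 3940), (4341, 4773)), True, "orf_short", False,
          "Non_coding_Known", "brain"),
        t("short_novel", ((3492, 3940), (4341, 5173)), False, "orf_short", False,
          "Non_coding_Novel", "blood"),
        t("retained_i6", (E1, E2, E3, E4, E5, (3852, 4573)), False, "orf_retained", False,
          "Novel_ORF_and_UTR", None),
    ]


def _partner_and_readthrough() -> Tuple[TruthTranscript, TruthTranscript]:
    partner = TruthTranscript(
        name="partner",
        gene=PARTNER_GENE,
        sense_exons=(B1, B2, B3),
        in_reference=True,
        orf_name="orf_partner",
        protein_length=_cds_len(_CDS["orf_partner"]) // 3 - 1,
        nmd=False,
        category=None,
        tissue_specific=None,
        cds_sense=_CDS["orf_partner"],
    )
    readthrough = TruthTranscript(
        name="readthrough",
        gene=READTHROUGH_GENE,
        sense_exons=(E1, E2, E3, B2, B3),
        in_reference=True,
        orf_name=None,  # its only start codons never reach an in-frame stop
        protein_length=None,
        nmd=False,
        category=None,
        tissue_specific=None,
    )
    return partner, readthrough


# reference-only model making the long 3'UTR known while pairing it with a
# distinct 5'UTR (so the detected pairing is a novel combination)
_REF_ALT_COMBO = TruthTranscript(
    name="ref_alt_combo",
    gene=TARGET_GENE,
    sense_exons=((1161, 1400), E2, E3, E4, E5, E6, (4341, 4973)),
    in_reference=True,
    orf_name="orf_canonical",
    protein_length=240,
    nmd=False,
    category=None,
    tissue_specific=None,
    cds_sense=_CDS["orf_canonical"],
)


@dataclass
class TruthCatalog:
    genome: Dict[str, str]
    locus: LocusConfig
    transcripts: List[TruthTranscript]  # the ten valid target models
    partner: TruthTranscript
    readthrough: TruthTranscript
    reference_only: List[TruthTranscript]
    tss_peaks: Set[GenomicInterval]
    pas_clusters: Set[GenomicInterval]
    junctions: Set[GenomicInterval]
    covered_tss: Set[str]  # truth names whose 5' end a peak covers
    covered_pas: Set[str]
    covered_junction_set: Set[GenomicInterval]

    def by_name(self, name: str) -> TruthTranscript:
        for t in [*self.transcripts, self.partner, self.readthrough, *self.reference_only]:
            if t.name == name:
                return t
        raise KeyError(name)

    def reference_calls(self) -> List[TranscriptCall]:
        """The reference annotation as caller-agnostic transcript models."""
        refs = [t for t in self.transcripts if t.in_reference]
        refs += [self.partner, self.readthrough, *self.reference_only]
        return [
            TranscriptCall(
                sample_id="",
                call_id=f"ref_{t.name}",
                gene_label=t.gene,
                exons=t.chain,
            )
            for t in refs
        ]

    def protein(self, name: str) -> str:
        """Construction-derived protein of a truth transcript (stop excluded)."""
        t = self.by_name(name)
        if not t.cds_sense:
            raise ValueError(f"{name} has no designed ORF")
        sense = self._sense
        cds = "".join(sense[s - 1 : e] for s, e in t.cds_sense)
        return str(Seq(cds[:-3]).translate())

    _sense: str = ""


def _build_sense(rng: np.random.Generator) -> str:
    """The sense-axis sequence: {A,C} filler plus planted codons."""
    filler = rng.choice(np.array(["A", "C"]), size=_SENSE_LEN)
    sense = bytearray("".join(filler), "ascii")
    for pos, motif in _PLANTS.items():
        sense[pos - 1 : pos - 1 + len(motif)] = motif.encode()
    out = sense.decode()
    # construction guarantee: every start/stop codon is planted
    planted_starts = {p for p, m in _PLANTS.items() if m.startswith("ATG")}
    found = {i + 1 for i in range(len(out)) if out.startswith("ATG", i)}
    if found != planted_starts:
        raise AssertionError("unplanned ATG in synthetic sense sequence")
    return out


def _exact_class_cover(
    classes: Dict[int, List[str]], k: int
) -> Tuple[Set[int], Set[str]]:
    """Choose end classes whose member counts sum exactly to ``k``.

    Ends shared between transcripts cannot be covered independently of each
    other at validation tolerance, so coverage is resolved per distal-end
    equivalence class with an exact subset-sum.
    """
    keys = sorted(classes, key=lambda p: (-len(classes[p]), p))
    sizes = [len(classes[p]) for p in keys]
    # DP subset-sum, reconstructing one solution
    reachable: List[Optional[Tuple[int, int]]] = [None] * (k + 1)  # total -> (idx, prev)
    reachable[0] = (-1, -1)
    for idx, size in enumerate(sizes):
        for total in range(k, size - 1, -1):
            if reachable[total] is None and reachable[total - size] is not None:
                reachable[total] = (idx, total - size)
    if reachable[k] is None:
        raise ValueError(f"no subset of end classes reaches exactly {k} transcripts")
    chosen: Set[int] = set()
    total = k
    while total > 0:
        idx, prev = reachable[total]  # type: ignore[misc]
        chosen.add(idx)
        total = prev
    positions = {keys[i] for i in chosen}
    names = {n for p in positions for n in classes[p]}
    return positions, names


def build_truth(cfg: SimConfig = SimConfig()) -> TruthCatalog:
    """Deterministically build the locus, its truth catalog and reference sets."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sense = _build_sense(rng)
    genome_seq = (
        "".join(rng.choice(np.array(["A", "C"]), size=_PAD))
        + str(Seq(sense).reverse_complement())
        + "".join(rng.choice(np.array(["A", "C"]), size=_PAD))
    )

    transcripts = _truth_transcripts()
    partner, readthrough = _partner_and_readthrough()

    locus = LocusConfig(
        target_locus=_sense_to_genomic(701, 5773),
        partner_locus=_sense_to_genomic(7201, 8500),
        target_gene_id=TARGET_GENE,
        readthrough_gene_id=READTHROUGH_GENE,
    )

    # distal-end equivalence classes (genomic positions)
    tss_classes: Dict[int, List[str]] = {}
    pas_classes: Dict[int, List[str]] = {}
    for t in transcripts:
        tss_classes.setdefault(t.five_prime_genomic, []).append(t.name)
        pas_classes.setdefault(t.three_prime_genomic, []).append(t.name)

    n = len(transcripts)
    hw = cfg.peak_halfwidth
    tss_positions, covered_tss = _exact_class_cover(tss_classes, round(cfg.tss_coverage * n))
    pas_positions, covered_pas = _exact_class_cover(pas_classes, round(cfg.pas_coverage * n))
    tss_peaks = {GenomicInterval(CHROM, p - hw, p + hw, "-") for p in tss_positions}
    pas_clusters = {GenomicInterval(CHROM, p - hw, p + hw, "-") for p in pas_positions}

    all_junctions = sorted(
        {j for t in transcripts for j in t.chain.introns()},
        key=lambda j: (j.start, j.end),
    )
    k_j = round(cfg.junction_coverage * len(all_junctions))
    covered_junctions = set(all_junctions[:k_j])

    catalog = TruthCatalog(
        genome={CHROM: genome_seq},
        locus=locus,
        transcripts=transcripts,
        partner=partner,
        readthrough=readthrough,
        reference_only=[_REF_ALT_COMBO],
        tss_peaks=tss_peaks,
        pas_clusters=pas_clusters,
        junctions=covered_junctions,
        covered_tss=covered_tss,
        covered_pas=covered_pas,
        covered_junction_set=covered_junctions,
    )
    catalog._sense = sense
    return catalog


# ---------------------------------------------------------------------------
# per-sample simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSamples:
    calls: List[TranscriptCall]
    quant: Dict[Tuple[str, str], int]
    sample_tissue: Dict[str, str]

    def calls_of(self, sample: str) -> List[TranscriptCall]:
        return [c for c in self.calls if c.sample_id == sample]


def _jitter_chain(chain: ExonChain, d5: int, d3: int) -> ExonChain:
    """Shift the two distal termini; splice sites are never touched."""
    exons = list(chain.exons)
    first, last = exons[0], exons[-1]
    if chain.strand == "-":
        exons[0] = replace(first, end=first.end + d5)
        exons[-1] = replace(last, start=last.start - d3)
    else:
        exons[0] = replace(first, start=first.start - d5)
        exons[-1] = replace(last, end=last.end + d3)
    return ExonChain(exons)


def simulate_samples(truth: TruthCatalog, cfg: SimConfig = SimConfig()) -> SimulatedSamples:
    """Draw per-sample transcript calls, counts and tissue labels.

    Each truth transcript is detected with probability 1 - dropout; detected
    transcripts receive >= 1 read and the sample's remaining depth is
    multinomial over the tissue's designed usage fractions (renormalised to
    the detected set). Distal UTR ends are jittered within the configured
    spread; one unspliced "Genomic" decoy and one "Antisense" decoy per
    sample exercise the artifact filter.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    profile = cfg.profile()
    names = [t.name for t in truth.transcripts]

    tissues = [cfg.tissues[i % len(cfg.tissues)] for i in range(cfg.n_samples)]
    sample_ids = [f"s{i:03d}" for i in range(cfg.n_samples)]
    sample_tissue = dict(zip(sample_ids, tissues))

    calls: List[TranscriptCall] = []
    quant: Dict[Tuple[str, str], int] = {}
    forced_counter: Dict[str, int] = {}

    for sample, tissue in zip(sample_ids, tissues):
        detected = [n for n in names if rng.random() >= cfg.dropout]
        if not detected:  # resample once, then warn
            detected = [n for n in names if rng.random() >= cfg.dropout]
            if not detected:
                warnings.warn(f"sample {sample} detected no target transcript")
        depth = max(int(rng.poisson(cfg.count_depth)), len(detected))
        if detected:
            probs = np.array([profile[n][tissue] for n in detected])
            probs = probs / probs.sum()
            counts = rng.multinomial(depth - len(detected), probs) + 1
        else:
            counts = np.array([], dtype=int)

        for name, count in zip(detected, counts):
            t = truth.by_name(name)
            if name in cfg.forced_jitter:
                half = cfg.forced_jitter[name] // 2
                idx = forced_counter.get(name, 0)
                forced_counter[name] = idx + 1
                d5 = d3 = (-half, half)[idx % 2]
            else:
                half = cfg.utr_jitter_bp // 2
                d5 = int(rng.integers(-half, half + 1)) if half else 0
                d3 = int(rng.integers(-half, half + 1)) if half else 0
            call_id = f"{name}@{sample}"
            calls.append(
                TranscriptCall(
                    sample_id=sample,
                    call_id=call_id,
                    gene_label=t.gene,
                    exons=_jitter_chain(t.chain, d5, d3),
                    caller_status="Known" if t.in_reference else "Novel",
                    gene_status="Known",
                    read_count=int(count),
                )
            )
            quant[(sample, call_id)] = int(count)

        # partner and readthrough expression (outside the usage denominator)
        for t, rate in ((truth.partner, 0.5), (truth.readthrough, 0.02)):
            count = int(rng.poisson(rate * cfg.count_depth))
            if t is truth.partner:
                count = max(count, 1)
            if count > 0:
                call_id = f"{t.name}@{sample}"
                calls.append(
                    TranscriptCall(
                        sample_id=sample,
                        call_id=call_id,
                        gene_label=t.gene,
                        exons=t.chain,
                        caller_status="Known",
                        gene_status="Known",
                        read_count=count,
                    )
                )
                quant[(sample, call_id)] = count

        # caller artifacts the pipeline must remove
        decoys = [
            TranscriptCall(
                sample_id=sample,
                call_id=f"genomic_decoy@{sample}",
                gene_label=TARGET_GENE,
                exons=ExonChain([_sense_to_genomic(3000, 3400)]),
                caller_status="Genomic",
                gene_status="Known",
                read_count=3,
            ),
            TranscriptCall(
                sample_id=sample,
                call_id=f"antisense_decoy@{sample}",
                gene_label="GENA-AS1",
                exons=ExonChain([GenomicInterval(CHROM, 4000, 4400, "+")]),
                caller_status="Novel",
                gene_status="Antisense",
                read_count=2,
            ),
        ]
        for d in decoys:
            calls.append(d)
            quant[(d.sample_id, d.call_id)] = d.read_count

    return SimulatedSamples(calls=calls, quant=quant, sample_tissue=sample_tissue)


# ---------------------------------------------------------------------------
# file emission (everything is plain text)
# ---------------------------------------------------------------------------


def write_truth(truth: TruthCatalog, outdir) -> None:
    """Emit genome.fa, ref.gtf, tss.bed, pas.bed, junctions.tsv, truth tables."""
    import os

    import pandas as pd

    from .io import write_bed_intervals, write_fasta, write_gtf, write_junction_table

    os.makedirs(outdir, exist_ok=True)
    join = lambda f: os.path.join(outdir, f)  # noqa: E731
    write_fasta(truth.genome, join("genome.fa"))
    write_gtf(truth.reference_calls(), join("ref.gtf"))
    write_bed_intervals(truth.tss_peaks, join("tss.bed"), name="tss")
    write_bed_intervals(truth.pas_clusters, join("pas.bed"), name="pas")
    write_junction_table(truth.junctions, join("junctions.tsv"))
    rows = [
        {
            "name": t.name,
            "gene": t.gene,
            "in_reference": t.in_reference,
            "orf": t.orf_name or "noORF",
            "expected_orf_id": _EXPECTED_ORF_ID.get(t.orf_name, "noORF"),
            "protein_length_aa": t.protein_length if t.protein_length is not None else 0,
            "nmd": t.nmd,
            "category": t.category or "",
            "tissue_specific": t.tissue_specific or "",
            "tss_covered": t.name in truth.covered_tss,
            "pas_covered": t.name in truth.covered_pas,
        }
        for t in truth.transcripts
    ]
    pd.DataFrame(rows).to_csv(join("truth_transcripts.tsv"), sep="\t", index=False)
    usage_rows = [
        {"name": name, **fractions} for name, fractions in DEFAULT_USAGE.items()
    ]
    pd.DataFrame(usage_rows).to_csv(join("truth_usage.tsv"), sep="\t", index=False)


def write_samples(sim: SimulatedSamples, outdir) -> None:
    """One caller GTF + quant TSV per sample, plus the sample metadata table."""
    import os

    import pandas as pd

    from .io import write_gtf, write_quant

    os.makedirs(outdir, exist_ok=True)
    for sample in sorted(sim.sample_tissue):
        sample_calls = sim.calls_of(sample)
        write_gtf(sample_calls, os.path.join(outdir, f"{sample}.gtf"))
        write_quant(
            {k: v for k, v in sim.quant.items() if k[0] == sample},
            os.path.join(outdir, f"{sample}.quant.tsv"),
        )
    pd.DataFrame(
        [{"sample_id": s, "tissue": t} for s, t in sorted(sim.sample_tissue.items())]
    ).to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)


def expected_orf_id(orf_name: Optional[str]) -> str:
    """Construction-derived length-rank id for a designed ORF."""
    if orf_name is None:
        return "noORF"
    return _EXPECTED_ORF_ID[orf_name]
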