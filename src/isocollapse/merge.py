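"""Cross-sample transcript merging with tolerance-based UTR identity.

Long-read callers emit per-sample transcript models whose splice sites are
already corrected but whose 5'/3' termini wobble by a few bases. Two calls
describe the same transcript when they share (a) the same ORF, (b) the same
proximal UTR internal boundaries, and (c) distal UTR ends within a fixed
tolerance (20 bp by default). UTR clustering is *anchored*: every member is
compared against its cluster's anchor, which bounds cluster diameter and
prevents single-linkage drift (A-B 20 bp plus B-C 20 bp never unifies an
A-C 40 bp pair).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .model import MergedTranscript, MergeParams, TranscriptCall, UtrRecord
from .orfs import TranscriptDecomposition

__all__ = ["AnnotatedCall", "cluster_utrs", "merge_calls", "filter_valid"]

NO_ORF_ID = "noORF"


@dataclass
class AnnotatedCall:
    """A transcript call plus its ORF/UTR identities, ready to merge."""

    call: TranscriptCall
    decomposition: TranscriptDecomposition
    orf_id: Optional[str] = None
    utr5_id: Optional[str] = None
    utr3_id: Optional[str] = None


def cluster_utrs(
    utrs: Sequence[UtrRecord],
    side: str,
    params: MergeParams = MergeParams(),
    support: Optional[Sequence[float]] = None,
) -> List[str]:
    """Assign a UTR id to each record; same id = same UTR.

    Two records share an id iff their internal boundaries are identical and
    their distal ends lie within ``end_tolerance`` (inclusive) of the cluster
    anchor. Anchors are chosen greedily over records ordered by support
    (descending) then coordinate, so the numbering is deterministic under
    input permutation. Ids are ``{side}UTR_{n}`` with n counting anchors from
    1; empty UTRs all receive the reserved ``{side}UTR_0``.
    """
    if side not in ("5", "3"):
        raise ValueError("side must be '5' or '3'")
    for u in utrs:
        if u.side != side:
            raise ValueError(f"mixed UTR sides: expected {side}, got {u.side}")
    if support is None:
        support = [0.0] * len(utrs)
    if len(support) != len(utrs):
        raise ValueError("support must align with utrs")

    order = sorted(
        range(len(utrs)),
        key=lambda i: (
            -support[i],
            utrs[i].distal_end if utrs[i].distal_end is not None else 0,
            utrs[i].internal_boundaries,
        ),
    )
    # anchors[key] -> list of (anchor_distal, cluster_id)
    anchors: Dict[Tuple, List[Tuple[int, str]]] = defaultdict(list)
    ids: List[Optional[str]] = [None] * len(utrs)
    n_clusters = 0
    for i in order:
        u = utrs[i]
        if u.is_empty:
            ids[i] = f"{side}UTR_0"
            continue
        assigned = None
        for anchor_distal, cid in anchors[u.cluster_key]:
            if abs(u.distal_end - anchor_distal) <= params.end_tolerance:
                assigned = cid
                break
        if assigned is None:
            n_clusters += 1
            assigned = f"{side}UTR_{n_clusters}"
            anchors[u.cluster_key].append((u.distal_end, assigned))
        ids[i] = assigned
    return ids  # type: ignore[return-value]


def annotate_utr_ids(calls: Sequence[AnnotatedCall], params: MergeParams = MergeParams()) -> None:
    """Cluster both UTR sides across calls and stamp the ids in place.

    Support for anchor ordering is the call's read count, so the most
    supported end of each UTR family defines its reference coordinate.
    """
    weights = [float(c.call.read_count) for c in calls]
    for side, attr in (("5", "utr5_id"), ("3", "utr3_id")):
        records = [getattr(c.decomposition, f"utr{side}") for c in calls]
        for c, cid in zip(calls, cluster_utrs(records, side, params, weights)):
            setattr(c, attr, cid)


def merge_calls(calls: Sequence[AnnotatedCall]) -> List[MergedTranscript]:
    """Group annotated calls by their (ORF, 5'UTR, 3'UTR) identity triple.

    The composite id concatenates the three ids; occurrence counts distinct
    samples; the representative exon chain comes from the member with the
    highest read count (ties to the lexicographically first member).
    """
    for c in calls:
        if c.orf_id is None or c.utr5_id is None or c.utr3_id is None:
            raise ValueError(f"call {c.call.call_id!r} is missing ORF/UTR ids")
    groups: Dict[Tuple[str, str, str], List[AnnotatedCall]] = defaultdict(list)
    for c in calls:
        groups[(c.orf_id, c.utr5_id, c.utr3_id)].append(c)

    merged = []
    for (orf_id, u5, u3), members in sorted(groups.items()):
        members = sorted(members, key=lambda c: (c.call.sample_id, c.call.call_id))
        rep = max(members, key=lambda c: (c.call.read_count, c.call.sample_id, c.call.call_id))
        member_calls = tuple((c.call.sample_id, c.call.call_id) for c in members)
        merged.append(
            MergedTranscript(
                composite_id=f"{orf_id}_{u5}_{u3}",
                orf_id=orf_id,
                utr5_id=u5,
                utr3_id=u3,
                member_calls=member_calls,
                occurrence=len({s for s, _ in member_calls}),
                representative_exons=rep.decomposition.chain,
                representative_member=(rep.call.sample_id, rep.call.call_id),
                representative_orf=(
                    rep.decomposition.orf.with_id(orf_id)
                    if rep.decomposition.orf is not None
                    else None
                ),
                nmd=rep.decomposition.nmd,
            )
        )
    return merged


def filter_valid(
    merged: Sequence[MergedTranscript], min_occurrence: int = 3
) -> Tuple[List[MergedTranscript], List[MergedTranscript]]:
    """Split merged transcripts into valid (occurrence >= threshold) and minor.

    Sub-threshold transcripts are returned, not dropped: rare isoforms (for
    example disease-associated ones seen once) are still reportable.
    """
    valid = [m for m in merged if m.occurrence >= min_occurrence]
    minor = [m for m in merged if m.occurrence < min_occurrence]
    return valid, minor
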