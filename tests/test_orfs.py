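"""ORF scanning against a brute-force oracle, UTR tiling and the NMD rule."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocollapse.model import ExonChain, GenomicInterval, OrfParams
from isocollapse.orfs import (
    OrfCandidate,
    assign_orf_ids,
    decompose,
    extract_utrs,
    find_orfs,
    predict_nmd,
    select_orf,
)

from conftest import chain

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq, longest_per_stop=True):
    """Independent enumeration of every in-frame ATG..first-stop pair."""
    seq = seq.upper()
    pairs = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                pairs.append((i + 1, j + 3))
                break
            j += 3
    if longest_per_stop:
        best = {}
        for s, e in pairs:
            if e not in best or s < best[e]:
                best[e] = s
        pairs = [(s, e) for e, s in best.items()]
    return sorted(pairs)


def as_pairs(cands):
    return sorted((c.tx_start, c.tx_end) for c in cands)


class TestFindOrfs:
    def test_hand_translatable_example(self):
        (orf,) = find_orfs("ATGAAATGA")
        assert (orf.tx_start, orf.tx_end, orf.nt_length) == (1, 9, 9)

    def test_nested_start_sharing_stop_discarded(self):
        (orf,) = find_orfs("ATGATGTAA")
        assert (orf.tx_start, orf.tx_end) == (1, 9)

    def test_no_orf_gives_empty(self):
        assert find_orfs("CCCCCCCC") == []

    def test_n_codons_never_match(self):
        assert find_orfs("ANGAAATAA") == []
        # N inside the body is fine; N in the stop is not
        assert find_orfs("ATGAAATNA") == []

    def test_matches_oracle_on_random_sequences(self):
        rng = random.Random(42)
        for _ in range(300):
            seq = "".join(rng.choice("ACGT") for _ in range(120))
            assert as_pairs(find_orfs(seq)) == brute_force_orfs(seq)

    def test_matches_oracle_without_per_stop_filter(self):
        rng = random.Random(7)
        p = OrfParams(longest_per_stop=False)
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(90))
            assert as_pairs(find_orfs(seq, p)) == brute_force_orfs(seq, longest_per_stop=False)


class TestSelectOrf:
    def test_longest_candidate_wins(self):
        seq = "ATGTAACCCATGAAAAAAAAATAA"  # 6-nt ORF then 15-nt ORF
        c = chain((1, len(seq)))
        orf = select_orf(find_orfs(seq), c, seq)
        assert orf.tx_end - orf.tx_start + 1 == 15
        assert orf.protein_seq.startswith("M")

    def test_tie_breaks_to_most_five_prime_start(self):
        cands = [OrfCandidate(10, 18), OrfCandidate(1, 9)]
        seq = "ATGAAATAAATGAAATAA"
        orf = select_orf(cands, chain((1, 18)), seq)
        assert orf.tx_start == 1

    def test_no_candidates_gives_none(self):
        assert select_orf([], chain((1, 9)), "CCCCCCCCC") is None

    def test_cds_blocks_match_per_base_projection_oracle(self):
        # CDS spans an exon junction on the minus strand
        c = chain((101, 130), (51, 70), (11, 30), strand="-")
        seq = "C" * c.tx_length
        orf = select_orf([OrfCandidate(25, 45)], c, seq)
        oracle = [c.genomic_position(p) for p in range(25, 46)]
        projected = [
            pos
            for b in orf.cds_blocks
            for pos in (range(b.end, b.start - 1, -1))  # minus strand: 5'->3'
        ]
        assert projected == oracle
        assert sum(b.length for b in orf.cds_blocks) == 21

    def test_protein_length_accounts_cds_codons_minus_stop(self):
        rng = random.Random(5)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(150))
            c = chain((1, 150))
            orf = select_orf(find_orfs(seq), c, seq)
            if orf is not None:
                assert orf.protein_length * 3 + 3 == orf.tx_end - orf.tx_start + 1


class TestUtrs:
    def test_cds_at_base_one_gives_empty_five_utr(self):
        seq = "ATGAAATAACCC"
        c = chain((1, 12))
        orf = select_orf(find_orfs(seq), c, seq)
        utr5, utr3 = extract_utrs(c, orf)
        assert utr5.is_empty
        assert not utr3.is_empty

    def test_single_exon_middle_cds_gives_single_block_utrs(self):
        seq = "CCCATGAAATAACCC"
        c = chain((101, 115))
        orf = select_orf(find_orfs(seq), c, seq)
        utr5, utr3 = extract_utrs(c, orf)
        assert [(b.start, b.end) for b in utr5.blocks] == [(101, 103)]
        assert [(b.start, b.end) for b in utr3.blocks] == [(113, 115)]
        assert utr5.distal_end == 101 and utr3.distal_end == 115

    def test_multi_exon_five_utr_blocks_match_complement_oracle(self):
        # CDS starts inside exon 2
        c = chain((1, 50), (101, 200))
        seq = "C" * 60 + "ATG" + "A" * 30 + "TAA" + "C" * (c.tx_length - 96)
        orf = select_orf(find_orfs(seq), c, seq)
        assert orf.tx_start == 61
        utr5, _ = extract_utrs(c, orf)
        assert [(b.start, b.end) for b in utr5.blocks] == [(1, 50), (101, 110)]

    def test_utrs_and_cds_tile_the_exon_chain_exactly(self):
        rng = random.Random(11)
        for _ in range(40):
            seq = "".join(rng.choice("ACGT") for _ in range(180))
            c = chain((1, 60), (101, 160), (201, 260))
            orf = select_orf(find_orfs(seq), c, seq)
            if orf is None:
                continue
            utr5, utr3 = extract_utrs(c, orf)
            covered = []
            for block in (*utr5.blocks, *orf.cds_blocks, *utr3.blocks):
                covered.extend(range(block.start, block.end + 1))
            exonic = [p for e in c.exons for p in range(e.start, e.end + 1)]
            assert sorted(covered) == sorted(exonic)
            assert len(covered) == len(set(covered))


class TestNmd:
    @pytest.mark.parametrize("distance,expected", [(49, False), (50, False), (51, True)])
    def test_fifty_nt_rule_boundary(self, distance, expected):
        # stop codon ends `distance` nt upstream of the last junction
        first_len = 3 + 9 + 3 + distance  # ATG + body + TAA + spacer
        c = chain((1, first_len), (first_len + 101, first_len + 200))
        seq = "ATG" + "AAA" * 3 + "TAA" + "C" * distance + "C" * 100
        orf = select_orf(find_orfs(seq), c, seq)
        assert orf.tx_end == 15
        assert predict_nmd(c, orf) is expected

    def test_single_exon_never_nmd(self):
        seq = "ATGAAATAA" + "C" * 100
        c = chain((1, 109))
        orf = select_orf(find_orfs(seq), c, seq)
        assert predict_nmd(c, orf) is False

    def test_invariant_to_upstream_exons(self):
        tail = "C" * 60 + "C" * 100
        seq = "ATG" + "AAA" * 3 + "TAA" + tail
        c1 = chain((1, 75), (201, 300))
        orf1 = select_orf(find_orfs(seq), c1, seq)
        # same transcript with the first exon split in the 5'UTR-free region:
        # stop-to-last-junction distance is unchanged
        seq2 = "CCC" + seq
        c2 = chain((501, 503), (601, 675), (801, 900))
        orf2 = select_orf(find_orfs(seq2), c2, seq2)
        assert predict_nmd(c1, orf1) == predict_nmd(c2, orf2) is True


class TestOrfIds:
    def _orf(self, start, plen, chrom="chr1", strand="+"):
        nt = (plen + 1) * 3
        from isocollapse.model import OrfRecord

        return OrfRecord(
            tx_start=1,
            tx_end=nt,
            cds_blocks=(GenomicInterval(chrom, start, start + nt - 1, strand),),
            protein_length=plen,
            protein_seq="M" * plen,
        )

    def test_ranks_follow_descending_length(self):
        orfs = [self._orf(1000, 438), self._orf(2000, 489), self._orf(3000, 181)]
        ids = assign_orf_ids(orfs, "GENE")
        assert ids[orfs[1].block_key] == "GENE_1_489aa"
        assert ids[orfs[0].block_key] == "GENE_2_438aa"
        assert ids[orfs[2].block_key] == "GENE_3_181aa"

    def test_id_format_matches_field_convention(self):
        import re

        (orf,) = [self._orf(100, 438)]
        ids = assign_orf_ids([orf], "CLN3")
        m = re.fullmatch(r"(\w+)_(\d+)_(\d+)aa", ids[orf.block_key])
        assert m.group(1) == "CLN3" and int(m.group(3)) == 438
        # the convention decodes published ids the same way
        rank, length = re.fullmatch(r"CLN3_(\d+)_(\d+)aa", "CLN3_24_438aa").groups()
        assert (int(rank), int(length)) == (24, 438)

    def test_equal_length_orfs_get_distinct_deterministic_ranks(self):
        orfs = [self._orf(5000, 200), self._orf(1000, 200), self._orf(3000, 200)]
        ids = assign_orf_ids(orfs, "G")
        assert sorted(ids.values()) == ["G_1_200aa", "G_2_200aa", "G_3_200aa"]
        for perm in itertools.permutations(orfs):
            assert assign_orf_ids(list(perm), "G") == ids
        # 5'-most start ranks first among equals
        assert ids[orfs[1].block_key] == "G_1_200aa"


@given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
@settings(deadline=None, max_examples=300)
def test_find_orfs_equals_oracle_property(seq):
    assert as_pairs(find_orfs(seq)) == brute_force_orfs(seq)
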