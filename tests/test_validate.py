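"""End/junction validation rules, detection rates and peptide uniqueness."""

import numpy as np
import pandas as pd
import pytest

from isocollapse.model import GenomicInterval, MergedTranscript, ValidationParams
from isocollapse.validate import (
    exon_identity_screen,
    junction_detection_rates,
    unique_peptides,
    validate_junctions,
    validate_pas,
    validate_tss,
)

from conftest import chain


def merged(exon_chain, cid="m1"):
    return MergedTranscript(
        composite_id=cid,
        orf_id="o",
        utr5_id="5UTR_1",
        utr3_id="3UTR_1",
        member_calls=(("s1", cid),),
        occurrence=1,
        representative_exons=exon_chain,
    )


def peak(start, end, strand="+"):
    return GenomicInterval("chr1", start, end, strand)


class TestEndValidation:
    def test_five_prime_end_inside_peak_validates(self):
        m = merged(chain((100, 200)))
        flags, frac = validate_tss([m], [peak(90, 110)])
        assert flags["m1"] and frac == 1.0

    def test_fifty_one_bp_away_fails(self):
        m = merged(chain((100, 200)))
        flags, _ = validate_tss([m], [peak(20, 49)])
        assert not flags["m1"]
        flags, _ = validate_tss([m], [peak(20, 50)])
        assert flags["m1"]

    def test_strand_must_be_compatible(self):
        m = merged(chain((100, 200)))
        assert not validate_tss([m], [peak(95, 105, "-")])[0]["m1"]
        assert validate_tss([m], [peak(95, 105, ".")])[0]["m1"]

    def test_three_prime_end_for_pas(self):
        m = merged(chain((100, 200), strand="+"))
        assert validate_pas([m], [peak(195, 260)])[0]["m1"]
        assert not validate_pas([m], [peak(260, 400)])[0]["m1"]

    def test_empty_reference_warns_and_fails_all(self):
        m = merged(chain((100, 200)))
        with pytest.warns(UserWarning):
            flags, frac = validate_tss([m], [])
        assert frac == 0.0

    def test_flags_monotone_in_tolerance(self):
        rng = np.random.default_rng(0)
        ms = [merged(chain((int(s), int(s) + 50)), cid=f"m{i}") for i, s in
              enumerate(rng.integers(100, 2000, size=20))]
        peaks = [peak(int(p), int(p) + 10) for p in rng.integers(100, 2000, size=10)]
        previous = 0.0
        for tol in (0, 10, 25, 50, 200, 5000):
            _, frac = validate_tss(ms, peaks, ValidationParams(tss_tolerance=tol))
            assert frac >= previous
            previous = frac


class TestJunctions:
    def test_exact_match_and_one_bp_shift(self):
        m = merged(chain((100, 200), (301, 400)))
        intron = GenomicInterval("chr1", 201, 300, "+")
        matched, unmatched = validate_junctions([m], [intron])
        assert [j.start for j in matched] == [201] and unmatched == []
        shifted = GenomicInterval("chr1", 202, 300, "+")
        matched, unmatched = validate_junctions([m], [shifted])
        assert matched == [] and len(unmatched) == 1

    def test_self_reference_matches_everything(self, truth):
        ms = [merged(t.chain, cid=t.name) for t in truth.transcripts]
        all_introns = {j for t in truth.transcripts for j in t.chain.introns()}
        matched, unmatched = validate_junctions(ms, all_introns)
        assert unmatched == []
        assert len(matched) == len(all_introns)


class TestDetectionRates:
    def test_small_example(self):
        counts = pd.DataFrame([[0, 0, 2]], index=["j1"], columns=["a", "b", "c"])
        df = junction_detection_rates(counts, {"a": "t", "b": "t", "c": "t"})
        row = df[(df.junction == "j1") & (df.tissue == "t")].iloc[0]
        assert row.detection_rate == pytest.approx(1 / 3)
        assert row.mean_count == pytest.approx(2 / 3)

    def test_all_zero(self):
        counts = pd.DataFrame([[0, 0]], index=["j"], columns=["a", "b"])
        df = junction_detection_rates(counts, {"a": "x", "b": "x"})
        row = df[(df.junction == "j") & (df.tissue == "x")].iloc[0]
        assert row.detection_rate == 0.0 and row.mean_count == 0.0

    def test_matches_independent_tabulation_on_poisson_counts(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(30)]
        tissue = {s: ("brain" if i < 12 else "heart") for i, s in enumerate(samples)}
        counts = pd.DataFrame(
            rng.poisson(0.8, size=(6, 30)), index=[f"j{i}" for i in range(6)], columns=samples
        )
        df = junction_detection_rates(counts, tissue)
        for j in counts.index:
            for t in ("brain", "heart"):
                cols = [s for s in samples if tissue[s] == t]
                sub = counts.loc[j, cols]
                row = df[(df.junction == j) & (df.tissue == t)].iloc[0]
                assert row.detection_rate == pytest.approx((sub > 0).sum() / len(cols))
                assert row.mean_count == pytest.approx(sub.mean())
            glob = df[(df.junction == j) & (df.tissue == "__all__")].iloc[0]
            means = [counts.loc[j, [s for s in samples if tissue[s] == t]].mean()
                     for t in ("brain", "heart")]
            assert glob.min_tissue_mean == pytest.approx(min(means))
            assert glob.max_tissue_mean == pytest.approx(max(means))


class TestExonIdentity:
    def test_shared_exons_between_target_and_readthrough(self, truth):
        target = truth.by_name("canonical").chain.exons
        rt = truth.readthrough.chain.exons
        pairs = exon_identity_screen(target, rt, truth.genome)
        # the readthrough transcript reuses three target-gene exons verbatim
        identical = {(a.start, a.end) for a, b in pairs if (a.start, a.end) == (b.start, b.end)}
        assert len(identical) >= 3

    def test_substitution_breaks_identity(self):
        genome = {"chr1": "AACGTACGTACC"}
        a = GenomicInterval("chr1", 1, 4, "+")
        b = GenomicInterval("chr1", 5, 8, "+")  # GTAC != AACG
        assert exon_identity_screen([a], [b], genome) == []

    def test_self_screen_matches_every_exon(self, truth):
        exons = truth.by_name("canonical").chain.exons
        pairs = exon_identity_screen(exons, exons, truth.genome)
        self_pairs = {(a, b) for a, b in pairs if a == b}
        assert len(self_pairs) == len(exons)


class TestUniquePeptides:
    def test_identical_background_leaves_nothing(self):
        p = "MKTAYIAKQRQISFVKSHFSR"
        assert unique_peptides(p, [p]) == []

    def test_frameshift_isoform_peptides_overlap_novel_segment(self, truth):
        canonical = truth.protein("canonical")
        frameshift = truth.protein("ptc_novel")
        shared = 160  # designed length of the shared N-terminal stretch
        assert frameshift[:shared] == canonical[:shared]
        unique = unique_peptides(frameshift, [canonical])
        assert unique, "the frameshift isoform must expose at least one unique peptide"
        for pep in unique:
            start = frameshift.find(pep)
            assert start + len(pep) > shared  # reaches into the novel segment
            assert pep not in canonical

    def test_output_disjoint_from_background_substrings(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        bg = ["".join(rng.choice(list(aas), 80)) for _ in range(3)]
        iso = bg[0][:40] + "".join(rng.choice(list(aas), 40))
        for pep in unique_peptides(iso, bg):
            assert all(pep not in b for b in bg)
            assert pep in iso

    def test_cleavage_rule_no_cut_before_proline(self):
        # K before P is not a cleavage site; with no other site the whole
        # chain stays intact
        peps = unique_peptides("AAAKPAAAK", [])
        assert peps == ["AAAKPAAAK"]
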