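"""Usage statistics, structural novelty and the category cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isocollapse import classify as clf
from isocollapse.classify import (
    CATEGORIES,
    NoveltyFlags,
    build_reference_structures,
    classify,
    median_usage,
    novelty,
    orf_usage,
    tissue_specific,
    usage,
)
from isocollapse.model import ClassifyParams, MergeParams
from isocollapse.orfs import decompose
from isocollapse.io import spliced_sequence


def usage_df(data, samples=None):
    return pd.DataFrame(data, index=samples).T if samples else pd.DataFrame(data).T


class TestUsage:
    def _merged(self, members):
        """members: composite_id -> list of (sample, call)"""
        from isocollapse.merge import AnnotatedCall, merge_calls
        from isocollapse.model import TranscriptCall
        from conftest import chain

        genome = {"chr1": "C" * 40}
        annotated = []
        for cid, mems in members.items():
            for s, c in mems:
                call = TranscriptCall(sample_id=s, call_id=c, gene_label="g", exons=chain((1, 30)))
                a = AnnotatedCall(call=call, decomposition=decompose(call.exons, spliced_sequence(call.exons, genome)))
                a.orf_id, a.utr5_id, a.utr3_id = cid, "5UTR_1", "3UTR_1"
                annotated.append(a)
        return merge_calls(annotated)

    def test_single_transcript_takes_all_usage(self):
        merged = self._merged({"a": [("s1", "t1")]})
        u = usage(merged, {("s1", "t1"): 17})
        assert u.loc[merged[0].composite_id, "s1"] == 1.0

    def test_fractions_follow_counts(self):
        merged = self._merged({"a": [("s1", "t1")], "b": [("s1", "t2")]})
        u = usage(merged, {("s1", "t1"): 30, ("s1", "t2"): 70})
        by_orf = {m.orf_id: m.composite_id for m in merged}
        assert u.loc[by_orf["a"], "s1"] == pytest.approx(0.3)
        assert u.loc[by_orf["b"], "s1"] == pytest.approx(0.7)

    def test_zero_locus_sample_is_undefined(self):
        merged = self._merged({"a": [("s1", "t1"), ("s2", "t1")]})
        u = usage(merged, {("s1", "t1"): 10, ("s2", "t1"): 0})
        assert u["s2"].isna().all()
        assert u["s1"].sum() == pytest.approx(1.0)


class TestMedianUsage:
    def test_single_sample(self):
        u = pd.DataFrame({"s1": [0.4]}, index=["t"])
        assert median_usage("t", u) == pytest.approx(0.4)

    def test_odd_sample_median(self):
        u = pd.DataFrame([[0.1, 0.3, 0.5]], index=["t"], columns=["a", "b", "c"])
        assert median_usage("t", u) == pytest.approx(0.3)

    def test_median_over_detected_samples_only(self):
        row = [0.0] * 77 + [0.015] * 22  # detected in 22 of 99 samples
        u = pd.DataFrame([row], index=["t"], columns=[f"s{i}" for i in range(99)])
        assert median_usage("t", u) == pytest.approx(0.015)

    def test_never_detected_errors(self):
        u = pd.DataFrame([[0.0, np.nan]], index=["t"], columns=["a", "b"])
        with pytest.raises(ValueError):
            median_usage("t", u)


class TestOrfUsage:
    def test_transcripts_sharing_an_orf_sum(self):
        u = pd.DataFrame([[0.2], [0.3], [0.5]], index=["a", "b", "c"], columns=["s1"])
        ou = orf_usage(u, {"a": "o1", "b": "o1", "c": "o2"})
        assert ou.loc["o1", "s1"] == pytest.approx(0.5)
        assert ou.loc["o2", "s1"] == pytest.approx(0.5)
        assert ou["s1"].sum() == pytest.approx(1.0)

    def test_identity_when_orfs_distinct(self):
        u = pd.DataFrame([[0.4], [0.6]], index=["a", "b"], columns=["s1"])
        ou = orf_usage(u, {"a": "o1", "b": "o2"})
        assert ou.loc["o1", "s1"] == pytest.approx(0.4)

    def test_unmapped_transcript_errors(self):
        u = pd.DataFrame([[1.0]], index=["a"], columns=["s1"])
        with pytest.raises(KeyError):
            orf_usage(u, {})


class TestTissueSpecific:
    def _flags(self, means_by_tissue, fold=2.0):
        # one sample per tissue makes the mean equal the designed value
        samples = {f"s_{t}": t for t in means_by_tissue}
        u = pd.DataFrame(
            {f"s_{t}": [v] for t, v in means_by_tissue.items()}, index=["t"]
        )
        return tissue_specific(u, samples, ClassifyParams(tissue_fold=fold))["t"]

    def test_twofold_boundary_is_inclusive(self):
        assert self._flags({"a": 0.4, "b": 0.2, "c": 0.1}) == "a"

    def test_below_twofold_not_specific(self):
        assert self._flags({"a": 0.4, "b": 0.25}) is None

    def test_single_tissue_presence_is_specific(self):
        assert self._flags({"a": 0.3, "b": 0.0, "c": 0.0}) == "a"

    def test_single_tissue_design_warns_and_unflags(self):
        u = pd.DataFrame([[0.5, 0.5]], index=["t"], columns=["s1", "s2"])
        with pytest.warns(UserWarning):
            flags = tissue_specific(u, {"s1": "brain", "s2": "brain"})
        assert flags["t"] is None


class TestNovelty:
    def test_reference_against_itself_has_zero_novel_items(self, truth):
        ref_calls = truth.reference_calls()
        structures = build_reference_structures(ref_calls, truth.genome)
        for call in ref_calls:
            d = decompose(call.exons, spliced_sequence(call.exons, truth.genome))
            flags = novelty(d, structures)
            assert not flags.transcript_novel
            assert not flags.orf_novel
            assert not (flags.utr5_novel or flags.utr3_novel)

    def test_utr_beyond_tolerance_is_novel(self, truth):
        from isocollapse.simulate import _jitter_chain

        structures = build_reference_structures(truth.reference_calls(), truth.genome)
        base = truth.by_name("canonical").chain
        shifted = _jitter_chain(base, -25, 0)  # 5' end 25 bp from the nearest reference end
        d = decompose(shifted, spliced_sequence(shifted, truth.genome))
        flags = novelty(d, structures)
        assert flags.utr5_novel and not flags.utr3_novel
        assert flags.transcript_novel and not flags.orf_novel

    def test_empty_reference_makes_everything_novel(self, truth):
        structures = build_reference_structures([], truth.genome)
        base = truth.by_name("canonical").chain
        d = decompose(base, spliced_sequence(base, truth.genome))
        flags = novelty(d, structures)
        assert flags.orf_novel and flags.transcript_novel


class TestClassify:
    def flags(self, orf=False, u5=False, u3=False, tx=True):
        return NoveltyFlags(orf_novel=orf, utr5_novel=u5, utr3_novel=u3, transcript_novel=tx)

    def test_nmd_trumps_everything(self):
        assert classify(True, 438, self.flags(tx=True)) == "NMD_Novel"
        assert classify(True, 100, self.flags(tx=False)) == "NMD_Known"

    def test_sub_150aa_is_non_coding_strictly(self):
        assert classify(False, 149, self.flags(tx=False)) == "Non_coding_Known"
        assert classify(False, 150, self.flags(tx=False)) == "Coding_Known"
        assert classify(False, None, self.flags(tx=True)) == "Non_coding_Novel"

    def test_novel_coding_subcategories(self):
        assert classify(False, 300, self.flags(orf=False, u5=True)) == "Novel_3/5UTR_only"
        assert classify(False, 300, self.flags(orf=False)) == "Novel_combination"
        assert classify(False, 300, self.flags(orf=True, u3=True)) == "Novel_ORF_and_UTR"
        assert classify(False, 300, self.flags(orf=True)) == "Novel_ORF_only"

    def test_cascade_is_total_over_all_flag_combinations(self):
        for nmd, plen, orf, u5, u3, tx in itertools.product(
            [True, False], [None, 10, 150, 438], [True, False], [True, False],
            [True, False], [True, False],
        ):
            cat = classify(nmd, plen, self.flags(orf, u5, u3, tx))
            assert cat in CATEGORIES
            if nmd:
                assert cat.startswith("NMD")
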