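"""Consensus variant logic against set-intersection and pairing oracles."""

import numpy as np
import pytest

from gemmomics import synthdata as sd
from gemmomics import variants as va
from gemmomics.variants import Impact, SnvCall, SvCall, SvType


def snv(chrom="chr1", pos=100, ref="C", alt="A", **kw):
    return SnvCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def sv(type=SvType.DEL, chrom="chr1", pos_a=1_000_000, length=15_000, mapq=60, **kw):
    return SvCall(
        type=type, chromA=chrom, posA=pos_a, chromB=chrom, posB=pos_a + length,
        length=length, mapq=mapq, **kw,
    )


class TestConsensusSnvs:
    def test_exact_match_retained_alt_mismatch_dropped(self):
        a = [snv(alt="A"), snv(pos=200, alt="T")]
        b = [snv(alt="A"), snv(pos=200, alt="G")]
        out = va.consensus_snvs(a, b)
        assert [c.pos for c in out] == [100]

    def test_planted_intersection_counts(self):
        res = sd.gen_snv_callsets(seed=17, n_shared=50, n_private_a=30,
                                  n_private_b=20, n_germline=0)
        out = va.consensus_snvs(res.caller_a, res.caller_b)
        assert len(out) == 50
        assert {c.key for c in out} == {c.key for c in res.truth_shared}

    def test_annotation_from_caller_a(self):
        a = [snv(impact=Impact.HIGH, gene="Kit")]
        b = [snv(impact=Impact.LOW, gene="")]
        out = va.consensus_snvs(a, b)
        assert out[0].impact is Impact.HIGH and out[0].gene == "Kit"

    def test_mixed_sample_rejected(self):
        with pytest.raises(ValueError, match="mixed-sample"):
            va.consensus_snvs([snv(sample="t1")], [snv(sample="t2")])

    def test_output_sorted(self):
        a = [snv(chrom="chr2", pos=5), snv(chrom="chr1", pos=9)]
        out = va.consensus_snvs(a, list(a))
        assert [(c.chrom, c.pos) for c in out] == [("chr1", 9), ("chr2", 5)]


class TestGermlineSubtraction:
    def test_planted_difference_counts(self):
        res = sd.gen_snv_callsets(seed=3, n_shared=100, n_private_a=0,
                                  n_private_b=0, n_germline=25)
        out = va.subtract_germline(res.caller_a, res.germline)
        assert len(out) == 75

    def test_empty_germline_is_identity(self):
        calls = [snv(), snv(pos=200)]
        assert va.subtract_germline(calls, []) == calls

    def test_idempotent(self):
        res = sd.gen_snv_callsets(seed=3, n_germline=10)
        once = va.subtract_germline(res.caller_a, res.germline)
        twice = va.subtract_germline(once, res.germline)
        assert once == twice


class TestConsensusSvs:
    def test_margin_and_filters_worked_examples(self):
        # pair within 100 bp at both ends, MAPQ 60, length 15,000: retained
        a = sv(pos_a=1_000_000, length=15_000)
        b = sv(pos_a=1_000_050, length=15_030)  # |dstart|=50, |dend|=80
        assert len(va.consensus_svs([a], [b])) == 1
        # matched pair with length 9,000: filtered by the length rule
        short_a = sv(pos_a=2_000_000, length=9_000)
        short_b = sv(pos_a=2_000_010, length=9_000)
        assert va.consensus_svs([short_a], [short_b]) == []
        # low mapq on one side: min rule filters
        low = sv(pos_a=1_000_050, length=15_030, mapq=59)
        assert va.consensus_svs([a], [low]) == []

    def test_wildtype_subtraction(self):
        a = sv(); b = sv(pos_a=1_000_020, length=15_010)
        wt = [sv(sample="wt")]
        assert len(va.consensus_svs([a], [b])) == 1
        assert va.consensus_svs([a], [b], wildtype=wt) == []

    def test_merged_call_uses_caller_a_coordinates(self):
        a = sv(pos_a=1_000_000, mapq=60, caller="A")
        b = sv(pos_a=1_000_030, length=15_040, mapq=61 - 1, caller="B")
        out = va.consensus_svs([a], [b])
        assert out[0].posA == 1_000_000 and out[0].mapq == 60

    def test_kind_mismatch_rejected(self):
        inv = sv(type=SvType.INV)
        with pytest.raises(ValueError, match="inconsistent"):
            va.consensus_svs([inv], [inv], kind="CNV")

    def test_symmetry_of_matched_set(self, small_cfg):
        res = sd.gen_sv_callsets(small_cfg)
        ab = va.consensus_svs(res.caller_a, res.caller_b, res.wildtype)
        ba = va.consensus_svs(res.caller_b, res.caller_a, res.wildtype)
        # the retained pair set is the same; coordinates come from the
        # first argument, so compare by truth slot (3 Mb grid)
        slot = lambda c: (c.chromA, round(c.posA, -5), c.type)
        assert {slot(c) for c in ab} == {slot(c) for c in ba}

    def test_recall_on_jittered_callsets(self):
        # with independent per-caller jitter sd=20 the caller-vs-caller
        # breakpoint offset has sd ~28 bp, so the 100 bp margin retains
        # each event with probability ~0.999
        cfg = sd.SynthConfig(seed=21, n_sv_events=100, sv_jitter_sd=20.0,
                             fp_rate=0.0, wt_frac=0.0)
        res = sd.gen_sv_callsets(cfg)
        out = va.consensus_svs(res.caller_a, res.caller_b)
        assert len(out) / len(res.truth) >= 0.99


def brute_force_pairs(calls_a, calls_b, margin):
    """Independent quadratic oracle: repeatedly take the globally
    closest compatible pair until none remains."""
    remaining = [
        (abs(a.posA - b.posA) + abs(a.posB - b.posB), a.posA, b.posA, i, j)
        for i, a in enumerate(calls_a)
        for j, b in enumerate(calls_b)
        if a.type is b.type
        and a.chromA == b.chromA
        and a.chromB == b.chromB
        and abs(a.posA - b.posA) <= margin
        and abs(a.posB - b.posB) <= margin
    ]
    pairs = []
    while remaining:
        best = min(remaining)
        _, _, _, i, j = best
        pairs.append((i, j))
        remaining = [r for r in remaining if r[3] != i and r[4] != j]
    return sorted(pairs)


class TestGreedyMatcherOracle:
    @pytest.mark.parametrize("jitter", [0.0, 20.0, 50.0])
    def test_agrees_with_quadratic_oracle(self, jitter):
        for seed in range(10):
            cfg = sd.SynthConfig(seed=seed, n_sv_events=60, sv_jitter_sd=jitter,
                                 fp_rate=0.3, wt_frac=0.0)
            res = sd.gen_sv_callsets(cfg)
            got = sorted(va._match_pairs(res.caller_a, res.caller_b, 100))
            assert got == brute_force_pairs(res.caller_a, res.caller_b, 100)

    def test_agrees_on_dense_random_instances(self, rng):
        # clustered calls where multiple candidates compete for a partner
        for trial in range(20):
            base = rng.integers(1_000_000, 2_000_000)
            mk = lambda: sv(
                pos_a=int(base + rng.integers(0, 300)),
                length=int(20_000 + rng.integers(0, 150)),
            )
            a = [mk() for _ in range(6)]
            b = [mk() for _ in range(6)]
            got = sorted(va._match_pairs(a, b, 100))
            assert got == brute_force_pairs(a, b, 100)


class TestTranslocations:
    def tra(self, pos_a=5_000_000, pos_b=9_000_000, mapq=55, genes=("Fgfr2",)):
        return SvCall(
            type=SvType.TRA, chromA="chr7", posA=pos_a, chromB="chr14",
            posB=pos_b, length=0, mapq=mapq, sample="t1",
            genes=frozenset(genes),
        )

    def test_wide_margin_and_gene_break_requirement(self):
        a = self.tra()
        b = self.tra(pos_a=5_000_800, pos_b=9_000_800)  # 800 bp off both ends
        assert len(va.consensus_translocations([a], [b], [("Fgfr2", "t1")])) == 1
        assert va.consensus_translocations([a], [b], [("Other", "t1")]) == []
        assert va.consensus_translocations([a], [b], [("Fgfr2", "t2")]) == []

    def test_low_mapq_dropped(self):
        a = self.tra(mapq=49)
        b = self.tra(pos_a=5_000_100, pos_b=9_000_100, mapq=49)
        assert va.consensus_translocations([a], [b], [("Fgfr2", "t1")]) == []

    def test_beyond_margin_dropped(self):
        a = self.tra()
        b = self.tra(pos_a=5_001_100, pos_b=9_000_000)
        assert va.consensus_translocations([a], [b], [("Fgfr2", "t1")]) == []


class TestIntegerCn:
    @pytest.mark.parametrize(
        "log2,expected", [(0.0, 2), (-1.0, 1), (0.585, 3), (1.0, 4), (-10.0, 0)]
    )
    def test_closed_form(self, log2, expected):
        seg = va.CopySegment(chrom="chr11", start=0, end=1000, log2_ratio=log2)
        assert va.integer_cn_from_log2(seg) == expected

    def test_non_finite_rejected(self):
        seg = va.CopySegment(chrom="chr1", start=0, end=10, log2_ratio=float("nan"))
        with pytest.raises(ValueError):
            va.integer_cn_from_log2(seg)

    def test_baseline_ploidy(self):
        seg = va.CopySegment(chrom="chrX", start=0, end=10, log2_ratio=1.0)
        assert va.integer_cn_from_log2(seg, baseline_ploidy=1) == 2


class TestConservedMutations:
    def test_threshold_and_impact_rules(self):
        groups = {"s1": "emt", "s2": "emt", "s3": "emt"}
        calls = {
            "s1": [snv(gene="Kras", impact=Impact.MODERATE),
                   snv(pos=5, gene="Low3", impact=Impact.LOW)],
            "s2": [snv(gene="Kras", impact=Impact.HIGH),
                   snv(pos=5, gene="Low3", impact=Impact.LOW)],
            "s3": [snv(pos=9, gene="Solo", impact=Impact.HIGH),
                   snv(pos=5, gene="Low3", impact=Impact.LOW)],
        }
        conserved, venn = va.conserved_mutations(calls, groups)
        # 2/3 = 0.667 >= 0.66 moderate/high: conserved
        assert conserved["emt"] == {"Kras"}
        assert venn == {frozenset({"emt"}): 1}

    def test_venn_counts_across_groups(self):
        groups = {"a1": "A", "b1": "B"}
        calls = {
            "a1": [snv(gene="Shared", impact=Impact.HIGH),
                   snv(pos=7, gene="OnlyA", impact=Impact.MODERATE)],
            "b1": [snv(gene="Shared", impact=Impact.HIGH)],
        }
        conserved, venn = va.conserved_mutations(calls, groups)
        assert venn[frozenset({"A", "B"})] == 1
        assert venn[frozenset({"A"})] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            va.conserved_mutations({}, {}, frac=0.66)
        with pytest.raises(ValueError):
            va.conserved_mutations({}, {"s": "g"}, frac=0.0)


class TestBurden:
    def test_counts_and_permutation_invariance(self, rng):
        res = sd.gen_snv_callsets(seed=1, n_shared=120, n_private_a=0,
                                  n_private_b=0, n_germline=0)
        calls = list(res.caller_a)
        assert va.mutational_burden({"t": calls}) == {"t": 120}
        shuffled = [calls[i] for i in rng.permutation(len(calls))]
        assert va.mutational_burden({"t": shuffled}) == {"t": 120}
        assert va.mutational_burden({"t": []}) == {"t": 0}
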