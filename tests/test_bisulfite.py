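import itertools
import math

import numpy as np
import pytest

from stripemeth.bisulfite import (AMBIGUOUS, METHYLATED, UNMETHYLATED,
                                  AlignerConfig, analyze_clones, align_clone,
                                  call_methylation, check_primer_bias,
                                  classify_context_at, compare_stripes,
                                  convert_in_silico, motif_methylation,
                                  summarize_region)
from stripemeth.coords import AmpliconFragment
from stripemeth.features import reverse_complement
from stripemeth.simulate import gen_bisulfite_clones, gen_profile, gen_reference

from conftest import CONTEXT_TRUTH


class TestClassifyContext:
    @pytest.mark.parametrize("seq,i,expected", [
        ("ACGA", 1, "CG"),
        ("ACTGA", 1, "CHG"),
        ("ACTTA", 1, "CHH"),
        ("AC", 1, "unknown"),        # C at final position
        ("ACT", 1, "unknown"),       # CHH/CHG undecidable with 1 base
        ("ACNG", 1, "unknown"),
        ("ACAN", 1, "unknown"),
    ])
    def test_examples(self, seq, i, expected):
        assert classify_context_at(seq, i) == expected

    def test_not_a_c(self):
        with pytest.raises(ValueError):
            classify_context_at("AAG", 0)

    def test_exhaustive_partition(self):
        # over all 16 following dinucleotides: one label each, sizes {CG:4, CHG:3, CHH:9}
        counts = {"CG": 0, "CHG": 0, "CHH": 0}
        for b1, b2 in itertools.product("ACGT", repeat=2):
            label = classify_context_at("C" + b1 + b2, 0)
            counts[label] += 1
        assert counts == {"CG": 4, "CHG": 3, "CHH": 9}


class TestConvertInSilico:
    def test_unmethylated_all_convert(self):
        assert convert_in_silico("ACGC") == "ATGT"

    def test_methylated_c_retained(self):
        assert convert_in_silico("ACGC", {1}) == "ACGT"

    def test_no_cytosines_identity(self):
        assert convert_in_silico("AGTT") == "AGTT"

    def test_non_c_position_rejected(self):
        with pytest.raises(ValueError):
            convert_in_silico("ACGC", {0})


class TestCallMethylation:
    @pytest.mark.parametrize("clone_base,expected", [
        ("C", METHYLATED), ("T", UNMETHYLATED),
        ("-", AMBIGUOUS), ("A", AMBIGUOUS), ("G", AMBIGUOUS), ("N", AMBIGUOUS),
    ])
    def test_calls(self, clone_base, expected):
        assert call_methylation("C", clone_base) == expected

    def test_requires_reference_c(self):
        with pytest.raises(ValueError):
            call_methylation("G", "C")


REF20 = "ATGCAGTCAGTTACGGATCA"


class TestAlignClone:
    def test_fully_converted_clone_maps_cleanly(self):
        clone = convert_in_silico(REF20)
        aln = align_clone(clone, REF20)
        assert aln.ok
        assert aln.mapped == clone
        assert "-" not in aln.mapped

    def test_single_deletion_maps_one_gap(self):
        # delete the G at index 5 of the converted clone; every other
        # reference position still matches, so the gap must land there
        clone = convert_in_silico(REF20)
        clone = clone[:5] + clone[6:]
        aln = align_clone(clone, REF20)
        assert aln.ok
        assert aln.mapped[5] == "-"
        rest = [aln.mapped[i] for i in range(len(REF20)) if i != 5]
        assert rest == [convert_in_silico(REF20)[i]
                        for i in range(len(REF20)) if i != 5]

    def test_reverse_complement_rejected(self):
        clone = reverse_complement(convert_in_silico(REF20 * 3))
        aln = align_clone(clone, REF20 * 3)
        assert not aln.ok
        assert "identity" in aln.reason

    def test_empty_clone_rejected(self):
        assert not align_clone("", REF20).ok

    def test_length_gate(self):
        assert not align_clone("ACGT", REF20 * 3).ok


def _clone_set_from_calls(ref, rows):
    """Build a clone set via real sequences that will yield given calls."""
    clones = []
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    for k, calls in enumerate(rows):
        meth = {p for p, call in zip(c_positions, calls) if call == METHYLATED}
        clones.append((f"c{k}", convert_in_silico(ref, meth)))
    return analyze_clones("s", clones, ref)


class TestSummarizeRegion:
    def test_two_clones_single_c(self):
        ref = "AGCAG"  # one C at index 2
        cs = _clone_set_from_calls(ref, [[METHYLATED], [UNMETHYLATED]])
        summ = summarize_region(cs)
        assert summ.per_position_percent[0] == 50.0
        assert summ.region_percent == 50.0
        assert summ.per_clone_percent == [100.0, 0.0]

    def test_counts_conserved_at_every_position(self, promoter_region,
                                                upstream_fragment):
        pair = gen_profile(promoter_region, CONTEXT_TRUTH, stripe_delta=0.0)
        sim = gen_bisulfite_clones(pair.red, upstream_fragment, 12,
                                   conversion_efficiency=0.9,
                                   seq_error_rate=0.01, seed=3)
        cs = analyze_clones("red", sim.clones, promoter_region, upstream_fragment)
        m, u, a = cs.counts()
        assert ((m + u + a) == cs.n_clones).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_region(analyze_clones("s", [], "AGCAG"))

    def test_all_ambiguous_column_is_nan_not_zero(self):
        ref = "ACGAG"  # C at index 1
        cs = analyze_clones("s", [("c1", "AAGAG")], ref)  # A over the C
        with pytest.raises(ValueError):
            # no unambiguous calls anywhere -> cannot summarize
            summarize_region(cs)

    def test_parameter_recovery_48_clones(self, promoter_region, upstream_fragment):
        pair = gen_profile(promoter_region, CONTEXT_TRUTH, stripe_delta=0.0)
        sim = gen_bisulfite_clones(pair.red, upstream_fragment, 48,
                                   conversion_efficiency=1.0,
                                   seq_error_rate=0.0, seed=11)
        cs = analyze_clones("red", sim.clones, promoter_region, upstream_fragment)
        summ = summarize_region(cs)
        for ctx in ("CG", "CHG", "CHH"):
            truth = CONTEXT_TRUTH[ctx]
            n = summ.per_context_calls[ctx]
            se = 100 * math.sqrt(truth * (1 - truth) / n)
            assert summ.per_context_percent[ctx] == pytest.approx(
                100 * truth, abs=max(3 * se, 1e-9))


class TestCompareStripes:
    def test_identical_summaries(self):
        ref = "AGCAGCAG"
        cs = _clone_set_from_calls(ref, [[METHYLATED, UNMETHYLATED],
                                         [UNMETHYLATED, METHYLATED]])
        summ = summarize_region(cs)
        cmp_ = compare_stripes(summ, summ)
        assert cmp_.region_difference == 0.0
        assert cmp_.fraction_green_higher == 0.0

    def test_extreme_difference(self):
        ref = "AGCAGCAG"
        green = summarize_region(_clone_set_from_calls(
            ref, [[METHYLATED, METHYLATED]] * 2))
        red = summarize_region(_clone_set_from_calls(
            ref, [[UNMETHYLATED, UNMETHYLATED]] * 2))
        cmp_ = compare_stripes(green, red)
        assert cmp_.region_difference == 100.0
        assert cmp_.fraction_green_higher == 100.0

    def test_offset_recovery(self, promoter_region, upstream_fragment):
        offset = 0.093
        pair = gen_profile(promoter_region, CONTEXT_TRUTH, stripe_delta=offset)
        sims = {
            "green": gen_bisulfite_clones(pair.green, upstream_fragment, 24,
                                          1.0, 0.0, seed=21, sample="green"),
            "red": gen_bisulfite_clones(pair.red, upstream_fragment, 24,
                                        1.0, 0.0, seed=22, sample="red"),
        }
        summs = {k: summarize_region(analyze_clones(
            k, s.clones, promoter_region, upstream_fragment))
            for k, s in sims.items()}
        cmp_ = compare_stripes(summs["green"], summs["red"])
        pg, ng = summs["green"].region_percent / 100, summs["green"].region_calls
        pr, nr = summs["red"].region_percent / 100, summs["red"].region_calls
        se = 100 * math.sqrt(pg * (1 - pg) / ng + pr * (1 - pr) / nr)
        assert cmp_.region_difference == pytest.approx(100 * offset, abs=3 * se)

    def test_position_mismatch_rejected(self):
        a = summarize_region(_clone_set_from_calls("AGCAG", [[METHYLATED]]))
        b = summarize_region(_clone_set_from_calls("AGCAGCAG",
                                                   [[METHYLATED, METHYLATED]]))
        with pytest.raises(ValueError):
            compare_stripes(a, b)


class TestPrimerBias:
    # unconverted reference whose 5' end carries Cs exactly under the Ys
    REF = "TGGAGTTAAATTAACAAGGC" + "GATTAGGATTAGGATTAGGATT" + "TACGGT"

    def test_degenerate_forward_primer_unbiased(self):
        res = check_primer_bias("TGGAGTTAAATTAAYAAGGY", self.REF, "forward")
        assert res.unbiased
        assert res.offset == 0

    def test_fixed_c_over_reference_c_biased(self):
        res = check_primer_bias("TGGAGTTAAATTAACAAGGC", self.REF, "forward")
        assert not res.unbiased
        assert res.biased_positions == [14, 19]

    def test_degenerate_reverse_primer_unbiased(self):
        # revcomp("ACCRTA") == "TAYGGT": Y admits both readings of the ref C
        res = check_primer_bias("ACCRTA", self.REF, "reverse")
        assert res.unbiased

    def test_fixed_reverse_primer_biased(self):
        res = check_primer_bias("ACCGTA", self.REF, "reverse")
        assert not res.unbiased

    def test_unlocatable_primer_errors(self):
        with pytest.raises(ValueError):
            check_primer_bias("GGGGGGGGGG", self.REF, "forward")


class TestMotifMethylation:
    def test_recovery_inside_vs_flanks(self):
        region = gen_reference(400, 0.45, [("CACATG", -200)], seed=9,
                               atg_offset=350)
        pair = gen_profile(
            region, {"CG": 0.8, "CHG": 0.8, "CHH": 0.8, "unknown": 0.8},
            blocks=[(-200, -195, 0.0)], stripe_delta=0.0)
        frag = AmpliconFragment(-260, -140)
        sim = gen_bisulfite_clones(pair.red, frag, 200, 1.0, 0.0, seed=10)
        cs = analyze_clones("s", sim.clones, region, frag)
        # fragment-local span of the embedded motif
        start = 60  # -260..-200 spans 61 positions -> local index 60
        results = motif_methylation(cs, [(start, start + 5)], flank=10)
        (res,) = results
        assert res.status == "scored"
        assert res.inside_percent == 0.0
        assert res.flank_percent == pytest.approx(80.0, abs=10.0)

    def test_no_scorable_cytosines(self):
        ref = "AGCAGTTAGG"
        cs = _clone_set_from_calls(ref, [[METHYLATED]])
        (res,) = motif_methylation(cs, [(4, 7)])  # GTTA: no C inside
        assert res.status == "no scorable cytosines"

    def test_partially_outside_skipped(self):
        ref = "AGCAG"
        cs = _clone_set_from_calls(ref, [[METHYLATED]])
        (res,) = motif_methylation(cs, [(3, 9)])
        assert res.status.startswith("skipped")


def test_estimator_unbiased_over_many_sets():
    region = gen_reference(400, 0.40, seed=77, atg_offset=350)
    pair = gen_profile(region, CONTEXT_TRUTH, stripe_delta=0.0)
    frag = AmpliconFragment(-300, -180)
    errs = {"CG": [], "CHG": [], "CHH": []}
    for s in range(200):
        sim = gen_bisulfite_clones(pair.red, frag, 12, 1.0, 0.0, seed=1000 + s)
        summ = summarize_region(analyze_clones("s", sim.clones, region, frag))
        for ctx in errs:
            if summ.per_context_calls[ctx]:
                errs[ctx].append(summ.per_context_percent[ctx]
                                 - 100 * CONTEXT_TRUTH[ctx])
    for ctx, es in errs.items():
        es = np.array(es)
        mc_se = es.std(ddof=1) / math.sqrt(len(es))
        assert abs(es.mean()) <= 4 * mc_se + 1e-9, ctx
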