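import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tssvar import selection
from tssvar.selection import (
    ClassBoundaries,
    assign_class,
    classify_tss,
    compute_maf,
    density_contrast,
    derive_class_boundaries,
    exclude_multi_tss,
    filter_variants,
    predict_cgi,
    rare_maf_threshold,
)
from tssvar.track_io import GenomicInterval, TssRecord, VariantRecord

REFERENCE_BOUNDARIES = ClassBoundaries(4.59e-4, 0.0014, 0.01)


def make_variant(allele_ns=(500.0, 600.0), var_class="single",
                 submitters=("1000GENOMES", "BCM"), afc=2, pos=100):
    return VariantRecord("chr1", pos, "rs", var_class, frozenset(submitters),
                         afc, tuple(allele_ns))


class TestFilterVariants:
    def test_all_criteria_pass(self):
        kept, tally = filter_variants([make_variant()])
        assert len(kept) == 1 and tally.n_kept == 1

    @pytest.mark.parametrize(
        "variant, field",
        [
            (make_variant(submitters=("BCM",)), "not_1000genomes"),
            (make_variant(var_class="deletion"), "not_single"),
            (make_variant(afc=3), "allele_freq_count_not_2"),
            (make_variant(allele_ns=(0.0, 2000.0)), "zero_allele_count"),
            (make_variant(allele_ns=(400.0, 600.0)), "sample_too_small"),
        ],
    )
    def test_rejections_tallied(self, variant, field):
        kept, tally = filter_variants([variant])
        assert kept == [] and getattr(tally, field) == 1

    def test_sum_exactly_1000_rejected(self):
        # strict > 1000: a 1000-chromosome sample is not enough
        kept, _ = filter_variants([make_variant(allele_ns=(400.0, 600.0))])
        assert kept == []
        kept, _ = filter_variants([make_variant(allele_ns=(400.0, 601.0))])
        assert len(kept) == 1

    def test_tally_partition(self):
        records = [make_variant(), make_variant(submitters=("X",)),
                   make_variant(var_class="in-del"),
                   make_variant(allele_ns=(0.0, 2000.0))]
        kept, tally = filter_variants(records)
        rejected = (tally.not_1000genomes + tally.not_single
                    + tally.allele_freq_count_not_2 + tally.zero_allele_count
                    + tally.sample_too_small)
        assert tally.n_input == len(records) == tally.n_kept + rejected


class TestMaf:
    def test_single_heterozygote(self):
        assert compute_maf((1, 2183)) == pytest.approx(4.5788e-4, rel=1e-4)

    def test_examples(self):
        assert compute_maf((500, 500)) == 0.5
        assert compute_maf((300, 700)) == pytest.approx(0.3)

    @given(st.tuples(st.floats(0.5, 1e6), st.floats(0.5, 1e6)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_bound(self, ns):
        a, b = ns
        assert compute_maf((a, b)) == compute_maf((b, a)) <= 0.5

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_maf((0, 100))

    def test_arithmetic_threshold(self):
        assert rare_maf_threshold(1092) == pytest.approx(4.58e-4)
        assert rare_maf_threshold(1092, digits=4) == pytest.approx(4.579e-4)


class TestClassBoundaries:
    def test_median_split_even(self):
        b = derive_class_boundaries([0.001, 0.002, 0.003, 0.004])
        assert b.mid_boundary == pytest.approx(0.0025)
        labels = [assign_class(m, b) for m in [0.001, 0.002, 0.003, 0.004]]
        assert labels == ["mid1", "mid1", "mid2", "mid2"]

    def test_single_intermediate_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            b = derive_class_boundaries([0.002])
        assert "mid2" in caplog.text
        assert assign_class(0.002, b) == "mid1"

    def test_no_intermediate_errors(self):
        with pytest.raises(ValueError):
            derive_class_boundaries([1e-5, 0.3])

    def test_reference_class_examples(self):
        assert assign_class(4.59e-4, REFERENCE_BOUNDARIES) == "rare"
        assert assign_class(0.02, REFERENCE_BOUNDARIES) == "common"
        assert assign_class(0.005, REFERENCE_BOUNDARIES) == "mid2"
        assert assign_class(0.0014, REFERENCE_BOUNDARIES) == "mid1"
        assert assign_class(0.01, REFERENCE_BOUNDARIES) == "mid2"

    @given(st.floats(1e-6, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition(self, maf):
        labels = [c.label for c in REFERENCE_BOUNDARIES.classes if c.contains(maf)]
        assert len(labels) == 1
        assert assign_class(maf, REFERENCE_BOUNDARIES) == labels[0]

    def test_maf_domain(self):
        with pytest.raises(ValueError):
            assign_class(0.0, REFERENCE_BOUNDARIES)
        with pytest.raises(ValueError):
            assign_class(0.6, REFERENCE_BOUNDARIES)


def brute_force_segments(sequence):
    """All greedy maximal positive segments by full O(L^2) enumeration."""
    scores = selection._dinucleotide_scores(sequence)
    chosen = []
    free = [(0, len(scores))]
    while free:
        lo, hi = free.pop()
        if hi <= lo:
            continue
        best = None
        for a in range(lo, hi):
            total = 0.0
            for b in range(a + 1, hi + 1):
                total += scores[b - 1]
                cand = (total, a, b)
                if best is None or (cand[0], -cand[1], -cand[2]) > (
                        best[0], -best[1], -best[2]):
                    best = cand
        if best is None or best[0] <= 0:
            continue
        _, a, b = best
        chosen.append((a, b))
        free.append((lo, a))
        free.append((b, hi))
    return sorted(chosen)


class TestPredictCgi:
    def test_cg_repeat_is_one_island(self):
        seq = "CG" * 150
        islands = predict_cgi(seq)
        assert len(islands) == 1
        assert islands[0].start == 0 and islands[0].end == 300

    def test_at_repeat_has_none(self):
        assert predict_cgi("AT" * 150) == []

    def test_length_must_exceed_200(self):
        # candidate islands of exactly 200 bp fail the length criterion
        ok = selection._cgi_criteria("CG" * 100 + "C")   # 201 bp
        too_short = selection._cgi_criteria("CG" * 100)  # 200 bp
        assert ok and not too_short

    def test_n_scores_as_other(self):
        assert predict_cgi("N" * 300) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # CG-enriched alphabet so positive segments actually occur
        seq = "".join(rng.choice(list("ACGTCG"), size=320))
        expected = [(a, b + 1) for a, b in brute_force_segments(seq)
                    if selection._cgi_criteria(seq[a:b + 1])]
        got = [(iv.start, iv.end) for iv in predict_cgi(seq)]
        assert got == expected
        # the underlying greedy segment sets agree too
        assert selection._greedy_segments(
            selection._dinucleotide_scores(seq)) == brute_force_segments(seq)


class TestClassifyTss:
    CGI = [GenomicInterval("chr1", 100, 300)]

    def test_inside_with_distance(self):
        t = TssRecord("chr1", 150, "+", 30, "a")
        c = classify_tss(t, self.CGI)
        assert c.cgi_status == "CGI" and c.distance_from_cgi_center == -50

    def test_minus_strand_flips_sign(self):
        t = TssRecord("chr1", 150, "-", 30, "a")
        assert classify_tss(t, self.CGI).distance_from_cgi_center == 50

    def test_half_open_end(self):
        t = TssRecord("chr1", 300, "+", 30, "a")
        assert classify_tss(t, self.CGI).cgi_status == "nCGI"

    def test_no_cgis(self):
        t = TssRecord("chr1", 150, "+", 30, "a")
        c = classify_tss(t, [])
        assert c.cgi_status == "nCGI" and c.distance_from_cgi_center is None

    def test_overlapping_uses_first_by_coordinate(self, caplog):
        import logging
        ivs = [GenomicInterval("chr1", 120, 400), GenomicInterval("chr1", 100, 300)]
        t = TssRecord("chr1", 150, "+", 30, "a")
        with caplog.at_level(logging.WARNING):
            c = classify_tss(t, ivs)
        assert c.distance_from_cgi_center == 150 - 200
        assert "overlapping" in caplog.text

    def test_order_invariance_disjoint(self):
        ivs = [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 500, 700)]
        t = TssRecord("chr1", 600, "+", 30, "a")
        for perm in itertools.permutations(ivs):
            assert classify_tss(t, list(perm)).distance_from_cgi_center == 0


class TestExcludeMultiTss:
    def _tss(self, pos, chrom="chr1"):
        return TssRecord(chrom, pos, "+", 30, f"t{pos}")

    def test_close_pair_both_excluded(self):
        assert exclude_multi_tss([self._tss(0), self._tss(4000)]) == []

    def test_distant_pair_kept(self):
        pair = [self._tss(0), self._tss(10001)]
        assert exclude_multi_tss(pair) == pair

    def test_singleton_chromosome_kept(self):
        trio = [self._tss(0), self._tss(4000), self._tss(100, chrom="chr2")]
        kept = exclude_multi_tss(trio)
        assert [t.chrom for t in kept] == ["chr2"]


class TestDensityContrast:
    def _tss(self, pos):
        return TssRecord("chr1", pos, "+", 30, f"t{pos}")

    def _var(self, pos):
        return make_variant(pos=pos)

    def test_all_inside(self):
        tss = [self._tss(10_000)]
        variants = [self._var(p) for p in (6000, 10_000, 14_000)]
        d_in, d_out = density_contrast(variants, tss, {"chr1": 100_000})
        assert d_out == 0 and d_in == pytest.approx(3 / 10_000)

    def test_union_semantics(self):
        # overlapping windows counted once: two TSSs 2 kb apart share bases
        tss = [self._tss(10_000), self._tss(12_000)]
        d_in, _ = density_contrast([self._var(11_000)], tss, {"chr1": 100_000})
        assert d_in == pytest.approx(1 / 12_000)

    def test_empty_complement_rejected(self):
        with pytest.raises(ValueError):
            density_contrast([], [self._tss(5000)], {"chr1": 10_000})

    def test_uniform_placement_balances(self):
        rng = np.random.default_rng(3)
        genome = 400_000
        tss = [self._tss(p) for p in range(10_000, 390_000, 40_000)]
        n = 20_000
        variants = [self._var(int(p)) for p in rng.integers(0, genome, n)]
        d_in, d_out = density_contrast(variants, tss, {"chr1": genome})
        p = n / genome
        se = np.sqrt(p / 100_000)  # binomial SE on the 100 kb union
        assert abs(d_in - d_out) < 3 * (se + np.sqrt(p / (genome - 100_000)))
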