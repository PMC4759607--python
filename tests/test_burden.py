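"""Burden statistics: Fisher, Mann-Whitney, Ti/Tv, means, report assembly."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mthet.burden import (DegenerateTableError, UndefinedStatisticError,
                          bonferroni, burden_report, fisher_exact_2x2,
                          grantham_distance, mann_whitney, mean_heteroplasmy,
                          pathogenicity_compare, pearson_chi2_2x2,
                          sample_burden, surrogate_pathogenicity, titv_ratio,
                          unique_variants)
from mthet.sample_qc import Sample
from conftest import brute_fisher_p, make_call


class TestUniqueVariants:
    def test_same_variant_many_samples_counts_once(self):
        calls = [make_call(100, "A", "G", 0.05) for _ in range(10)]
        assert unique_variants(calls) == {(100, "G")}

    def test_two_alts_at_one_position(self):
        calls = [make_call(100, "A", "G", 0.05), make_call(100, "A", "T", 0.02)]
        assert len(unique_variants(calls)) == 2

    def test_union_over_spiked_samples(self, locus_map):
        rng = np.random.default_rng(9)
        spikes = [set(), set(), set()]
        for s in spikes:
            while len(s) < 20:
                pos = int(rng.integers(1000, 9000))
                s.add((pos, "G" if locus_map.ref_base(pos) != "G" else "A"))
        calls = [make_call(p, locus_map.ref_base(p), a, 0.05)
                 for s in spikes for p, a in s]
        assert unique_variants(calls, locus_map) == set().union(*spikes)

    def test_masked_positions_excluded(self, locus_map):
        calls = [make_call(310, locus_map.ref_base(310), "G"
                           if locus_map.ref_base(310) != "G" else "A", 0.05),
                 make_call(5000, locus_map.ref_base(5000), "G"
                           if locus_map.ref_base(5000) != "G" else "A", 0.05)]
        assert {p for p, _ in unique_variants(calls, locus_map)} == {5000}


class TestTiTv:
    def test_constructed_ratio_nine_point_five(self):
        subs = ([("A", "G")] * 500 + [("C", "T")] * 405
                + [("A", "T")] * 50 + [("G", "C")] * 45)
        ratio, tv_frac = titv_ratio(subs)
        assert round(ratio, 1) == 9.5
        assert round(tv_frac * 100, 1) == 9.5

    def test_equal_counts(self):
        ratio, tv_frac = titv_ratio([("A", "G")] * 10 + [("A", "C")] * 10)
        assert ratio == 1.0 and tv_frac == 0.5

    def test_all_transversions(self):
        ratio, _ = titv_ratio([("A", "C")] * 5)
        assert ratio == 0.0

    def test_zero_transversions_reported_as_infinite(self):
        ratio, tv_frac = titv_ratio([("A", "G")] * 5)
        assert math.isinf(ratio) and tv_frac == 0.0

    @given(st.integers(1, 400), st.integers(1, 400))
    @settings(max_examples=50, deadline=None)
    def test_ratio_fraction_identity(self, ti, tv):
        ratio, f = titv_ratio([("A", "G")] * ti + [("A", "C")] * tv)
        assert ratio == pytest.approx((1 - f) / f)


class TestMeanHeteroplasmy:
    def test_arithmetic_mean(self):
        calls = [make_call(100, "A", "G", v) for v in (0.02, 0.04, 0.06)]
        assert mean_heteroplasmy(calls) == pytest.approx(0.04, abs=1e-3)

    def test_single_call_identity(self):
        calls = [make_call(100, "A", "G", 0.0102, depth=10000)]
        assert mean_heteroplasmy(calls) == pytest.approx(0.0102, abs=1e-4)

    def test_homoplasmic_excluded(self):
        calls = [make_call(100, "A", "G", 0.05), make_call(200, "C", "T", 0.999)]
        assert mean_heteroplasmy(calls) == pytest.approx(0.05, abs=1e-3)

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mean_heteroplasmy([])

    def test_beta_cohort_mean_matches_generator(self):
        rng = np.random.default_rng(11)
        vafs = rng.beta(1.3, 30.0, size=2000)
        vafs = vafs[(vafs >= 0.0101) & (vafs < 0.99)]
        calls = [make_call(100, "A", "G", v, depth=10 ** 6) for v in vafs]
        assert mean_heteroplasmy(calls) == pytest.approx(
            float(vafs.mean()), abs=3 * float(vafs.std()) / len(vafs) ** 0.5 + 1e-6)


class TestFisher:
    @pytest.mark.parametrize("table, expected, digits", [
        ([[17, 253], [1, 46]], 0.49, 2),   # >10% heteroplasmy, SN tissue
        ([[7, 216], [1, 31]], 1.00, 2),    # >10% heteroplasmy, FC tissue
        ([[0, 10], [0, 10]], 1.0, 6),      # zero-margin table
    ])
    def test_printed_tables(self, table, expected, digits):
        assert round(fisher_exact_2x2(table), digits) == expected

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_agrees_with_brute_enumeration_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            t = rng.integers(0, 40, size=(2, 2)).tolist()
            assert fisher_exact_2x2(t) == pytest.approx(
                brute_fisher_p(t), abs=1e-9)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_full_ties_midranks(self):
        u, p = mann_whitney([1, 1, 1], [1, 1, 1])
        assert u == 4.5 and p == 1.0

    def test_exact_matches_permutation_oracle(self):
        # oracle: enumerate every labeling, U by pairwise win counting
        rng = np.random.default_rng(4)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4), (8, 8)]:
            data = rng.integers(0, 5, size=n1 + n2).astype(float)  # ties likely
            x, y = data[:n1], data[n1:]
            u, p = mann_whitney(x, y)
            u_values = []
            for subset in itertools.combinations(range(n1 + n2), n1):
                sel = set(subset)
                xs = data[list(subset)]
                ys = data[[i for i in range(n1 + n2) if i not in sel]]
                u_k = sum(1.0 * (a > b) + 0.5 * (a == b)
                          for a in xs for b in ys)
                u_values.append(u_k)
            u_values = np.array(u_values)
            lo = np.mean(u_values <= u + 1e-9)
            hi = np.mean(u_values >= u - 1e-9)
            assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 10, 50).astype(float)
        y = rng.integers(2, 12, 60).astype(float)
        _, p = mann_whitney(x, y)
        from scipy import stats
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert p == pytest.approx(float(expected))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestChi2AndBonferroni:
    def test_flat_table(self):
        stat, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0 and p == 1

    def test_direct_formula_values(self):
        stat, _ = pearson_chi2_2x2([[17, 253], [1, 46]])
        assert stat == pytest.approx(1.30, abs=0.01)
        stat, _ = pearson_chi2_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2_2x2([[0, 0], [5, 5]])

    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 13, 0.13), (0.2, 13, 1.0), (0.05, 1, 0.05)])
    def test_bonferroni(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_bonferroni_bad_family(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestPathogenicity:
    def test_grantham_reference_values(self):
        # spot values of the published distance matrix (to rounding of the
        # published property tables)
        assert grantham_distance("L", "I") == pytest.approx(5, abs=1)
        assert grantham_distance("R", "W") == pytest.approx(101, abs=1)
        assert grantham_distance("C", "W") == pytest.approx(215, abs=1)

    def test_synonymous_scores_zero(self, locus_map):
        # find a synonymous coding change and check the surrogate gives 0
        for pos in range(5904, 7445):
            ref = locus_map.ref_base(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                call = make_call(pos, ref, alt, 0.05,
                                 annotation=locus_map.annotate(pos, ref, alt))
                if call.annotation.consequence == "synonymous":
                    assert surrogate_pathogenicity(call) == 0.0
                    return
        pytest.fail("no synonymous change found")

    def test_user_table_lookup_wins(self, locus_map):
        pos = 6000
        ref = locus_map.ref_base(pos)
        alt = "G" if ref != "G" else "A"
        call = make_call(pos, ref, alt, 0.05,
                         annotation=locus_map.annotate(pos, ref, alt))
        from mthet.burden import score_call
        assert score_call(call, {(pos, alt): 0.77}) == 0.77

    def test_shifted_distributions_detected(self, locus_map):
        rng = np.random.default_rng(8)
        coding = [p for p in range(5904, 7445)]

        def cohort(n, nonsyn_bias):
            calls = []
            while len(calls) < n:
                pos = int(rng.choice(coding))
                ref = locus_map.ref_base(pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                ann = locus_map.annotate(pos, ref, alt)
                if ann.consequence == "nonsynonymous" or rng.random() > nonsyn_bias:
                    calls.append(make_call(pos, ref, alt, 0.05, annotation=ann))
            return calls

        heavy = cohort(120, nonsyn_bias=0.9)   # almost all nonsynonymous
        light = cohort(120, nonsyn_bias=0.0)   # natural mix
        res = pathogenicity_compare(heavy, light)
        row = res[res.stratum == "total"].iloc[0]
        assert row.mean_a > row.mean_b
        assert row.p < 0.05


class TestBurdenReport:
    def _cohort(self, locus_map, case_extra_mtco1=6):
        rng = np.random.default_rng(12)
        co1 = locus_map["MTCO1"]
        samples = []
        for i in range(12):
            status = "case" if i < 8 else "control"
            calls = []
            n = 3 + (case_extra_mtco1 if status == "case" else 0)
            for _ in range(n):
                # case excess concentrated in MTCO1; rejection-sample a
                # nonsynonymous change so the tested variant type is hit
                for _ in range(200):
                    pos = int(rng.integers(co1.start, co1.end + 1))
                    ref = locus_map.ref_base(pos)
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    ann = locus_map.annotate(pos, ref, alt)
                    if ann.consequence == "nonsynonymous":
                        break
                calls.append(make_call(pos, ref, alt, 0.05, annotation=ann))
            samples.append(Sample(f"S{i}_SNpc", f"I{i}", "SNpc", status,
                                  calls=calls))
        return samples

    def test_injected_locus_excess_flagged(self, locus_map):
        rep = burden_report(self._cohort(locus_map), locus_map)
        row = rep.tests[(rep.tests.stratum == "MTCO1")
                        & (rep.tests.tissue == "SNpc")].iloc[0]
        assert row.mean_case > row.mean_control
        assert row.p_adjusted < 0.05

    def test_burden_conservation(self, locus_map):
        samples = self._cohort(locus_map)
        burden = sample_burden(samples, locus_map)
        for s in samples:
            sub = burden[(burden["sample"] == s.sample_id)
                         & (burden.variant_type == "all")]
            total = sub[sub.stratum == "total"]["count"].iloc[0]
            coding = sub[sub.stratum == "coding"]["count"].iloc[0]
            assert total == len(s.calls) == coding  # all calls coding here
            locus_sum = sub[~sub.stratum.isin(
                ["total", "coding", "tRNA", "rRNA", "DLOOP"])]["count"].sum()
            overlap_extra = sum(
                1 for c in s.calls for _ in c.annotation.loci) - total
            assert locus_sum == total + overlap_extra

    def test_single_sample_groups_marked_not_computable(self, locus_map):
        samples = self._cohort(locus_map)[:2]
        samples[1].status = "control"
        rep = burden_report(samples, locus_map)
        assert not rep.tests.computable.any()
        assert rep.tests.p.isna().all()

    def test_missing_status_group_is_error(self, locus_map):
        samples = [s for s in self._cohort(locus_map) if s.status == "case"]
        with pytest.raises(ValueError):
            burden_report(samples, locus_map)
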