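"""Fisher-test site calling, Z/fold-change statistics, LOD and indels."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import umicall as uc
from umicall.calling import site_p_value

from _oracles import fisher_greater_oracle


def model_from_counts(err, tot, strata=(2, 3, 4)):
    """Background model with the pooled counts split across strata."""
    n = len(strata)
    error_bases = {s: err // n for s in strata}
    total_bases = {s: tot // n for s in strata}
    error_bases[strata[0]] += err - sum(error_bases.values())
    total_bases[strata[0]] += tot - sum(total_bases.values())
    return uc.ErrorModel(error_bases, total_bases, None, None,
                         {s: 0 for s in strata}, 0, 0.2)


class TestFisherP:
    @given(st.integers(0, 60), st.integers(0, 200), st.integers(0, 40),
           st.integers(0, 400))
    def test_matches_exact_enumeration(self, alt, ref, err, tot_extra):
        depth = alt + ref
        tot = err + tot_extra
        p = site_p_value(alt, depth, err, tot)
        oracle = fisher_greater_oracle(alt, ref, err, tot - err)
        assert p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_deep_site_example_matches_oracle(self):
        # 5 alt reads in 5000x against 10 errors in 1e6 background bases
        p = site_p_value(5, 5000, 10, 1_000_000)
        oracle = fisher_greater_oracle(5, 4995, 10, 999_990)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p <= 0.05

    def test_zero_alt_gives_one(self):
        assert site_p_value(0, 5000, 100, 10 ** 6) == 1.0
        assert site_p_value(0, 0, 0, 10) == 1.0

    def test_scipy_fisher_exact_agreement(self):
        from scipy.stats import fisher_exact
        for table in [(3, 1000, 5, 10 ** 5), (12, 4988, 40, 10 ** 6)]:
            a, b, c, d = table
            expected = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert site_p_value(a, a + b, c, c + d) == pytest.approx(expected,
                                                                     rel=1e-9)

    @pytest.mark.parametrize("alts", [(1, 3, 5, 8), (0, 2, 10)])
    def test_monotone_in_alt_count(self, alts):
        ps = [site_p_value(a, 5000, 20, 10 ** 6) for a in alts]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_monotone_in_depth_at_fixed_fraction(self):
        ps = [site_p_value(int(0.001 * d), d, 20, 10 ** 6)
              for d in (2000, 5000, 10_000, 20_000)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestZAndFold:
    def test_z_exact_arithmetic(self):
        vaf, e, n = 0.001, 0.00002, 5000
        expected = (vaf - e) / math.sqrt(e * (1 - e) / n)
        assert uc.proportion_z(vaf, e, n, 10 ** 6) == pytest.approx(expected)

    def test_z_zero_at_background(self):
        assert uc.proportion_z(0.001, 0.001, 5000, 10 ** 6) == 0.0

    def test_z_scales_with_sqrt_depth(self):
        z1 = uc.proportion_z(0.001, 0.0001, 5000, 10 ** 6)
        z2 = uc.proportion_z(0.001, 0.0001, 10_000, 10 ** 6)
        assert z2 == pytest.approx(z1 * math.sqrt(2))

    def test_z_zero_background_floored(self):
        z = uc.proportion_z(0.001, 0.0, 5000, 10 ** 6)
        e = 1e-6
        assert z == pytest.approx((0.001 - e) / math.sqrt(e * (1 - e) / 5000))

    @pytest.mark.parametrize("vaf,e,tot,expected", [
        (0.001, 0.001, 10 ** 6, 1.0),
        (0.001, 0.00001, 10 ** 6, 100.0),
        (0.001, 0.0, 10 ** 6, 1000.0),  # zero-rate floor at 1/total
    ])
    def test_fold_change(self, vaf, e, tot, expected):
        assert uc.fold_change(vaf, e, tot) == pytest.approx(expected)


class TestTestSite:
    def test_strong_variant_called(self):
        model = model_from_counts(10, 10 ** 6)
        call = uc.test_site({2: (3, 1000), 3: (4, 1500), 4: (8, 2500)},
                            "A", "C", model)
        assert call.alt_count == 15 and call.depth == 5000
        assert call.vaf == pytest.approx(0.003)
        assert call.called and call.filter_reasons == []

    def test_min_alt_reads_filter(self):
        model = model_from_counts(0, 10 ** 6)
        call = uc.test_site({4: (2, 5000)}, "A", "C", model,
                            uc.CallerConfig(included_strata=(4,)))
        assert call.p_value < 0.05  # significant, but under-supported
        assert not call.called
        assert call.filter_reasons == ["min_alt_reads"]

    def test_zero_alt_not_called(self):
        model = model_from_counts(10, 10 ** 6)
        call = uc.test_site({2: (0, 2000), 3: (0, 1000), 4: (0, 2000)},
                            "A", "C", model)
        assert call.p_value == 1.0 and not call.called

    def test_no_coverage_reason(self):
        model = model_from_counts(10, 10 ** 6)
        call = uc.test_site({}, "A", "C", model)
        assert not call.called and call.filter_reasons == ["no_coverage"]

    def test_excluded_strata_ignored(self):
        model = model_from_counts(0, 10 ** 6)
        call = uc.test_site({1: (50, 100), 4: (0, 5000)}, "A", "C", model,
                            uc.CallerConfig(included_strata=(4,)))
        assert call.alt_count == 0  # the noisy 1x stratum stays out

    def test_change_group_background_selected(self):
        strata = (4,)
        model = uc.ErrorModel({4: 100}, {4: 10 ** 6},
                              {(4, g): (90 if g == 4 else 2) for g in range(6)},
                              {(4, g): 10 ** 6 // 3 for g in range(6)},
                              {4: 0}, 0, 0.2)
        cfg = uc.CallerConfig(included_strata=strata, use_change_groups=True)
        # C->T falls in the error-rich C-T group; A->C in a quiet group
        noisy = uc.test_site({4: (5, 5000)}, "C", "T", model, cfg)
        quiet = uc.test_site({4: (5, 5000)}, "A", "C", model, cfg)
        assert quiet.p_value < noisy.p_value

    def test_fisher_method_combination(self):
        model = model_from_counts(9, 3 * 10 ** 5)
        cfg = uc.CallerConfig(combination="fisher_method")
        call = uc.test_site({2: (4, 1500), 3: (5, 1500), 4: (6, 2000)},
                            "A", "C", model, cfg)
        assert 0 < call.p_value <= 1
        assert call.p_value < 0.05


class TestLod:
    def test_zero_background_closed_form(self):
        model = model_from_counts(0, 10 ** 6, strata=(4,))
        cfg = uc.CallerConfig(included_strata=(4,))
        lod, flag = uc.compute_lod({4: 3000}, model, cfg)
        assert lod == pytest.approx(3 / 3000) and flag is None
        lod, _ = uc.compute_lod({4: 600}, model, cfg)
        assert lod == pytest.approx(0.005)

    def test_matches_exhaustive_scan(self):
        model = model_from_counts(10, 10 ** 6, strata=(4,))
        cfg = uc.CallerConfig(included_strata=(4,))
        depth = 2000
        lod, flag = uc.compute_lod({4: depth}, model, cfg)
        assert flag is None
        # oracle: scan every possible alt count
        for k in range(1, depth + 1):
            p = site_p_value(k, depth, 10, 10 ** 6)
            if k >= cfg.min_alt_reads and p <= cfg.alpha:
                assert lod == pytest.approx(k / depth)
                break

    def test_undetectable_flagged(self):
        model = model_from_counts(900, 1000, strata=(4,))
        cfg = uc.CallerConfig(included_strata=(4,))
        lod, flag = uc.compute_lod({4: 3}, model, cfg)
        assert lod == 1.0 and flag == "undetectable"

    def test_monotone_in_depth_and_background(self):
        cfg = uc.CallerConfig(included_strata=(4,))
        lods = [uc.compute_lod({4: d}, model_from_counts(10, 10 ** 6, (4,)),
                               cfg)[0] for d in (1000, 3000, 10_000)]
        assert all(l1 >= l2 for l1, l2 in zip(lods, lods[1:]))
        lods = [uc.compute_lod({4: 5000}, model_from_counts(e, 10 ** 6, (4,)),
                               cfg)[0] for e in (0, 10, 1000)]
        assert all(l1 <= l2 for l1, l2 in zip(lods, lods[1:]))

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            uc.compute_lod({4: 0}, model_from_counts(0, 10 ** 6, (4,)),
                           uc.CallerConfig(included_strata=(4,)))


class TestCallMonitored:
    def test_vaf_recovery_within_binomial_bounds(self, mixed_pipeline):
        calls = {c.pos: c for c in mixed_pipeline.calls}
        for site in mixed_pipeline.sim.sites:
            call = calls[site.pos]
            if site.true_vaf == 0:
                continue
            sd = math.sqrt(site.true_vaf * (1 - site.true_vaf) / call.depth)
            assert abs(call.vaf - site.true_vaf) <= 3 * sd
            assert call.called

    def test_wildtype_sites_not_called(self, mixed_pipeline):
        for site, call in zip(mixed_pipeline.sim.sites, mixed_pipeline.calls):
            if site.true_vaf == 0:
                assert not call.called

    def test_summary_counts(self, mixed_pipeline):
        summary = mixed_pipeline.call_summary
        assert summary["n_sites"] == 5
        assert summary["n_called"] == sum(c.called for c in mixed_pipeline.calls)
        assert len(summary["lod"]) == 5

    def test_no_coverage_site(self, mixed_pipeline):
        site = uc.Site("chr1", 1, "A", "C", 0.0)  # outside any target
        calls, _ = uc.call_monitored([site], mixed_pipeline.pileups,
                                     mixed_pipeline.model)
        assert not calls[0].called
        assert "no_coverage" in calls[0].filter_reasons


class TestIndels:
    def test_zero_alt_uncalled(self):
        call = uc.call_indel({4: (0, 2000)}, (5, 10 ** 6),
                             uc.CallerConfig(included_strata=(4,)))
        assert call.p_value == 1.0 and not call.called

    def test_p_matches_oracle(self):
        call = uc.call_indel({4: (20, 2000)}, (5, 10 ** 6),
                             uc.CallerConfig(included_strata=(4,)),
                             chrom="chr1", pos=10, ref="AT", alt="A")
        oracle = fisher_greater_oracle(20, 1980, 5, 10 ** 6 - 5)
        assert call.p_value == pytest.approx(oracle, rel=1e-9)
        assert call.called

    def test_left_alignment_normalization(self):
        seq = b"GCAAAAT"
        # deletion of one A, right-aligned at pos 4 -> leftmost at pos 1
        norm = uc.normalize_indel(seq, 4, "AA", "A")
        assert norm == (1, "CA", "C")
        assert uc.normalize_indel(seq, *norm) == norm  # idempotent

    def test_insertion_normalization(self):
        seq = b"GCTTTTA"
        norm = uc.normalize_indel(seq, 4, "T", "TT")
        assert norm == (1, "C", "CT")
        assert uc.normalize_indel(seq, *norm) == norm
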