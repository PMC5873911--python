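"""Somatic SNP statistics: filtering, spectrum, clustering, rates, artifacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import tumorgi as tgi
from tumorgi.snp import collapse_class

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _variants(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "aaf", "f1r2", "f2r1", "region_class"],
    )


class TestFilterSnps:
    def test_masked_variant_removed_and_counted(self):
        v = _variants([("2L", 500, "C", "A", 0.3, 5, 5, "intergenic"),
                       ("2L", 5000, "C", "T", 0.3, 5, 5, "intergenic")])
        mask = pd.DataFrame([("2L", 400, 600)], columns=["chrom", "start", "end"])
        out, rep = tgi.filter_snps(v, masks=mask)
        assert rep.n_masked == 1 and rep.n_kept == 1
        assert out.iloc[0].pos == 5000

    def test_aaf_filter_only_when_requested(self):
        v = _variants([("2L", 500, "C", "A", 0.05, 5, 5, "exonic-syn")])
        kept_spectrum, _ = tgi.filter_snps(v, min_aaf=0.0)
        kept_exome, rep = tgi.filter_snps(v, min_aaf=0.1)
        assert len(kept_spectrum) == 1
        assert len(kept_exome) == 0 and rep.n_low_aaf == 1

    def test_no_op_filters_return_input(self):
        v = _variants([("2L", 500, "C", "A", 0.3, 5, 5, "intron")])
        out, rep = tgi.filter_snps(v)
        pd.testing.assert_frame_equal(out, v)
        assert rep.n_kept == rep.n_input == 1

    def test_malformed_alleles_rejected_with_count(self):
        v = _variants([("2L", 500, "CT", "A", 0.3, 5, 5, "intron"),
                       ("2L", 600, "C", "C", 0.3, 5, 5, "intron"),
                       ("2L", 700, "C", "G", 0.3, 5, 5, "intron")])
        out, rep = tgi.filter_snps(v)
        assert rep.n_malformed == 2 and len(out) == 1


class TestSpectrum:
    def test_strand_collapse_g_to_t_counts_as_c_to_a(self):
        counts, fracs, _ = tgi.substitution_spectrum(
            _variants([("2L", 1, "G", "T", 0.3, 1, 1, "intron")])
        )
        assert counts["C>A"] == 1 and sum(counts.values()) == 1
        assert fracs["C>A"] == 1.0

    def test_twelve_raw_types_collapse_uniformly(self):
        rows = []
        pos = 1
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                for _ in range(2):
                    rows.append(("2L", pos, ref, alt, 0.3, 1, 1, "intron"))
                    pos += 1
        counts, fracs, _ = tgi.substitution_spectrum(_variants(rows))
        assert all(counts[c] == 4 for c in tgi.SIX_CLASSES)
        assert all(f == pytest.approx(1 / 6) for f in fracs.values())

    def test_empty_input_flagged_not_zeroed(self):
        counts, fracs, _ = tgi.substitution_spectrum(_variants([]))
        assert sum(counts.values()) == 0
        assert all(np.isnan(f) for f in fracs.values())

    def test_indels_skipped_with_count(self):
        _, _, skipped = tgi.substitution_spectrum(
            _variants([("2L", 1, "CT", "C", 0.3, 1, 1, "intron")])
        )
        assert skipped == 1

    @given(st.lists(st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")),
                    min_size=1, max_size=30))
    def test_spectrum_invariant_under_reverse_complement(self, pairs):
        pairs = [(r, a) for r, a in pairs if r != a]
        if not pairs:
            return
        fwd = _variants([("2L", i + 1, r, a, 0.3, 1, 1, "intron")
                         for i, (r, a) in enumerate(pairs)])
        rev = _variants([("2L", i + 1, COMP[r], COMP[a], 0.3, 1, 1, "intron")
                         for i, (r, a) in enumerate(pairs)])
        assert tgi.substitution_spectrum(fwd)[0] == tgi.substitution_spectrum(rev)[0]


class TestClusterTest:
    def test_dense_cluster_detected(self):
        # 10 of 20 SNPs within one 5 kb span on a 10 Mb effective genome
        rows = [("2L", 1_000_000 + 500 * i, "C", "A", 0.3, 1, 1, "intron")
                for i in range(10)]
        rows += [("2L", 3_000_000 + 400_000 * i, "C", "A", 0.3, 1, 1, "intron")
                 for i in range(10)]
        out = tgi.cluster_test(_variants(rows), n_eff=10e6)
        dense = out[out.pos < 1_010_000]
        assert (dense.k >= 10).all()
        assert (dense.p_value < 1e-3).all()
        assert dense.significant.all()
        # direct binomial tail for the densest window (focal SNP conditioned
        # out: k-1 others among the remaining 19)
        k = int(dense.k.max())
        direct = sum(stats.binom.pmf(i, 19, 50_000 / 10e6) for i in range(k - 1, 20))
        assert out.p_value.min() == pytest.approx(direct, rel=1e-6)

    def test_lone_snp_not_significant(self):
        rows = [("2L", 1_000_000, "C", "A", 0.3, 1, 1, "intron"),
                ("2L", 2_000_000, "C", "A", 0.3, 1, 1, "intron")]
        out = tgi.cluster_test(_variants(rows), n_eff=10e6)
        assert (out.k == 1).all()
        assert not out.significant.any()

    def test_p_values_monotone_in_k(self):
        rows = [("2L", 1_000_000 + 500 * i, "C", "A", 0.3, 1, 1, "intron")
                for i in range(8)]
        rows += [("2R", 5_000_000, "C", "A", 0.3, 1, 1, "intron")]
        out = tgi.cluster_test(_variants(rows), n_eff=50e6)
        out = out.sort_values("k")
        assert (np.diff(out.p_value.to_numpy()) <= 1e-15).all()

    def test_significant_windows_merged_into_regions(self):
        rows = [("2L", 1_000_000 + 2_000 * i, "C", "A", 0.3, 1, 1, "intron")
                for i in range(12)]
        out = tgi.cluster_test(_variants(rows), n_eff=100e6)
        sig = out[out.significant]
        assert sig.region_id.nunique() == 1

    def test_zero_effective_size_rejected(self):
        with pytest.raises(ValueError):
            tgi.cluster_test(_variants([]), n_eff=0)


class TestRegionEnrichment:
    def test_closed_form_small_case(self):
        # P(X>=2), X~Bin(10, 0.1) = 1 - 0.9^10 - 10*0.1*0.9^9
        expected = 1 - 0.9**10 - 10 * 0.1 * 0.9**9
        assert tgi.region_enrichment_test(2, 10, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_zero_successes_give_one(self):
        assert tgi.region_enrichment_test(0, 50, 0.1) == 1.0

    def test_hotspot_exceeds_printed_significance(self):
        assert tgi.region_enrichment_test(23, 134, 0.02) <= 1e-12

    @pytest.mark.parametrize("k,n,p0", [(3, 20, 0.05), (10, 50, 0.1), (25, 40, 0.3)])
    def test_log_space_matches_direct_summation(self, k, n, p0):
        import math
        direct = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert tgi.region_enrichment_test(k, n, p0) == pytest.approx(direct, rel=1e-10)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            tgi.region_enrichment_test(5, 3, 0.1)
        with pytest.raises(ValueError):
            tgi.region_enrichment_test(1, 10, 0.0)


class TestExomeRate:
    def test_rate_definition(self):
        exome = pd.DataFrame([("2L", 0, 1_000_000)], columns=["chrom", "start", "end"])
        rows = [("2L", 1 + i * 10, "C", "A", 0.3, 1, 1, "exonic-nonsyn") for i in range(36)]
        out = tgi.exome_rate(_variants(rows), exome, callable_exome_bp=10e6)
        assert out["rate_per_mb"] == pytest.approx(3.6)
        assert out["n_exonic"] == 36
        assert out["protein_affecting_fraction"] == 1.0

    def test_no_variants_give_zero_rate(self):
        exome = pd.DataFrame([("2L", 0, 1000)], columns=["chrom", "start", "end"])
        out = tgi.exome_rate(_variants([]), exome, callable_exome_bp=1e6)
        assert out["rate_per_mb"] == 0

    def test_zero_callable_exome_rejected(self):
        with pytest.raises(ValueError):
            tgi.exome_rate(_variants([]), None, callable_exome_bp=0)


class TestSnpTurnover:
    def test_identical_sets_fraction_one(self):
        v = _variants([("2L", 5, "C", "A", 0.3, 1, 1, "intron")])
        assert tgi.snp_turnover(v, v)["fraction_passed"] == 1.0

    def test_disjoint_sets_fraction_zero(self):
        a = _variants([("2L", 5, "C", "A", 0.3, 1, 1, "intron")])
        b = _variants([("2L", 6, "C", "A", 0.3, 1, 1, "intron")])
        out = tgi.snp_turnover(a, b)
        assert out["fraction_passed"] == 0.0
        assert out["n_new"] == 1

    def test_identity_requires_matching_alleles(self):
        a = _variants([("2L", 5, "C", "A", 0.3, 1, 1, "intron")])
        b = _variants([("2L", 5, "C", "T", 0.3, 1, 1, "intron")])
        assert tgi.snp_turnover(a, b)["n_passed"] == 0


class TestOrientationBias:
    def test_fully_skewed_c_to_a_flagged(self):
        rows = [("2L", 1 + i, "C", "A", 0.3, 2, 0, "intron") for i in range(20)]
        out = tgi.orientation_bias_check(_variants(rows))
        assert out["flagged"]
        assert out["p_value"] == pytest.approx(2 * 0.5**40, rel=1e-9)

    def test_balanced_counts_not_flagged(self):
        rows = [("2L", 1 + i, "G", "T", 0.3, 1, 1, "intron") for i in range(30)]
        out = tgi.orientation_bias_check(_variants(rows))
        assert not out["flagged"]

    def test_no_c_to_a_variants_reports_no_data(self):
        rows = [("2L", 1, "C", "T", 0.3, 5, 0, "intron")]
        out = tgi.orientation_bias_check(_variants(rows))
        assert out["status"] == "no data"
        assert not out["flagged"]

    def test_skew_direction_must_match_signature(self):
        rows = [("2L", 1 + i, "C", "A", 0.3, 0, 2, "intron") for i in range(20)]
        out = tgi.orientation_bias_check(_variants(rows), suspect_direction="f1r2")
        assert not out["flagged"]


def test_collapse_class_handles_all_inputs():
    assert collapse_class("G", "T") == "C>A"
    assert collapse_class("A", "G") == "T>C"
    assert collapse_class("C", "C") is None
    assert collapse_class("N", "A") is None
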