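"""Synthetic-data generator: determinism, geometry, lineage and mean model."""

import numpy as np
import pandas as pd
import pytest

import tumorgi as tgi
from tumorgi.sim import copy_number_track, gc_bias_log


def _autocorr1(x):
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


class TestGenome:
    def test_zero_ur_fraction_gives_no_ur_intervals(self):
        cfg = tgi.SimConfig(seed=3, ur_fraction=0.0)
        model = tgi.simulate_genome(cfg)
        assert len(model.ur_intervals) == 0

    def test_same_seed_gives_identical_models(self, small_config):
        a = tgi.simulate_genome(small_config)
        b = tgi.simulate_genome(small_config)
        np.testing.assert_array_equal(a.gc, b.gc)
        np.testing.assert_array_equal(a.mappability, b.mappability)
        pd.testing.assert_frame_equal(a.ur_intervals, b.ur_intervals)
        pd.testing.assert_frame_equal(a.gene_intervals, b.gene_intervals)

    def test_gc_track_is_smooth(self, default_genome):
        # lag-1 autocorrelation of the AR(1) GC track, > 0.5 over >= 1e4 bins
        gc = default_genome.gc[: default_genome.arm_slice("3R").stop]
        assert len(gc) >= 10_000
        assert _autocorr1(gc) > 0.5

    def test_iid_gc_when_smoothing_disabled(self):
        cfg = tgi.SimConfig(seed=3, gc_autocorr=0.0)
        model = tgi.simulate_genome(cfg)
        assert abs(_autocorr1(model.gc)) < 0.1

    def test_intervals_lie_within_their_arms(self, small_genome):
        for df in (small_genome.ur_intervals, small_genome.repeat_intervals,
                   small_genome.gene_intervals, small_genome.exome_intervals):
            for row in df.itertuples(index=False):
                assert 0 <= row.start < row.end <= small_genome.chrom_lengths[row.chrom]

    def test_track_lengths_match_bin_grid(self, small_genome):
        total = sum(
            -(-small_genome.chrom_lengths[c] // small_genome.bin_size)
            for c in small_genome.chrom_names
        )
        assert len(small_genome.gc) == total == small_genome.n_bins_total

    def test_invalid_config_rejected(self):
        with pytest.raises(tgi.InvalidConfigError):
            tgi.SimConfig(chrom_lengths={"X": -5})
        with pytest.raises(tgi.InvalidConfigError):
            tgi.SimConfig(bin_size=0)
        with pytest.raises(tgi.InvalidConfigError):
            tgi.SimConfig(spectrum={"C>A": 0.5, "C>T": 0.4})
        with pytest.raises(tgi.InvalidConfigError):
            tgi.SimConfig(ur_factor=0.0)


class TestLineage:
    def test_zero_rates_give_empty_lesion_sets(self, small_genome, small_config):
        cfg = small_config.replace(cnv_rate_per_passage=0, snp_rate_per_passage=0)
        truth = tgi.simulate_lineage(small_genome, cfg)
        assert len(truth.true_cnvs) == 0
        assert len(truth.true_snps) == 0

    def test_certain_retention_keeps_every_t0_lesion(self, small_genome, small_config):
        cfg = small_config.replace(retention_prob=1.0, timepoints=(0, 5),
                                   cnv_rate_per_passage=3, snp_rate_per_passage=10)
        truth = tgi.simulate_lineage(small_genome, cfg)
        t0 = truth.snps_for("L1-T0")[["chrom", "pos", "ref", "alt"]]
        t5 = truth.snps_for("L1-T5")[["chrom", "pos", "ref", "alt"]]
        assert tgi.snp_turnover(t0, t5)["fraction_passed"] == 1.0
        c0 = set(map(tuple, truth.cnvs_for("L1-T0")[["chrom", "start", "end"]].values))
        c5 = set(map(tuple, truth.cnvs_for("L1-T5")[["chrom", "start", "end"]].values))
        assert c0 <= c5

    def test_half_retention_matches_binomial_expectation(self, small_genome,
                                                         small_config):
        # one passage step at retention 0.5: retained fraction within 99% CI
        passed = total = 0
        for seed in range(12):
            cfg = small_config.replace(seed=100 + seed, retention_prob=0.5,
                                       timepoints=(0, 5), cnv_rate_per_passage=0,
                                       snp_rate_per_passage=200)
            truth = tgi.simulate_lineage(small_genome, cfg)
            t0 = truth.snps_for("L1-T0")
            t5 = truth.snps_for("L1-T5")
            tv = tgi.snp_turnover(t0, t5)
            passed += tv["n_passed"]
            total += tv["n_prev"]
        frac = passed / total
        assert abs(frac - 0.5) < 2.576 * np.sqrt(0.25 / total)

    def test_birth_passage_never_exceeds_timepoint(self, small_genome, small_config):
        cfg = small_config.replace(cnv_rate_per_passage=3, snp_rate_per_passage=20)
        truth = tgi.simulate_lineage(small_genome, cfg)
        for s in truth.samples:
            if s.role != "tumor":
                continue
            for df in (truth.cnvs_for(s.sample_id), truth.snps_for(s.sample_id)):
                if len(df):
                    assert (df.birth <= s.timepoint).all()

    def test_split_sublines_share_presplit_lesions(self, small_genome, small_config):
        cfg = small_config.replace(split_at=9, retention_prob=1.0,
                                   snp_rate_per_passage=50, cnv_rate_per_passage=0)
        truth = tgi.simulate_lineage(small_genome, cfg)
        ids = [s.sample_id for s in truth.samples]
        assert "L1-T10A" in ids and "L1-T10B" in ids
        key = ["chrom", "pos", "ref", "alt"]
        a = truth.snps_for("L1-T10A")
        b = truth.snps_for("L1-T10B")
        shared_a = set(map(tuple, a[a.birth < 10][key].values))
        shared_b = set(map(tuple, b[b.birth < 10][key].values))
        # retention 1: everything born before the split survives in both
        assert shared_a == shared_b


class TestCoverage:
    def test_male_x_autosome_coverage_ratio_is_half(self):
        cfg = tgi.SimConfig(seed=5, ur_factor=1.0, gc_bias_coeffs=(0, 0, 0),
                            zero_mappability_fraction=0.0, sex="male", depth=100)
        model = tgi.simulate_genome(cfg)
        cov = tgi.simulate_coverage(model, None, cfg, is_control=False)
        x = cov[model.arm_slice("X")].mean()
        auto = np.mean(np.concatenate(
            [cov[model.arm_slice(c)] for c in model.autosomes]))
        assert abs(x / auto - 0.5) < 0.02

    def test_three_copy_interval_elevates_ratio_by_half(self):
        cfg = tgi.SimConfig(seed=5, ur_factor=1.0, gc_bias_coeffs=(0, 0, 0),
                            zero_mappability_fraction=0.0, sex="female", depth=100)
        model = tgi.simulate_genome(cfg)
        cnvs = pd.DataFrame(
            [("2L", 1_000_000, 1_500_000, 1)],
            columns=["chrom", "start", "end", "state"],
        )
        tum = tgi.simulate_coverage(model, cnvs, cfg, is_control=False, stream=1)
        ctl = tgi.simulate_coverage(model, None, cfg, is_control=True, stream=2)
        idx = model.bins_in("2L", 1_000_000, 1_500_000)
        assert abs(tum[idx].mean() / ctl[idx].mean() - 1.5) < 0.03

    def test_control_under_replication_depresses_ur_coverage(self):
        cfg = tgi.SimConfig(seed=6, ur_factor=0.3, gc_bias_coeffs=(0, 0, 0),
                            zero_mappability_fraction=0.0, sex="female", depth=100)
        model = tgi.simulate_genome(cfg)
        ctl = tgi.simulate_coverage(model, None, cfg, is_control=True)
        ur = model.interval_mask(model.ur_intervals)
        auto = np.zeros_like(ur)
        for c in model.autosomes:
            auto[model.arm_slice(c)] = True
        inside = ctl[ur & auto].mean()
        outside = ctl[~ur & auto].mean()
        assert abs(inside / outside - 0.3) < 0.03

    def test_empirical_means_converge_to_mean_model(self):
        # depth 1e4: per-bin means within 1% of the stated formula
        cfg = tgi.SimConfig(seed=8, depth=1e4, sex="female",
                            chrom_lengths={"2L": 2_000_000}, y_length=0,
                            ur_fraction=0.0, zero_mappability_fraction=0.0)
        model = tgi.simulate_genome(cfg)
        cov = tgi.simulate_coverage(model, None, cfg, is_control=False)
        mu = cfg.depth * np.exp(gc_bias_log(model.gc, cfg))
        ratio = cov.mean() / mu.mean()
        assert abs(ratio - 1.0) < 0.01

    def test_control_with_lesions_rejected(self, small_genome, small_config):
        cnvs = pd.DataFrame([("X", 0, 1000, 1)],
                            columns=["chrom", "start", "end", "state"])
        with pytest.raises(tgi.InvalidConfigError):
            tgi.simulate_coverage(small_genome, cnvs, small_config, is_control=True)

    def test_coverage_deterministic_given_seed(self, small_genome, small_config):
        a = tgi.simulate_coverage(small_genome, None, small_config, is_control=True)
        b = tgi.simulate_coverage(small_genome, None, small_config, is_control=True)
        np.testing.assert_array_equal(a, b)

    def test_sex_scaling_on_y_region(self, small_genome, small_config):
        male = tgi.simulate_coverage(small_genome, None,
                                     small_config.replace(sex="male"), True)
        female = tgi.simulate_coverage(small_genome, None,
                                       small_config.replace(sex="female"), True)
        y = small_genome.arm_slice("Y")
        assert male[y].mean() > 0
        assert female[y].mean() == 0


def test_copy_number_track_applies_states(small_genome, small_config):
    cnvs = pd.DataFrame(
        [("2L", 100_000, 200_000, 2), ("2R", 0, 50_000, -2)],
        columns=["chrom", "start", "end", "state"],
    )
    cn = copy_number_track(small_genome, cnvs, small_config.replace(sex="female"))
    assert cn[small_genome.bins_in("2L", 100_000, 200_000)].max() == 4
    assert cn[small_genome.bins_in("2R", 0, 50_000)].min() == 0  # floored at zero
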