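"""Generator contracts: determinism, rate laws, read chemistry, cohorts, IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpclock import ConfigError, SimConfig, TruthState
from mpclock import io as mio
from mpclock import synthio


def _truth_single_locus(m: float, vaf: float = 0.0, vtype: int = synthio.VT_CT) -> TruthState:
    loci = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [100], "strand": ["+"], "context": ["CpG"], "ref": ["C"]}
    )
    if vaf > 0:
        variants = pd.DataFrame(
            {"locus": [0], "ref": ["C"], "alt": ["T"], "vaf": [vaf], "vtype": [vtype]}
        )
    else:
        variants = pd.DataFrame(columns=["locus", "ref", "alt", "vaf", "vtype"])
    return TruthState(loci=loci, true_methylation=np.array([m]), variants=variants)


class TestSimulateTruth:
    def test_zero_mutation_rate_gives_no_variants(self):
        truth = synthio.simulate_truth(SimConfig(mutation_rate=0.0, seed=1))
        assert len(truth.variants) == 0

    def test_variant_count_within_binomial_99_interval(self):
        # oracle: central 99% interval of Binomial(1000, 0.05) from the CDF
        cfg = SimConfig(n_loci=1000, mutation_rate=0.05, seed=42)
        truth = synthio.simulate_truth(cfg)
        lo = stats.binom.ppf(0.005, 1000, 0.05)
        hi = stats.binom.ppf(0.995, 1000, 0.05)
        assert lo <= len(truth.variants) <= hi

    def test_variants_predominantly_c_to_t(self):
        truth = synthio.simulate_truth(SimConfig(n_loci=5000, mutation_rate=0.1, seed=3))
        counts = truth.variants.groupby(["ref", "alt"]).size()
        assert counts[("C", "T")] > counts.get(("C", "A"), 0)
        assert counts[("C", "T")] > counts.get(("T", "C"), 0)

    def test_true_methylation_is_bimodal(self):
        truth = synthio.simulate_truth(SimConfig(n_loci=5000, seed=5))
        m = truth.true_methylation
        assert ((m < 0.2).mean() > 0.3) and ((m > 0.8).mean() > 0.2)
        assert ((m > 0.4) & (m < 0.6)).mean() < 0.1

    def test_determinism(self):
        cfg = SimConfig(seed=9)
        a, b = synthio.simulate_truth(cfg), synthio.simulate_truth(cfg)
        pd.testing.assert_frame_equal(a.loci, b.loci)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        np.testing.assert_array_equal(a.true_methylation, b.true_methylation)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(mutation_rate=1.5)
        with pytest.raises(ConfigError):
            SimConfig(n_loci=0)
        with pytest.raises(ConfigError):
            SimConfig(age_range=(24.0, 4.0))
        with pytest.raises(ConfigError):
            SimConfig(frac_age_loci_shared=0.5, frac_age_loci_converted=0.1)


class TestSimulateReads:
    def test_unknown_modality_rejected(self, tiny_seq_config):
        truth = synthio.simulate_truth(tiny_seq_config)
        with pytest.raises(ConfigError):
            synthio.simulate_reads(truth, tiny_seq_config, "nanopore")

    def test_fully_methylated_locus_yields_no_T(self):
        cfg = SimConfig(n_loci=1, n_samples=2, seq_error_rate=0.0, seed=2)
        pileup = synthio.simulate_reads(_truth_single_locus(1.0), cfg, "bisulfite")
        assert (pileup["count_T"] == 0).all()

    def test_raw_reads_match_reference_without_variants(self):
        cfg = SimConfig(n_loci=1, n_samples=2, seq_error_rate=0.0, seed=2)
        pileup = synthio.simulate_reads(_truth_single_locus(0.3), cfg, "raw")
        assert (pileup["count_T"] == 0).all()
        assert (pileup["count_C"] > 0).any()

    def test_capture_bias_inflates_apparent_methylation(self):
        # large-n frequency oracle: at a 50% methylated locus, retaining
        # unmethylated molecules with prob exp(-b) leaves %C above 50%
        cfg = SimConfig(
            n_loci=1, n_samples=1, coverage_mean=1e5,
            conversion_efficiency=1.0, capture_bias=1.0, seq_error_rate=0.0, seed=8,
        )
        pileup = synthio.simulate_reads(_truth_single_locus(0.5), cfg, "bisulfite")
        frac_c = pileup["count_C"] / (pileup["count_C"] + pileup["count_T"])
        assert float(frac_c.iloc[0]) > 0.5

    @pytest.mark.parametrize(
        "m,vaf,eff,bias",
        [(0.5, 0.0, 1.0, 1.0), (0.8, 0.3, 0.99, 0.3), (0.2, 0.5, 0.95, 0.0)],
    )
    def test_frequency_consistency_with_closed_form(self, m, vaf, eff, bias):
        # independent derivation: weight methylated-C reads (1-v)m by 1 and
        # every other read by exp(-b); %C = C-weight / total weight
        p = np.exp(-bias)
        c_w = (1 - vaf) * m + (1 - vaf) * (1 - m) * (1 - eff) * p
        t_w = (1 - vaf) * (1 - m) * eff * p + vaf * p
        expected = c_w / (c_w + t_w)

        cfg = SimConfig(
            n_loci=1, n_samples=1, coverage_mean=1e5,
            conversion_efficiency=eff, capture_bias=bias, seq_error_rate=0.0, seed=13,
        )
        pileup = synthio.simulate_reads(_truth_single_locus(m, vaf=vaf), cfg, "bisulfite")
        n = int(pileup["count_C"].iloc[0] + pileup["count_T"].iloc[0])
        observed = float(pileup["count_C"].iloc[0]) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se
        assert np.isclose(
            synthio.expected_bisulfite_fraction_c(m, vaf, eff, bias), expected
        )

    def test_determinism(self, tiny_seq_config):
        truth = synthio.simulate_truth(tiny_seq_config)
        a = synthio.simulate_reads(truth, tiny_seq_config, "bisulfite")
        b = synthio.simulate_reads(truth, tiny_seq_config, "bisulfite")
        pd.testing.assert_frame_equal(a, b)


class TestArrayCohort:
    def test_shared_zero_means_disjoint_age_loci(self):
        cfg = SimConfig(n_samples=38, frac_age_loci_shared=0.0, seed=4)
        sets = synthio.array_informative_loci(cfg)
        assert set(sets["converted"]) & set(sets["unconverted"]) == set()
        assert sets["shared"] == []

    def test_no_missing_when_rate_zero(self):
        cfg = SimConfig(n_samples=38, missing_rate=0.0, seed=4)
        conv, unconv, _ = synthio.simulate_array_cohort(cfg)
        assert not conv.values.isna().to_numpy().any()
        assert not unconv.values.isna().to_numpy().any()

    def test_values_clipped_to_percent_range(self):
        cfg = SimConfig(n_samples=38, noise_sd=30.0, missing_rate=0.0, seed=4)
        conv, unconv, _ = synthio.simulate_array_cohort(cfg)
        for bm in (conv, unconv):
            v = bm.values.to_numpy()
            assert v.min() >= 0.0 and v.max() <= 100.0

    def test_informative_loci_track_age(self):
        cfg = SimConfig(n_samples=38, missing_rate=0.0, seed=6)
        conv, _, ages = synthio.simulate_array_cohort(cfg)
        info = synthio.array_informative_loci(cfg)["converted"]
        corrs = [
            abs(np.corrcoef(conv.values.loc[l], ages)[0, 1]) for l in info
        ]
        assert np.median(corrs) > 0.8

    def test_determinism_and_shared_ages_with_genotype_cohort(self):
        cfg = SimConfig(n_samples=38, seed=15)
        _, _, ages_a = synthio.simulate_array_cohort(cfg)
        _, _, ages_b = synthio.simulate_genotype_cohort(cfg)
        pd.testing.assert_series_equal(ages_a, ages_b)


class TestGenotypeCohort:
    def test_allele_calls_are_trinary(self):
        allele, signal, _ = synthio.simulate_genotype_cohort(SimConfig(n_samples=38, seed=2))
        assert set(np.unique(allele.values.to_numpy())) <= {0.0, 1.0, 2.0}
        assert signal.values.to_numpy().std() > 0

    def test_determinism(self):
        cfg = SimConfig(n_samples=38, seed=21)
        a1, s1, _ = synthio.simulate_genotype_cohort(cfg)
        a2, s2, _ = synthio.simulate_genotype_cohort(cfg)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(s1.values, s2.values)


class TestRoundTrips:
    def test_vcf_round_trip(self, tmp_path, tiny_seq_config):
        truth = synthio.simulate_truth(tiny_seq_config.replace(mutation_rate=0.2))
        records = truth.variant_records()
        path = tmp_path / "variants.vcf"
        mio.write_vcf(records, path)
        back = mio.read_vcf(path)
        assert sorted((r.chrom, r.pos, r.ref, r.alt) for r in back) == sorted(
            (r.chrom, r.pos, r.ref, r.alt) for r in records
        )
        vafs_in = {(r.chrom, r.pos): r.vaf for r in records}
        for r in back:
            assert np.isclose(r.vaf, vafs_in[(r.chrom, r.pos)], atol=1e-5)

    def test_bed_round_trip(self, tmp_path, tiny_seq_config):
        truth = synthio.simulate_truth(tiny_seq_config)
        path = tmp_path / "loci.bed"
        mio.write_loci_bed(truth, path)
        df = mio.read_bed(path)
        assert len(df) == tiny_seq_config.n_loci
        assert (df["end"] - df["start"] == 1).all()
        assert list(df["start"]) == list(truth.loci["pos"])

    def test_pileup_round_trip(self, tmp_path, tiny_seq_config):
        truth = synthio.simulate_truth(tiny_seq_config)
        pileup = synthio.simulate_reads(truth, tiny_seq_config, "raw")
        path = tmp_path / "pileup.tsv"
        mio.write_pileup(pileup, path)
        pd.testing.assert_frame_equal(mio.read_pileup(path), pileup)

    def test_beta_matrix_round_trip(self, tmp_path):
        cfg = SimConfig(n_loci=100, n_samples=10, seed=3)
        conv, _, _ = synthio.simulate_array_cohort(cfg)
        mio.write_beta_matrix(conv, tmp_path / "beta.tsv", tmp_path / "ages.tsv")
        back = mio.read_beta_matrix(tmp_path / "beta.tsv", tmp_path / "ages.tsv", "converted")
        pd.testing.assert_frame_equal(back.values, conv.values, check_names=False)
        pd.testing.assert_series_equal(back.ages, conv.ages, check_names=False)

    def test_config_round_trip(self, tmp_path):
        from mpclock import ClockConfig

        cfg = SimConfig(n_loci=123, seed=77, capture_bias=0.4)
        clk = ClockConfig(n_iterations=7, seed=5)
        mio.save_config(cfg, tmp_path / "config.yaml", clk)
        sim_back, clk_back = mio.load_config(tmp_path / "config.yaml")
        assert sim_back == cfg
        assert clk_back == clk
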