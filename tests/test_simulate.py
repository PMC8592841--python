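import math

import numpy as np
import pytest

import rddmkit as rk
from rddmkit.calls import CALL_M
from rddmkit.simulate import simulate_qpcr, write_fastq


class TestBisulfiteSimulator:
    def test_fully_methylated_reads_equal_reference(self, small_amplicon):
        cfg = rk.BisulfiteSimConfig(
            small_amplicon, n_reads=20, pi=1.0, m_cg=1.0, m_chg=1.0, m_chh=1.0,
            rho=0.0, epsilon=0.0, seq_error=0.0, seed=1,
        )
        reads, truth = rk.simulate_bisulfite_reads(cfg)
        assert all(seq == small_amplicon.sequence for _, seq, _ in reads)
        runs = rk.runs_from_vectors(rk.call_reads(reads, small_amplicon))
        assert all(r.longest == small_amplicon.n_sites for r in runs)

    def test_unmethylated_library_fully_converted(self, small_amplicon):
        cfg = rk.BisulfiteSimConfig(
            small_amplicon, n_reads=50, pi=0.0, epsilon=0.0, seq_error=0.0, seed=2
        )
        reads, _ = rk.simulate_bisulfite_reads(cfg)
        vecs = rk.call_reads(reads, small_amplicon)
        recs = rk.aggregate_site_counts(vecs, small_amplicon)
        s = rk.summarize_methylation(recs)
        assert s["ALL"].percent == 0.0

    def test_nonconversion_rate_recovered(self, small_amplicon):
        """A pi=0 library's pooled methylation estimates epsilon."""
        cfg = rk.BisulfiteSimConfig(
            small_amplicon, n_reads=5000, pi=0.0, epsilon=0.004,
            seq_error=0.0, seed=3,
        )
        reads, _ = rk.simulate_bisulfite_reads(cfg)
        vecs = rk.call_reads(reads, small_amplicon)
        conv = rk.conversion_rate(rk.aggregate_site_counts(vecs, small_amplicon))
        # 5000 reads x 40 i.i.d. sites: binomial CI is valid here (pi=0
        # removes the mixture correlation and rho only acts on RdDM molecules)
        n = 5000 * small_amplicon.n_sites
        sd = math.sqrt(0.004 * 0.996 / n)
        assert abs(conv.nonconversion_rate - 0.004) < 4 * sd

    def test_seed_reproducibility(self, small_amplicon):
        cfg = rk.BisulfiteSimConfig(small_amplicon, n_reads=100, seed=9)
        r1, t1 = rk.simulate_bisulfite_reads(cfg)
        r2, t2 = rk.simulate_bisulfite_reads(cfg)
        assert r1 == r2
        assert np.array_equal(t1.true_methylation, t2.true_methylation)

    def test_metadata_closed_form(self, small_amplicon):
        cfg = rk.BisulfiteSimConfig(
            small_amplicon, pi=0.5, m_chh=0.6, epsilon=0.005, seq_error=0.0
        )
        expected = 0.5 * 0.6 + (1 - 0.5 * 0.6) * 0.005
        assert cfg.expected_call_rate(rk.Context.CHH) == pytest.approx(expected)
        assert cfg.metadata()["expected_call_rate"]["CHH"] == pytest.approx(expected)

    def test_invalid_probability_rejected(self, small_amplicon):
        with pytest.raises(ValueError):
            rk.BisulfiteSimConfig(small_amplicon, pi=1.2)

    def test_reverse_strand_emission(self):
        amp = rk.Amplicon("rev", "AT" + "CAT" * 20 + "GG", rk.Strand.REVERSE)
        cfg = rk.BisulfiteSimConfig(
            amp, n_reads=30, pi=0.0, epsilon=0.0, seq_error=0.0, seed=4
        )
        reads, _ = rk.simulate_bisulfite_reads(cfg)
        # every assayed G converted to A; C positions untouched
        for _, seq, _ in reads:
            for site in amp.sites:
                assert seq[site.position] == "A"
        vecs = rk.call_reads(reads, amp)
        assert all(set(v.calls) == {"U"} for v in vecs)

    def test_fastq_writer(self, small_amplicon, tmp_path):
        cfg = rk.BisulfiteSimConfig(small_amplicon, n_reads=5, seed=1)
        reads, _ = rk.simulate_bisulfite_reads(cfg)
        p = tmp_path / "r.fastq"
        with open(p, "w") as fh:
            write_fastq(reads, fh)
        back = list(rk.calls.read_fastq(p))
        assert [(r[0], r[1]) for r in back] == [(r[0], r[1]) for r in reads]
        assert back[0][2] == [37] * len(small_amplicon.sequence)


class TestMarkovClustering:
    def test_rho_increases_run_lengths_at_fixed_marginal(self, small_amplicon):
        """Persistence concentrates methylation into longer runs without
        changing the per-site rate."""
        medians, means = [], []
        for rho in (0.0, 0.8):
            cfg = rk.BisulfiteSimConfig(
                small_amplicon, n_reads=3000, pi=1.0, m_cg=0.3, m_chg=0.3,
                m_chh=0.3, rho=rho, epsilon=0.0, seq_error=0.0, seed=13,
            )
            reads, truth = rk.simulate_bisulfite_reads(cfg)
            means.append(truth.true_methylation.mean())
            vecs = rk.call_reads(reads, small_amplicon)
            runs = rk.runs_from_vectors(vecs)
            medians.append(np.percentile([r.longest for r in runs], 90))
        assert means[0] == pytest.approx(0.3, abs=0.01)
        assert means[1] == pytest.approx(0.3, abs=0.01)
        assert medians[1] > medians[0]


class TestSmallRnaSimulator:
    def test_spectrum_by_construction(self):
        source = "ACGT" * 30
        reads, total = rk.simulate_small_rna_library(
            source, {24: 500}, background_total=9_999_500, seed=1
        )
        assert len(reads) == 500 and total == 10_000_000
        p = rk.size_class_rpm(rk.map_exact(reads, source)[1], total)
        assert p.rpm[24] == pytest.approx(50.0)

    def test_empty_spectrum(self):
        reads, total = rk.simulate_small_rna_library("ACGT" * 30, {}, 100, seed=1)
        assert reads == [] and total == 100

    def test_seed_reproducibility(self):
        a, _ = rk.simulate_small_rna_library("ACGT" * 30, {21: 50, 24: 50}, seed=7)
        b, _ = rk.simulate_small_rna_library("ACGT" * 30, {21: 50, 24: 50}, seed=7)
        assert a == b

    def test_all_reads_map_to_source(self):
        source = "ATGGCGTACGATCGATTAGGCCATGCAAATTTCGGAGCTAGCTAGGATCC"
        reads, _ = rk.simulate_small_rna_library(source, {18: 20, 28: 20}, seed=3)
        flags, _ = rk.map_exact(reads, source)
        assert all(flags)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            rk.simulate_small_rna_library("ACGT" * 30, {30: 5}, seed=1)


class TestQpcrSimulator:
    def test_noise_free_inversion(self):
        ip, diluted = simulate_qpcr(1.5, 100 / 3, noise_sd=0.0, seed=1)
        rec = rk.percent_input(ip.ct, diluted.ct, diluted.dilution_factor)
        assert rec == pytest.approx(1.5)

    def test_full_input_ct(self):
        ip, diluted = simulate_qpcr(100.0, 100 / 3, noise_sd=0.0, seed=1, ct_100=20.0)
        assert ip.ct == pytest.approx(20.0)

    def test_lognormal_bias_documented(self):
        """With Gaussian Ct noise the mean recovered percent carries the
        positive lognormal bias exp(sigma^2 ln(2)^2) (both Cts add noise);
        the simulator reproduces it rather than correcting it."""
        truth, sd, n = 2.0, 0.2, 1000
        recovered = []
        for seed in range(n):
            ip, diluted = simulate_qpcr(truth, 100 / 3, noise_sd=sd, seed=seed)
            recovered.append(
                rk.percent_input(ip.ct, diluted.ct, diluted.dilution_factor)
            )
        recovered = np.asarray(recovered)
        sigma = sd * math.log(2) * math.sqrt(2)  # two independent noise terms
        predicted_mean = truth * math.exp(sigma**2 / 2)
        se = recovered.std(ddof=1) / math.sqrt(n)
        assert abs(recovered.mean() - predicted_mean) < 3 * se
        assert predicted_mean > truth  # the bias is positive

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0, 100 / 3)


class TestEnrichmentSimulator:
    def test_pure_fully_dependent_recovered(self):
        rows, labels = rk.simulate_enrichment_table(
            50, {"fully_dependent": 1.0}, seed=1
        )
        classified = rk.classify_suvh_dependence(rows)
        assert all(e.category.value == "fully_dependent" for e in classified)
        assert labels == ["fully_dependent"] * 50

    def test_mixed_confusion_diagonal(self):
        rows, labels = rk.simulate_enrichment_table(
            200,
            {"fully_dependent": 0.4, "partially_dependent": 0.4, "not_occupied": 0.2},
            seed=2,
        )
        classified = rk.classify_suvh_dependence(rows)
        assert [e.category.value for e in classified] == labels

    def test_seed_reproducibility(self):
        a, _ = rk.simulate_enrichment_table(30, {"fully_dependent": 1.0}, seed=5)
        b, _ = rk.simulate_enrichment_table(30, {"fully_dependent": 1.0}, seed=5)
        assert a == b

    def test_straddling_params_warn(self):
        with pytest.warns(UserWarning, match="straddle"):
            rk.simulate_enrichment_table(
                10,
                {"fully_dependent": 1.0},
                fe_params={"fully_dependent": ((3.0, 8.0), (1.0, 2.0))},
                seed=1,
            )

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            rk.simulate_enrichment_table(10, {"fully_dependent": 0.6}, seed=1)
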