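"""Generator contracts: determinism, planted truth, count model."""

import math

import numpy as np
import pytest

from cistromad.errors import ConfigurationError
from cistromad.synthetic import (SyntheticConfig, generate_counts,
                                 generate_expression, generate_peaks,
                                 generate_replicate_peaksets, generate_tss,
                                 write_dataset)

from conftest import brute_force_nearest


class TestConfigValidation:
    def test_bad_fractions_name_the_field(self):
        with pytest.raises(ConfigurationError, match="fraction_gained"):
            SyntheticConfig(fraction_gained=1.5)

    def test_fractions_must_not_exceed_one(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(fraction_gained=0.5, fraction_depleted=0.5,
                            fraction_maintained=0.5)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ConfigurationError, match="chrom_length"):
            SyntheticConfig(chrom_length=0)


class TestGeneratePeaks:
    def test_zero_peaks_gives_empty_output(self):
        peaks, truth = generate_peaks(SyntheticConfig(n_peaks=0))
        assert peaks == [] and truth.peak_names == []

    def test_determinism_under_fixed_seed(self):
        cfg = SyntheticConfig(n_peaks=100, seed=123)
        p1, t1 = generate_peaks(cfg)
        p2, t2 = generate_peaks(cfg)
        assert p1 == p2
        assert t1.true_class == t2.true_class
        assert t1.true_logratio == t2.true_logratio

    def test_degenerate_proportions_all_gained(self):
        cfg = SyntheticConfig(n_peaks=50, fraction_gained=1.0,
                              fraction_depleted=0.0, fraction_maintained=0.0)
        _, truth = generate_peaks(cfg)
        assert all(c == "gained" for c in truth.true_class.values())

    def test_intervals_within_bounds_sorted_with_inner_summits(self):
        cfg = SyntheticConfig(n_peaks=300, seed=4)
        peaks, _ = generate_peaks(cfg)
        keys = [(p.chrom, p.start) for p in peaks]
        assert keys == sorted(keys)
        for p in peaks:
            assert 0 <= p.start < p.end <= cfg.chrom_length
            assert p.start <= p.summit < p.end
            assert p.width >= 50


class TestGenerateCounts:
    def test_null_model_mean_log_ratio_near_zero(self):
        cfg = SyntheticConfig(n_peaks=2000, effect_size_logfc=0.0,
                              nb_dispersion=0.0, mean_count=1000,
                              fraction_gained=0, fraction_depleted=0,
                              fraction_maintained=1.0, seed=5)
        peaks, truth = generate_peaks(cfg)
        counts = generate_counts(peaks, truth, cfg)
        ratios = np.log([(c.t2 + 0.5) / (c.t1 + 0.5) for c in counts])
        se = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean()) < 3 * se

    def test_gained_subset_mean_log_ratio_matches_planted_effect(self):
        """Monte-Carlo across 20 seeds: the empirical log ratio of planted
        gained peaks reproduces the generative effect within 10%."""
        means = []
        for seed in range(20):
            cfg = SyntheticConfig(n_peaks=2000, effect_size_logfc=2.0,
                                  mean_count=500, nb_dispersion=0.02,
                                  seed=seed)
            peaks, truth = generate_peaks(cfg)
            counts = {c.peak_name: c for c in
                      generate_counts(peaks, truth, cfg)}
            gained = [np.log(counts[n].t2 / counts[n].t1)
                      for n in truth.peak_names
                      if truth.true_class[n] == "gained"]
            means.append(np.mean(gained))
        assert abs(np.mean(means) - 2.0) < 0.2

    def test_library_size_ratio_scales_raw_but_not_normalized_counts(self):
        cfg = SyntheticConfig(n_peaks=3000, effect_size_logfc=0.0,
                              library_size_ratio=10.0, mean_count=400,
                              nb_dispersion=0.0, fraction_gained=0,
                              fraction_depleted=0, fraction_maintained=1.0,
                              seed=9)
        peaks, truth = generate_peaks(cfg)
        counts = generate_counts(peaks, truth, cfg)
        t1 = np.array([c.t1 for c in counts], dtype=float)
        t2 = np.array([c.t2 for c in counts], dtype=float)
        assert t2.mean() / t1.mean() == pytest.approx(10.0, rel=0.05)
        lib1, lib2 = counts[0].lib1, counts[0].lib2
        assert (t2 / lib2).mean() / (t1 / lib1).mean() == \
            pytest.approx(1.0, rel=0.05)

    def test_misaligned_inputs_rejected(self):
        cfg = SyntheticConfig(n_peaks=10, seed=0)
        peaks, truth = generate_peaks(cfg)
        from cistromad.errors import AlignmentError
        with pytest.raises(AlignmentError):
            generate_counts(peaks[:5], truth, cfg)


class TestReplicates:
    def test_no_jitter_no_decoys_reproduces_input(self):
        cfg = SyntheticConfig(n_peaks=80, replicate_jitter=0.0,
                              boundary_noise_sd=0.0, decoy_fraction=0.0,
                              seed=2)
        peaks, _ = generate_peaks(cfg)
        rep1, rep2 = generate_replicate_peaksets(peaks, cfg)
        assert rep1 == peaks and rep2 == peaks

    def test_total_jitter_annihilates_consensus(self):
        from cistromad.consensus import consensus
        cfg = SyntheticConfig(n_peaks=50, replicate_jitter=1.0,
                              decoy_fraction=0.0, seed=2)
        peaks, _ = generate_peaks(cfg)
        rep1, rep2 = generate_replicate_peaksets(peaks, cfg)
        assert rep1 == [] and rep2 == []
        assert consensus(rep1, rep2) == []

    def test_consensus_size_matches_binomial_expectation(self):
        """With dropout q = 0.2 a true peak survives both replicates with
        probability 0.64; the consensus count of true peaks should fall
        within 99% binomial bounds around 1000 * 0.64."""
        from scipy import stats

        cfg = SyntheticConfig(n_peaks=1000, replicate_jitter=0.2,
                              decoy_fraction=0.25, seed=31)
        peaks, _ = generate_peaks(cfg)
        rep1, rep2 = generate_replicate_peaksets(peaks, cfg)
        names1 = {p.name for p in rep1 if not p.name.startswith("decoy")}
        names2 = {p.name for p in rep2 if not p.name.startswith("decoy")}
        n_both = len(names1 & names2)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.64)
        assert lo <= n_both <= hi

    def test_decoy_counts(self):
        cfg = SyntheticConfig(n_peaks=100, decoy_fraction=0.25, seed=3)
        peaks, _ = generate_peaks(cfg)
        rep1, rep2 = generate_replicate_peaksets(peaks, cfg)
        for rep in (rep1, rep2):
            assert sum(p.name.startswith("decoy") for p in rep) == 25


class TestTssAndExpression:
    def test_truth_nearest_gene_matches_exhaustive_search(self):
        cfg = SyntheticConfig(n_peaks=150, n_genes=120, seed=6)
        peaks, truth = generate_peaks(cfg)
        genes = generate_tss(peaks, truth, cfg)
        for p in peaks:
            expected = brute_force_nearest(p, genes, max_distance=10**12)
            if expected is None:
                assert p.name not in truth.nearest_gene
            else:
                assert truth.nearest_gene[p.name] == expected[1].gene_id

    def test_decoupled_expression_is_centered_at_zero(self):
        cfg = SyntheticConfig(n_peaks=400, n_genes=600,
                              expression_coupling=0.0, seed=7)
        peaks, truth = generate_peaks(cfg)
        generate_tss(peaks, truth, cfg)
        records = generate_expression(truth, cfg)
        vals = np.array([r.log2fc for r in records])
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 4 * se

    def test_full_coupling_separates_gained_from_depleted_genes(self):
        cfg = SyntheticConfig(n_peaks=500, n_genes=600,
                              expression_coupling=1.0, seed=8)
        peaks, truth = generate_peaks(cfg)
        generate_tss(peaks, truth, cfg)
        records = {r.gene_id: r.log2fc
                   for r in generate_expression(truth, cfg)}
        by_class: dict[str, list[float]] = {"gained": [], "depleted": []}
        for peak_name, gene in truth.nearest_gene.items():
            cls = truth.true_class[peak_name]
            if cls in by_class and truth.gene_response[gene] != 0.0:
                by_class[cls].append(records[gene])
        from scipy import stats
        t, p = stats.ttest_ind(by_class["gained"], by_class["depleted"])
        assert t > 0 and p < 1e-10

    def test_unlinked_gene_is_pure_noise(self):
        cfg = SyntheticConfig(n_peaks=10, n_genes=500,
                              expression_coupling=1.0,
                              expression_noise_sd=0.4, seed=10)
        peaks, truth = generate_peaks(cfg)
        generate_tss(peaks, truth, cfg)
        records = generate_expression(truth, cfg)
        unlinked = [r.log2fc for r in records
                    if truth.gene_response[r.gene_id] == 0.0]
        assert len(unlinked) > 400
        assert abs(np.mean(unlinked)) < 0.1
        assert np.std(unlinked) == pytest.approx(0.4, rel=0.15)


def test_write_dataset_is_byte_deterministic(tmp_path):
    cfg = SyntheticConfig(n_peaks=60, n_genes=50, seed=77)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    paths1 = write_dataset(cfg, d1)
    paths2 = write_dataset(cfg, d2)
    for key in paths1:
        with open(paths1[key], "rb") as f1, open(paths2[key], "rb") as f2:
            assert f1.read() == f2.read(), f"{key} differs between runs"
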