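"""Mosaic simulator: breakpoint statistics, marginals, spikes, emission."""

import numpy as np
import pytest

from admixlocus import (
    EnrichmentSpike,
    SimulationParams,
    concat_chromosomes,
    emit_cohort,
    recover_mixing,
    simulate_cohort,
    simulate_haplotype,
    summarize_ancestry,
)
from admixlocus.errors import ConfigError, DegenerateInputError
from admixlocus.pipeline import read_rfmix_dir


class TestParams:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationParams(mix=(0.5, 0.2, 0.2))

    def test_noise_bounded(self):
        with pytest.raises(ConfigError):
            SimulationParams(posterior_noise=0.5)


class TestHaplotypeMosaic:
    def test_breakpoint_count_matches_poisson_mean(self):
        # g=1, L=100 cM -> Poisson(1); mean over 10,000 haplotypes within 3 SE
        params = SimulationParams(generations=1, n_samples=1)
        rng = np.random.default_rng(123)
        counts = [
            len(simulate_haplotype(params, "1", rng)[0]) for _ in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.03)

    def test_degenerate_mix_gives_single_ancestry(self):
        params = SimulationParams(mix=(1.0, 0.0, 0.0), generations=50, n_samples=1)
        rng = np.random.default_rng(1)
        _, codes = simulate_haplotype(params, "1", rng)
        assert set(codes) == {1}

    def test_marginal_ancestry_matches_mix(self):
        # empirical segment-ancestry frequency at a locus ~ mix within 4 SE
        params = SimulationParams(
            mix=(0.3, 0.3, 0.4), n_samples=400, n_snps=5, posterior_noise=0.0, seed=3
        )
        _, vits, _, _ = simulate_cohort(params)
        codes = vits[0].codes  # (5, 800)
        n = codes.shape[1]
        for k, m in enumerate(params.mix):
            freq = (codes == k + 1).mean(axis=1)
            se = np.sqrt(m * (1 - m) / n)
            assert np.all(np.abs(freq - m) < 4 * se)

    @pytest.mark.parametrize("g,n_samples", [(5, 420), (20, 120)])
    def test_mean_tract_length_is_100_over_g(self, g, n_samples):
        params = SimulationParams(generations=g, n_samples=n_samples, n_snps=2, seed=g)
        _, _, truth, _ = simulate_cohort(params)
        n_tracts = truth.n_breakpoints() + 2 * n_samples  # segments per haplotype
        assert n_tracts >= 5000
        assert truth.mean_tract_length_cm() == pytest.approx(100 / g, rel=0.10)


class TestPosteriorEmission:
    def test_zero_noise_posteriors_are_one_hot(self):
        params = SimulationParams(n_samples=2, n_snps=5, posterior_noise=0.0, seed=4)
        parts, vits, _, _ = simulate_cohort(params)
        probs = parts[0].probs
        assert set(np.unique(probs)) == {0.0, 1.0}

    def test_truth_argmax_equals_viterbi(self):
        params = SimulationParams(n_samples=5, n_snps=20, seed=5)
        parts, vits, truth, _ = simulate_cohort(params)
        np.testing.assert_array_equal(
            parts[0].probs.argmax(axis=2) + 1, vits[0].codes
        )
        for j, h in enumerate(parts[0].haplotype_ids):
            np.testing.assert_array_equal(
                truth.codes_at(h, "1", parts[0].locations_cm), vits[0].codes[:, j]
            )

    def test_zero_noise_summary_equals_truth_frequencies(self):
        params = SimulationParams(
            mix=(0.2, 0.25, 0.55), n_samples=20, n_snps=50, posterior_noise=0.0, seed=7
        )
        parts, vits, _, samples = simulate_cohort(params)
        summary = summarize_ancestry(concat_chromosomes(parts), samples)
        freq = np.stack(
            [(vits[0].codes == k + 1).mean(axis=1) for k in range(3)], axis=1
        )
        np.testing.assert_allclose(summary.avg, freq, atol=1e-12)

    def test_fb_file_shape_contract(self, tmp_path):
        params = SimulationParams(n_samples=2, n_snps=5, seed=8)
        out = emit_cohort(params, out_dir=tmp_path / "sim")
        rows = (out / "chr1.ForwardBackward.txt").read_text().splitlines()
        assert len(rows) == 5
        assert all(len(r.split()) == 12 for r in rows)  # 4 haplotypes x K=3

    def test_emitted_files_reread_without_warnings(self, tmp_path):
        params = SimulationParams(n_samples=3, n_snps=10, seed=9)
        out = emit_cohort(params, out_dir=tmp_path / "sim")
        parts_disk, samples = read_rfmix_dir(out)
        parts_mem, _, _, _ = simulate_cohort(params)
        np.testing.assert_allclose(
            parts_disk[0].probs, parts_mem[0].probs, atol=1e-6
        )
        assert samples.sample_ids == params.sample_ids


class TestSpikes:
    def test_spike_raises_focal_ancestry_inside_window(self):
        spike = EnrichmentSpike(
            chrom="1", cm_start=40.0, cm_end=50.0, ancestry="NA", boost=0.9
        )
        params = SimulationParams(
            mix=(0.64, 0.21, 0.15), n_samples=500, n_snps=100, posterior_noise=0.0, seed=10
        )
        _, vits, _, _ = simulate_cohort(params, [spike])
        cm = (np.arange(100) + 0.5) * 1.0
        na_freq = (vits[0].codes == 3).mean(axis=1)
        inside = (cm >= 40) & (cm <= 50)
        assert na_freq[inside].mean() > 0.8
        assert na_freq[~inside].mean() < 0.25

    def test_boost_below_baseline_rejected(self):
        spike = EnrichmentSpike(chrom="1", cm_start=1, cm_end=2, ancestry="IBS", boost=0.5)
        params = SimulationParams(n_samples=1, n_snps=2, seed=1)
        with pytest.raises(ConfigError, match="boost"):
            simulate_cohort(params, [spike])


class TestRecoverMixing:
    def test_exact_for_degenerate_noiseless_mix(self):
        params = SimulationParams(
            mix=(1.0, 0.0, 0.0), n_samples=5, n_snps=10, posterior_noise=0.0, seed=11
        )
        parts, _, _, samples = simulate_cohort(params)
        est = recover_mixing(summarize_ancestry(concat_chromosomes(parts), samples))
        np.testing.assert_allclose(est, [1.0, 0.0, 0.0], atol=1e-12)

    def test_label_permutation_equivariance(self):
        params = SimulationParams(
            mix=(0.2, 0.3, 0.5), generations=5, n_samples=30, n_snps=50, seed=12
        )
        parts, _, _, samples = simulate_cohort(params)
        summary = summarize_ancestry(concat_chromosomes(parts), samples)
        est = recover_mixing(summary)
        permuted = summary.select(range(summary.n_variants))
        permuted.avg = summary.avg[:, ::-1]
        if permuted.per_sample is not None:
            permuted.per_sample = summary.per_sample[:, :, ::-1]
        permuted.labels = summary.labels[::-1]
        np.testing.assert_allclose(recover_mixing(permuted), est[::-1], atol=1e-12)

    def test_empty_summary_is_degenerate(self):
        from admixlocus.ancestry import LocusAncestrySummary

        empty = LocusAncestrySummary(
            rsids=[],
            chroms=np.empty(0, dtype=object),
            positions_bp=np.empty(0, dtype=int),
            locations_cm=np.empty(0),
            avg=np.empty((0, 3)),
            per_sample=None,
            sample_ids=[],
            labels=("IBS", "YRI", "NA"),
        )
        with pytest.raises(DegenerateInputError):
            recover_mixing(empty)
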