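"""Cohort ancestry summaries: averaging semantics, lookups, .anc round-trip."""

import numpy as np
import pytest

from admixlocus import (
    AncestryPosterior,
    SampleSet,
    concat_chromosomes,
    lookup_summary,
    read_anc,
    summarize_ancestry,
    write_anc,
)
from admixlocus.errors import ConsistencyError


def make_posterior(probs, chrom="1"):
    probs = np.asarray(probs, dtype=float)
    n, h, _ = probs.shape
    ids = [f"s{i // 2 + 1}.{i % 2}" for i in range(h)]
    return AncestryPosterior(
        chrom=chrom,
        probs=probs,
        haplotype_ids=ids,
        locations_cm=np.arange(n, dtype=float),
        positions_bp=(np.arange(n) + 1) * 1000,
        rsids=[f"rs{i}" for i in range(n)],
    )


class TestAveraging:
    def test_two_hard_called_samples_average(self):
        # sample 1 diploid (1,0,0); sample 2 diploid (0,0,1)
        probs = [[[1, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1]]]
        ls = summarize_ancestry(make_posterior(probs), SampleSet(["s1", "s2"]))
        np.testing.assert_allclose(ls.avg[0], [0.5, 0.0, 0.5])

    def test_heterozygous_sample_averages_its_haplotypes(self):
        probs = [[[1, 0, 0], [0, 1, 0]]]
        ls = summarize_ancestry(make_posterior(probs), SampleSet(["s1"]))
        np.testing.assert_allclose(ls.per_sample[0, 0], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(ls.avg[0], [0.5, 0.5, 0.0])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet([1, 2, 3], size=(3, 40))  # 3 variants, 20 samples
        ls = summarize_ancestry(make_posterior(probs), SampleSet([f"s{i+1}" for i in range(20)]))
        # independent double-loop oracle
        for v in range(3):
            expected = np.zeros(3)
            for s in range(20):
                expected += 0.5 * (probs[v, 2 * s] + probs[v, 2 * s + 1])
            expected /= 20
            np.testing.assert_allclose(ls.avg[v], expected, atol=1e-12)

    def test_avg_conserves_probability_mass(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet([1, 1, 1], size=(5, 8))
        ls = summarize_ancestry(make_posterior(probs), SampleSet([f"s{i+1}" for i in range(4)]))
        np.testing.assert_allclose(ls.avg.sum(axis=1), 1.0, atol=1e-9)

    def test_sample_order_does_not_change_avg(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet([1, 1, 1], size=(4, 6))
        ap = make_posterior(probs)
        a = summarize_ancestry(ap, SampleSet(["s1", "s2", "s3"]))
        b = summarize_ancestry(ap, SampleSet(["s3", "s1", "s2"]))
        np.testing.assert_allclose(a.avg, b.avg, atol=1e-12)

    def test_missing_haplotype_is_consistency_error(self):
        probs = [[[1, 0, 0], [0, 1, 0]]]
        with pytest.raises(ConsistencyError, match="s9"):
            summarize_ancestry(make_posterior(probs), SampleSet(["s9"]))

    def test_output_ordered_chromosome_major_then_cm(self):
        rng = np.random.default_rng(8)
        parts = [
            make_posterior(rng.dirichlet([1, 1, 1], size=(2, 4)), chrom="2"),
            make_posterior(rng.dirichlet([1, 1, 1], size=(2, 4)), chrom="10"),
        ]
        ls = summarize_ancestry(concat_chromosomes(parts), SampleSet(["s1", "s2"]))
        assert list(ls.chroms) == ["2", "2", "10", "10"]
        assert list(ls.locations_cm) == [0.0, 1.0, 0.0, 1.0]


class TestLookup:
    @pytest.fixture
    def summary(self):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet([1, 1, 1], size=(10, 4))
        return summarize_ancestry(make_posterior(probs), SampleSet(["s1", "s2"]))

    def test_partial_hit_reports_found_and_missing(self, summary):
        # mirrors inferring ancestry for 10 of 50 queried loci
        queries = [f"rs{i}" for i in range(50)]
        found, missing = lookup_summary(summary, queries)
        assert found.n_variants == 10
        assert len(missing) == 40
        assert found.n_variants + len(missing) == len(queries)

    def test_empty_query(self, summary):
        found, missing = lookup_summary(summary, [])
        assert found.n_variants == 0 and missing == []

    def test_all_present_query_has_no_missing(self, summary):
        found, missing = lookup_summary(summary, ["rs3", "rs7"])
        assert found.rsids == ["rs3", "rs7"] and missing == []


def test_anc_file_round_trip_preserves_averages(tmp_path):
    rng = np.random.default_rng(10)
    probs = rng.dirichlet([2, 1, 1], size=(6, 6))
    ls = summarize_ancestry(make_posterior(probs), SampleSet(["s1", "s2", "s3"]))
    path = tmp_path / "all_chr.anc"
    write_anc(ls, path)
    back = read_anc(path)
    np.testing.assert_allclose(back.avg, ls.avg, atol=1e-9)
    assert back.rsids == ls.rsids
    assert back.sample_ids == ["s1", "s2", "s3"]
    header = path.read_text().splitlines()[0].split("\t")
    assert header[:7] == ["rsid", "chrom", "pos_bp", "cM", "avg_IBS", "avg_YRI", "avg_NA"]
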