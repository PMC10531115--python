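"""Random controls, threshold classification, and contingency testing."""

import math

import numpy as np
import pandas as pd
import pytest

from admixlocus import (
    EnrichmentCounts,
    SampleSet,
    compare_enrichment,
    count_enriched,
    fisher_exact_2xc,
    random_control,
    summarize_ancestry,
)
from admixlocus.catalog import SnpCatalog, SnpRecord
from admixlocus.errors import DegenerateInputError, SizeError, ValidationError
from tests.test_ancestry import make_posterior


@pytest.fixture
def small_universe():
    rng = np.random.default_rng(21)
    probs = rng.dirichlet([1, 1, 1], size=(10, 4))
    return summarize_ancestry(make_posterior(probs), SampleSet(["s1", "s2"]))


class TestCountEnriched:
    def test_published_random_panel_counts(self, random_ancestry_frame):
        counts = count_enriched(random_ancestry_frame)
        assert counts.counts == {"IBS": 2, "YRI": 20, "NA": 25}
        assert counts.n_unclassified == 13
        assert counts.n_loci == 60

    def test_strongly_native_american_row_classified_na(self, random_ancestry_frame):
        row = random_ancestry_frame[random_ancestry_frame.rsid == "rs12033818"]
        counts = count_enriched(row)
        assert counts.counts == {"IBS": 0, "YRI": 0, "NA": 1}

    def test_exact_half_is_not_enriched(self, random_ancestry_frame):
        # strict > 0.50: a locus at exactly 0.50 stays unclassified
        row = random_ancestry_frame[random_ancestry_frame.rsid == "rs75910375"]
        assert float(row.NA.iloc[0]) == 0.50
        assert count_enriched(row).n_unclassified == 1

    def test_uniform_row_unclassified(self):
        df = pd.DataFrame({"IBS": [1 / 3], "YRI": [1 / 3], "NA": [1 / 3]})
        assert count_enriched(df).n_unclassified == 1

    def test_row_order_invariant(self, random_ancestry_frame):
        shuffled = random_ancestry_frame.sample(frac=1, random_state=3)
        assert count_enriched(shuffled).as_row() == count_enriched(
            random_ancestry_frame
        ).as_row()

    def test_bad_sum_is_validation_error(self):
        df = pd.DataFrame({"IBS": [0.9], "YRI": [0.4], "NA": [0.1]})
        with pytest.raises(ValidationError, match="sum"):
            count_enriched(df)

    def test_classes_partition_loci(self, cvd_ancestry_frame):
        c = count_enriched(cvd_ancestry_frame)
        assert sum(c.counts.values()) + c.n_unclassified == c.n_loci == 10


class TestRandomControl:
    def _exclude(self, summary, idx):
        return SnpCatalog(
            records=[
                SnpRecord(
                    summary.rsids[i],
                    str(summary.chroms[i]),
                    int(summary.positions_bp[i]),
                )
                for i in idx
            ]
        )

    def test_deterministic_and_respects_exclusion(self, small_universe):
        excl = self._exclude(small_universe, [0, 1])
        a = random_control(small_universe, excl, 3, seed=99)
        b = random_control(small_universe, excl, 3, seed=99)
        assert a.rsids == b.rsids
        assert len(set(a.rsids)) == 3
        assert not set(a.rsids) & {"rs0", "rs1"}

    def test_exclusion_matches_by_position_alone(self, small_universe):
        # exclude rs0 by its coordinates under a different name
        excl = SnpCatalog(
            records=[
                SnpRecord(
                    "renamed",
                    str(small_universe.chroms[0]),
                    int(small_universe.positions_bp[0]),
                )
            ]
        )
        out = random_control(small_universe, excl, 9, seed=1)
        assert "rs0" not in out.rsids

    def test_full_remainder_is_a_shuffle(self, small_universe):
        excl = self._exclude(small_universe, [0, 1])
        out = random_control(small_universe, excl, 8, seed=5)
        assert sorted(out.rsids) == [f"rs{i}" for i in range(2, 10)]

    def test_overdraw_is_size_error(self, small_universe):
        excl = self._exclude(small_universe, [0, 1])
        with pytest.raises(SizeError, match="8"):
            random_control(small_universe, excl, 9, seed=5)

    def test_inclusion_frequencies_uniform_over_seeds(self, small_universe):
        # every variant should be drawn with frequency n/|universe|
        n, universe = 3, small_universe.n_variants
        draws = 2000
        hits = {r: 0 for r in small_universe.rsids}
        for s in range(draws):
            for r in random_control(small_universe, None, n, seed=s).rsids:
                hits[r] += 1
        p = n / universe
        se = math.sqrt(p * (1 - p) / draws)
        for r, h in hits.items():
            assert abs(h / draws - p) < 4 * se, r


class TestCompareEnrichment:
    def test_fisher_oracle_value(self):
        # exhaustive hypergeometric enumeration: p = 2 / C(20, 10)
        p = fisher_exact_2xc(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / math.comb(20, 10), abs=1e-12)

    def test_scipy_agrees_on_2x2(self):
        from scipy.stats import fisher_exact

        table = np.array([[7, 3], [2, 8]])
        assert fisher_exact_2xc(table) == pytest.approx(
            fisher_exact(table).pvalue, rel=1e-9
        )

    def test_identical_counts_give_p_one_under_fisher(self):
        c = EnrichmentCounts(counts={"IBS": 4, "YRI": 3, "NA": 2}, n_loci=10, n_unclassified=1)
        res = compare_enrichment(c, c, method="fisher")
        assert res.p_value == pytest.approx(1.0)

    def test_balanced_table_chi_square_zero(self):
        a = EnrichmentCounts(counts={"IBS": 30, "YRI": 30}, n_loci=60, n_unclassified=0)
        res = compare_enrichment(a, a, method="chi-square")
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_auto_uses_chi_square_only_when_cells_large(self):
        big = EnrichmentCounts(counts={"IBS": 30, "YRI": 30}, n_loci=60, n_unclassified=0)
        small = EnrichmentCounts(counts={"IBS": 2, "YRI": 3}, n_loci=5, n_unclassified=0)
        assert compare_enrichment(big, big).method == "chi-square"
        assert compare_enrichment(small, small).method == "fisher-midp"

    def test_all_zero_table_is_degenerate(self):
        z = EnrichmentCounts(counts={"IBS": 0}, n_loci=0, n_unclassified=0)
        with pytest.raises(DegenerateInputError):
            compare_enrichment(z, z)

    def test_mid_p_is_smaller_than_classical(self):
        table = np.array([[8, 2], [20, 40]])
        assert fisher_exact_2xc(table, mid_p=True) < fisher_exact_2xc(table)

    def test_published_target_vs_control_comparison(
        self, cvd_ancestry_frame, random_ancestry_frame
    ):
        res = compare_enrichment(
            count_enriched(cvd_ancestry_frame), count_enriched(random_ancestry_frame)
        )
        assert 0.0 <= res.p_value <= 1.0
        assert res.table.sum() == 70
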