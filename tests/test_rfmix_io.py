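"""RFMix-dialect I/O: parsing, validation, restriction, concatenation."""

import numpy as np
import pytest

from admixlocus import (
    AncestryPosterior,
    SampleSet,
    concat_chromosomes,
    read_forward_backward,
    write_forward_backward,
)
from admixlocus.rfmix_io import read_sample_list, write_sample_list
from admixlocus.errors import ConsistencyError, ParseError, ValidationError


def write_files(tmp_path, fb_text, loc_text):
    fb, loc = tmp_path / "fb.txt", tmp_path / "loc.txt"
    fb.write_text(fb_text)
    loc.write_text(loc_text)
    return fb, loc


class TestReadForwardBackward:
    def test_hard_calls_parse_to_one_hot_tensor(self, tmp_path):
        fb, loc = write_files(
            tmp_path, "1 0 0 0 1 0\n0 0 1 1 0 0\n", "0.1\n0.5\n"
        )
        ap = read_forward_backward(fb, loc, SampleSet(["s1"]), K=3)
        assert ap.probs.shape == (2, 2, 3)
        assert ap.probs[0, 0, 0] == 1.0 and ap.probs[0, 1, 1] == 1.0
        assert ap.probs[1, 0, 2] == 1.0 and ap.probs[1, 1, 0] == 1.0
        np.testing.assert_allclose(ap.locations_cm, [0.1, 0.5])

    def test_line_count_mismatch_is_consistency_error(self, tmp_path):
        fb, loc = write_files(
            tmp_path, "1 0 0 0 1 0\n0 0 1 1 0 0\n1 0 0 1 0 0\n", "0.1\n0.5\n"
        )
        with pytest.raises(ConsistencyError):
            read_forward_backward(fb, loc, SampleSet(["s1"]), K=3)

    def test_row_not_divisible_by_k_is_format_error(self, tmp_path):
        fb, loc = write_files(tmp_path, "1 0 0 0 1\n", "0.1\n")
        with pytest.raises(ParseError, match="divisible"):
            read_forward_backward(fb, loc, SampleSet(["s1"]), K=3)

    def test_bad_probability_sum_errors_unless_renormalized(self, tmp_path):
        fb, loc = write_files(tmp_path, "0.5 0.2 0.2 0 1 0\n", "0.1\n")
        with pytest.raises(ValidationError, match="renormalize"):
            read_forward_backward(fb, loc, SampleSet(["s1"]), K=3)
        ap = read_forward_backward(
            fb, loc, SampleSet(["s1"]), K=3, renormalize=True
        )
        np.testing.assert_allclose(ap.probs.sum(axis=2), 1.0)

    def test_round_trip_lossless(self, tmp_path, two_sample_posterior):
        rng = np.random.default_rng(11)
        raw = rng.dirichlet([1.2, 0.7, 2.0], size=(7, 4))
        ap = AncestryPosterior(
            chrom="2",
            probs=raw[:, :, :],
            haplotype_ids=["a.0", "a.1", "b.0", "b.1"],
            locations_cm=np.sort(rng.uniform(0, 50, 7)),
        )
        fb, loc = tmp_path / "x.fb", tmp_path / "x.loc"
        write_forward_backward(ap, fb, loc)
        back = read_forward_backward(fb, loc, SampleSet(["a", "b"]), K=3)
        np.testing.assert_allclose(back.probs, ap.probs, atol=1e-6)
        np.testing.assert_allclose(back.locations_cm, ap.locations_cm, atol=1e-6)

    def test_empty_tensor_writes_headerless_empty_files(self, tmp_path):
        ap = AncestryPosterior(
            chrom="1",
            probs=np.empty((0, 2, 3)),
            haplotype_ids=["a.0", "a.1"],
            locations_cm=np.empty(0),
        )
        fb, loc = tmp_path / "e.fb", tmp_path / "e.loc"
        write_forward_backward(ap, fb, loc)
        assert fb.read_text() == "" and loc.read_text() == ""


class TestRestriction:
    def test_restrict_to_sample_subset(self, two_sample_posterior):
        sub = two_sample_posterior.restrict(SampleSet(["s2"]))
        assert sub.haplotype_ids == ["s2.0", "s2.1"]
        np.testing.assert_array_equal(
            sub.probs, two_sample_posterior.probs[:, 2:, :]
        )

    def test_restriction_composes(self, two_sample_posterior):
        via = two_sample_posterior.restrict(SampleSet(["s2", "s1"])).restrict(
            SampleSet(["s1"])
        )
        direct = two_sample_posterior.restrict(SampleSet(["s1"]))
        np.testing.assert_array_equal(via.probs, direct.probs)
        assert via.haplotype_ids == direct.haplotype_ids

    def test_missing_sample_is_consistency_error(self, two_sample_posterior):
        with pytest.raises(ConsistencyError, match="s9"):
            two_sample_posterior.restrict(SampleSet(["s9"]))


class TestConcat:
    def _part(self, chrom, n, seed):
        rng = np.random.default_rng(seed)
        return AncestryPosterior(
            chrom=chrom,
            probs=rng.dirichlet([1, 1, 1], size=(n, 2)),
            haplotype_ids=["s.0", "s.1"],
            locations_cm=np.sort(rng.uniform(0, 10, n)),
        )

    def test_two_chromosomes_concatenate_chromosome_major(self):
        gp = concat_chromosomes([self._part("1", 2, 0), self._part("2", 2, 1)])
        assert gp.n_variants == 4
        assert list(gp.chroms) == ["1", "1", "2", "2"]

    def test_single_part_is_identity(self):
        part = self._part("1", 3, 2)
        gp = concat_chromosomes([part])
        np.testing.assert_array_equal(gp.probs, part.probs)

    def test_permuted_haplotypes_rejected(self):
        a = self._part("1", 2, 3)
        b = self._part("2", 2, 4)
        b.haplotype_ids = ["s.1", "s.0"]
        with pytest.raises(ConsistencyError):
            concat_chromosomes([a, b])


def test_sample_list_round_trip(tmp_path):
    p = tmp_path / "samples.txt"
    write_sample_list(SampleSet(["s1", "s2", "s3"]), p)
    assert read_sample_list(p).sample_ids == ["s1", "s2", "s3"]


def test_sample_set_invariants():
    with pytest.raises(ValidationError):
        SampleSet([])
    with pytest.raises(ValidationError):
        SampleSet(["a", "a"])
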