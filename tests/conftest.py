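import numpy as np
import pytest

from admixlocus import AncestryPosterior, SampleSet


@pytest.fixture(scope="session")
def published_catalog():
    from admixlocus.datasets import load_snp_catalog

    return load_snp_catalog()


@pytest.fixture(scope="session")
def cvd_ancestry_frame():
    from admixlocus.datasets import load_cvd_locus_ancestry

    return load_cvd_locus_ancestry()


@pytest.fixture(scope="session")
def random_ancestry_frame():
    from admixlocus.datasets import load_random_locus_ancestry

    return load_random_locus_ancestry()


@pytest.fixture
def two_sample_posterior():
    """2 variants x 2 samples (4 haplotypes) x K=3, hard calls."""
    probs = np.zeros((2, 4, 3))
    # variant 0: haps -> IBS, YRI, NA, IBS ; variant 1: NA, NA, IBS, YRI
    for v, calls in enumerate([(0, 1, 2, 0), (2, 2, 0, 1)]):
        for h, k in enumerate(calls):
            probs[v, h, k] = 1.0
    return AncestryPosterior(
        chrom="1",
        probs=probs,
        haplotype_ids=["s1.0", "s1.1", "s2.0", "s2.1"],
        locations_cm=np.array([10.0, 20.0]),
        positions_bp=np.array([10_000_000, 20_000_000]),
        rsids=["rs_a", "rs_b"],
    )


@pytest.fixture
def two_samples():
    return SampleSet(sample_ids=["s1", "s2"])
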