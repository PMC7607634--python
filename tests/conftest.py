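import pytest

from rfoma import fixtures

# Printed per-replicate transcript ratios of the four NK-198 Rf1 copies
# (biological replicates N1, N2, N3) — used both as deconvolution inputs and
# as simulation ground truth.
NK198_RATIO_REPLICATES = {
    "orf20_NK-198-1": (0.20, 0.17, 0.16),
    "orf20_NK-198-2": (0.39, 0.41, 0.38),
    "orf20_NK-198-3": (0.16, 0.17, 0.17),
    "orf20_NK-198-4": (0.25, 0.25, 0.29),
}

NK198_RATIO_MEANS = {
    "orf20_NK-198-1": 0.18,
    "orf20_NK-198-2": 0.39,
    "orf20_NK-198-3": 0.17,
    "orf20_NK-198-4": 0.26,
}


@pytest.fixture(scope="session")
def locus():
    """Full six-allele cluster fixture (copies, alleles)."""
    return fixtures.rf1_locus_catalog()


@pytest.fixture(scope="session")
def locus_copies(locus):
    return locus[0]


@pytest.fixture(scope="session")
def nk198_copies():
    """The four NK-198 Rf1 copies used for transcript-ratio deconvolution."""
    return fixtures.nk198_family()
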