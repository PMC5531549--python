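import warnings

import pytest

from bhlhkit import synthetic_data as sd

# saturated-distance cap warnings are expected on toy alignments
warnings.filterwarnings("ignore", message=".*capped at.*")


PAPER_LIKE_CATEGORY_COUNTS = {
    "GBOX_BINDER": 75,
    "EBOX_NON_GBOX": 24,
    "NON_EBOX_BINDER": 5,
    "NON_BINDING": 28,
}

PAPER_LIKE_PATTERN_COUNTS = {
    "I": 20, "II": 4, "III": 4, "IV": 6, "V": 7, "VI": 42,
    "VII": 4, "VIII": 2, "IX": 2, "X": 13,
}


@pytest.fixture(scope="session")
def family_bundle():
    spec = sd.FamilySpec(category_counts=dict(PAPER_LIKE_CATEGORY_COUNTS), seed=7)
    return sd.generate_family(spec)


@pytest.fixture(scope="session")
def locus_bundle():
    spec = sd.LocusSpec(pattern_counts=dict(PAPER_LIKE_PATTERN_COUNTS), seed=3)
    return sd.generate_gene_models(spec)


@pytest.fixture(scope="session")
def expression_bundle():
    return sd.generate_expression(seed=5)


@pytest.fixture()
def locus_dir(locus_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("loci")
    locus_bundle.to_files(d)
    return d
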