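import pytest

from seedmir import annotate, discover, preprocess
from seedmir.simulate import LibraryProfile, SimConfig, simulate_study


def small_config(seed: int = 7) -> SimConfig:
    """Reduced two-library study: 8 precursors, one 8x up-regulated locus."""
    return SimConfig(
        seed=seed, n_precursors=8, n_decoy_contigs=8,
        libraries=[
            LibraryProfile("mature_seed", total_reads=6000,
                           per_locus_abundance=120.0),
            LibraryProfile("developing_seed", total_reads=6000,
                           per_locus_abundance=120.0,
                           fold_change_map={"prec002": 8.0}),
        ])


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def cleaned_libraries(small_study):
    return {lib: preprocess.clean_library(reads, small_study.config.adapter3)
            for lib, reads in small_study.reads.items()}


@pytest.fixture(scope="session")
def small_tags(small_study, cleaned_libraries):
    tags = preprocess.collapse_tags(
        {lib: res.reads for lib, res in cleaned_libraries.items()})
    annotate.match_conserved(tags, small_study.references.plant_matures)
    annotate.classify_ncrna(tags, small_study.references.ncrna)
    return tags


@pytest.fixture(scope="session")
def small_candidates(small_study, small_tags):
    return discover.discover_precursors(
        small_tags, small_study.contigs, small_study.references.bna_matures,
        small_study.references.plant_matures)
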