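"""Shared fixtures: one toy pHMM library and simulated BGC sets.

The library build runs pyhmmer a few dozen times, so it is session
scoped; the simulated sets derive from it deterministically.
"""

from __future__ import annotations

import pytest

from gcfkit.synthetic import make_toy_hmm_library, simulate_bgc_set


@pytest.fixture(scope="session")
def toy_library(tmp_path_factory):
    out = tmp_path_factory.mktemp("toylib")
    return make_toy_hmm_library(out, n_biosyn=6, n_core=2, clades_per_core=3,
                                motif_length=40, seed=11)


@pytest.fixture(scope="session")
def library_index(toy_library):
    return toy_library.load()


@pytest.fixture(scope="session")
def planted_set(tmp_path_factory, toy_library):
    """Noise-free planted set: 5 GCFs × 8 BGCs, feature-identical members."""
    out = tmp_path_factory.mktemp("planted")
    return simulate_bgc_set(out, toy_library, n_gcfs=5, bgcs_per_gcf=8,
                            within_mutation_rate=0.0, fragment_fraction=0.0, seed=21)


@pytest.fixture(scope="session")
def noisy_set(tmp_path_factory, toy_library):
    """Planted set with sequence noise and 25% fragments."""
    out = tmp_path_factory.mktemp("noisy")
    return simulate_bgc_set(out, toy_library, n_gcfs=5, bgcs_per_gcf=8,
                            within_mutation_rate=0.02, fragment_fraction=0.25, seed=22)


@pytest.fixture(scope="session")
def planted_bgcs(planted_set):
    from gcfkit.genbank import parse_dataset_dir

    return parse_dataset_dir(planted_set.bgc_dir, dataset="planted")


@pytest.fixture(scope="session")
def planted_matrix(planted_bgcs, library_index):
    from gcfkit.features import assemble_matrix
    from gcfkit.pipeline import extract_features

    vectors, _, _ = extract_features(planted_bgcs, library_index)
    return assemble_matrix(vectors, library_index.feature_columns())
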