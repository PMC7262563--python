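"""Shared fixtures: synthetic bundles and derived promoter signal matrices.

Everything is generated programmatically at test time; session scope keeps
the default study bundle (n=1200 transcripts, seed 7) to a single build.
"""

from __future__ import annotations

import pytest

from gametrace.chromatin_state import (
    label_thresholds,
    promoter_windows,
    signal_matrix,
)
from gametrace.simulate import GERM_LAYERS, Bundle, SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    """The default study bundle: n=1200, seed 7, zero dropout."""
    return simulate_bundle()


@pytest.fixture(scope="session")
def dropout_bundle() -> Bundle:
    """Same design with 10% dropout on planted-miscellaneous transcripts."""
    return simulate_bundle(SimConfig(dropout_misc=0.1))


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """A light bundle (n=150, seed 3) with a genome, for file-level tests."""
    return simulate_bundle(SimConfig(seed=3, n_transcripts=150), include_genome=True)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    small_bundle.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def windows(bundle):
    return promoter_windows(bundle.transcripts)


@pytest.fixture(scope="session")
def sperm_signal(bundle, windows):
    """(K4, K27) promoter signal matrices for sperm."""
    k4 = signal_matrix(bundle.coverage[("H3K4me3", "sperm")], windows)
    k27 = signal_matrix(bundle.coverage[("H3K27me3", "sperm")], windows)
    return k4, k27


@pytest.fixture(scope="session")
def sperm_thresholds(sperm_signal):
    return label_thresholds(*sperm_signal)


@pytest.fixture(scope="session")
def germlayer_signal(bundle, windows):
    """compartment -> (K4, K27) matrices for the three germ layers."""
    return {
        comp: (
            signal_matrix(bundle.coverage[("H3K4me3", comp)], windows),
            signal_matrix(bundle.coverage[("H3K27me3", comp)], windows),
        )
        for comp in GERM_LAYERS
    }


@pytest.fixture(scope="session")
def group_assignments(bundle, sperm_signal, sperm_thresholds):
    """Per (category, biotype) chromatin assignments, clustered with auto-k."""
    from gametrace.chromatin_state import cluster_promoters, label_clusters

    k4, k27 = sperm_signal
    truth = bundle.truth.df
    out = {}
    for cat, bio in [
        ("Sp", "lincRNA"),
        ("SpOc", "lincRNA"),
        ("Sp", "protein_coding"),
        ("SpOc", "protein_coding"),
    ]:
        ids = list(
            truth.index[(truth.gamete_category == cat) & (truth.biotype == bio)]
        )
        sk4, sk27 = k4.subset(ids), k27.subset(ids)
        clusters = cluster_promoters(sk4, sk27, k="auto", seed=7)
        out[(cat, bio)] = (
            clusters,
            label_clusters(clusters, sk4, sk27, thresholds=sperm_thresholds),
        )
    return out
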