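import numpy as np
import pytest

from tsrnakit.reference import cluster_by_prefix
from tsrnakit.simulate import (
    LibraryConfig,
    random_contigs,
    simulate_small_rna_library,
    simulate_trna_reference,
)


@pytest.fixture(scope="session")
def reference():
    """60 simulated tRNA genes (12 anticodons) plus planting manifest."""
    genes, manifest = simulate_trna_reference(60, 12, seed=101)
    return genes, manifest


@pytest.fixture(scope="session")
def clusters(reference):
    genes, _ = reference
    return cluster_by_prefix(genes)


@pytest.fixture(scope="session")
def decoys():
    return random_contigs(2, 2500, seed=102, prefix="decoy")


@pytest.fixture(scope="session")
def rrna():
    return random_contigs(1, 1500, seed=103, prefix="rRNA")


@pytest.fixture(scope="session")
def clean_library(clusters, decoys, rrna):
    """Error-free 4000-read library with its truth manifest."""
    cfg = LibraryConfig(n_reads=4000, error_rate=0.0, seed=104)
    reads, manifest = simulate_small_rna_library(cfg, clusters, decoys, rrna)
    return cfg, reads, manifest
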