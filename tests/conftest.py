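from pathlib import Path

import numpy as np
import pytest

import sweepmap as sm

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_paths():
    return DATA / "toy_genotypes.tsv", DATA / "toy_markers.tsv"


@pytest.fixture(scope="session")
def toy_matrix(toy_paths):
    return sm.read_genotype_tsv(toy_paths[0])


@pytest.fixture(scope="session")
def toy_table(toy_paths):
    return sm.read_marker_table(toy_paths[1])


@pytest.fixture(scope="session")
def f2_clean():
    """Error-free, missing-free F2: 30 well-spaced markers on one 150-cM
    chromosome (spacing wide enough that chance co-segregation is negligible),
    plus 25% twin duplicates."""
    cfg = sm.F2SimConfig(
        n_progeny=113,
        chromosomes=[("chr1", 150.0, 15_000_000)],
        n_markers_per_chrom=40,
        twin_cluster_rate=0.25,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=101,
    )
    return sm.simulate_f2_population(cfg)


@pytest.fixture(scope="session")
def f2_two_chrom():
    """Two-chromosome error-free F2 for linkage-group recovery."""
    cfg = sm.F2SimConfig(
        n_progeny=113,
        chromosomes=[("chrA", 100.0, 10_000_000), ("chrB", 80.0, 8_000_000)],
        n_markers_per_chrom=15,
        twin_cluster_rate=0.0,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=7,
    )
    return sm.simulate_f2_population(cfg)


@pytest.fixture(scope="session")
def panel_default():
    """Default 86-accession three-subpopulation panel with the planted sweep."""
    return sm.simulate_diversity_panel(sm.PanelSimConfig(seed=5))


def sim_f2_pair(r_true: float, n: int, rng: np.random.Generator):
    """Two F2 dosage columns at a known recombination fraction (coupling)."""
    g1a = (rng.random(n) < 0.5).astype(np.int8)
    g1b = (rng.random(n) < 0.5).astype(np.int8)
    rec = lambda a: np.where(rng.random(n) < r_true, 1 - a, a)  # noqa: E731
    return (g1a + g1b).astype(np.int8), (rec(g1a) + rec(g1b)).astype(np.int8)
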