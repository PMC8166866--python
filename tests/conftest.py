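import numpy as np
import pandas as pd
import pytest

from ilkit.genome import ChromosomeSpec, GeneticMap, Genome, default_genome, linear_map, uniform_panel
from ilkit.segments import call_segments
from ilkit.sim import (
    DONOR,
    RECURRENT,
    Individual,
    SimulationConfig,
    genotype_population,
    make_cross,
    run_breeding_scheme,
)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def gmap(genome):
    return linear_map(genome)


@pytest.fixture(scope="session")
def two_marker_map():
    """One 30 Mb chromosome with markers (10 Mb, 20 cM) and (20 Mb, 40 cM)."""
    genome = Genome((ChromosomeSpec("chr1", 30_000_000, 60.0),))
    df = pd.DataFrame(
        [("m1", "chr1", 10_000_000, 20.0), ("m2", "chr1", 20_000_000, 40.0)],
        columns=["marker_id", "chrom", "bp", "cm"],
    )
    return GeneticMap(df), genome


@pytest.fixture(scope="session")
def founders(genome):
    return (
        Individual.founder("REC", genome, RECURRENT),
        Individual.founder("DON", genome, DONOR),
    )


@pytest.fixture(scope="session")
def bc1_pool(genome, gmap, founders):
    """320 BC1 individuals genotyped on a 48-SNP panel, with called segments."""
    rec, don = founders
    rng = np.random.default_rng(20180615)
    f1 = make_cross(rec, don, gmap, genome, rng, "F1")
    bc1 = [
        make_cross(rec, f1, gmap, genome, rng, f"BC1_{i:04d}", generation="BC1")
        for i in range(320)
    ]
    panel = uniform_panel(genome, 48, gmap)
    matrix = genotype_population(bc1, panel, genome)
    segments = {
        ind: call_segments(matrix.row(ind), panel, genome, gmap)
        for ind in matrix.individuals
    }
    return {"individuals": bc1, "panel": panel, "matrix": matrix, "segments": segments}


SMALL_CONFIG = dict(
    seed=11,
    n_bc1=60,
    n_progeny=10,
    panel_set1=24,
    panel_full=48,
    max_generations=8,
)


@pytest.fixture(scope="session")
def small_config():
    return dict(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_scheme_run():
    """One complete (scaled-down) breeding-scheme run, shared across tests."""
    collection, stats = run_breeding_scheme(SimulationConfig(**SMALL_CONFIG))
    return collection, stats
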