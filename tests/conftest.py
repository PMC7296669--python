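import numpy as np
import pandas as pd
import pytest

from ripmut.genome import GenomeAssembly, encode, empty_intervals
from ripmut.simulate import (
    PARENTS,
    SPORES,
    AscusCalls,
    SimConfig,
    simulate_depth_and_calls,
    simulate_genome,
    simulate_tetrad,
)


def small_config(**overrides) -> SimConfig:
    """A fast, small cross: ~120 kb genome, paper-like architecture."""
    defaults = dict(
        seed=7,
        n_contigs=2,
        contig_length=60_000,
        n_te_duplicates=4,
        n_cds_duplicates=3,
        centromere_length=4000,
        low_coverage_fraction=0.0,
        depth_floor=10,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def genome(config):
    return simulate_genome(config)


@pytest.fixture(scope="session")
def tetrad(config, genome):
    return simulate_tetrad(genome, config, tetrad_id=0)


@pytest.fixture(scope="session")
def ascus(config, tetrad):
    return simulate_depth_and_calls(tetrad, config)


CALL_COLUMNS = ["sample_id", "contig", "pos", "ref", "alt", "qual", "depth", "zygosity"]


def make_ascus(call_rows, contig_length=10_000, depth=50, ascus_id=0) -> AscusCalls:
    """Hand-built ascus: uniform coverage plus explicit call rows.

    call_rows: (sample_id, contig, pos[1-based], ref, alt, qual, depth,
    zygosity) tuples; missing trailing fields default to qual=60/depth/hom.
    """
    rows = []
    contigs = set()
    for row in call_rows:
        row = list(row)
        while len(row) < 8:
            row.append({5: 60.0, 6: depth, 7: "hom"}[len(row)])
        contigs.add(row[1])
        rows.append(tuple(row))
    contigs = sorted(contigs) or ["chr1"]
    profiles = {
        s: {c: np.full(contig_length, depth, dtype=np.int32) for c in contigs}
        for s in PARENTS + SPORES
    }
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return AscusCalls(
        ascus_id=ascus_id, calls=calls, depth=profiles,
        contig_lengths={c: contig_length for c in contigs},
    )


def toy_genome(sequence: str, duplicates=None, name="chr1") -> GenomeAssembly:
    dup = empty_intervals()
    if duplicates:
        dup = pd.DataFrame(duplicates, columns=["contig", "start", "end"])
    return GenomeAssembly(sequences={name: encode(sequence)}, duplicates=dup)
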