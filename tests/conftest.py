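"""Shared fixtures: small and full-scale synthetic datasets.

The tiny fixture (two 400 kb chromosomes, shallow depth) exercises every
pipeline stage in seconds and is used by unit/integration tests. The
full-scale fixture uses the generator defaults and is session-scoped so the
end-to-end recovery tests share one realisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylhet import io, readstats, simulate


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small seeded genome + reads; returns paths, tables and ground truth."""
    rng = np.random.default_rng(11)
    spec = simulate.GenomeSpec(
        chromosomes=[("chrT1", 400_000), ("chrT2", 400_000)],
        region_min=80_000,
        region_max=150_000,
    )
    genome = simulate.generate_genome(spec, rng)
    data = simulate.generate_reads(
        genome, simulate.ReadSpec(depth=12.0), rng, seed_for_tracks=11
    )
    outdir = tmp_path_factory.mktemp("tiny_fixture")
    paths = simulate.write_fixture(outdir, genome, data)
    sites = io.read_site_calls(paths["calls_cpg"])
    return {
        "genome": genome,
        "data": data,
        "paths": paths,
        "sites": sites,
    }


@pytest.fixture(scope="session")
def tiny_reads(tiny_dataset):
    """Retained read vectors + per-read statistics for the tiny dataset."""
    vectors = readstats.build_read_vectors(tiny_dataset["sites"])
    reads = readstats.compute_read_stats(vectors)
    truth = tiny_dataset["data"]["truth_reads"].set_index("read_id")["regime"]
    reads["regime"] = reads["read_id"].map(truth)
    return {"vectors": vectors, "reads": reads}


@pytest.fixture(scope="session")
def full_dataset():
    """Generator-default dataset (in memory) for end-to-end recovery tests."""
    rng = np.random.default_rng(7)
    genome = simulate.generate_genome(simulate.GenomeSpec(), rng)
    data = simulate.generate_reads(genome, simulate.ReadSpec(), rng, seed_for_tracks=7)
    calls = data["calls_cpg"]
    # route through the parser exactly as a real run would
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        path = os.path.join(td, "calls.tsv")
        calls.to_csv(path, sep="\t", index=False)
        sites = io.read_site_calls(path)
    vectors = readstats.build_read_vectors(sites)
    reads = readstats.compute_read_stats(vectors)
    truth = data["truth_reads"].set_index("read_id")["regime"]
    reads["regime"] = reads["read_id"].map(truth)
    return {
        "genome": genome,
        "data": data,
        "sites": sites,
        "vectors": vectors,
        "reads": reads,
    }


def random_read_vector(rng, n_sites=120, spacing=50, p=0.5) -> readstats.ReadMethVector:
    """Helper: a random binary read vector for oracle tests."""
    gaps = 2 + rng.geometric(1.0 / spacing, size=n_sites)
    positions = np.cumsum(gaps).astype(np.int64)
    states = (rng.random(n_sites) < p).astype(np.uint8)
    return readstats.ReadMethVector(
        read_id="r", chrom="c", span_start=int(positions[0]),
        span_end=int(positions[-1]) + 2, positions=positions, states=states,
    )
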