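import pytest

from readthrough.detect import DetectParams, call_readthroughs
from readthrough.iar_partition import partition_iars
from readthrough.index import build_all
from readthrough.simulate import SimConfig, make_genome, simulate_reads
from readthrough.sketch import SketchParams


@pytest.fixture(scope="session")
def small_sim():
    """Tiny error-free benchmark: 8 genes, 3 read-through pairs, x20 depth."""
    config = SimConfig(seed=11, n_chroms=1, genes_per_chrom=8, n_readthrough_pairs=3, depth=20)
    sim = make_genome(config)
    reads = simulate_reads(sim.transcripts, config)
    return config, sim, reads


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    config, sim, reads = small_sim
    params = SketchParams()
    iars = partition_iars(sim.genes, thr=params.thr)
    indexes = build_all(iars, sim.chrom_seqs, params)
    return sim, reads, params, iars, indexes


@pytest.fixture(scope="session")
def small_calls(small_pipeline):
    sim, reads, params, iars, indexes = small_pipeline
    calls = call_readthroughs(
        ((r.read_id, r.seq) for r in reads), indexes, iars, params, DetectParams()
    )
    return sim, reads, calls
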