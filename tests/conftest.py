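import io

import numpy as np
import pytest

import trnaquant as tq
from trnaquant.preprocess import parse_fastq
from trnaquant.simulate import SimConfig, simulate_genome, simulate_reads


@pytest.fixture
def toy_genome():
    """Two chromosomes with deterministic sequence for hand-checked tests."""
    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        "chr1": rng.choice(bases, 600).tobytes().decode(),
        "chr2": rng.choice(bases, 400).tobytes().decode(),
    }


def build_sim_pipeline(cfg: SimConfig, align_seed: int = 5):
    """Run genome sim -> bundle -> read sim -> two-round quantification."""
    genome, ann = simulate_genome(cfg)
    genes = tq.assign_gtrnadb_names(
        tq.parse_trna_annotation(ann.splitlines(), genome), genome
    )
    bundle = tq.build_bundle(genome, genes)
    fastq, truth = simulate_reads(bundle, genome, genes, cfg)
    reads = [(r.read_id, r.seq) for r in parse_fastq(io.StringIO(fastq))]
    table, tally, drop = tq.quantify_reads(reads, bundle, seed=align_seed)
    return dict(genome=genome, annotation=ann, genes=genes, bundle=bundle,
                fastq=fastq, truth=truth, reads=reads, table=table,
                tally=tally, drop=drop)


@pytest.fixture(scope="session")
def small_sim():
    """Small deterministic simulation shared across end-to-end tests."""
    cfg = SimConfig(seed=42, n_reads=3000, n_genes=12, n_chroms=1,
                    chrom_len=30_000, intron_prob=0.0, error_rate=0.0)
    return build_sim_pipeline(cfg)
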