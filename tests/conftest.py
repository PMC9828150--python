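"""Shared fixtures: synthetic genomes, containers and a small database."""

from __future__ import annotations

import numpy as np
import pytest

from chunkprof.bloom import IndexParams, build_index
from chunkprof.genome_prep import KmerContainer, PrepParams, split_genome
from chunkprof.hashing import canonical_kmer_hashes
from chunkprof.search import Database
from chunkprof.simulate import CommunitySpec, make_taxdump, random_genome, simulate_reads
from chunkprof.taxonomy import Taxonomy

K = 21


def containers_from_genome(
    genome: str, reference_id: str, n_chunks: int = 10, overlap: int = 150, k: int = K
) -> list[KmerContainer]:
    """Chunk one plain sequence into containers (no FASTA round-trip)."""
    intervals = split_genome(len(genome), n_chunks, overlap)
    return [
        KmerContainer(
            reference_id=reference_id,
            chunk_index=i,
            n_chunks=len(intervals),
            hashes=canonical_kmer_hashes(genome[a:b], k),
            genome_size=len(genome),
            k=k,
        )
        for i, (a, b) in enumerate(intervals)
    ]


@pytest.fixture(scope="session")
def ten_genomes() -> list[str]:
    return [random_genome(20_000, 1000 + i) for i in range(10)]


@pytest.fixture(scope="session")
def hundred_chunks(ten_genomes) -> list[KmerContainer]:
    out = []
    for i, g in enumerate(ten_genomes):
        out.extend(containers_from_genome(g, f"g{i}"))
    return out


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """3-species community with database, taxonomy and error-free reads."""
    spec = CommunitySpec(
        genome_lengths=[60_000, 60_000, 60_000],
        proportions=[0.5, 0.3, 0.2],
        n_reads=3000,
        read_length=150,
        identity=1.0,
        seed=11,
    )
    reads, truth, genomes = simulate_reads(spec)
    containers = []
    for name, g in zip(spec.genome_names, genomes):
        containers.extend(containers_from_genome(g, name))
    blocks, meta = build_index(containers, IndexParams(fpr=0.3))
    db = Database(blocks, meta)
    taxdir = tmp_path_factory.mktemp("taxdump")
    mapping = make_taxdump(taxdir, n_species=3, genome_names=spec.genome_names)
    taxonomy = Taxonomy.from_taxdump(taxdir)
    return {
        "spec": spec,
        "reads": reads,
        "truth": truth,
        "genomes": genomes,
        "containers": containers,
        "db": db,
        "taxid_map": mapping,
        "taxonomy": taxonomy,
    }
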