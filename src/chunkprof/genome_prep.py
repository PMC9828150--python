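"""Reference preparation: FASTA -> per-chunk canonical k-mer containers.

Each reference genome is (i) filtered by sequence name against a
blacklist (plasmids travel between genomes and pollute profiling), (ii)
concatenated with k-1 `N` spacers between contigs so no fake k-mers
appear at joins, (iii) split into ``n_chunks`` equal-size chunks with a
fixed overlap so that a read never straddles a chunk boundary unseen,
and (iv) reduced to the set of distinct canonical k-mer hashes per
chunk.  The per-chunk hash sets plus provenance (reference id, chunk
index, genome size) are the unit the Bloom index stores.
"""

from __future__ import annotations

import gzip
import json
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from chunkprof.hashing import HASH_ID, canonical_kmer_hashes

_MAGIC = b"CPKC"
_VERSION = 1


@dataclass
class PrepParams:
    """Parameters of the compute stage.

    k: k-mer length in bases.
    n_chunks: number of chunks per genome.
    overlap: chunk overlap in bases; overlap bases belong to both
        neighboring chunks and should match the read length so a read
        always falls entirely within one chunk.
    name_blacklist: case-insensitive substrings excluding sequences by
        name (plasmids by default).
    """

    k: int = 21
    n_chunks: int = 10
    overlap: int = 150
    name_blacklist: list[str] = field(default_factory=lambda: ["plasmid"])

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


@dataclass
class KmerContainer:
    """Hashed canonical k-mer set of one genome chunk plus provenance."""

    reference_id: str
    chunk_index: int
    n_chunks: int
    hashes: np.ndarray  # sorted distinct uint64
    genome_size: int
    k: int
    hash_id: str = HASH_ID

    @property
    def n_kmers(self) -> int:
        return int(self.hashes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerContainer):
            return NotImplemented
        return (
            self.reference_id == other.reference_id
            and self.chunk_index == other.chunk_index
            and self.n_chunks == other.n_chunks
            and self.genome_size == other.genome_size
            and self.k == other.k
            and self.hash_id == other.hash_id
            and np.array_equal(self.hashes, other.hashes)
        )


def filter_sequences(
    records: Sequence[tuple[str, str]], blacklist: Sequence[str]
) -> list[tuple[str, str]]:
    """Drop records whose name contains any blacklist substring.

    Matching is case-insensitive; order is preserved; an empty result is
    allowed (the caller decides whether that is an error).
    """
    lowered = [b.lower() for b in blacklist]
    return [
        (name, seq)
        for name, seq in records
        if not any(b in name.lower() for b in lowered)
    ]


def concat_contigs(contigs: Sequence[str], k: int) -> str:
    """Join contigs with k-1 ``N`` spacers so no k-mer spans a join."""
    if not contigs:
        raise ValueError("cannot concatenate an empty contig list")
    if k < 1:
        raise ValueError("k must be >= 1")
    return ("N" * (k - 1)).join(contigs)


def split_genome(length: int, n_chunks: int, overlap: int) -> list[tuple[int, int]]:
    """Half-open chunk intervals tiling ``[0, length)``.

    Chunks have equal width ``w = ceil((L + (n-1)*overlap) / n)`` and
    stride ``w - overlap``; consecutive chunks share exactly ``overlap``
    bases and the last chunk is clipped to the genome end (it may be
    shorter).  Genomes too short to split (``L < n_chunks + overlap`` or
    ``L < 2 * n_chunks``) yield a single chunk -- tiny viral genomes are
    common and must still be indexable.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_chunks == 1 or length < max(n_chunks + overlap, 2 * n_chunks):
        return [(0, length)]
    w = math.ceil((length + (n_chunks - 1) * overlap) / n_chunks)
    stride = w - overlap
    intervals = []
    for i in range(n_chunks):
        start = i * stride
        end = min(start + w, length)
        intervals.append((start, end))
    intervals[-1] = (intervals[-1][0], length)
    return intervals


def compute_containers(
    fasta_path: str | Path,
    params: PrepParams | None = None,
    reference_id: str | None = None,
) -> list[KmerContainer]:
    """Compute per-chunk k-mer containers for one reference FASTA.

    ``reference_id`` defaults to the file name stem.  ``genome_size`` is
    the total number of real bases of the kept sequences (spacer N's are
    not counted).  Raises if the file is empty or every sequence is
    blacklisted.
    """
    params = params or PrepParams()
    path = Path(fasta_path)
    if reference_id is None:
        reference_id = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if reference_id.endswith(suffix):
                reference_id = reference_id[: -len(suffix)]
    records = list(read_fasta(path))
    if not records:
        raise ValueError(f"{path}: empty or unreadable FASTA")
    kept = filter_sequences(records, params.name_blacklist)
    if not kept:
        raise ValueError(f"{path}: all sequences filtered by name blacklist")
    genome_size = sum(len(seq) for _, seq in kept)
    merged = concat_contigs([seq for _, seq in kept], params.k)
    intervals = split_genome(len(merged), params.n_chunks, params.overlap)
    containers = []
    for idx, (start, end) in enumerate(intervals):
        hashes = canonical_kmer_hashes(merged[start:end], params.k)
        containers.append(
            KmerContainer(
                reference_id=reference_id,
                chunk_index=idx,
                n_chunks=len(intervals),
                hashes=hashes,
                genome_size=genome_size,
                k=params.k,
            )
        )
    return containers


def read_fasta(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (description, sequence) pairs; transparently handles .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.description, str(rec.seq)


# -- container serialization -------------------------------------------------
# Layout: magic "CPKC", version u8, header-length u32 LE, header JSON,
# then the sorted uint64 hash array as little-endian bytes.


def save_container(container: KmerContainer, path: str | Path) -> None:
    header = {
        "reference_id": container.reference_id,
        "chunk_index": container.chunk_index,
        "n_chunks": container.n_chunks,
        "genome_size": container.genome_size,
        "k": container.k,
        "hash_id": container.hash_id,
        "n_kmers": container.n_kmers,
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BI", _VERSION, len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(container.hashes, dtype="<u8").tobytes())


def load_container(path: str | Path) -> KmerContainer:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != _MAGIC:
        raise ValueError(f"{path}: not a k-mer container (bad magic)")
    version, hlen = struct.unpack_from("<BI", data, 4)
    if version != _VERSION:
        raise ValueError(f"{path}: unsupported container version {version}")
    header = json.loads(data[9 : 9 + hlen])
    body = data[9 + hlen :]
    expected = header["n_kmers"] * 8
    if len(body) != expected:
        raise ValueError(f"{path}: truncated container file")
    hashes = np.frombuffer(body, dtype="<u8").astype(np.uint64)
    return KmerContainer(
        reference_id=header["reference_id"],
        chunk_index=header["chunk_index"],
        n_chunks=header["n_chunks"],
        hashes=hashes,
        genome_size=header["genome_size"],
        k=header["k"],
        hash_id=header["hash_id"],
    )


def write_manifest(containers: Sequence[KmerContainer], path: str | Path) -> None:
    """TSV manifest: reference_id, chunk_index, n_kmers, genome_size."""
    with open(path, "w") as fh:
        fh.write("reference_id\tchunk_index\tn_kmers\tgenome_size\n")
        for c in containers:
            fh.write(f"{c.reference_id}\t{c.chunk_index}\t{c.n_kmers}\t{c.genome_size}\n")
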