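"""Bit-sliced Bloom-filter block index (BIGSI/COBS family).

Genome chunks are sorted by ascending k-mer count and grouped into
blocks of at most N chunks; each block stores one Bloom filter per chunk,
all of the same length m, concatenated column-wise into an m x ceil(N/8)
byte matrix.  Row r of the matrix holds bit r of every column's filter,
so one row lookup tests a k-mer against every chunk of the block at
once.  m is sized from the largest chunk of the block at the requested
false-positive rate, so every other column meets the same or a lower
rate.  Size thresholds close blocks early so the largest chunks end up
in small blocks and do not inflate m for everyone else.

Bit order within a matrix row is little-endian: column c lives at bit
``c % 8`` of byte ``c // 8``.  Bloom errors are one-sided: an inserted
k-mer always queries positive.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from chunkprof.genome_prep import KmerContainer
from chunkprof.hashing import HASH_ID, splitmix64

_MAGIC = b"CPIX"
_VERSION = 1

#: geometric spacing of the default block-size thresholds above the
#: median chunk k-mer count (three thresholds at ratio 4)
_THRESHOLD_RATIO = 4.0
_N_THRESHOLDS = 3


class CorruptIndexError(ValueError):
    """Raised when an index file fails its magic/length checks."""


@dataclass
class IndexParams:
    """Bloom index construction parameters.

    fpr: desired per-k-mer false-positive rate f of each Bloom filter.
    n_hashes: number of hash functions h per filter.
    block_size: maximum chunks N per block.
    size_thresholds: ascending k-mer-count thresholds that close the
        current block early, isolating the largest chunks in smaller
        blocks; ``None`` derives three thresholds at geometric steps
        above the median chunk size at partition time.
    """

    fpr: float = 0.3
    n_hashes: int = 1
    block_size: int = 32
    size_thresholds: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fpr < 1.0:
            raise ValueError("fpr must be in (0, 1)")
        if self.n_hashes < 1:
            raise ValueError("n_hashes must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class ColumnMeta:
    """Provenance of one column (genome chunk) of a block."""

    reference_id: str
    chunk_index: int
    n_chunks: int
    n_kmers: int
    genome_size: int


@dataclass
class IndexBlock:
    n_bits: int
    columns: list[ColumnMeta]
    bit_matrix: np.ndarray  # (n_bits, ceil(n_columns / 8)) uint8

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class DatabaseMeta:
    k: int
    hash_id: str
    fpr: float
    n_hashes: int
    n_blocks: int
    taxid_map: str | None = None


def bloom_fpr(n_kmers: int, n_bits: int, n_hashes: int) -> float:
    """Standard Bloom false-positive rate (1 - e^{-hn/m})^h."""
    return (1.0 - math.exp(-n_hashes * n_kmers / n_bits)) ** n_hashes


def bloom_size(n_kmers: int, fpr: float, n_hashes: int = 1) -> int:
    """Smallest filter length m with analytic FPR <= ``fpr``.

    For h=1 this is ceil(-n / ln(1-f)); the closed form is used as a
    starting point and the exact minimality condition is enforced by a
    local scan so float rounding can never return an off-by-one m.
    """
    if not 0.0 < fpr < 1.0:
        raise ValueError("fpr must be in (0, 1)")
    if n_kmers < 1:
        raise ValueError("n_kmers must be >= 1")
    if n_hashes < 1:
        raise ValueError("n_hashes must be >= 1")
    # analytic start: m = -h*n / ln(1 - f^{1/h})
    m = max(1, int(-n_hashes * n_kmers / math.log1p(-(fpr ** (1.0 / n_hashes)))) - 2)
    while bloom_fpr(n_kmers, m, n_hashes) > fpr:
        m += 1
    return m


def default_size_thresholds(containers: Sequence[KmerContainer]) -> list[int]:
    """Three thresholds at geometric steps above the median chunk size."""
    sizes = np.array([c.n_kmers for c in containers])
    median = max(1.0, float(np.median(sizes)))
    return [int(median * _THRESHOLD_RATIO**i) for i in range(1, _N_THRESHOLDS + 1)]


def partition_blocks(
    containers: Sequence[KmerContainer], params: IndexParams | None = None
) -> list[list[KmerContainer]]:
    """Group containers into blocks of at most N, ascending by k-mer count.

    When a container's k-mer count crosses the next size threshold the
    current group is closed early, so the largest chunks land in smaller
    groups.  Every container appears in exactly one group.
    """
    if not containers:
        raise ValueError("no containers to partition")
    params = params or IndexParams()
    thresholds = params.size_thresholds
    if thresholds is None:
        thresholds = default_size_thresholds(containers)
    thresholds = sorted(thresholds)
    order = sorted(containers, key=lambda c: (c.n_kmers, c.reference_id, c.chunk_index))
    groups: list[list[KmerContainer]] = []
    current: list[KmerContainer] = []
    ti = 0
    for cont in order:
        crossed = False
        while ti < len(thresholds) and cont.n_kmers >= thresholds[ti]:
            ti += 1
            crossed = True
        if current and (crossed or len(current) >= params.block_size):
            groups.append(current)
            current = []
        current.append(cont)
    if current:
        groups.append(current)
    return groups


def _positions(hashes: np.ndarray, n_bits: int, n_hashes: int) -> np.ndarray:
    """(h, n) bit positions for each k-mer hash.

    One 64-bit hash is stored per k-mer; additional probe positions are
    derived by double hashing with an odd, hash-dependent step:
    ``pos_i = (base + i * step) mod m``.
    """
    m = np.uint64(n_bits)
    base = hashes % m
    if n_hashes == 1:
        return base[None, :]
    step = splitmix64(hashes ^ np.uint64(0xA5A5A5A5A5A5A5A5)) % np.uint64(n_bits - 1)
    step = step + np.uint64(1)
    out = np.empty((n_hashes, hashes.size), dtype=np.uint64)
    for i in range(n_hashes):
        out[i] = (base + np.uint64(i) * step) % m
    return out


def build_block(
    group: Sequence[KmerContainer], params: IndexParams | None = None
) -> IndexBlock:
    """Build one bit-sliced block; m is sized from the group's largest chunk."""
    if not group:
        raise ValueError("cannot build a block from an empty group")
    params = params or IndexParams()
    n_max = max(c.n_kmers for c in group)
    m = bloom_size(max(1, n_max), params.fpr, params.n_hashes)
    n_bytes = (len(group) + 7) // 8
    matrix = np.zeros((m, n_bytes), dtype=np.uint8)
    for c, cont in enumerate(group):
        if cont.n_kmers == 0:
            continue
        pos = _positions(cont.hashes, m, params.n_hashes).ravel()
        byte, bit = c // 8, np.uint8(1 << (c % 8))
        np.bitwise_or.at(matrix, (pos, byte), bit)
    columns = [
        ColumnMeta(c.reference_id, c.chunk_index, c.n_chunks, c.n_kmers, c.genome_size)
        for c in group
    ]
    return IndexBlock(n_bits=m, columns=columns, bit_matrix=matrix)


def query_block(
    hashes: np.ndarray, block: IndexBlock, n_hashes: int = 1
) -> np.ndarray:
    """Matched-k-mer count per column for a query hash set.

    ``count[c]`` is the number of query hashes whose h probe positions
    are all set in column c; counts never exceed ``len(hashes)`` and are
    an upper bound on the exact set-intersection size (Bloom errors are
    one-sided).
    """
    hashes = np.asarray(hashes, dtype=np.uint64)
    if hashes.size == 0:
        return np.zeros(block.n_columns, dtype=np.int64)
    pos = _positions(hashes, block.n_bits, n_hashes)
    rows = block.bit_matrix[pos[0]]
    for i in range(1, n_hashes):
        rows = rows & block.bit_matrix[pos[i]]
    bits = np.unpackbits(rows, axis=1, bitorder="little")[:, : block.n_columns]
    return bits.sum(axis=0, dtype=np.int64)


def build_index(
    containers: Sequence[KmerContainer], params: IndexParams | None = None
) -> tuple[list[IndexBlock], DatabaseMeta]:
    """Partition containers and build all blocks plus database metadata."""
    params = params or IndexParams()
    ks = {c.k for c in containers}
    hash_ids = {c.hash_id for c in containers}
    if len(ks) != 1 or len(hash_ids) != 1:
        raise ValueError("all containers must share one k and one hash_id")
    groups = partition_blocks(containers, params)
    blocks = [build_block(g, params) for g in groups]
    meta = DatabaseMeta(
        k=ks.pop(),
        hash_id=hash_ids.pop(),
        fpr=params.fpr,
        n_hashes=params.n_hashes,
        n_blocks=len(blocks),
    )
    return blocks, meta


# -- serialization -----------------------------------------------------------
# Block files stay separate on disk (block-XXXX.cpidx), mirroring the
# one-file-per-block layout that makes blocks independently loadable and
# queryable; meta.json ties them together.


def save_index(blocks: Sequence[IndexBlock], meta: DatabaseMeta, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_doc = {
        "format": "chunkprof-index",
        "version": _VERSION,
        "k": meta.k,
        "hash_id": meta.hash_id,
        "fpr": meta.fpr,
        "n_hashes": meta.n_hashes,
        "n_blocks": len(blocks),
        "taxid_map": meta.taxid_map,
    }
    (directory / "meta.json").write_text(json.dumps(meta_doc, indent=1))
    for i, block in enumerate(blocks):
        header = {
            "n_bits": block.n_bits,
            "columns": [
                [c.reference_id, c.chunk_index, c.n_chunks, c.n_kmers, c.genome_size]
                for c in block.columns
            ],
        }
        blob = json.dumps(header).encode()
        body = np.ascontiguousarray(block.bit_matrix).tobytes()
        with open(directory / f"block-{i:04d}.cpidx", "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<BIQ", _VERSION, len(blob), len(body)))
            fh.write(blob)
            fh.write(body)


def load_index(directory: str | Path) -> tuple[list[IndexBlock], DatabaseMeta]:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise CorruptIndexError(f"{directory}: missing meta.json")
    doc = json.loads(meta_path.read_text())
    if doc.get("format") != "chunkprof-index" or doc.get("version") != _VERSION:
        raise CorruptIndexError(f"{directory}: unrecognized index format/version")
    meta = DatabaseMeta(
        k=doc["k"],
        hash_id=doc["hash_id"],
        fpr=doc["fpr"],
        n_hashes=doc["n_hashes"],
        n_blocks=doc["n_blocks"],
        taxid_map=doc.get("taxid_map"),
    )
    blocks = []
    for i in range(meta.n_blocks):
        blocks.append(_load_block(directory / f"block-{i:04d}.cpidx"))
    return blocks, meta


def _load_block(path: Path) -> IndexBlock:
    if not path.exists():
        raise CorruptIndexError(f"{path}: missing block file")
    data = path.read_bytes()
    if data[:4] != _MAGIC:
        raise CorruptIndexError(f"{path}: bad magic")
    version, hlen, blen = struct.unpack_from("<BIQ", data, 4)
    if version != _VERSION:
        raise CorruptIndexError(f"{path}: unsupported block version {version}")
    off = 4 + struct.calcsize("<BIQ")
    if len(data) != off + hlen + blen:
        raise CorruptIndexError(f"{path}: truncated block file")
    header = json.loads(data[off : off + hlen])
    columns = [ColumnMeta(*row) for row in header["columns"]]
    n_bits = header["n_bits"]
    n_bytes = (len(columns) + 7) // 8
    matrix = np.frombuffer(data[off + hlen :], dtype=np.uint8).reshape(n_bits, n_bytes).copy()
    return IndexBlock(n_bits=n_bits, columns=columns, bit_matrix=matrix)
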