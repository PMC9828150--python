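"""Pseudo-mapping of reads against the Bloom-filter block index.

A read (or the pooled distinct k-mers of a read pair) is compared as a
whole against every genome chunk: the match statistic is the k-mer
coverage m / l, the fraction of the query's l distinct canonical k-mers
matched in a chunk.  Chunks with coverage >= the threshold t (0.55 by
default, roughly 96.5% sequence identity) are reported as hits.  The
per-k-mer Bloom false-positive rate f (0.3 by default) is high, but the
probability that an absent chunk reaches the coverage threshold decays
exponentially with l: it is the binomial survival probability
P(X > m), X ~ Binomial(l, f) -- e.g. 5.3e-10 for a 150-bp read with 72
of 130 k-mers matched.

Search results carry no taxonomic labels, so hit tables produced
against different databases (same k and hash) can be merged; block
visit order never changes the result.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import binom

from chunkprof.bloom import DatabaseMeta, IndexBlock, load_index, query_block, save_index
from chunkprof.hashing import canonical_kmer_hashes

#: column order of the search TSV contract consumed by merge and profile
TSV_COLUMNS = [
    "query",
    "qLen",
    "qKmers",
    "target",
    "chunkIdx",
    "chunks",
    "matchedKmers",
    "coverage",
    "tLen",
]

_BATCH_READS = 2048


@dataclass
class SearchParams:
    """Search-time thresholds.

    min_coverage: k-mer coverage threshold t in (0, 1].
    min_matched_kmers: absolute floor on matched k-mers.
    keep_main_only: drop secondary matches whose coverage is sharply
        lower than the best match (see :func:`apply_main_match_filter`).
    main_match_gap: coverage gap defining "sharply lower".
    """

    min_coverage: float = 0.55
    min_matched_kmers: int = 1
    keep_main_only: bool = False
    main_match_gap: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass
class SearchHit:
    query_id: str
    reference_id: str
    chunk_index: int
    n_chunks: int
    genome_size: int
    n_query_kmers: int
    n_matched: int
    query_length: int

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_query_kmers


class Database:
    """A loaded index: blocks + metadata + flattened column tables."""

    def __init__(self, blocks: Sequence[IndexBlock], meta: DatabaseMeta):
        self.blocks = list(blocks)
        self.meta = meta
        cols = [c for b in self.blocks for c in b.columns]
        self.col_target = np.array([c.reference_id for c in cols])
        self.col_chunk = np.array([c.chunk_index for c in cols])
        self.col_nchunks = np.array([c.n_chunks for c in cols])
        self.col_gsize = np.array([c.genome_size for c in cols])

    @classmethod
    def load(cls, directory: str | Path) -> "Database":
        return cls(*load_index(directory))

    def save(self, directory: str | Path) -> None:
        save_index(self.blocks, self.meta, directory)

    @property
    def n_columns(self) -> int:
        return int(self.col_target.size)

    def query_counts(self, hashes: np.ndarray) -> np.ndarray:
        """Matched-k-mer count for one hash set against every column."""
        return np.concatenate(
            [query_block(hashes, b, self.meta.n_hashes) for b in self.blocks]
        )


def query_fpr(n_query_kmers: int, n_matched: int, per_kmer_fpr: float) -> float:
    """False-positive probability of a query hit: P(X > m), X~Bin(l, f).

    The strict tail (more than m of the l query k-mers matching by
    chance) is the calibrated significance of a chunk hit with m matched
    k-mers; it decays exponentially in l at fixed coverage m/l > f.
    """
    if not 0.0 < per_kmer_fpr < 1.0:
        raise ValueError("per_kmer_fpr must be in (0, 1)")
    if not 0 <= n_matched <= n_query_kmers:
        raise ValueError("need 0 <= n_matched <= n_query_kmers")
    return float(binom.sf(n_matched, n_query_kmers, per_kmer_fpr))


def _read_hashes(
    read: str | tuple[str, str] | tuple[str, None], k: int
) -> np.ndarray:
    """Distinct canonical k-mer hashes of a read or a pooled read pair."""
    if isinstance(read, str):
        return canonical_kmer_hashes(read, k)
    mate1, mate2 = read
    h1 = canonical_kmer_hashes(mate1, k) if mate1 else np.empty(0, np.uint64)
    h2 = canonical_kmer_hashes(mate2, k) if mate2 else np.empty(0, np.uint64)
    return np.union1d(h1, h2)


def search_read(
    read: str | tuple[str, str],
    database: Database,
    params: SearchParams | None = None,
    query_id: str = "read",
) -> list[SearchHit]:
    """Pseudo-map one read (or pooled pair); hits sorted by coverage
    descending, ties by (reference_id, chunk_index)."""
    params = params or SearchParams()
    hashes = _read_hashes(read, database.meta.k)
    if isinstance(read, str):
        qlen = len(read)
    else:
        qlen = sum(len(m) for m in read if m)
    return _hits_from_counts(
        database, params, query_id, qlen, hashes.size, database.query_counts(hashes)
    )


def _hits_from_counts(
    db: Database,
    params: SearchParams,
    query_id: str,
    qlen: int,
    n_kmers: int,
    counts: np.ndarray,
) -> list[SearchHit]:
    if n_kmers == 0:
        return []
    floor = max(params.min_matched_kmers, 1)
    keep = (counts >= floor) & (counts / n_kmers >= params.min_coverage)
    idx = np.flatnonzero(keep)
    hits = [
        SearchHit(
            query_id=query_id,
            reference_id=str(db.col_target[i]),
            chunk_index=int(db.col_chunk[i]),
            n_chunks=int(db.col_nchunks[i]),
            genome_size=int(db.col_gsize[i]),
            n_query_kmers=int(n_kmers),
            n_matched=int(counts[i]),
            query_length=qlen,
        )
        for i in idx
    ]
    hits.sort(key=lambda h: (-h.coverage, h.reference_id, h.chunk_index))
    if params.keep_main_only and hits:
        hits = apply_main_match_filter(hits, params.main_match_gap)
    return hits


def apply_main_match_filter(
    hits: Sequence[SearchHit], gap: float = 0.2
) -> list[SearchHit]:
    """Keep hits whose coverage is within ``gap`` of the best coverage.

    Abandoning matches with sharply lower coverage helps recover
    uniquely matched reads for low-coverage genomes (pathogen mode).
    Expects hits sorted by coverage descending.
    """
    if not hits:
        return []
    best = hits[0].coverage
    return [h for h in hits if h.coverage >= best - gap]


def search_reads(
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    database: Database,
    params: SearchParams | None = None,
) -> pd.DataFrame:
    """Pseudo-map a stream of reads; returns the search hit table.

    ``reads`` yields ``(query_id, sequence)`` for single-end data or
    ``(query_id, mate1, mate2)`` for paired-end data (the distinct
    canonical k-mers of both mates are pooled).  Reads are processed in
    batches so all Bloom lookups of a batch are vectorized; results are
    independent of batch and block order.
    """
    params = params or SearchParams()
    rows: list[tuple] = []
    batch_ids: list[str] = []
    batch_qlen: list[int] = []
    batch_hashes: list[np.ndarray] = []

    def flush() -> None:
        if not batch_ids:
            return
        lengths = np.array([h.size for h in batch_hashes])
        allh = (
            np.concatenate(batch_hashes) if lengths.sum() else np.empty(0, np.uint64)
        )
        counts = np.zeros((len(batch_ids), database.n_columns), dtype=np.int64)
        if allh.size:
            per_block = []
            for b in database.blocks:
                per_block.append(_block_counts_batched(allh, lengths, b, database.meta.n_hashes))
            counts = np.concatenate(per_block, axis=1)
        for i, qid in enumerate(batch_ids):
            hits = _hits_from_counts(
                database, params, qid, batch_qlen[i], int(lengths[i]), counts[i]
            )
            for h in hits:
                rows.append(
                    (
                        h.query_id,
                        h.query_length,
                        h.n_query_kmers,
                        h.reference_id,
                        h.chunk_index,
                        h.n_chunks,
                        h.n_matched,
                        h.coverage,
                        h.genome_size,
                    )
                )
        batch_ids.clear()
        batch_qlen.clear()
        batch_hashes.clear()

    for rec in reads:
        if len(rec) == 2:
            qid, seq = rec
            hashes = _read_hashes(seq, database.meta.k)
            qlen = len(seq)
        else:
            qid, m1, m2 = rec
            hashes = _read_hashes((m1, m2), database.meta.k)
            qlen = len(m1 or "") + len(m2 or "")
        batch_ids.append(qid)
        batch_qlen.append(qlen)
        batch_hashes.append(hashes)
        if len(batch_ids) >= _BATCH_READS:
            flush()
    flush()
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def _block_counts_batched(
    all_hashes: np.ndarray, lengths: np.ndarray, block: IndexBlock, n_hashes: int
) -> np.ndarray:
    """Per-read per-column counts for one block over a concatenated batch."""
    from chunkprof.bloom import _positions

    pos = _positions(all_hashes, block.n_bits, n_hashes)
    rows = block.bit_matrix[pos[0]]
    for i in range(1, n_hashes):
        rows = rows & block.bit_matrix[pos[i]]
    bits = np.unpackbits(rows, axis=1, bitorder="little")[:, : block.n_columns]
    # reads with zero k-mers would corrupt reduceat segments; drop and refill
    nonzero = np.flatnonzero(lengths)
    starts = np.zeros(nonzero.size, dtype=np.int64)
    np.cumsum(lengths[nonzero][:-1], out=starts[1:])
    counts = np.zeros((lengths.size, block.n_columns), dtype=np.int64)
    counts[nonzero] = np.add.reduceat(bits, starts, axis=0, dtype=np.int64)
    return counts


# -- FASTA/FASTQ input -------------------------------------------------------


def iter_fastx(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, optionally gzipped."""
    path = Path(path)
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq)


def iter_fastx_paired(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[str, str, str]]:
    for (id1, s1), (_, s2) in zip(iter_fastx(path1), iter_fastx(path2), strict=True):
        yield id1, s1, s2


# -- TSV contract ------------------------------------------------------------


def write_search_tsv(df: pd.DataFrame, path: str | Path, meta: DatabaseMeta) -> None:
    """Write the hit table with a compatibility comment header."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"# k={meta.k} hash={meta.hash_id} fpr={meta.fpr:g}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_search_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a hit table and its compatibility header."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        meta: dict = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                meta[key] = val
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return df, meta


def merge_results(
    tables: Sequence[pd.DataFrame], metas: Sequence[dict] | None = None
) -> pd.DataFrame:
    """Merge hit tables from searches against different databases.

    Per query, hits are unioned; identical (target, chunk) rows are
    deduplicated keeping the maximum matched-k-mer count.  The result is
    re-sorted by (query, coverage desc, target, chunk), which makes the
    operation associative and commutative over input order.  Tables with
    incompatible k or hash (from their TSV headers) are refused.
    """
    if metas is not None and len(metas) > 1:
        keys = [(m.get("k"), m.get("hash")) for m in metas if m]
        if len(set(keys)) > 1:
            raise ValueError(f"incompatible search results: {sorted(set(keys))}")
    frames = [t for t in tables if len(t)]
    if not frames:
        return pd.DataFrame(columns=TSV_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    df = (
        df.sort_values("matchedKmers", ascending=False, kind="mergesort")
        .drop_duplicates(subset=["query", "target", "chunkIdx"], keep="first")
        .copy()
    )
    df["coverage"] = df["matchedKmers"] / df["qKmers"]
    df = df.sort_values(
        ["query", "coverage", "target", "chunkIdx"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df[TSV_COLUMNS]
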