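"""Synthetic genomes, taxonomies, communities and reads.

Everything the pipeline consumes can be generated here, so the full
index -> search -> profile path is testable without downloads.  Genomes
are uniform ACGT; reads are drawn multinomially by target proportion at
uniform positions on a random strand; sequencing error is a
substitution-only model parameterized by per-base identity (no indels).
All generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chunkprof.hashing import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """A synthetic community: genome sizes, proportions and read model."""

    genome_lengths: list[int]
    proportions: list[float]
    n_reads: int = 2000
    read_length: int = 150
    identity: float = 1.0
    seed: int = 0
    genome_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genome_lengths) != len(self.proportions):
            raise ValueError("genome_lengths and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        if self.read_length > min(self.genome_lengths):
            raise ValueError("read_length exceeds the shortest genome")
        if not self.genome_names:
            self.genome_names = [f"genome{i + 1}" for i in range(len(self.genome_lengths))]


def random_genome(length: int, seed: int | np.random.Generator = 0) -> str:
    """Uniform-ACGT sequence; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, identity: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each base independently with probability 1 - identity.

    A substituted base always changes (one of the three other bases).
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    if identity == 1.0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < (1.0 - identity)
    idx = np.flatnonzero(hit)
    if idx.size:
        codes = np.searchsorted(_BASES, arr[idx])  # ACGT are sorted
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    spec: CommunitySpec, genomes: list[str] | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame, list[str]]:
    """Draw reads from a community; returns (reads, truth table, genomes).

    Reads are ``(read_id, sequence)``; the truth table records source
    genome, 0-based position and strand per read.  If ``genomes`` is not
    given they are generated from the spec (seed-derived per genome).
    """
    rng = np.random.default_rng(spec.seed)
    if genomes is None:
        genomes = [
            random_genome(L, np.random.default_rng([spec.seed, 1000 + i]))
            for i, L in enumerate(spec.genome_lengths)
        ]
    counts = rng.multinomial(spec.n_reads, spec.proportions)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    ridx = 0
    for g, n in enumerate(counts):
        genome = genomes[g]
        positions = rng.integers(0, len(genome) - spec.read_length + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for pos, strand in zip(positions, strands):
            frag = genome[pos : pos + spec.read_length]
            if spec.identity < 1.0:
                frag = mutate(frag, spec.identity, rng)
            if strand:
                frag = reverse_complement(frag)
            rid = f"r{ridx:06d}"
            reads.append((rid, frag))
            truth_rows.append(
                {
                    "read": rid,
                    "genome": spec.genome_names[g],
                    "position": int(pos),
                    "strand": "-" if strand else "+",
                }
            )
            ridx += 1
    # shuffle so reads of one genome are not contiguous
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    return reads, truth, genomes


def make_taxdump(
    directory: str | Path,
    n_species: int,
    n_genera: int = 1,
    genome_names: list[str] | None = None,
) -> dict[str, int]:
    """Write a minimal valid taxdump; returns genome -> species taxid map.

    Layout: root (1) -> superkingdom Bacteria (2) -> genera (10+g) ->
    species (100+s), species assigned to genera round-robin.  All four
    dmp files are written (merged.dmp and delnodes.dmp empty).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if genome_names is None:
        genome_names = [f"genome{i + 1}" for i in range(n_species)]
    if len(genome_names) < n_species:
        raise ValueError("need at least one genome name per species")
    nodes = [(1, 1, "no rank"), (2, 1, "superkingdom")]
    names = [(1, "root"), (2, "Bacteria")]
    for g in range(n_genera):
        nodes.append((10 + g, 2, "genus"))
        names.append((10 + g, f"Genus{g + 1}"))
    for s in range(n_species):
        genus = 10 + (s % n_genera)
        nodes.append((100 + s, genus, "species"))
        names.append((100 + s, f"Genus{(s % n_genera) + 1} species{s + 1}"))
    with open(directory / "nodes.dmp", "w") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(directory / "names.dmp", "w") as fh:
        for taxid, name in names:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    (directory / "merged.dmp").write_text("")
    (directory / "delnodes.dmp").write_text("")
    # map extra genome names (e.g. decoys or co-strains) round-robin too
    mapping = {}
    for i, g in enumerate(genome_names):
        mapping[g] = 100 + (i % n_species)
    return mapping


def benchmark_community(seed: int = 1, n_reads: int = 20_000):
    """The package's standard validation community.

    Five 200-kb genomes at proportions (0.4, 0.3, 0.15, 0.1, 0.05) with
    error-free 150-bp reads, plus a decoy genome that shares 20% of
    genome 1's sequence but contributes no reads (it must be rejected by
    the uniquely-matched-read criterion).  Returns a dict with the spec,
    reads, truth table, genome sequences (decoy last) and the name list.
    """
    spec = CommunitySpec(
        genome_lengths=[200_000] * 5,
        proportions=[0.4, 0.3, 0.15, 0.1, 0.05],
        n_reads=n_reads,
        read_length=150,
        identity=1.0,
        seed=seed,
    )
    reads, truth, genomes = simulate_reads(spec)
    decoy_rng = np.random.default_rng([seed, 424242])
    decoy = genomes[0][:40_000] + random_genome(160_000, decoy_rng)
    return {
        "spec": spec,
        "reads": reads,
        "truth": truth,
        "genomes": genomes + [decoy],
        "names": spec.genome_names + ["decoy"],
        "true_proportions": dict(zip(spec.genome_names, spec.proportions)),
    }


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
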