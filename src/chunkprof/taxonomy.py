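"""NCBI-style taxdump parsing and lineage queries.

Loads the pipe-delimited nodes.dmp / names.dmp dialect (plus optional
merged.dmp and delnodes.dmp), remaps merged taxids, flags deleted ones,
and answers the lineage and same-species queries the profiler needs.
Only the "scientific name" class is read from names.dmp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

#: canonical ranks reported in CAMI profiles, root to leaf
CANONICAL_RANKS = [
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
]


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


@dataclass
class Taxonomy:
    nodes: dict[int, TaxNode] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)

    @classmethod
    def from_taxdump(cls, directory: str | Path) -> "Taxonomy":
        directory = Path(directory)
        nodes_path = directory / "nodes.dmp"
        names_path = directory / "names.dmp"
        for p in (nodes_path, names_path):
            if not p.exists():
                raise FileNotFoundError(f"missing taxdump file: {p}")
        tax = cls()
        for line in nodes_path.read_text().splitlines():
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            tax.nodes[taxid] = TaxNode(taxid=taxid, parent=parent, rank=rank)
        for line in names_path.read_text().splitlines():
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) >= 4 and fields[3] == "scientific name":
                taxid = int(fields[0])
                if taxid in tax.nodes:
                    tax.nodes[taxid].name = fields[1]
        merged_path = directory / "merged.dmp"
        if merged_path.exists():
            for line in merged_path.read_text().splitlines():
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line)
                tax.merged[int(fields[0])] = int(fields[1])
        del_path = directory / "delnodes.dmp"
        if del_path.exists():
            for line in del_path.read_text().splitlines():
                if line.strip():
                    tax.deleted.add(int(_parse_dmp_line(line)[0]))
        tax._check_acyclic()
        return tax

    def _check_acyclic(self) -> None:
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while True:
                if cur in seen:
                    raise ValueError(f"cyclic parent chain at taxid {cur}")
                seen.add(cur)
                parent = self.nodes[cur].parent
                if parent == cur:  # root
                    break
                if parent not in self.nodes:
                    raise ValueError(f"taxid {cur} has unknown parent {parent}")
                cur = parent

    def resolve(self, taxid: int) -> int:
        """Apply merged-taxid remapping; raise for deleted/unknown ids."""
        taxid = self.merged.get(taxid, taxid)
        if taxid in self.deleted:
            raise KeyError(f"taxid {taxid} is deleted")
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        return taxid

    def path_to_root(self, taxid: int) -> list[TaxNode]:
        """Nodes from root down to ``taxid`` (all ranks)."""
        taxid = self.resolve(taxid)
        path = []
        cur = taxid
        while True:
            node = self.nodes[cur]
            path.append(node)
            if node.parent == cur:
                break
            cur = node.parent
        return path[::-1]

    def lineage(self, taxid: int) -> dict[str, tuple[int, str]]:
        """Ordered rank -> (taxid, name) over the canonical ranks.

        The root node is always present under the key ``"root"``.
        """
        path = self.path_to_root(taxid)
        out: dict[str, tuple[int, str]] = {"root": (path[0].taxid, path[0].name)}
        for node in path:
            if node.rank in CANONICAL_RANKS:
                out[node.rank] = (node.taxid, node.name)
        return out

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """Taxid of the ancestor (or self) at ``rank``, if any."""
        for node in self.path_to_root(taxid):
            if node.rank == rank:
                return node.taxid
        return None

    def species_of(self, taxid: int) -> int | None:
        return self.rank_ancestor(taxid, "species")

    def same_species(self, taxid_a: int, taxid_b: int) -> bool:
        """True iff both taxids share a species-rank ancestor.

        Identical taxids are always the same species; without a species
        rank on either path the answer is False for distinct taxids.
        """
        a, b = self.resolve(taxid_a), self.resolve(taxid_b)
        if a == b:
            return True
        sa, sb = self.species_of(a), self.species_of(b)
        return sa is not None and sa == sb


def load_taxid_map(path: str | Path) -> dict[str, int]:
    """2-column TSV (reference_id, taxid) -> dict."""
    mapping: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        ref, taxid = line.split("\t")[:2]
        mapping[ref] = int(taxid)
    return mapping


def write_taxid_map(mapping: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref, taxid in mapping.items():
            fh.write(f"{ref}\t{taxid}\n")
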