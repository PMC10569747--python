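"""Taxonomy graph and rank roll-up queries.

The profiling ladder is fixed to seven ranks, strain through phylum.
Classification is done independently at each rank, so the only query that
matters is "what is this taxon's ancestor at rank r" — memoized here.

NCBI models strains as below-species leaves with rank "no rank", "strain" or
"subspecies"; on load any node below a species is normalized to the synthetic
``strain`` rank so the ladder is uniform.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

RANKS: tuple[str, ...] = ("strain", "species", "genus", "family", "order", "class", "phylum")
_RANK_POS = {r: i for i, r in enumerate(RANKS)}

_UNCULTURED_MARKERS = ("uncultured", "unclassified", "unidentified", "metagenome")

_MAX_DEPTH = 64


@dataclass
class TaxonomyNode:
    taxid: int
    parent: int
    rank: str
    name: str


def rank_order(rank: str) -> int:
    """Position on the ladder; strain=0 (finest) ... phylum=6 (coarsest)."""
    return _RANK_POS[rank]


class TaxonomyTree:
    """Taxid graph with memoized rank-ancestor lookup.

    Invariants checked on construction: every parent exists, exactly one root
    (a node whose parent is itself), and every lineage reaches the root in at
    most 64 steps (no cycles).
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        self._validate()
        self._normalize_below_species()
        self._rank_cache: dict[tuple[int, str], int | None] = {}

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        roots = []
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise ValueError(
                    f"taxid {node.taxid} references missing parent {node.parent}"
                )
            if node.parent == node.taxid:
                roots.append(node.taxid)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        for taxid in self.nodes:
            path = [taxid]
            cur = taxid
            for _ in range(_MAX_DEPTH):
                parent = self.nodes[cur].parent
                if parent == cur:
                    break
                cur = parent
                path.append(cur)
            else:
                raise ValueError(f"cycle or over-deep lineage: {path}")

    def _normalize_below_species(self) -> None:
        for node in self.nodes.values():
            if node.taxid == self.root:
                node.rank = "root"
                continue
            if node.rank in _RANK_POS or node.rank == "root":
                continue
            # non-ladder rank: strain if under a species, else opaque
            if self._has_strict_ancestor_rank(node.taxid, "species"):
                node.rank = "strain"
            else:
                node.rank = "other"

    def _has_strict_ancestor_rank(self, taxid: int, rank: str) -> bool:
        cur = self.nodes[taxid].parent
        while True:
            if self.nodes[cur].rank == rank:
                return True
            nxt = self.nodes[cur].parent
            if nxt == cur:
                return False
            cur = nxt

    # -- queries -----------------------------------------------------------

    def lineage_of(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (inclusive) at the requested rank, or None."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        key = (taxid, rank)
        if key in self._rank_cache:
            return self._rank_cache[key]
        cur = taxid
        result = None
        while True:
            if self.nodes[cur].rank == rank:
                result = cur
                break
            nxt = self.nodes[cur].parent
            if nxt == cur:
                break
            cur = nxt
        self._rank_cache[key] = result
        return result

    def rank_of(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def name_of(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def is_uncultured(self, taxid: int) -> bool:
        """Name-substring test for uncultured/unclassified/environmental taxa."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        name = self.nodes[taxid].name.lower()
        return any(marker in name for marker in _UNCULTURED_MARKERS)

    def ancestors(self, taxid: int) -> list[int]:
        """Lineage from the node (inclusive) up to the root."""
        out = [taxid]
        cur = taxid
        while True:
            nxt = self.nodes[cur].parent
            if nxt == cur:
                break
            cur = nxt
            out.append(cur)
        return out


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    """Load a flat taxonomy TSV: taxid, parent_taxid, rank, name.

    A header line is detected by a non-numeric first field and skipped.
    """
    nodes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[0].isdigit():
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            nodes.append(TaxonomyNode(int(fields[0]), int(fields[1]), fields[2], fields[3]))
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("taxid\tparent_taxid\trank\tname\n")
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            out.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load an NCBI taxdump pair (nodes.dmp + names.dmp, scientific names)."""
    names: dict[int, str] = {}
    with open(names_path) as handle:
        for line in handle:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[int(fields[0])] = fields[1]
    nodes = []
    with open(nodes_path) as handle:
        for line in handle:
            fields = [f.strip() for f in line.split("\t|\t")]
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes.append(TaxonomyNode(taxid, parent, rank, names.get(taxid, str(taxid))))
    return TaxonomyTree(nodes)
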