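"""Sequence similarity network and connected-component gene families.

Edges join sequence pairs with at least one alignment at >=30% identity and
>=80% mutual coverage (both inclusive, unlike the strict homolog-filter
thresholds — the two rules are deliberately distinct).  Gene families are
the connected components of the resulting undirected simple graph, computed
with union-find (path compression + union by size); family ids are assigned
deterministically by each family's lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

from .decontamination import mutual_coverage
from .io_model import AlignmentHit

MIN_IDENTITY = 30.0       # inclusive
MIN_MUTUAL_COV = 0.8      # inclusive
FAMILY_SIZE_THRESHOLD = 100  # families are selected when strictly larger


def build_network(
    hits: Iterable[AlignmentHit],
    min_identity: float = MIN_IDENTITY,
    min_mutual_cov: float = MIN_MUTUAL_COV,
) -> set[tuple[str, str]]:
    """Undirected simple edge set over sequence ids.

    Self-hits are dropped, reciprocal hits merge into one edge, and a pair is
    connected when any of its hits passes both thresholds.
    """
    edges: set[tuple[str, str]] = set()
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if hit.pct_identity >= min_identity and mutual_coverage(hit) >= min_mutual_cov:
            a, b = sorted((hit.query_id, hit.subject_id))
            edges.add((a, b))
    return edges


@dataclass(frozen=True, slots=True)
class GeneFamily:
    family_id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def connected_components(
    nodes: Collection[str], edges: Iterable[tuple[str, str]]
) -> list[GeneFamily]:
    """Partition ``nodes`` into gene families under ``edges``.

    Families are returned ordered (and numbered) by smallest member id;
    an edge endpoint outside the node set is a consistency error.
    """
    uf = _UnionFind(nodes)
    for a, b in edges:
        if a not in uf.parent or b not in uf.parent:
            missing = a if a not in uf.parent else b
            raise ValueError(f"edge endpoint {missing!r} not in node set")
        uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for node in uf.parent:
        groups.setdefault(uf.find(node), set()).add(node)
    families = sorted(groups.values(), key=min)
    return [GeneFamily(i, frozenset(members)) for i, members in enumerate(families)]


def select_families(
    families: Iterable[GeneFamily], min_size: int = FAMILY_SIZE_THRESHOLD
) -> list[GeneFamily]:
    """Families with more than ``min_size`` members (strict, as printed)."""
    return [f for f in families if f.size > min_size]


def write_edges(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_a\tseq_b\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def write_families(families: Iterable[GeneFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsize\tseq_id\n")
        for fam in families:
            for seq in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{fam.size}\t{seq}\n")
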