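"""Rank-weighted, condition-tagged bait->prey interaction networks.

Each significant (bait, prey, condition) association becomes one directed
edge carrying the 1-5 confidence rank and the growth condition; the same
bait-prey pair observed in both sulfur states contributes two edges.  The
bait's own protein appearing among its significant preys is a
purification-success annotation, not a partnership, so self-edges are kept
separately and never counted as partners.

Condition tags live on edges rather than in separate per-condition graphs,
so sulfur-state contrasts are plain edge-set queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .enrichment import EnrichmentRecord
from .io import Condition


@dataclass(frozen=True)
class Edge:
    bait_gene: str
    prey_protein: str
    sulfur: bool
    pyruvate: bool
    rank: int
    rescued: bool = False

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3, 4, 5):
            raise ValueError(f"rank must be 1..5, got {self.rank}")

    @property
    def key(self) -> tuple:
        return (self.bait_gene, self.prey_protein, self.sulfur, self.pyruvate)


@dataclass(frozen=True)
class ComplexGroup:
    """A named protein complex and the bait genes tagged within it."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex group {self.name!r} has no members")


@dataclass
class BaitNetwork:
    """An edge set plus the baits it was built from.

    Baits are tracked explicitly so that filtering never drops a bait node
    even when all of its edges are removed.
    """

    edges: list[Edge] = field(default_factory=list)
    baits: set[str] = field(default_factory=set)
    self_edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.key in seen:
                raise ValueError(f"duplicate edge for {e.key}")
            seen.add(e.key)

    @property
    def preys(self) -> set[str]:
        return {e.prey_protein for e in self.edges}

    @property
    def nodes(self) -> set[str]:
        return self.baits | self.preys

    def prey_of(self, baits: Iterable[str], condition: Condition | None = None,
                min_rank: int = 1) -> set[str]:
        """Preys copurified by any of ``baits`` (optionally in one condition)."""
        baits = set(baits)
        return {
            e.prey_protein
            for e in self.edges
            if e.bait_gene in baits
            and e.rank >= min_rank
            and (condition is None
                 or (e.sulfur, e.pyruvate) == (condition.sulfur, condition.pyruvate))
        }

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for bait in sorted(self.baits):
            g.add_node(bait, is_bait=True)
        for e in sorted(self.edges, key=lambda e: e.key):
            if e.prey_protein not in g:
                g.add_node(e.prey_protein, is_bait=False)
            g.add_edge(
                e.bait_gene, e.prey_protein,
                sulfur=e.sulfur, pyruvate=e.pyruvate,
                rank=e.rank, rescued=e.rescued,
            )
        return g


def build_network(records: Iterable[EnrichmentRecord]) -> BaitNetwork:
    """Assemble the network of all significant, ranked associations."""
    edges: list[Edge] = []
    self_edges: list[Edge] = []
    baits: set[str] = set()
    for rec in records:
        baits.add(rec.bait_gene)
        if not rec.significant:
            continue
        if rec.rank is None:
            raise ValueError(
                f"significant record {rec.protein_id} ({rec.bait_gene}) has no rank; "
                "assign ranks before building the network"
            )
        edge = Edge(
            bait_gene=rec.bait_gene,
            prey_protein=rec.protein_id,
            sulfur=rec.condition.sulfur,
            pyruvate=rec.condition.pyruvate,
            rank=rec.rank,
            rescued=rec.rescued,
        )
        (self_edges if rec.is_self else edges).append(edge)
    return BaitNetwork(edges=edges, baits=baits, self_edges=self_edges)


def filter_rank(network: BaitNetwork, min_rank: int) -> BaitNetwork:
    """Keep edges with rank >= min_rank; bait nodes are always retained."""
    if min_rank not in (1, 2, 3, 4, 5):
        raise ValueError(f"min_rank must be within 1..5, got {min_rank}")
    return BaitNetwork(
        edges=[e for e in network.edges if e.rank >= min_rank],
        baits=set(network.baits),
        self_edges=[e for e in network.self_edges if e.rank >= min_rank],
    )


@dataclass
class ReciprocityResult:
    """Evidence for reciprocal copurification between two complexes."""

    group_a: str
    group_b: str
    a_to_b: list[Edge]
    b_to_a: list[Edge]
    excluded_shared: tuple[str, ...] = ()

    @property
    def reciprocal(self) -> bool:
        return bool(self.a_to_b) and bool(self.b_to_a)


def reciprocal_pairs(
    network: BaitNetwork,
    group_a: ComplexGroup,
    group_b: ComplexGroup,
    condition: Condition,
) -> ReciprocityResult:
    """Test whether two complexes copurify each other's subunits.

    Reciprocity requires both directions in the stated condition: some bait
    of ``group_a`` recovering a protein encoded by a ``group_b`` member AND
    vice versa.  Subunits shared between the groups cannot evidence
    inter-complex association and are excluded (with a warning).
    """
    shared = tuple(sorted(set(group_a.members) & set(group_b.members)))
    if shared:
        warnings.warn(
            f"complex groups {group_a.name!r} and {group_b.name!r} share "
            f"subunit(s) {list(shared)}; excluded from the reciprocity test",
            stacklevel=2,
        )
    a_only = set(group_a.members) - set(shared)
    b_only = set(group_b.members) - set(shared)

    def cross(from_baits: set[str], to_genes: set[str]) -> list[Edge]:
        return sorted(
            (e for e in network.edges
             if e.bait_gene in from_baits
             and e.prey_protein in to_genes
             and (e.sulfur, e.pyruvate) == (condition.sulfur, condition.pyruvate)),
            key=lambda e: e.key,
        )

    return ReciprocityResult(
        group_a=group_a.name,
        group_b=group_b.name,
        a_to_b=cross(a_only, b_only),
        b_to_a=cross(b_only, a_only),
        excluded_shared=shared,
    )


def intersect_groups(
    network: BaitNetwork,
    groups: list[ComplexGroup],
    condition: Condition,
    min_rank: int = 1,
) -> set[str]:
    """Preys copurified by >= 1 bait of EVERY group in the stated condition.

    This is the shared-partner query behind multi-complex hub analyses:
    proteins recovered independently by several distinct complexes in the
    same growth condition.
    """
    if len(groups) < 2:
        raise ValueError("intersect_groups requires at least two complex groups")
    result: set[str] | None = None
    for group in groups:
        preys = network.prey_of(group.members, condition, min_rank=min_rank)
        result = preys if result is None else (result & preys)
    assert result is not None
    return result


# ---------------------------------------------------------------------------
# export / import

EXPORT_FORMATS = ("sif", "graphml", "tsv")

_EDGE_COLUMNS = ("bait", "prey", "sulfur", "pyruvate", "rank", "rescued")


def export_network(network: BaitNetwork, fmt: str, path) -> None:
    """Write the network as SIF, GraphML, or an edge-table TSV.

    Output ordering is deterministic (sorted by edge key).  SIF lines read
    ``bait<TAB>copurifies<TAB>prey``; GraphML carries rank, condition and
    rescue status as typed edge attributes and declares bait nodes even
    when the edge set is empty.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected one of {EXPORT_FORMATS}")
    ordered = sorted(network.edges, key=lambda e: e.key)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for bait in sorted(network.baits - {e.bait_gene for e in ordered}):
                fh.write(f"{bait}\n")  # isolated bait node declaration
            for e in ordered:
                fh.write(f"{e.bait_gene}\tcopurifies\t{e.prey_protein}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for e in ordered:
                fh.write(
                    f"{e.bait_gene}\t{e.prey_protein}\t"
                    f"{str(e.sulfur).lower()}\t{str(e.pyruvate).lower()}\t"
                    f"{e.rank}\t{str(e.rescued).lower()}\n"
                )
    else:
        nx.write_graphml(network.to_networkx(), path)


def read_network_tsv(path) -> BaitNetwork:
    """Read an edge-table TSV written by :func:`export_network`."""
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EDGE_COLUMNS:
            raise ValueError(
                f"unexpected edge-table header {header}; expected {list(_EDGE_COLUMNS)}"
            )
        for line in fh:
            bait, prey, sulfur, pyruvate, rank, rescued = line.rstrip("\n").split("\t")
            edges.append(Edge(
                bait_gene=bait, prey_protein=prey,
                sulfur=sulfur == "true", pyruvate=pyruvate == "true",
                rank=int(rank), rescued=rescued == "true",
            ))
    return BaitNetwork(edges=edges, baits={e.bait_gene for e in edges})


def read_network_graphml(path) -> BaitNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path, force_multigraph=True)
    edges = [
        Edge(
            bait_gene=u, prey_protein=v,
            sulfur=bool(d["sulfur"]), pyruvate=bool(d["pyruvate"]),
            rank=int(d["rank"]), rescued=bool(d["rescued"]),
        )
        for u, v, d in g.edges(data=True)
    ]
    baits = {n for n, d in g.nodes(data=True) if d.get("is_bait")}
    return BaitNetwork(edges=edges, baits=baits or {e.bait_gene for e in edges})
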