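"""Taxonomy tree with lowest-common-ancestor and rank-rollup queries.

The tree is read from the NCBI taxdump dialect (``nodes`` / ``names`` files
with ``\\t|\\t`` field separators and ``\\t|`` record terminators, scientific
names only).  Metaprotein annotation, krona export and taxon restrictions all
query the same tree through :func:`lca`, :func:`ancestor_at_rank` and
:func:`lineage`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence


#: Closed set of rank labels the pipeline rolls up to.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "no rank",
)

#: Conventional root-first ordering used for lineages and krona rows.
DEFAULT_RANKS = RANKS[:-1]


class _Unassigned:
    """Sentinel for "no ancestor at this rank" — deliberately not a tax_id."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "unassigned"

    def __bool__(self) -> bool:
        return False


UNASSIGNED = _Unassigned()


class TaxonomyError(Exception):
    """Structural or lookup failure in a taxonomy tree."""


@dataclass(frozen=True)
class TaxonomyNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Validated taxonomy: unique tax_ids, single self-parented root, acyclic."""

    nodes: dict[int, TaxonomyNode]
    root_id: int
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._compute_depths()

    def _compute_depths(self) -> None:
        self._depth = {self.root_id: 0}
        for tax_id in self.nodes:
            self._walk_depth(tax_id)

    def _walk_depth(self, tax_id: int) -> int:
        chain: list[int] = []
        current = tax_id
        while current not in self._depth:
            if current in chain:
                cycle = chain[chain.index(current):] + [current]
                raise TaxonomyError(f"cycle in taxonomy: {cycle}")
            chain.append(current)
            node = self.nodes.get(current)
            if node is None:
                raise TaxonomyError(f"unknown parent tax_id {current}")
            current = node.parent_id
        depth = self._depth[current]
        for tid in reversed(chain):
            depth += 1
            self._depth[tid] = depth
        return self._depth[tax_id]

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def node(self, tax_id: int) -> TaxonomyNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise TaxonomyError(f"unknown tax_id {tax_id}") from None

    def depth(self, tax_id: int) -> int:
        if tax_id not in self.nodes:
            raise TaxonomyError(f"unknown tax_id {tax_id}")
        return self._depth[tax_id]

    def path_to_root(self, tax_id: int) -> list[int]:
        """Tax_ids from the node up to and including the root."""
        node = self.node(tax_id)
        path = [node.tax_id]
        while node.tax_id != self.root_id:
            node = self.nodes[node.parent_id]
            path.append(node.tax_id)
        return path


def _parse_taxdump_lines(source: IO[str]) -> Iterable[list[str]]:
    for line in source:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.endswith("\t|"):
            line = line[: -len("\t|")]
        yield [f.strip() for f in line.split("\t|\t")]


def load_taxonomy(nodes_source: IO[str], names_source: IO[str]) -> TaxonomyTree:
    """Load a :class:`TaxonomyTree` from taxdump-dialect node and name streams.

    ``nodes_source`` rows are ``tax_id | parent_id | rank``; ``names_source``
    rows are ``tax_id | name [| unique name | name class]``.  Rows whose name
    class is present and not ``scientific name`` are ignored.  Nodes without a
    scientific name are named ``unnamed_<tax_id>``.  Unknown rank labels map
    to ``no rank`` with a warning.
    """
    raw: dict[int, tuple[int, str]] = {}
    for fields in _parse_taxdump_lines(nodes_source):
        if len(fields) < 3:
            raise TaxonomyError(f"malformed nodes record: {fields!r}")
        tax_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
        if tax_id in raw:
            raise TaxonomyError(f"duplicate tax_id {tax_id}")
        if rank not in RANKS:
            warnings.warn(f"unknown rank {rank!r} for tax_id {tax_id}; using 'no rank'")
            rank = "no rank"
        raw[tax_id] = (parent_id, rank)

    names: dict[int, str] = {}
    for fields in _parse_taxdump_lines(names_source):
        if len(fields) < 2:
            raise TaxonomyError(f"malformed names record: {fields!r}")
        if len(fields) >= 4 and fields[3] != "scientific name":
            continue
        names.setdefault(int(fields[0]), fields[1])

    nodes: dict[int, TaxonomyNode] = {}
    roots = []
    for tax_id, (parent_id, rank) in raw.items():
        if parent_id not in raw:
            raise TaxonomyError(
                f"tax_id {tax_id} references unknown parent_id {parent_id}"
            )
        if parent_id == tax_id:
            roots.append(tax_id)
        nodes[tax_id] = TaxonomyNode(
            tax_id=tax_id,
            parent_id=parent_id,
            rank=rank,
            name=names.get(tax_id, f"unnamed_{tax_id}"),
        )
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root, found {roots}")
    return TaxonomyTree(nodes=nodes, root_id=roots[0])


def lca(tree: TaxonomyTree, tax_ids: Iterable[int]) -> int:
    """Deepest node lying on the root path of every input tax_id.

    Singleton sets return their element; any set containing the root returns
    the root.
    """
    ids = set(tax_ids)
    if not ids:
        raise ValueError("lca of an empty set is undefined")
    common: set[int] | None = None
    for tid in ids:
        path = set(tree.path_to_root(tid))
        common = path if common is None else common & path
    assert common  # root is on every path
    return max(common, key=tree.depth)


def ancestor_at_rank(tree: TaxonomyTree, tax_id: int, rank: str):
    """Ancestor-or-self of ``tax_id`` with the requested rank, else UNASSIGNED."""
    if rank not in RANKS:
        raise TaxonomyError(f"unknown rank label {rank!r}")
    for tid in tree.path_to_root(tax_id):
        if tree.nodes[tid].rank == rank:
            return tid
    return UNASSIGNED


def lineage(
    tree: TaxonomyTree, tax_id: int, ranks: Sequence[str] = DEFAULT_RANKS
) -> list:
    """One name (or UNASSIGNED) per requested rank, root-first order preserved."""
    tree.node(tax_id)  # raise early on unknown id
    out = []
    for rank in ranks:
        ancestor = ancestor_at_rank(tree, tax_id, rank)
        out.append(UNASSIGNED if ancestor is UNASSIGNED else tree.nodes[ancestor].name)
    return out
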