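"""Rooted taxonomy trees: loading, lineage extraction and lowest common ancestor.

The taxonomy is the backing structure for conservative taxonomic binning of
sequences: when the homology hits of a query disagree, the query is assigned
the most specific taxon that is ancestral to every hit taxon.  "Most specific"
is defined by tree depth, not by rank labels, so unranked nodes ("no rank") are
legitimate assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "load_taxonomy",
    "lowest_common_ancestor",
    "lineage",
]

#: parent_id values (besides self-reference) treated as "this node is the root"
NULL_PARENTS = frozenset({"", "-", "none", "null"})


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy: cycle, dangling parent, or no/multiple roots."""


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy.

    A node whose ``parent_id`` equals its own ``taxon_id`` (NCBI taxdump
    convention), or is one of the null sentinels, is the root.
    """

    taxon_id: str
    parent_id: str
    rank: str = "no rank"
    name: str = ""

    @property
    def is_root(self) -> bool:
        return self.parent_id == self.taxon_id or self.parent_id.lower() in NULL_PARENTS


class TaxonomyTree:
    """Validated rooted tree over :class:`TaxonNode` objects.

    Construction verifies that exactly one root exists, every parent reference
    resolves, and there are no cycles; node depths (root = 0) are computed
    eagerly so lineage and LCA queries are cheap.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise TaxonomyError("taxonomy has no nodes")

        roots = [n.taxon_id for n in self._nodes.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}: {roots[:5]}")
        self._root = roots[0]

        self._depth: dict[str, int] = {self._root: 0}
        for node in self._nodes.values():
            self._resolve_depth(node.taxon_id)

    def _resolve_depth(self, taxon_id: str) -> int:
        # Iterative walk to the first ancestor of known depth; detects cycles
        # and dangling parents along the way.
        path: list[str] = []
        seen: set[str] = set()
        current = taxon_id
        while current not in self._depth:
            if current in seen:
                raise TaxonomyError(f"cycle detected involving taxon {current!r}")
            seen.add(current)
            node = self._nodes.get(current)
            if node is None:
                raise TaxonomyError(
                    f"dangling parent: taxon {path[-1] if path else taxon_id!r} "
                    f"references missing node {current!r}"
                )
            path.append(current)
            current = node.parent_id
        base = self._depth[current]
        for offset, tid in enumerate(reversed(path), start=1):
            self._depth[tid] = base + offset
        return self._depth[taxon_id]

    # -- queries ---------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> Mapping[str, TaxonNode]:
        return self._nodes

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def parent(self, taxon_id: str) -> str:
        node = self.node(taxon_id)
        return taxon_id if node.is_root else node.parent_id

    def depth(self, taxon_id: str) -> int:
        try:
            return self._depth[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def lineage(self, taxon_id: str) -> list[str]:
        """Path of taxon ids from the root down to ``taxon_id`` (inclusive)."""
        self.depth(taxon_id)  # raises on unknown id
        path = [taxon_id]
        current = taxon_id
        while current != self._root:
            current = self._nodes[current].parent_id
            path.append(current)
        path.reverse()
        return path

    def leaves(self) -> list[str]:
        parents = {n.parent_id for n in self._nodes.values() if not n.is_root}
        return [tid for tid in self._nodes if tid not in parents]

    def is_ancestor_or_self(self, ancestor: str, descendant: str) -> bool:
        d_anc, d_desc = self.depth(ancestor), self.depth(descendant)
        if d_anc > d_desc:
            return False
        current = descendant
        for _ in range(d_desc - d_anc):
            current = self._nodes[current].parent_id
        return current == ancestor

    def ancestor_at_rank(self, taxon_id: str, ranks: Iterable[str]) -> str | None:
        """Deepest ancestor-or-self of ``taxon_id`` whose rank is in ``ranks``."""
        wanted = set(ranks)
        for tid in reversed(self.lineage(taxon_id)):
            if self._nodes[tid].rank in wanted:
                return tid
        return None

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa.

        Implemented by pairwise depth-equalised climbing (not lineage
        intersection): the deeper node is lifted to the shallower one's depth,
        then both walk up in lockstep until they meet.
        """
        ids = list(taxa)
        if not ids:
            raise ValueError("lca() requires a non-empty set of taxa")
        result = ids[0]
        self.depth(result)
        for tid in ids[1:]:
            result = self._lca_pair(result, tid)
        return result

    def _lca_pair(self, a: str, b: str) -> str:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self._nodes[a].parent_id
            da -= 1
        while db > da:
            b = self._nodes[b].parent_id
            db -= 1
        while a != b:
            a = self._nodes[a].parent_id
            b = self._nodes[b].parent_id
        return a


# -- module-level functional API -----------------------------------------


def lineage(tree: TaxonomyTree, taxon_id: str) -> list[str]:
    return tree.lineage(taxon_id)


def lowest_common_ancestor(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    return tree.lca(taxa)


# -- loading -------------------------------------------------------------


def _open(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "rt", encoding="utf-8"), True


def _iter_simple_tsv(handle: IO[str]) -> Iterator[TaxonNode]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0] == "taxon_id":
            continue  # optional header
        if len(fields) < 2:
            raise TaxonomyError(f"line {lineno}: expected >=2 tab-separated columns")
        rank = fields[2] if len(fields) > 2 and fields[2] else "no rank"
        name = fields[3] if len(fields) > 3 else ""
        yield TaxonNode(fields[0].strip(), fields[1].strip(), rank, name)


def _iter_ncbi_nodes(handle: IO[str]) -> Iterator[tuple[str, str, str]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\t|")
        if not line:
            continue
        fields = [f.strip() for f in line.split("\t|\t")]
        if len(fields) < 3:
            raise TaxonomyError(f"nodes.dmp line {lineno}: expected >=3 pipe-delimited fields")
        yield fields[0], fields[1], fields[2]


def load_ncbi_names(source: str | Path | IO[str]) -> dict[str, str]:
    """Scientific names from an NCBI names.dmp-style file."""
    handle, close = _open(source)
    names: dict[str, str] = {}
    try:
        for raw in handle:
            line = raw.rstrip("\n").rstrip("\t|")
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[fields[0]] = fields[1]
    finally:
        if close:
            handle.close()
    return names


def load_taxonomy(
    source: str | Path | IO[str],
    dialect: str = "simple_tsv",
    names_source: str | Path | IO[str] | None = None,
) -> TaxonomyTree:
    """Load and validate a taxonomy.

    Parameters
    ----------
    source
        Path or text handle. For ``simple_tsv``: 4 tab-separated columns
        (taxon_id, parent_id, rank, name), optional header. For ``ncbi_dump``:
        a nodes.dmp-style file with ``\\t|\\t``-separated fields.
    dialect
        ``"simple_tsv"`` or ``"ncbi_dump"``.
    names_source
        Optional names.dmp-style file (ncbi_dump only); scientific names are
        attached to the nodes.
    """
    handle, close = _open(source)
    try:
        if dialect == "simple_tsv":
            nodes = list(_iter_simple_tsv(handle))
        elif dialect == "ncbi_dump":
            names = load_ncbi_names(names_source) if names_source is not None else {}
            nodes = [
                TaxonNode(tid, pid, rank or "no rank", names.get(tid, ""))
                for tid, pid, rank in _iter_ncbi_nodes(handle)
            ]
        else:
            raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    finally:
        if close:
            handle.close()
    return TaxonomyTree(nodes)
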