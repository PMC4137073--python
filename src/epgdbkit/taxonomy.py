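"""Taxonomic hierarchy: loading, depths, ancestry, LCA, paths, group collapsing.

The tree models the NCBI Taxonomy hierarchy: a single root (which is its own
parent, as in NCBI's ``nodes.dmp`` where tax_id 1 has parent 1), a parent
pointer per node, a primary (scientific) name per node and an optional rank
label.  Two loaders are provided: the standard NCBI taxdump dialect
(``nodes.dmp``/``names.dmp``) and a compact lineage-table dialect in which one
row carries a full root-first label chain — convenient for fixtures and for
annotation pipelines that emit lineages rather than tax ids.

Depth counts *all* nodes on the parent chain by default, including "no rank"
nodes; pass ``ranked_only=True`` to count only canonically ranked nodes
(useful for sensitivity analysis, since real NCBI chains are padded with
unranked internal nodes).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .errors import (
    AmbiguousNameError,
    DomainError,
    LookupError_,
    ParseError,
    StructuralError,
)

logger = logging.getLogger(__name__)

#: ranks counted when ``ranked_only`` is requested
CANONICAL_RANKS = frozenset(
    {
        "superkingdom",
        "domain",
        "kingdom",
        "phylum",
        "class",
        "order",
        "family",
        "genus",
        "species",
    }
)

#: default anchors for collapsing expected taxonomic ranges into the ten
#: high-level groups used when summarising disagreement classes.  Keys are
#: node labels as they appear in NCBI; values are the group names.  Any taxon
#: whose ancestor chain hits none of these anchors collapses to "other".
DEFAULT_GROUP_ANCHORS: dict[str, str] = {
    "root": "root",
    "cellular organisms": "cellular organisms",
    "Prokaryotes": "prokaryotes",
    "Bacteria": "bacteria",
    "Archaea": "archaea",
    "Eukaryota": "eukaryotes",
    "Metazoa": "animals",
    "Fungi": "fungi",
    "Viridiplantae": "plants",
}


@dataclass(frozen=True)
class TaxonPath:
    """Simple path between two taxa through their lowest common ancestor.

    ``edges`` is an ordered list of ``(parent, child)`` pairs; the parent is
    always the shallower node of the edge.  The list is empty iff the two
    endpoints coincide.
    """

    edges: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.edges)

    def reversed(self) -> "TaxonPath":
        """Same path walked from the other endpoint (edge orientations kept)."""
        return TaxonPath(tuple(reversed(self.edges)))


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent links, names and optional ranks."""

    parent: dict[str, str]
    name: dict[str, str]
    rank: dict[str, str] = field(default_factory=dict)
    root: str = "1"
    # name -> list of tax ids (homonyms keep several); synonyms included
    _name_index: dict[str, list[str]] = field(default_factory=dict, repr=False)
    _depth_cache: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        if not self._name_index:
            for taxon, label in self.name.items():
                self._name_index.setdefault(label, []).append(taxon)

    # -- structure ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.parent)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def validate(self) -> None:
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one self-parented root, found {len(roots)}")
        self.root = roots[0]
        for taxon, par in self.parent.items():
            if par not in self.parent:
                raise StructuralError(f"node {taxon!r} has unknown parent {par!r}")
        # no cycles: every chain must reach the root
        for taxon in self.parent:
            seen = set()
            node = taxon
            while node != self.root:
                if node in seen:
                    raise StructuralError(f"cycle detected through node {node!r}")
                seen.add(node)
                node = self.parent[node]

    def _require(self, taxon: str) -> None:
        if taxon not in self.parent:
            raise LookupError_(f"unknown taxon {taxon!r}")

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.parent}
        for taxon, par in self.parent.items():
            if taxon != self.root:
                out[par].append(taxon)
        return out

    def leaves(self) -> list[str]:
        kids = self.children()
        return [t for t, c in kids.items() if not c]

    # -- queries -----------------------------------------------------------

    def ancestors(self, taxon: str, include_self: bool = True) -> list[str]:
        """Chain from ``taxon`` up to the root (ancestor-or-self by default)."""
        self._require(taxon)
        chain = [taxon] if include_self else []
        node = taxon
        while node != self.root:
            node = self.parent[node]
            chain.append(node)
        return chain

    def depth(self, taxon: str, ranked_only: bool = False) -> int:
        """Number of edges from the root; with ``ranked_only``, number of
        canonically ranked nodes strictly above ``taxon``."""
        self._require(taxon)
        if ranked_only:
            return sum(
                1
                for a in self.ancestors(taxon, include_self=False)
                if self.rank.get(a, "no rank") in CANONICAL_RANKS
            )
        if taxon not in self._depth_cache:
            # fill cache along the chain
            chain = []
            node = taxon
            while node != self.root and node not in self._depth_cache:
                chain.append(node)
                node = self.parent[node]
            base = 0 if node == self.root else self._depth_cache[node]
            if node == self.root:
                self._depth_cache[self.root] = 0
            for i, n in enumerate(reversed(chain), start=1):
                self._depth_cache[n] = base + i
        return self._depth_cache[taxon]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is an ancestor of ``b`` or ``a == b``."""
        self._require(a)
        return a in self.ancestors(b)

    def lca(self, taxa: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input taxon."""
        taxa = list(taxa)
        if not taxa:
            raise DomainError("lca of an empty taxon collection is undefined")
        common: set[str] | None = None
        for t in taxa:
            anc = set(self.ancestors(t))
            common = anc if common is None else common & anc
        assert common  # root is always shared
        return max(common, key=self.depth)

    def path_edges(self, a: str, b: str) -> TaxonPath:
        """Edges from ``a`` up to ``lca(a, b)`` then down to ``b``.

        Every edge is reported ``(parent, child)`` with the parent the
        shallower node, regardless of walking direction.
        """
        self._require(a)
        self._require(b)
        anc = self.lca([a, b])
        up = []  # a -> anc, walked upward
        node = a
        while node != anc:
            up.append((self.parent[node], node))
            node = self.parent[node]
        down = []  # anc -> b
        node = b
        while node != anc:
            down.append((self.parent[node], node))
            node = self.parent[node]
        down.reverse()
        return TaxonPath(tuple(up + down))

    # -- names -------------------------------------------------------------

    def add_synonym(self, taxon: str, label: str) -> None:
        self._require(taxon)
        ids = self._name_index.setdefault(label, [])
        if taxon not in ids:
            ids.append(taxon)

    def resolve_name(self, label: str, anchor: str | None = None) -> str:
        """Resolve a name (or tax id) to a taxon id.

        Scientific names and registered synonyms both resolve.  Homonyms are
        resolved by preferring the candidate whose ancestor chain contains
        ``anchor``; with no deciding anchor an :class:`AmbiguousNameError` is
        raised.
        """
        if label in self.parent:
            return label
        candidates = self._name_index.get(label, [])
        if not candidates:
            raise LookupError_(f"name {label!r} does not resolve in the taxonomy")
        if len(candidates) == 1:
            return candidates[0]
        if anchor is not None:
            anchored = [c for c in candidates if anchor in self.ancestors(c) or anchor in (self.name.get(t) for t in self.ancestors(c))]
            if len(anchored) == 1:
                return anchored[0]
        raise AmbiguousNameError(
            f"name {label!r} is a homonym for taxa {sorted(candidates)}; supply a disambiguation anchor"
        )

    def resolve_many(
        self, labels: Sequence[str], anchor: str | None = None
    ) -> tuple[list[str], int]:
        """Resolve a list of labels, skipping unresolvable ones with a warning.

        Returns ``(resolved_ids, n_skipped)``.  An all-unresolvable list is a
        domain error.
        """
        resolved: list[str] = []
        skipped = 0
        for label in labels:
            try:
                resolved.append(self.resolve_name(label, anchor=anchor))
            except LookupError_:
                skipped += 1
        if skipped:
            logger.warning("skipped %d unresolvable taxon label(s)", skipped)
        if labels and not resolved:
            raise DomainError("no taxon label in the list resolves in the tree")
        return resolved, skipped

    # -- collapsing --------------------------------------------------------

    def collapse_to_group(
        self, taxon: str, group_map: Mapping[str, str] | None = None
    ) -> str:
        """Collapse a taxon to a high-level group.

        Walks the ancestor-or-self chain and returns the group of the deepest
        anchor found; falls back to ``"other"`` when no anchor (not even the
        root) matches.  ``group_map`` maps anchor *labels* to group names.
        """
        anchors = DEFAULT_GROUP_ANCHORS if group_map is None else group_map
        self._require(taxon)
        for node in self.ancestors(taxon):  # deepest first
            label = self.name.get(node, node)
            if label in anchors:
                return anchors[label]
            if node in anchors:
                return anchors[node]
        return "other"


# ---------------------------------------------------------------------------
# loaders


def _split_dmp_line(line: str, lineno: int, path_hint: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    fields = line.split("\t|\t")
    if len(fields) < 2:
        raise ParseError(f"{path_hint}: malformed line {lineno}: {line!r}")
    return fields


def read_ncbi_dump(nodes_source: IO[str] | str, names_source: IO[str] | str) -> TaxonomyTree:
    """Load a taxonomy from NCBI taxdump ``nodes.dmp`` / ``names.dmp`` streams.

    Fields are separated by ``"\\t|\\t"`` and lines terminated by ``"\\t|"``.
    Scientific names become primary labels; other name classes (synonyms,
    equivalent names, common names) are registered as synonyms.
    """
    if isinstance(nodes_source, str):
        nodes_source = io.StringIO(nodes_source)
    if isinstance(names_source, str):
        names_source = io.StringIO(names_source)

    parent: dict[str, str] = {}
    rank: dict[str, str] = {}
    for lineno, line in enumerate(nodes_source, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, "nodes.dmp")
        taxon, par = fields[0].strip(), fields[1].strip()
        parent[taxon] = par
        if len(fields) >= 3:
            rank[taxon] = fields[2].strip()
    for taxon, par in parent.items():
        if par not in parent:
            raise StructuralError(f"nodes.dmp: node {taxon!r} references unknown parent {par!r}")

    name: dict[str, str] = {}
    synonyms: list[tuple[str, str]] = []
    for lineno, line in enumerate(names_source, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, "names.dmp")
        taxon, label = fields[0].strip(), fields[1].strip()
        name_class = fields[3].strip() if len(fields) >= 4 else "scientific name"
        if taxon not in parent:
            raise StructuralError(f"names.dmp: name for unknown node {taxon!r} (line {lineno})")
        if name_class == "scientific name":
            name[taxon] = label
        else:
            synonyms.append((taxon, label))
    for taxon in parent:
        name.setdefault(taxon, taxon)

    tree = TaxonomyTree(parent=parent, name=name, rank=rank)
    for taxon, label in synonyms:
        tree.add_synonym(taxon, label)
    return tree


def read_lineage_table(source: IO[str] | str) -> TaxonomyTree:
    """Load a taxonomy from a lineage table.

    Dialect: UTF-8 TSV with a ``lineage`` column holding semicolon-separated
    root-first label chains; ``#`` starts a comment line.  A bare stream of
    chains (no header) is also accepted.  Labels double as node identifiers,
    so the same label appearing under two different parents is a structural
    error (conflicting parentage).
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    parent: dict[str, str] = {}
    rows = 0
    header_seen = False
    lineage_col = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if not header_seen:
            header_seen = True
            if "lineage" in cells:
                lineage_col = cells.index("lineage")
                continue  # header row
        if lineage_col >= len(cells):
            raise ParseError(f"lineage table: line {lineno} has no lineage column")
        chain = [c.strip() for c in cells[lineage_col].split(";") if c.strip()]
        if not chain:
            raise ParseError(f"lineage table: empty lineage on line {lineno}")
        rows += 1
        for i, label in enumerate(chain):
            par = chain[i - 1] if i > 0 else label  # root self-parented
            if label in parent and parent[label] != par:
                raise StructuralError(
                    f"conflicting parentage for {label!r}: {parent[label]!r} vs {par!r} (line {lineno})"
                )
            parent[label] = par
    if rows == 0:
        raise ParseError("lineage table contains no data rows")
    name = {t: t for t in parent}
    return TaxonomyTree(parent=parent, name=name)


def lineage_chains(tree: TaxonomyTree) -> list[str]:
    """Root-first semicolon chains, one per leaf (inverse of read_lineage_table)."""
    return [
        ";".join(tree.name.get(t, t) for t in reversed(tree.ancestors(leaf)))
        for leaf in sorted(tree.leaves())
    ]


# thin module-level wrappers mirroring the functional surface -----------------


def depth(tree: TaxonomyTree, taxon: str, ranked_only: bool = False) -> int:
    return tree.depth(taxon, ranked_only=ranked_only)


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    return tree.lca(taxa)


def is_ancestor(tree: TaxonomyTree, a: str, b: str) -> bool:
    return tree.is_ancestor(a, b)


def path_edges(tree: TaxonomyTree, a: str, b: str) -> TaxonPath:
    return tree.path_edges(a, b)


def collapse_to_group(
    tree: TaxonomyTree, taxon: str, group_map: Mapping[str, str] | None = None
) -> str:
    return tree.collapse_to_group(taxon, group_map)
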