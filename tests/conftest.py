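"""Shared fixtures and independent graph-search oracles.

The oracles deliberately avoid the toolkit's own tree code: they operate on a
networkx graph rebuilt from the raw parent map, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from epgdbkit.simulate import make_taxonomy
from epgdbkit.taxonomy import TaxonomyTree, read_lineage_table

TOY_LINEAGES = """\
lineage
root;cellular organisms;Bacteria;Proteobacteria;Escherichia coli
root;cellular organisms;Bacteria;Proteobacteria;Salmonella enterica
root;cellular organisms;Bacteria;Firmicutes;Bacillus subtilis
root;cellular organisms;Archaea;Euryarchaeota;Methanococcus
root;cellular organisms;Eukaryota;Fungi;Saccharomyces cerevisiae
root;cellular organisms;Eukaryota;Metazoa;Homo sapiens
root;cellular organisms;Eukaryota;Viridiplantae;Arabidopsis thaliana
"""


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    return read_lineage_table(TOY_LINEAGES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_trees(seed: int, n_trees: int, max_leaves: int = 60, max_depth: int = 9):
    """Stream of random taxonomies for property sweeps."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        yield make_taxonomy(
            int(rng.integers(2**31)),
            n_leaves=int(rng.integers(2, max_leaves)),
            max_depth=int(rng.integers(2, max_depth)),
        )


# -- networkx oracles ---------------------------------------------------------


def nx_graph(tree: TaxonomyTree) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(tree.parent)
    g.add_edges_from((p, c) for c, p in tree.parent.items() if c != p)
    return g


def oracle_depth(tree: TaxonomyTree, taxon: str) -> int:
    return nx.shortest_path_length(nx_graph(tree), tree.root, taxon)


def oracle_ancestors(tree: TaxonomyTree, taxon: str) -> set[str]:
    return set(nx.shortest_path(nx_graph(tree), tree.root, taxon))


def oracle_lca(tree: TaxonomyTree, taxa) -> str:
    common = set.intersection(*(oracle_ancestors(tree, t) for t in taxa))
    return max(common, key=lambda n: oracle_depth(tree, n))


def oracle_path_nodes(tree: TaxonomyTree, a: str, b: str) -> list[str]:
    return nx.shortest_path(nx_graph(tree), a, b)


def oracle_signed_distance(tree: TaxonomyTree, expected: str, observed: str, base: float = 2.0) -> float:
    g = nx_graph(tree)
    nodes = nx.shortest_path(g, expected, observed)
    depth = {n: nx.shortest_path_length(g, tree.root, n) for n in nodes}
    mag = sum(
        base ** (-min(depth[u], depth[v])) for u, v in zip(nodes, nodes[1:])
    )
    sign = 1.0 if expected in oracle_ancestors(tree, observed) else -1.0
    return sign * mag


def oracle_pathway_wtd(tree: TaxonomyTree, range_taxa, observed: str, base: float = 2.0) -> float:
    dists = [oracle_signed_distance(tree, x, observed, base=base) for x in range_taxa]
    nonneg = [d for d in dists if d >= 0]
    return min(nonneg) if nonneg else max(dists)
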