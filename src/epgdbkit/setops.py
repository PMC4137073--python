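"""Set analyses over pathway presence/absence across samples and genomes.

Three families of operation:

* k-way region reports — every pathway in the union of k named sets assigned
  to its exact membership pattern (the regions of a k-set Venn diagram);
* DNA/RNA fraction partitions per depth, and their unions across depths
  (a pathway classified differently at two depths appears in both components);
* distributed-pathway detection — pathways predicted from a *combined* pair of
  genomes but from neither genome alone are candidates for metabolism
  distributed across the pair, and a candidate is deemed *plausible* when a
  sufficient share of its reactions (default 75%) carries coding sequences
  from both members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SetRegionReport:
    """Exact membership regions of a family of named pathway sets."""

    set_names: tuple[str, ...]
    regions: dict[tuple[bool, ...], frozenset[str]]

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return frozenset(out)

    def region(self, pattern: Sequence[bool]) -> frozenset[str]:
        return self.regions[tuple(bool(x) for x in pattern)]

    def exclusive_to(self, name: str) -> frozenset[str]:
        """Pathways present in exactly one named set."""
        i = self.set_names.index(name)
        pattern = tuple(j == i for j in range(len(self.set_names)))
        return self.regions[pattern]


@dataclass(frozen=True)
class DistributedCandidate:
    pathway: str
    pair: tuple[str, str]
    coverage_both: float
    plausible: bool


def kway_regions(
    named_sets: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
) -> SetRegionReport:
    """Assign every pathway in the union to its exact membership pattern.

    ``named_sets`` is an ordered mapping or an iterable of (label, set) pairs
    (2 to 6 sets); all 2^k - 1 non-empty patterns are reported, empty regions
    as empty sets.  Duplicate labels are a schema error.
    """
    pairs = list(named_sets.items()) if isinstance(named_sets, Mapping) else list(named_sets)
    names = tuple(n for n, _ in pairs)
    if len(names) != len(set(names)):
        raise SchemaError("duplicate set labels")
    if not 2 <= len(names) <= 6:
        raise DomainError("k-way set analysis supports 2 to 6 sets")
    sets = [frozenset(s) for _, s in pairs]
    regions: dict[tuple[bool, ...], set[str]] = {
        p: set() for p in product((False, True), repeat=len(names)) if any(p)
    }
    for pathway in frozenset().union(*sets):
        pattern = tuple(pathway in s for s in sets)
        regions[pattern].add(pathway)
    return SetRegionReport(names, {p: frozenset(m) for p, m in sorted(regions.items())})


def fraction_partition(
    dna: Iterable[str], rna: Iterable[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition one depth's pathways into (DNA-only, shared, RNA-only)."""
    dna, rna = frozenset(dna), frozenset(rna)
    return dna - rna, dna & rna, rna - dna


def union_fractions_over_depths(
    partitions: Mapping[str, tuple[Iterable[str], Iterable[str], Iterable[str]]],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Component-wise unions of per-depth fraction partitions.

    A pathway that is DNA-only at one depth and shared at another contributes
    to both union components, so component sizes may exceed the overall union.
    """
    if not partitions:
        raise DomainError("at least one depth partition is required")
    dna_only: set[str] = set()
    shared: set[str] = set()
    rna_only: set[str] = set()
    for d, s, r in partitions.values():
        dna_only |= set(d)
        shared |= set(s)
        rna_only |= set(r)
    return frozenset(dna_only), frozenset(shared), frozenset(rna_only)


def distributed_candidates(
    combined: Iterable[str], individuals: Sequence[Iterable[str]]
) -> frozenset[str]:
    """Pathways predicted from the combined genomes but from no individual one."""
    if len(individuals) < 2:
        raise DomainError("need at least two individual pathway sets")
    union_ind: set[str] = set()
    for s in individuals:
        union_ind |= set(s)
    return frozenset(combined) - union_ind


def plausibility_filter(
    candidates: Iterable[str],
    reaction_coverage: Mapping[str, Mapping[str, Iterable[str]]],
    pair: tuple[str, str],
    threshold: float = 0.75,
    coverage_mode: str = "per_reaction",
) -> list[DistributedCandidate]:
    """Score distributed-pathway candidates by both-member reaction coverage.

    ``reaction_coverage`` maps pathway -> reaction -> contributing genome
    labels.  Under the default ``per_reaction`` mode a reaction counts toward
    coverage only when *both* pair members contribute at least one CDS to it;
    the looser ``per_pathway`` mode counts reactions covered by anyone,
    requiring merely that each member contributes somewhere in the pathway.
    A candidate is plausible iff its coverage reaches ``threshold`` (closed
    boundary).  Candidates without coverage data are reported implausible
    with a logged warning.
    """
    if coverage_mode not in ("per_reaction", "per_pathway"):
        raise DomainError(f"unknown coverage_mode {coverage_mode!r}")
    a, b = pair
    out = []
    for pathway in sorted(set(candidates)):
        if pathway not in reaction_coverage:
            logger.warning("candidate %r has no reaction coverage data; implausible", pathway)
            out.append(DistributedCandidate(pathway, pair, 0.0, False))
            continue
        per_reaction = {rxn: set(who) for rxn, who in reaction_coverage[pathway].items()}
        n = len(per_reaction)
        if n == 0:
            out.append(DistributedCandidate(pathway, pair, 0.0, False))
            continue
        if coverage_mode == "per_reaction":
            covered = sum(1 for who in per_reaction.values() if a in who and b in who)
            coverage = covered / n
            plausible = coverage >= threshold
        else:
            covered = sum(1 for who in per_reaction.values() if who)
            coverage = covered / n
            contributors = set().union(*per_reaction.values())
            plausible = coverage >= threshold and a in contributors and b in contributors
        out.append(DistributedCandidate(pathway, pair, coverage, plausible))
    return out
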