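"""Synthetic taxonomies, communities and pathway tables.

These generators reproduce the *statistical structure* of pathway-prediction
experiments on simulated metagenomes so that every other module is testable
without external downloads:

* multi-genome communities with even abundances or one genome in n-fold
  excess (the 20-fold skew of a dominated community is the canonical case);
* a shared core of pathways plus genome-specific accessory pathways, which
  yields the collector's-curve shape — core pathways accumulate early as
  coverage grows, accessory pathways near the asymptote;
* coverage emulated by subsampling CDS observations with replacement at
  fractional levels of the total (1/20 ... 1/1), not by read simulation —
  ORF calling and homology annotation sit upstream and out of scope;
* engineered *split* pathways whose reactions are divided between two member
  genomes, so that neither genome alone completes the pathway: ground-truth
  positives for distributed-metabolism detection;
* expected-range maps with a controlled misassignment rate, giving known
  sign ground truth for the weighted taxonomic distance.

A pathway counts as "recovered" when at least one of its CDS is drawn; the
evidence heuristics of upstream pathway inference are deliberately not
imitated.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .pathway_table import PathwayRecord, PathwayTable
from .taxonomy import TaxonomyTree
from .wtd import ExpectedRangeMap

#: the subsampling fractions used in coverage experiments
DEFAULT_FRACTIONS = (1 / 20, 1 / 10, 3 / 20, 1 / 5, 2 / 5, 3 / 5, 4 / 5, 1.0)


@dataclass(frozen=True)
class Genome:
    label: str
    taxon: str
    weight: float
    # pathway -> reaction id -> CDS multiplicity held by this genome
    pathways: Mapping[str, Mapping[str, int]]


@dataclass
class CommunityModel:
    tree: TaxonomyTree
    genomes: list[Genome]
    # full reference definition: pathway -> ordered reaction ids
    pathway_reactions: dict[str, tuple[str, ...]]
    # engineered distributed pathways: pathway -> (genome A label, genome B label)
    split_pathways: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def true_pathways(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.genomes:
            out |= set(g.pathways)
        return frozenset(out)

    @property
    def total_multiplicity(self) -> int:
        return sum(m for g in self.genomes for rxns in g.pathways.values() for m in rxns.values())

    def genome(self, label: str) -> Genome:
        for g in self.genomes:
            if g.label == label:
                return g
        raise DomainError(f"unknown genome {label!r}")


@dataclass(frozen=True)
class SubsampleSpec:
    fraction: float
    seed: int
    replacement: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise DomainError("subsampling fraction must lie in (0, 1]")
        if not self.replacement:
            raise DomainError("only sampling with replacement is supported")


def make_taxonomy(seed: int, n_leaves: int, max_depth: int) -> TaxonomyTree:
    """Random rooted tree with exactly ``n_leaves`` leaves and depth <= max_depth.

    Leaves are attached under randomly grown chains of internal nodes; leaf
    nodes never receive children, so the leaf count is exact.  Deterministic
    per seed.
    """
    if n_leaves < 1 or max_depth < 1:
        raise DomainError("n_leaves and max_depth must be positive")
    rng = np.random.default_rng(seed)
    parent = {"root": "root"}
    depth = {"root": 0}
    internal = ["root"]
    n_int = 0
    for i in range(n_leaves):
        # pick an internal attachment point shallower than max_depth
        pool = [u for u in internal if depth[u] < max_depth]
        u = pool[rng.integers(len(pool))]
        # optionally deepen with new internal nodes before hanging the leaf
        while depth[u] + 1 < max_depth and rng.random() < 0.5:
            n_int += 1
            v = f"i{n_int}"
            parent[v] = u
            depth[v] = depth[u] + 1
            internal.append(v)
            u = v
        leaf = f"L{i + 1}"
        parent[leaf] = u
        depth[leaf] = depth[u] + 1
    name = {t: t for t in parent}
    return TaxonomyTree(parent=parent, name=name)


def make_community(
    seed: int,
    n_genomes: int = 10,
    skew: float = 1.0,
    pathways_per_genome: int = 20,
    shared_fraction: float = 0.5,
    n_split_pathways: int = 0,
    split_overlap: float = 0.0,
    reactions_range: tuple[int, int] = (4, 10),
    cds_per_reaction_range: tuple[int, int] = (1, 5),
    tree: TaxonomyTree | None = None,
) -> CommunityModel:
    """Synthesize a multi-genome community with core/accessory pathway structure.

    Genome 1 receives abundance weight ``skew`` and all others weight 1, so
    ``skew=1`` is the even-abundance design and ``skew=20`` the design with
    one genome in 20-fold excess.  A ``shared_fraction`` of each genome's
    pathways is drawn from a common core pool (shared pathways accumulate
    early under subsampling; accessory ones late).  ``n_split_pathways``
    engineered pathways have their reactions divided between the first two
    genomes — neither holds a complete set — as distributed-metabolism
    ground truth.  ``split_overlap`` is the fraction of each split pathway's
    reactions contributed by *both* members (the both-taxa coverage the
    plausibility filter will see); each member always keeps at least one
    exclusive reaction, so the pathway stays incomplete in either genome
    alone.
    """
    if n_genomes < 1 or pathways_per_genome < 1:
        raise DomainError("n_genomes and pathways_per_genome must be positive")
    if not 0 <= shared_fraction <= 1:
        raise DomainError("shared_fraction must lie in [0, 1]")
    if skew <= 0:
        raise DomainError("skew must be positive")
    if n_split_pathways and n_genomes < 2:
        raise DomainError("split pathways need at least two genomes")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = make_taxonomy(int(rng.integers(2**31)), n_leaves=max(n_genomes * 3, 12), max_depth=7)
    leaves = sorted(tree.leaves())
    if len(leaves) < n_genomes:
        raise DomainError("tree has fewer leaves than genomes")
    taxa = [leaves[i] for i in rng.choice(len(leaves), size=n_genomes, replace=False)]

    lo_r, hi_r = reactions_range
    lo_c, hi_c = cds_per_reaction_range

    pathway_reactions: dict[str, tuple[str, ...]] = {}

    def define_pathway(pid: str) -> tuple[str, ...]:
        n_rxn = int(rng.integers(lo_r, hi_r + 1))
        rxns = tuple(f"{pid}:rxn{j + 1}" for j in range(n_rxn))
        pathway_reactions[pid] = rxns
        return rxns

    n_core = round(pathways_per_genome * shared_fraction)
    core_ids = [f"PWY-CORE-{k + 1}" for k in range(n_core)]
    for pid in core_ids:
        define_pathway(pid)

    genomes: list[Genome] = []
    for gi in range(n_genomes):
        holdings: dict[str, dict[str, int]] = {}
        for pid in core_ids:
            holdings[pid] = {
                rxn: int(rng.integers(lo_c, hi_c + 1)) for rxn in pathway_reactions[pid]
            }
        for k in range(pathways_per_genome - n_core):
            pid = f"PWY-G{gi + 1}-{k + 1}"
            rxns = define_pathway(pid)
            holdings[pid] = {rxn: int(rng.integers(lo_c, hi_c + 1)) for rxn in rxns}
        genomes.append(
            Genome(
                label=f"G{gi + 1}",
                taxon=taxa[gi],
                weight=float(skew) if gi == 0 else 1.0,
                pathways=holdings,
            )
        )

    split: dict[str, tuple[str, str]] = {}
    if n_split_pathways:
        g_a, g_b = genomes[0], genomes[1]
        hold_a = dict(g_a.pathways)
        hold_b = dict(g_b.pathways)
        if not 0 <= split_overlap <= 1:
            raise DomainError("split_overlap must lie in [0, 1]")
        for k in range(n_split_pathways):
            pid = f"PWY-SPLIT-{k + 1}"
            rxns = define_pathway(pid)
            n = len(rxns)
            # first reaction exclusive to A, last exclusive to B; of the rest,
            # round(split_overlap * n) are held by both, the remainder divided
            n_both = min(round(split_overlap * n), n - 2) if n > 2 else 0
            middle = list(rxns[1:-1])
            both_rxns = set(middle[:n_both])
            rest = middle[n_both:]
            cut = len(rest) // 2
            a_rxns = {rxns[0]} | both_rxns | set(rest[:cut])
            b_rxns = {rxns[-1]} | both_rxns | set(rest[cut:])
            hold_a[pid] = {rxn: int(rng.integers(lo_c, hi_c + 1)) for rxn in rxns if rxn in a_rxns}
            hold_b[pid] = {rxn: int(rng.integers(lo_c, hi_c + 1)) for rxn in rxns if rxn in b_rxns}
            split[pid] = (g_a.label, g_b.label)
        genomes[0] = Genome(g_a.label, g_a.taxon, g_a.weight, hold_a)
        genomes[1] = Genome(g_b.label, g_b.taxon, g_b.weight, hold_b)

    return CommunityModel(tree=tree, genomes=genomes, pathway_reactions=pathway_reactions, split_pathways=split)


def _draw_units(model: CommunityModel, genome_labels: Sequence[str] | None = None):
    """Flatten (genome, pathway, reaction) units with sampling probabilities."""
    units = []
    probs = []
    selected = set(genome_labels) if genome_labels is not None else None
    for g in model.genomes:
        if selected is not None and g.label not in selected:
            continue
        for pid, rxns in g.pathways.items():
            for rxn, mult in rxns.items():
                units.append((g, pid, rxn))
                probs.append(g.weight * mult)
    p = np.asarray(probs, dtype=float)
    return units, p / p.sum()


def sample_pathway_table(
    model: CommunityModel,
    spec: SubsampleSpec,
    sample_name: str = "sim",
    genome_labels: Sequence[str] | None = None,
) -> PathwayTable:
    """Subsample CDS observations with replacement and tabulate per pathway.

    The number of draws is ``round(fraction * total CDS multiplicity)`` (at
    least 1); each draw picks a (genome, pathway, reaction) unit with
    probability proportional to genome abundance weight times per-reaction
    CDS multiplicity.  Records aggregate draws per pathway: ``n_cds`` is the
    number of draws, ``n_covered`` the distinct reactions hit, ``cds_taxa``
    the contributing genome taxa, one label per draw.
    """
    rng = np.random.default_rng(spec.seed)
    units, p = _draw_units(model, genome_labels)
    total_mult = sum(
        mult
        for g in model.genomes
        if genome_labels is None or g.label in set(genome_labels)
        for rxns in g.pathways.values()
        for mult in rxns.values()
    )
    n_draws = max(1, round(spec.fraction * total_mult))
    idx = rng.choice(len(units), size=n_draws, replace=True, p=p)

    per_pathway: dict[str, dict] = {}
    for i in idx:
        g, pid, rxn = units[i]
        slot = per_pathway.setdefault(pid, {"taxa": [], "rxns": set()})
        slot["taxa"].append(g.taxon)
        slot["rxns"].add(rxn)

    records = [
        PathwayRecord(
            sample=sample_name,
            pathway=pid,
            pathway_name=pid,
            n_reactions=len(model.pathway_reactions[pid]),
            n_covered=len(slot["rxns"]),
            n_cds=len(slot["taxa"]),
            cds_taxa=tuple(slot["taxa"]),
        )
        for pid, slot in sorted(per_pathway.items())
    ]
    return PathwayTable(records, {sample_name: n_draws})


def predicted_pathways(
    model: CommunityModel,
    genome_labels: Sequence[str],
    min_completeness: float = 1.0,
) -> frozenset[str]:
    """Pathways whose reference reaction list is covered by the given genomes.

    A pathway is "predicted" for a genome combination when the union of the
    reactions those genomes hold covers at least ``min_completeness`` of the
    pathway's full reference definition.  With the default of 1.0 an
    engineered split pathway is predicted from its two members combined but
    from neither alone.
    """
    if not 0 < min_completeness <= 1:
        raise DomainError("min_completeness must lie in (0, 1]")
    selected = [model.genome(lbl) for lbl in genome_labels]
    out = set()
    for pid, rxns in model.pathway_reactions.items():
        held: set[str] = set()
        for g in selected:
            held |= set(g.pathways.get(pid, ()))
        if rxns and len(held & set(rxns)) / len(rxns) >= min_completeness:
            out.add(pid)
    return frozenset(out)


def reaction_coverage_map(
    model: CommunityModel, genome_labels: Sequence[str]
) -> dict[str, dict[str, set[str]]]:
    """pathway -> reaction -> contributing genome labels, for a genome subset."""
    selected = [model.genome(lbl) for lbl in genome_labels]
    out: dict[str, dict[str, set[str]]] = {}
    for pid, rxns in model.pathway_reactions.items():
        cov = {rxn: set() for rxn in rxns}
        touched = False
        for g in selected:
            for rxn in g.pathways.get(pid, ()):
                cov[rxn].add(g.label)
                touched = True
        if touched:
            out[pid] = cov
    return out


def collector_curve(
    model: CommunityModel,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean pathway-recovery fraction (with sd) at each subsampling fraction.

    Recovery at fraction f is the share of the community's true pathways with
    at least one sampled CDS, averaged over replicate subsamples.
    """
    if list(fractions) != sorted(fractions):
        raise DomainError("fractions must be sorted ascending")
    rng = np.random.default_rng(seed)
    n_true = len(model.true_pathways)
    rows = []
    for f in fractions:
        recov = []
        for _ in range(replicates):
            sub = SubsampleSpec(fraction=f, seed=int(rng.integers(2**31)))
            table = sample_pathway_table(model, sub)
            recov.append(len(table.pathways & model.true_pathways) / n_true)
        rows.append(
            {"fraction": f, "mean_recovery": float(np.mean(recov)), "sd": float(np.std(recov, ddof=1)) if replicates > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def make_expected_ranges(
    model: CommunityModel, seed: int, misassignment_rate: float = 0.0
) -> ExpectedRangeMap:
    """Expected taxonomic ranges with a controlled misassignment rate.

    For each pathway the expected taxon is, with probability
    ``1 - misassignment_rate``, an ancestor-or-self of the LCA of all genomes
    holding it (so any observed CDS LCA lies inside the range and the WTD is
    non-negative); otherwise it is a node that is an ancestor of *no* holder
    taxon, which guarantees a negative WTD for any observed LCA drawn from
    the holders.
    """
    if not 0 <= misassignment_rate <= 1:
        raise DomainError("misassignment_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = model.tree
    holders: dict[str, list[str]] = {}
    for g in model.genomes:
        for pid in g.pathways:
            holders.setdefault(pid, []).append(g.taxon)

    ranges: dict[str, frozenset[str]] = {}
    for pid in sorted(holders):
        anchor = tree.lca(holders[pid])
        chain = tree.ancestors(anchor)  # valid expected taxa
        if rng.random() < misassignment_rate:
            holder_anc = set()
            for t in holders[pid]:
                holder_anc |= set(tree.ancestors(t))
            outsiders = sorted(set(tree.parent) - holder_anc)
            if not outsiders:
                raise DomainError("tree has no clade disjoint from the pathway's holders")
            pick = outsiders[int(rng.integers(len(outsiders)))]
        else:
            pick = chain[int(rng.integers(len(chain)))]
        ranges[pid] = frozenset({pick})
    return ExpectedRangeMap(ranges)
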