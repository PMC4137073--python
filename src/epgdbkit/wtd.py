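"""Weighted taxonomic distance (WTD) and taxonomic disagreement classes.

Pathways predicted from community sequence data carry an *observed* taxonomy —
the lowest common ancestor (LCA) of the taxa annotated on the pathway's coding
sequences — and an *expected taxonomic range*: the set of taxa in which the
pathway has been observed by curators.  The WTD is a signed, depth-weighted
path length between the observed LCA and the closest member of the expected
range on the taxonomy tree:

    D(x_exp, x_obs) = sign * sum over edges (a, b) on the path of w^(-d(a))

where ``d(a)`` is the depth of the shallower node of each edge (root depth 0)
and ``w`` is the weight base (default 2, so edge weights halve with each level
and every distance is bounded by the geometric series, |D| < 2).  Steps near
the root therefore dominate: crossing a domain boundary costs more than any
number of steps among the tips.  The sign is non-negative iff the expected
taxon is an ancestor-or-self of the observed LCA (the observation lies inside
the expected range) and negative otherwise.

For a pathway with several expected taxa the reported distance is the minimum
over the non-negative candidates when any exist, otherwise the maximum
(closest to zero) over the negative ones.  Within one sample, pathways are
then binned into disagreement classes: "None" for non-negative distances, and
"Low" / "Medium" / "High" by rank quartiles of the strictly negative
distances ("High" = most negative quartile).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, LookupError_
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

DISAGREEMENT_CLASSES = ("None", "Low", "Medium", "High")


@dataclass(frozen=True)
class ExpectedRangeMap:
    """Map pathway id -> set of expected taxon identifiers (curated range)."""

    ranges: dict[str, frozenset[str]]

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.ranges

    def __getitem__(self, pathway: str) -> frozenset[str]:
        return self.ranges[pathway]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Iterable[str]]]) -> "ExpectedRangeMap":
        return cls({p: frozenset(taxa) for p, taxa in pairs})

    def resolved(self, tree: TaxonomyTree) -> "ExpectedRangeMap":
        """Resolve every range label in the tree, skipping unresolvable ones
        with a warning; a pathway whose whole range is unresolvable is dropped."""
        out: dict[str, frozenset[str]] = {}
        dropped = 0
        for pathway, taxa in self.ranges.items():
            resolved = []
            for t in taxa:
                try:
                    resolved.append(tree.resolve_name(t))
                except LookupError_:
                    logger.warning("range taxon %r of pathway %r not in tree", t, pathway)
            if resolved:
                out[pathway] = frozenset(resolved)
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d pathway range(s) with no resolvable taxon", dropped)
        return ExpectedRangeMap(out)


@dataclass(frozen=True)
class WTDResult:
    """Outcome of scoring one pathway in one sample."""

    pathway: str
    observed_taxon: str | None
    matched_expected: str | None
    distance: float | None
    disagreement_class: str | None = None
    sample: str | None = None


def edge_weight(parent_depth: int, base: float = 2.0) -> float:
    """Weight of a tree edge whose shallower node sits at ``parent_depth``."""
    if parent_depth < 0:
        raise DomainError("parent depth must be non-negative")
    return float(base) ** (-parent_depth)


def signed_distance(
    tree: TaxonomyTree,
    expected: str,
    observed: str,
    base: float = 2.0,
    ranked_only: bool = False,
) -> float:
    """Signed WTD between one expected taxon and the observed LCA taxon.

    Magnitude is the sum of depth-weighted edge costs along the unique path
    through the LCA of the two taxa; the sign is non-negative iff ``expected``
    is an ancestor-or-self of ``observed``.
    """
    path = tree.path_edges(expected, observed)
    magnitude = sum(
        edge_weight(tree.depth(parent, ranked_only=ranked_only), base=base)
        for parent, _child in path.edges
    )
    if tree.is_ancestor(expected, observed):
        return magnitude
    return -magnitude


def observed_taxon_for_pathway(
    tree: TaxonomyTree, cds_taxa: Sequence[str], anchor: str | None = None
) -> str:
    """LCA of the resolvable CDS taxon labels of a pathway.

    Unresolvable labels are skipped with a logged count; an all-unresolvable
    list raises a domain error.
    """
    if not cds_taxa:
        raise DomainError("pathway has no CDS taxon annotations")
    resolved, _skipped = tree.resolve_many(list(cds_taxa), anchor=anchor)
    return tree.lca(resolved)


def pathway_wtd(
    tree: TaxonomyTree,
    ranges: ExpectedRangeMap,
    pathway: str,
    observed: str,
    base: float = 2.0,
    ranked_only: bool = False,
    on_missing_range: str = "none_class",
) -> WTDResult:
    """Score one pathway against its expected taxonomic range.

    Evaluates the signed distance to every expected taxon and reports the
    minimum non-negative distance when the observed LCA falls inside at least
    one expected range, else the negative distance closest to zero.  Ties are
    broken toward the lexicographically smallest expected taxon label for
    determinism.

    ``on_missing_range``: "none_class" (default) reports a null distance and
    class "None" for pathways absent from the range map — they cannot
    disagree; "skip" returns None semantics via a null result; "error" raises.
    """
    if pathway not in ranges:
        if on_missing_range == "error":
            raise DomainError(f"pathway {pathway!r} has no expected taxonomic range")
        if on_missing_range == "skip":
            logger.warning("pathway %r has no expected range; skipped", pathway)
            return WTDResult(pathway, observed, None, None, None)
        logger.warning("pathway %r has no expected range; class 'None' assigned", pathway)
        return WTDResult(pathway, observed, None, None, "None")

    scored = sorted(
        (
            (signed_distance(tree, x_exp, observed, base=base, ranked_only=ranked_only), x_exp)
            for x_exp in ranges[pathway]
        ),
        key=lambda dx: dx[1],
    )
    nonneg = [(d, x) for d, x in scored if d >= 0]
    if nonneg:
        dist, matched = min(nonneg, key=lambda dx: dx[0])
    else:
        dist, matched = max(scored, key=lambda dx: dx[0])
    return WTDResult(pathway, observed, matched, dist)


def _rank_quartile_classes(negatives: Sequence[float]) -> list[str]:
    """Classes for strictly negative distances, sorted ascending on input.

    Rank bins on the ascending (most negative first) sort: the bottom quarter
    of ranks is "High", the next quarter up to the median is "Medium", the
    upper half "Low".  Bin edges use floor(n/4) and floor(n/2) so that with a
    single negative value no strictly lower quartile exists and the value is
    "Low"; tied values all take the class of their first occurrence.
    """
    n = len(negatives)
    hi_end, med_end = n // 4, n // 2
    order = sorted(range(n), key=lambda i: negatives[i])
    classes = [""] * n
    first_rank_of_value: dict[float, int] = {}
    for rank, i in enumerate(order):
        v = negatives[i]
        rank0 = first_rank_of_value.setdefault(v, rank)
        if rank0 < hi_end:
            classes[i] = "High"
        elif rank0 < med_end:
            classes[i] = "Medium"
        else:
            classes[i] = "Low"
    return classes


def assign_disagreement_classes(
    results: Sequence[WTDResult], zero_is_none: bool = True
) -> list[WTDResult]:
    """Assign per-sample disagreement classes to a batch of WTD results.

    Non-negative distances (strictly positive, plus zero under the default
    ``zero_is_none`` policy — a zero distance means the observed LCA *equals*
    an expected taxon) take class "None".  The remaining distances are
    rank-partitioned into Low / Medium / High quartile bins.  Results with a
    null distance keep their pre-assigned class (missing-range pathways).
    """
    out: list[WTDResult | None] = [None] * len(results)
    neg_idx: list[int] = []
    neg_val: list[float] = []
    for i, r in enumerate(results):
        if r.distance is None:
            out[i] = r
        elif r.distance > 0 or (zero_is_none and r.distance == 0):
            out[i] = replace(r, disagreement_class="None")
        else:
            neg_idx.append(i)
            neg_val.append(r.distance)
    for i, cls in zip(neg_idx, _rank_quartile_classes(neg_val)):
        out[i] = replace(results[i], disagreement_class=cls)
    return [r for r in out if r is not None]


def summarize_by_group(
    results: Sequence[WTDResult],
    tree: TaxonomyTree,
    group_map: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], int]:
    """Count results per (high-level group of matched expected taxon, class).

    Results without a matched expected taxon are grouped under "other".
    Counts always sum to ``len(results)``.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        if r.disagreement_class is None:
            raise DomainError("assign_disagreement_classes must run before summarizing")
        group = (
            tree.collapse_to_group(r.matched_expected, group_map)
            if r.matched_expected is not None
            else "other"
        )
        key = (group, r.disagreement_class)
        counts[key] = counts.get(key, 0) + 1
    return counts


def score_table(
    tree: TaxonomyTree,
    ranges: ExpectedRangeMap,
    records: Iterable,
    base: float = 2.0,
    zero_is_none: bool = True,
    ranked_only: bool = False,
    on_missing_range: str = "none_class",
) -> list[WTDResult]:
    """Score every record of a pathway table and assign classes per sample.

    ``records`` are :class:`~epgdbkit.pathway_table.PathwayRecord`-like objects
    with ``sample``, ``pathway`` and ``cds_taxa`` attributes; records without
    CDS taxon annotations are skipped with a logged count.  Disagreement
    classes are computed within each sample (the class is a per-sample
    quantile statistic, not a global one).
    """
    by_sample: dict[str, list[WTDResult]] = {}
    skipped = 0
    for rec in records:
        if not rec.cds_taxa:
            skipped += 1
            continue
        try:
            observed = observed_taxon_for_pathway(tree, rec.cds_taxa)
        except DomainError:
            skipped += 1
            continue
        res = pathway_wtd(
            tree, ranges, rec.pathway, observed,
            base=base, ranked_only=ranked_only, on_missing_range=on_missing_range,
        )
        by_sample.setdefault(rec.sample, []).append(replace(res, sample=rec.sample))
    if skipped:
        logger.warning("skipped %d record(s) without usable CDS taxon annotations", skipped)
    out: list[WTDResult] = []
    for sample in sorted(by_sample):
        out.extend(assign_disagreement_classes(by_sample[sample], zero_is_none=zero_is_none))
    return out


def max_possible_distance(base: float = 2.0) -> float:
    """Supremum of |WTD| under a given weight base.

    Each of the two path legs (expected up to the LCA, LCA down to observed)
    is bounded by the geometric series sum over depths >= 0, i.e.
    base/(base-1); a containment (non-negative) distance has a single leg and
    is bounded by base/(base-1), which is 2 for the default base.
    """
    if base <= 1:
        return math.inf
    return 2 * base / (base - 1)
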