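# Methods

## The weighted taxonomic distance

Pathway inference on community sequence data is taxonomically promiscuous:
annotations from many donor genotypes feed one prediction, so a pathway can be
called far outside the taxa in which it has ever been observed. The weighted
taxonomic distance (WTD) quantifies that tension on the taxonomy tree.

Let `x_obs` be the lowest common ancestor (LCA) of the taxa annotated on a
pathway's coding sequences, and `TR(p)` the pathway's curated expected
taxonomic range. For each `x_exp ∈ TR(p)` the unique tree path
`P(x_exp, x_obs)` through their LCA is charted, and each edge `(a, b)` is
weighted `w^(−d(a))`, where `d(a)` is the depth of the edge's shallower node
(root depth 0) and `w > 1` is the weight base (default 2). The magnitude of
the distance is the sum of edge weights; the sign is non-negative iff `x_exp`
is an ancestor-or-self of `x_obs`, i.e. the observation descends from the
expected range. Over the whole range the reported distance is the minimum
non-negative candidate when any exists, otherwise the maximum (closest to
zero) negative one; ties break to the lexicographically smallest expected
taxon so output is deterministic.

Properties of the halving weight scheme:

* **Root-step dominance.** Within one leg of a path (a strictly descending
  chain), an edge at depth `d` outweighs the sum of all deeper edges on that
  leg — steps near the root represent larger evolutionary jumps than any
  accumulation of steps near the tips. Note that the guarantee is per leg:
  a divergent path has two legs meeting at the LCA and each depth can occur
  once per leg.
* **Boundedness.** Each leg is bounded by the geometric series
  `w/(w−1)` (= 2 for `w = 2`), so containment distances are < 2 and any
  distance < 4 in magnitude.
* **Scale-freeness of signs and classes.** Rescaling all edge weights by a
  positive constant changes neither any sign nor any rank-based class.

The printed description of the weighting factor in the source method is
typographically incomplete; geometric halving per depth is adopted here as
the simplest scheme with the dominance property, and the base is exposed as
`weight_base` for sensitivity analysis.

### Disagreement classes

Within one sample, scored pathways are binned: non-negative distances take
class **None** (a distance of exactly 0 means the observed LCA *is* an
expected taxon — perfect agreement — and is treated as None by default;
`zero_is_none=false` pushes zeros into the quantile pool for the stricter
reading that only strictly positive distances are agreement). The strictly
negative distances are sorted most-negative-first and partitioned by rank:
the first `floor(n/4)` are **High** disagreement, up to `floor(n/2)` are
**Medium**, the remainder (the half closest to zero, i.e. above the median)
are **Low**. Floor-based bin edges make the degenerate cases well defined —
with a single negative distance no strictly lower quartile exists and the
value is Low — and tied values always share the class of their first
occurrence, so the partition is a function of the multiset of distances.
Classes are per-sample statistics; they are never pooled across samples.

For summaries, each result's matched expected taxon is collapsed to one of
ten high-level groups (root, cellular organisms, prokaryotes, archaea,
bacteria, eukaryotes, animals, fungi, plants, other) by walking its ancestor
chain and taking the deepest anchor found.

### Taxonomy model

The tree is the NCBI-style hierarchy: single self-parented root, parent
pointer per node, scientific names primary with synonyms accepted. Homonyms
resolve via a user-supplied disambiguation anchor (a taxon that must appear
on the candidate's ancestor chain) or raise an explicit ambiguity error —
annotation strings are names, not tax-ids, so silent guessing is avoided.
Depth counts **all** nodes on the parent chain, including unranked ones,
because real NCBI chains are padded with "no rank" nodes and dropping them
would make depths incomparable across clades; `ranked_only=True` restricts
the count to canonical ranks for sensitivity analysis. Ancestor-or-self is
the convention everywhere, so `WTD(x, x) = 0` is well defined. Unresolvable
CDS taxon labels are skipped with a logged count; a record whose labels are
all unresolvable is skipped entirely.

## QC and normalization

A (sample, pathway) record is retained when it has at least `min_cds = 10`
mapped coding sequences; each sample is judged independently, so a pathway
may survive in one dataset and not another. Counts are normalized to percent
of the sample's total predicted ORFs (`100 · n_cds / total_orfs`); the
denominator is a required per-sample input, with an alternate denominator
column accepted when a different normalization basis is wanted.

## Set analyses and distributed pathways

Presence/absence sets feed three operations: exact-membership regions for 2–6
named sets (every pathway of the union assigned to its unique pattern);
per-depth DNA/RNA partitions (DNA-only / shared / RNA-only); and unions of
those partitions across depths, in which one pathway may legitimately appear
in two components when its classification differs by depth — the component
totals are therefore not a partition of the overall union, which is the
arithmetically consistent reading of per-depth fraction analysis.

A pathway is a *distributed-metabolism candidate* for a genome pair when it
is predicted from the combined pair but from neither member alone (set
difference). Candidates pass the plausibility filter when at least 75% of
the pathway's reactions carry coding sequences from **both** members
(closed boundary: exactly 75% passes). The default reads "from both taxa"
per reaction — a reaction counts only when both genomes contribute to it —
with a looser `per_pathway` mode (75% of reactions covered by anyone, each
member contributing somewhere) for the complementarity pattern in which two
reduced genomes hold disjoint halves of a biosynthetic pathway. Pairwise
combinations are the default; larger combinations are supported but
experimental.

## Performance metrics

True negatives are meaningless without a universe, so the confusion table
takes the pathway universe as a required input (typically the full reference
catalogue) rather than guessing one. Sensitivity, specificity, precision,
accuracy, F-measure and Matthews correlation coefficient (MCC) use their
standard definitions; a ratio with zero denominator is reported as null
rather than 0, except MCC with a zero marginal, which is 0 by the common
no-signal convention (logged). Recovery fraction — the share of gold-standard
pathways recovered — is sensitivity under another name and is provided for
building coverage curves.

## Synthetic communities

The generator emulates the *statistical structure* of pathway prediction on
simulated metagenomes, at the pathway-table level:

* random rooted taxonomies with an exact leaf count and bounded depth;
* `n` genomes on distinct leaves; genome 1 carries abundance weight `skew`
  (1 = even community; 20 = one genome in 20-fold excess), all others 1;
* each genome holds `pathways_per_genome` pathways, a `shared_fraction` of
  them drawn from a common core pool — the core/accessory split that
  produces collector's-curve recovery (core early, accessory late);
* pathways have 4–10 reactions with 1–5 coding sequences each by default —
  small MetaCyc-like pathway sizes with modest per-reaction redundancy;
* coverage is emulated by drawing `round(fraction · total CDS)` observations
  with replacement, probability ∝ abundance × multiplicity, at the fraction
  levels 1/20, 1/10, 3/20, 1/5, 2/5, 3/5, 4/5, 1/1;
* engineered *split* pathways divide their reactions between two member
  genomes (each keeps at least one exclusive reaction, so neither is complete
  alone); `split_overlap` controls the fraction of reactions contributed by
  both members, i.e. the both-taxa coverage the plausibility filter sees;
* expected-range maps assign each pathway an ancestor of the LCA of its
  holder genomes (guaranteed non-negative WTD), except a `misassignment_rate`
  fraction assigned a node that is ancestor to no holder (guaranteed
  negative) — sign ground truth for the WTD.

A pathway counts as "recovered" when at least one of its CDS is drawn. The
generator does **not** model read-level effects (read length, sequencing
error, ORF-calling and homology-annotation loss) or the evidence heuristics
of upstream pathway inference, so passing tests demonstrate correctness of
the downstream analyses and the qualitative coverage/skew behaviour — not the
absolute recovery values attainable on real sequence data. Every generator is
a pure function of its seed and parameters; there is no global random state.

## Problem sizes and numerical choices

The acceptance computations use 10-genome communities with 20 pathways per
genome (110–200 distinct pathways), 50 replicate subsamples per coverage
fraction, and 4-genome pair models with 5 split pathways of 8 reactions —
sizes at which sampling noise on reported percentages is about a point and
the whole recomputation completes in seconds. Distances for the default
base-2 weights are sums of dyadic rationals and therefore exact in floating
point; tests against the independent graph-search oracle assert exact
equality, not approximate. Degenerate inputs are defined explicitly: empty
LCA input, empty gold standard, zero normalization denominators and
out-of-universe pathways are domain errors; an empty result list classifies
to an empty list; pathways without an expected range are class None with a
null distance by default (they cannot disagree), configurable to skip or
error.

## Known limitations

* Expected taxonomic ranges are consumed as data; no attempt is made to
  re-derive them from a pathway catalogue.
* The toolkit starts from pathway-prediction tables; nothing upstream
  (ORF calling, homology annotation, pathway inference, taxonomic pruning)
  is re-implemented or simulated at the read level.
* Homonym resolution needs a user anchor; there is no probabilistic name
  reconciliation, and merged/deleted-node reconciliation of taxonomy dumps
  is out of scope.
* Distributed-pathway detection is set-difference over explicit genome
  combinations; it does not scale combinatorially to large genome
  collections and no optimization-based "distribution score" is computed.
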