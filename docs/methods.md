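# Methods

## Overview

`rbprior` prioritizes candidate breast-cancer RNA-binding proteins (RBPs)
by intersecting four independent lines of evidence — genomic alteration
burden, high-confidence protein–protein interactions with known BC
proteins, immunohistochemical (IHC) overexpression, and loss-of-function
essentiality — and then characterizes the candidates' functional
neighborhood with MCODE complex detection. Because the upstream databases
are external and version-pinned, the package validates itself on synthetic
cohorts with planted signal; this note records the generative model, the
analytical conventions, and the design decisions taken where the procedure
was genuinely open.

## The synthetic generative model

The generator emulates each data source at the granularity the pipeline
consumes, not at the level of raw measurements.

**Gene universe.** Three disjoint sets: 200 RBPs, 40 BC genes, 40
non-cancer genes (defaults; configurable). A driver-gene catalog of 60
entries is drawn over the BC set (breast cancer type) and the RBP set
(other types) with oncogene / tumor-suppressor / unknown roles. Five RBPs
are planted as progressors and five as suppressors; twelve RBPs (the five
progressors plus seven others) form the planted complex.

**Alteration cohort** (994 patients, echoing the size of the TCGA breast
cohort the criteria were designed for). Each (sample, gene, category) cell
is an independent Bernoulli event. The background per-(sample, gene) event
probability is 0.02, distributed over the six categories with mRNA
upregulation and amplification dominating (0.55 / 0.15 of events), which
mirrors the category mix seen in breast tumors. RBP and BC genes carry a
2× rate multiplier over non-cancer genes so that set-level burden
comparisons have signal. Planted progressors multiply their amplification
and mRNA-up rates by `progressor_boost` (default 10); suppressors
mirror this on deep deletion and mRNA-down. Subtype and stage labels are
drawn from configurable proportions, uniform by default (the real cohorts'
proportions are a property of the data, not of the method).

**IHC.** One normal level and 12 tumor samples per RBP on the 0–3 ordinal
scale. Background genes keep their level with probability 0.8 and move ±1
otherwise. Planted progressors shift each tumor sample by +2/+3 (0.6/0.4)
and draw their normal level from {not detected, low}; suppressors mirror
this from {medium, high}. Restricting the planted normal levels is
deliberate: a +2 shift from "medium" would clamp at "high" and be
indistinguishable from a moderate change, so without the restriction the
planted guarantee (a ≥ 2-level consensus shift) could not hold on the
bounded scale.

**Dependency screens.** Two matrices (30 cell lines each, separate line
panels as in real RNAi vs CRISPR screens). Background gene scores are
Normal(0, 0.2); planted progressors *and* suppressors score
Normal(−1.5, 0.2) in both screens. The planted mean and the −0.5 call
threshold give a per-gene flag probability that is effectively 1 with ≥ 20
lines (the standard error of the mean is 0.2/√30 ≈ 0.037). Suppressors are
planted as essential too so that the mirrored suppression-direction
analysis is recoverable end to end.

**Networks.** The PPI edge list guarantees every planted gene one
experimental-channel edge with score in [0.9, 0.99] to a random BC
protein (again, suppressors included, for the mirrored direction), plus
400 background edges with mixed channels and scores Uniform(0.4, 0.95).
The functional network is Erdős–Rényi over the 280-gene universe at edge
probability 0.05 with the planted 12-clique superimposed; the complex
catalog names that clique (`SPLICEOSOME_PLANTED`) alongside five random
decoy complexes.

**Determinism.** Each output table draws from its own
`numpy.random.default_rng([seed, stream_label])` stream, so adding a table
never perturbs another and a fixed config is byte-reproducible.

**What the simulation does not emulate** — and hence what passing tests do
not show about real data: mutational signatures and copy-number
segmentation (events are independent Bernoullis), correlated alterations
across genes or samples, batch effects, antibody variability in IHC,
off-target structure in screens, and the scale-free degree structure of
real interactomes. Recovery results demonstrate the pipeline's correctness
and its behavior at the planted effect sizes, not database-level
reproduction of the original candidate lists, which depend on pinned
external database versions.

## Analytical conventions

* **Event counting.** A gene–sample pair altered in several categories
  contributes one event per category; totals are event counts, not
  altered-patient counts. Mutations and fusions count toward both the
  progression and suppression profiles, since they occur in both kinds of
  genes.
* **Burden normalization.** Per patient: events in the gene set ÷ set
  size. Per subtype/stage: events in the group ÷ patients in the group.
* **First quartile.** Genes with event counts ≥ the 75th percentile of
  the count distribution, computed with linear interpolation between order
  statistics; boundary ties are included, so the selection is
  deterministic and has at least ⌈N/4⌉ members even under heavy ties.
  Counts, not patient-corrected frequencies, feed the percentile.
* **Mann–Whitney U.** U counts (x > y) pairs plus half-ties. The exact
  two-sided p (by the null permutation distribution) is used for tie-free
  samples with n₁, n₂ ≤ 8; otherwise the normal approximation with tie
  correction and continuity correction. The statistic is delegated to
  `scipy.stats.mannwhitneyu`; the test suite verifies the exact branch
  against an independent brute-force enumeration over all C(n₁+n₂, n₁)
  labelings. A fully tied comparison has an undefined standardized
  statistic and reports p = 1.
* **IHC consensus.** Modal tumor level; tied modes resolve to the *higher*
  level. The consensus this replaces was manual, specified only as
  frequency-based; a deterministic rule is required, and the higher-level
  tie-break is applied symmetrically to every gene, so it cannot
  selectively favor one shift class on balanced data. "Twofold variation"
  is read as a shift of ≥ 2 ordinal levels, the natural contrast to the
  one-level "moderate" change. Genes missing either tissue are excluded
  and reported.
* **PPI filter.** Inclusive threshold (score ≥ 0.9), matching the common
  usage of the highest-confidence preset; an interaction passes if any
  allowed channel (experimental, database) meets the score. Genes in both
  the RBP and BC sets sit on both sides of the bipartite network and are
  reported as dual members. Hub ties break lexicographically.
* **Essentiality.** Despite the sign ambiguity in prose descriptions of
  dependency scores, essential means *mean score ≤ −0.5* (inclusive):
  depleting directions are negative and every published essential example
  has a negative mean. The gene-level call uses the mean across lines.
* **Criterion 2 definition.** Membership in the filtered
  (experimental + database, ≥ 0.9) bipartite network, not the
  experimental-only subnetwork used for visualization.
* **Suppression direction.** Not enumerated in the source procedure; it is
  implemented as the exact mirror: suppression alteration profile, the
  same PPI criterion, IHC shift ≤ −1, the same essentiality criterion.
* **Near-miss set.** Strictly c1 ∧ c2 ∧ c3 ∧ ¬c4.
* **MCODE.** Vertex weight = k × density of the highest k-core of the
  closed neighborhood (k-cores computed via core numbers; density
  2|E|/(|V|(|V|−1))). Seeds are processed in descending weight, ties
  lexicographic; expansion admits unvisited neighbors with weight ≥
  seed_weight × (1 − node score cutoff); every admitted vertex is marked
  visited, making complexes vertex-disjoint (this also applies to
  fluff-added members, a deliberate simplification that preserves the
  disjointness invariant). Haircut removes members with a single
  intra-complex connection. Defaults follow the reference "level-3"
  parameter set: cutoff 0.1, fluff 0, no haircut. Edge weights are carried
  for reporting only; the algorithm is topological. Complex score =
  density × size; complexes need ≥ 2 members.
* **Disease network.** One-hop induced subgraph around the prioritized
  seeds, restricted to RBPs ∪ driver-catalog genes ∪ seeds. The one-hop
  reading is the reproducible interpretation of a disease-gene network
  query around five seeds.
* **Catalog annotation.** Best entry by matched-member count; ties break
  by coverage (matched ÷ complex size — constant across ties, so
  effectively lexicographic by name). Coverage is reported against the
  complex, not the catalog entry, because the question is how much of the
  *prediction* the catalog explains.
* **Gene identity for deduplication.** Stable id when present, otherwise
  case-normalized symbol; two entries sharing either key collapse onto the
  first seen. Both directions are needed in practice (two stable ids can
  resolve to one current symbol after reannotation).

## Problem sizes

The default configuration (994 patients × 280 genes, 30 cell lines × 200
genes per screen, a 280-node functional network) runs the full pipeline in
well under a second, so the recovery analyses use 20 independent seeds and
the small-graph oracle sweeps sample 1000 graphs; these sizes give stable
averages while keeping any run comfortably interactive.

## Known limitations

* The IHC tie-break and the ordinal reading of "twofold variation" are
  conventions; a different manual consensus could classify borderline
  genes differently.
* The driver-catalog cross-tabulation assigns each gene to a single
  (type, role) cell using the queried type first, then the gene's first
  remaining entry; genes with heterogeneous multi-type roles are therefore
  summarized, not enumerated.
* The quartile criterion is computed on raw event counts; cohorts of very
  different sizes should be compared on corrected burdens instead.
* MCODE here is the unweighted published algorithm; confidence-weighted
  variants could behave differently on dense noisy networks.
* Planted-recovery guarantees hold at the default effect sizes
  (boost ×10, essential mean −1.5, 12-clique over p = 0.05 noise); weaker
  effects degrade gracefully but are not covered by the acceptance
  checks.
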