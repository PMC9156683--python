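# Methods

This note records the models, conventions and numerical choices behind
`biogeofit`, in the order data flows through the package.

## Trees

Trees are rooted, leaf-labelled and may be polytomous. Polytomies are
treated as **hard** throughout: a multifurcation is scored exactly as
given, with no credit for hypothetical resolutions. This matches how
published consensus topologies are used in congruence studies, and it
is what makes tree resolution a meaningful covariate (an unresolved
tree pays for its polytomies in parsimony length). Branch lengths are
parsed and carried but ignored by every congruence metric; node ages in
Ma are used only by the simulator and the stratigraphic metrics.

Shape covariates: the proportion of resolved nodes is
(internal nodes excluding the root)/(n − 2), which is exactly 1 for a
fully bifurcating rooted tree and 0 for a star — the denominator only
normalises correctly when the root is excluded from the count, so that
is the convention used and recorded in output (`res_excludes_root`).
Colless imbalance is summed |L − R| over strictly bifurcating internal
nodes, normalised by (n−1)(n−2)/2; the classical index has no polytomy
extension, so polytomous nodes contribute zero and the convention is
again recorded rather than silently assumed.

## Region coding

Occurrence records arrive at mixed spatial scales ("California",
"U.S.A.", "North America"). Every recorded area is expanded to the
finest-scale areas beneath it in a containment forest; an area with no
containment entry is its own finest-scale area. Taxa are scored 1/0 in
each finest-scale area, then two merge rules simplify the matrix:

1. regions with identical presence/absence columns are combined,
   closest geographic pair first, until every region carries unique
   grouping information;
2. regions occupied by exactly one taxon (autapomorphic region
   characters, phylogenetically uninformative) are absorbed into their
   geographically closest neighbour by element-wise OR.

Rule 2 can create new duplicates or new autapomorphies, so the two
rules iterate to a fixpoint; termination is guaranteed because every
merge strictly reduces the region count. "Closest" requires geography
the source data rarely formalise, so the package takes an explicit
distance table (or adjacency with unit distances); merged regions
inherit the **minimum** distance over constituents (single linkage),
which keeps the closest-neighbour relation order-independent, and ties
break lexicographically on region ids for determinism. Identical
columns that are not adjacent are still merged once adjacent merges are
exhausted (logged as `nonadjacent-duplicate`), since the end condition
is uniqueness of every region's taxon set. Every merge is written to an
audit log. A matrix that collapses to one region, or retains no
variable column, is flagged untestable and every downstream test
refuses it.

Note that rule 1 conserves each taxon's covered area exactly (identical
columns mean the same taxa occupied both regions), while rule 2
necessarily coarsens coverage: the OR credits the absorbed region's
taxon with the neighbour's area and vice versa. This is the price of
removing uninformative characters and is visible in the audit log.

## Parsimony engine

Character lengths use Hartigan's generalisation of the Fitch downpass,
exact for multifurcations: at each internal node the optimal state set
is the set of states present in a maximal number of children's optimal
sets, and the node contributes (children − that maximum) changes. The
implementation is vectorised over characters, so all permuted
replicates of a matrix are scored in a single postorder sweep; the test
suite proves equivalence against brute-force minimisation over all
internal labelings on every rooted topology with up to 6 leaves
(2,752 multifurcating topologies at n = 6) and on random 7–8 leaf
trees. Bounds per binary character are MINL = (observed states − 1)
and MAXL = min(#0, #1) (the star-tree length). Missing states cannot
occur for region characters (every taxon occupies somewhere) and are
rejected rather than imputed.

## bHER and its permutation null

bHER = 1 − (L − MINL)/(MEANNS − MINL), with MEANNS the mean ensemble
length of the matrix after random reassignment of whole rows to taxa on
the fixed topology. Rows — not column entries — are permuted so the
multiset of observed range patterns is preserved exactly. MINL and MAXL
are invariant under row permutation, so CI and RI are both strictly
decreasing functions of L alone, and a single tail count
#{L_perm ≤ L_obs} serves both: the package reports that identity as an
assertable diagnostic. Conventions:

* ties count toward the tail ("as short or shorter");
* sampled runs use the add-one estimator p = (r + 1)/(n_perm + 1), so
  p is never zero; default n_perm = 10,000 and a seed is mandatory;
* when the distinct row arrangements number ≤ 5,000 (and n ≤ 8 so the
  n! scan is cheap) the full permutation group is enumerated instead,
  and MEANNS and p are exact — the exact p is the plain tail fraction,
  with no pseudo-count;
* bHER may be negative (fit worse than the random mean) and is
  reported unclamped.

## Compatibility and MCPTP

Two complete binary characters are compatible iff some tree fits both
without homoplasy, which is exactly the four-gamete condition (proved
against exhaustive topology enumeration in the tests). The MCPTP test
counts incompatible pairs and compares against matrices whose columns
are permuted **independently** across taxa. The choice of null is
forced by logic rather than convention: permuting whole rows relabels
taxa simultaneously in every character and provably cannot change the
incompatibility count (asserted as a test), so a row-permutation null
would have zero power. The test is one-sided toward few
incompatibilities (more hierarchical structure), with the same add-one
estimator and mandatory seed.

## Stratigraphic congruence

First occurrences are resolved to stages; an interval-valued first
occurrence takes the *oldest* stage of its interval (first fossils lag
true origins, so the oldest consistent reading is conservative), and a
stage maps to a numeric age at its base (older bound) by default, with
midpoint/top selectable and the choice recorded in output. Leaves
without a fossil record are pruned before computation, gated by a
configurable minimum coverage (default 50% of leaves). Each internal
node is aged at its oldest descendant FAD; MIG is the sum over edges of
(parent age − child age). Gmin = oldest − youngest FAD and
Gmax = Σ(oldest − FAD_i) are the best and worst MIG any topology could
achieve (both attained, as the tests verify by exhaustive topology
enumeration). SCI assesses every non-root internal node against the
union of its parent's other children (so polytomies are handled
naturally); both root children are assessed against each other, equal
ages count as consistent, and the convention is switchable. GER* is
implemented as the mid-rank position of the observed MIG in the
FAD-permutation distribution, 1 − (#below + ½·#ties)/N, exact by full
enumeration for ≤ 6 leaves and sampled (seeded) above; the formula is
emitted in result metadata. Mid-rank tie handling matters: on a
pectinate tree half of all FAD assignments achieve the worst-case MIG,
so the "worst" GER* is 0.25 rather than 0. Last occurrences are stored
but enter none of the four indices.

## Paired statistics

Wilcoxon signed-rank conventions follow the R idiom (`wilcox.test` with
`rcompanion`'s helpers): zero differences dropped before ranking
(n_effective ≤ n), mid-ranks for tied |d|, W = positive-rank sum,
Z = (W − n(n+1)/4)/σ with the tie-corrected variance and **no**
continuity correction, rc = 2W/(n(n+1)/2) − 1. These conventions are
pinned by three published (W, n) → (Z, rc) triplets reproduced to the
printed precision in the tests. Exact two-sided p-values are computed
by enumerating all 2ⁿ sign assignments for n ≤ 12 (threshold
configurable); larger samples use the normal approximation. The sign
test is the exact two-sided binomial at ½ with ties dropped (a
`majority` tie policy exists purely for replication experiments).
Spearman correlation and OLS residuals are delegated to scipy and
statsmodels respectively.

## Synthetic studies

The generator emulates the statistical structure a paired congruence
study assumes, with defaults chosen once to resemble a moderately sized
literature clade:

* **true tree** — pure-birth (Yule) conditioned on n = 16 tips at
  birth rate 0.1/Ma (root ages ~20–40 Ma), simulated forward with an
  extra Exp(nλ) wait after the last split so E[root age] =
  Σ_{k=2..n} 1/(kλ); tip labels are assigned in random order, because
  lineage-creation order is topologically informative and must not
  leak into the labels (two "independent" trees would otherwise share
  label structure — this bias is real and was caught by the null
  calibration);
* **ranges** — a dispersal–extirpation process on a ring of 8
  unit-spaced regions: dispersal (0.15/Ma per lineage) adds one region
  adjacent to the current range, extirpation (0.05/Ma per occupied
  region) removes one but never the last. Adjacency-limited dispersal
  gives the closest-neighbour merge rules realistic structure;
* **estimates** — the molecular tree is the truth degraded by 1 NNI
  move; the morphological tree by 6 NNI moves plus a 15% independent
  chance of collapsing each internal edge, reflecting the resolution
  gap between published morphological and molecular topologies. The
  two knobs are independent so resolution-matched designs can be
  simulated;
* **fossils** — Poisson preservation at 0.1/Ma along each root-to-tip
  path; a tip's FAD is its oldest event, snapped to 5-Ma synthetic
  stages; roughly half the tips record a fossil, straddling the 50%
  coverage gate.

What the generator does **not** emulate: real geographic barriers and
area shapes, cladogenetic range inheritance (vicariance-explicit
DEC-style models), correlated preservation across lineages, and
character-data estimation error (degradation is purely topological).
Passing tests therefore demonstrate the statistical machinery —
calibration of the permutation tests and recoverability of a known
accuracy contrast — not the realism of any particular empirical
setting.

## Validation experiments

Two built-in experiments (also run by `scripts/acceptance.py`):

* **null calibration** — 50 clades whose matrices are generated on one
  tree but tested against an independently simulated tree
  (1,000 permutations each): mean bHER is ~0 and the permutation test
  approximately holds its 5% size. At this problem size the null
  length distribution is discrete (10–16 atoms), and with ties counted
  into the tail the realised false-positive rate fluctuates between
  streams (~0.015–0.08 around a pooled ~0.05); the test errs
  conservative, never anticonservative.
* **recovery** — 40 clades with the default accuracy contrast: the
  paired Wilcoxon on bHER recovers the molecular advantage
  (rc ≈ 0.5–0.9 across seeds, p ≪ 0.05).

Generation and permutation randomness use separate per-clade
substreams derived from the master seed, so the simulated clades do
not depend on the permutation budget and every result is reproducible
from the seed alone. The experiment sizes (50 and 40 clades, 1,000
permutations) keep both experiments to well under a minute while
leaving the paired test clearly powered.

## Known limitations

* Compatibility and parsimony handle complete binary characters only —
  all a region matrix needs, but not multistate or missing data.
* The original column-permutation homoplasy excess ratio (with tree
  re-search) is deliberately out of scope; the row-permutation,
  fixed-topology variant is the statistic implemented.
* Region merging defers the meaning of "closest" to the supplied
  distance table; centroid vs shared-border operationalisations will
  differ and the audit log is the reconciliation tool.
* Time-scaling of trees, Signor–Lipps corrections and stage-binning
  sensitivity analyses are not implemented.
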