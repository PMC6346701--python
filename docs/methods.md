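# Methods

This note records the modeling assumptions, numerical choices and known
limitations behind `cdmnet`, in the spirit of a model-documentation page.

## Problem setting

The package analyzes a multilayer disease network: the same set of diseases
connected by several independent similarity relations (interactome-based,
symptom-based, and one layer per ontology). A *conserved disease module*
(CDM) is a disease subset whose induced subgraph is heavy in every layer
simultaneously. The unit of computation is the third-order tensor
`a[i, j, k]` — the weight of disease pair (i, j) in layer k — over the
diseases common to all layers, in fixed lexicographic order.

## Layer construction

**Interactome separation.** Disease gene sets are mapped onto an unweighted
protein-interaction network (genes absent from the network are dropped and
counted). Distances are unweighted shortest-path hop counts computed by
breadth-first search. The internal distance of a set is the mean over its
genes of the distance to the nearest *other* member; the cross distance
pools, over all genes of both sets, the distance to the nearest gene of the
other set. Genes with no finite path are excluded from the means rather than
imputed — separation is computed on the observed, incomplete interactome —
and the exclusion count is logged. A singleton gene set has no internal
distance; it contributes 0 by default (configurable) so single-gene diseases
are not discarded. Three separation-to-weight transforms are provided, all
monotonically decreasing into [0, 1]:

* `logistic` (default): `1/(1 + exp(s))`, smooth, 0.5 at s = 0;
* `neg`: `min(1, max(0, −s))`, nonzero only for overlapping modules — the
  right choice when only clearly related pairs should receive edges;
* `minmax`: min–max rescaling of −s across the computed pairs.

The transform is an artifact decision, not a literature constant; it is
therefore explicit configuration.

**Ontology similarity.** The Wang construction on a typed DAG. Contribution
factors default to `is_a` = 0.8 and `part_of` = 0.6, the usual calibration
for this similarity family; any value in (0, 1) per relation type is
accepted. Contribution maps are computed by dynamic programming in
topological order from the anchor toward the roots, which equals the maximum
decayed path product over all paths (verified against exhaustive path
enumeration in tests). Terms in different DAG components share no ancestors
and get similarity exactly 0; the layer builder computes similarities on the
union DAG, so multiple ontology branches need no special casing. Diseases
whose annotations contain no known term are dropped with a log entry.

**Harmonization.** Layers arrive on heterogeneous scales, so tensor assembly
rescales each layer by its maximum weight by default (`none` available).
Dense similarity layers should additionally be filtered to high-confidence
edges (`filter_edges_by_weight`) before assembly; similarity measures with a
high baseline otherwise let the whole network masquerade as one module.
Filter cutoffs are per-layer configuration with default 0.3 on the layer's
native scale.

## Module extraction

The objective `H_A(x, y) = ½ Σ a_ijk x_i x_j y_k` is maximized over
nonnegative x (disease membership) and y (layer membership) under p-norm
constraints `‖x‖_p = ‖y‖_q = 1`, by alternating multiplicative updates

```
x ← (A ×₂ x ×₃ y)^(1/(p−1)) , renormalize;   y ← (½ x'A x)^(1/(q−1)) , renormalize.
```

Numerical choices:

* **Norm exponents, p = 1.5 and q = 2.** With p = 2 the update is the
  classical tensor power iteration, but on unstructured random background
  the resulting x is diffuse (support spanning half the network), and no
  prefix-based discretization can then separate signal from noise — in a
  uniformly random weighted graph the induced weight per member *grows* with
  prefix size, so diffuse solutions sprawl. Sub-quadratic p raises the
  update exponent `1/(p−1)` above 1 and acts as a soft winner-take-all: at
  p = 1.5 the solution support collapses exactly onto a planted module
  (measured: support 8 of 200 nodes) while pure background concentrates on a
  single heavy edge or clique-let far below the acceptance thresholds.
  Exponents at or below ~1.2 destabilize the ascent and are not recommended.
  q stays 2: with only a handful of layers, y should remain dense — a CDM
  must live in all layers.
* **Ascent safeguard.** For nonnegative tensors the update empirically
  increases H_A, but the layer-combined adjacency can be indefinite and a
  step can overshoot. Each iteration evaluates H_A and stops at the previous
  iterate if a decrease beyond tolerance (1e-9) would occur, so the reported
  objective trace is non-decreasing by construction. Convergence is declared
  when |ΔH_A| < 1e-9; the iteration cap is 200.
* **Initialization and restarts.** Multiplicative updates preserve zeros, so
  starts are strictly positive: uniform plus seeded jitter (5%). The best of
  10 seeded restarts is kept. All randomness flows from one integer seed;
  identical seeds give identical extractions.
* **Discretization.** Diseases are ranked by x (ties broken by node id).
  Only the solver's support (x ≥ 1% of max x) is eligible. Prefixes of size
  5..30 are scored by their induced binary weight; the prefix with maximal
  weight per member is the candidate, accepted only if its induced weight
  reaches 0.3 *in every layer*. Three deliberate choices here:
  * the density peak is located *before* thresholding — a sprawling
    low-density set can accumulate 0.3 from many tiny edges but is never the
    weight-per-member maximizer;
  * the weight threshold applies per layer, because a conserved module must
    be heavy in each of its appearances; a cross-layer total lets one strong
    layer subsidize absence in another;
  * the size cap (default 30) bounds the search space. The underlying
    combinatorial problem is fixed-size heaviest-subgraph search, and
    realistic disease modules are tens of diseases at most; without the cap,
    sets of half the network can cross any absolute weight threshold on
    background noise alone.
* **Multiplicity.** After a module is reported, its intra-module entries are
  zeroed in every layer and its members are excluded from later rounds, so
  modules are pairwise disjoint. Extraction stops when discretization
  returns nothing or after 20 modules.
* **Oracle.** `brute_force_heaviest` enumerates all fixed-size subsets
  (guarded to n ≤ 15) with lexicographic tie-breaking; it is the independent
  reference the solver is tested against.

## Significance

* **Degree-preserving rewiring** performs seeded double-edge swaps
  (10 attempts per edge by default); each new edge inherits the weight of
  the removed edge it replaces, so both the degree sequence and the weight
  multiset are conserved. Graphs with no valid swap (stars) are returned
  unchanged with a warning. Caveat: when a network's degree sequence is
  dominated by one extreme heavy clique, rewired heavy weights partially
  re-concentrate on those hub nodes; the null is most meaningful when no
  single structure dominates the degrees, as in the dense empirical
  similarity networks this emulates.
* **Permutation p-value** draws same-size node sets uniformly without
  replacement from a reference network and compares induced weight sums,
  with the add-one estimator `(1 + r)/(1 + N)` so p is never 0 (the floor at
  10,000 draws is 1/10,001 ≈ 1e-4). Calibration: for modules drawn from the
  null itself the p-values are uniform up to the discrete grid, verified by
  a Kolmogorov–Smirnov check. The reference network should be dense enough
  that same-size weight sums rarely tie at zero; on a near-empty network the
  p-value distribution is degenerate by construction.

## Annotation

Class labeling follows a strict majority rule: a module takes a class only
if *more than* the threshold fraction (default 0.6) of members carry it,
otherwise it is `mixed`; members outside the top class are reported as the
module's candidate novel relationships. Diseases missing from the class map
count as their own singleton classes rather than erroring. Drug scores use
exact rational arithmetic (`fractions.Fraction`), so `score × N = n_T` holds
identically; candidate selection at the 0.6 boundary is *inclusive* (a drug
covering exactly 60% qualifies), deliberately different from the strict
classification rule. Only therapeutic ("T") associations enter Jaccard and
Drug_score computations; other markers are carried but ignored.

## Synthetic data

The generators emulate the statistical shape of the real input stack at desk
scale with known planted truth:

* **Multilayer tensors**: 200 diseases × 4 layers by default (the empirical
  study shape at roughly half size). Background edges appear independently
  per layer with density 0.01 and truncated-exponential weights (mean 0.01,
  capped at 1 — nonnegative and right-skewed); planted modules are fully
  connected blocks with Normal(0.6, 0.1) weights truncated positive in their
  designated layers. The background is deliberately thin enough that the
  heaviest background-only small subset stays well below the 0.3 threshold
  (extreme-value estimate ~0.1–0.2 at n = 200), mirroring data whose
  randomized layers contain no conserved module; the planted/background
  contrast (60×) is far above the regime where recovery becomes marginal.
* **Ontology worlds**: random typed DAGs grown as a forest of six branches
  (new terms attach to 1–2 parents within their branch; relation types
  sampled 70/30 is_a/part_of), mirroring the disjoint top-level branches of
  real ontologies so random term sets have realistically low baseline
  similarity. Disease groups share per-group term cores from a single
  branch.
* **Interactome worlds**: preferential-attachment (Barabási–Albert, m = 3)
  gene networks. Related diseases draw genes from one shared, deliberately
  tight neighborhood (1.5× the per-disease gene count), so their gene sets
  interleave and separation is clearly negative; unrelated diseases scatter
  genes uniformly. Note that separation subtracts internal compactness, so
  merely *nearby* gene sets do not score negative — overlap is required,
  which is what the tight shared pool provides.
* **Drug tables**: per module, drugs link therapeutically to each member
  independently with probability `coverage`, so the expected Drug_score
  equals the coverage; a sprinkling of non-therapeutic rows is included.

What the synthetic data does *not* emulate: real ontology term semantics,
literature-derived symptom co-occurrence structure, degree-correlated
disease-gene annotation biases, and the curation biases of real drug
association databases. Passing the recovery and null tests therefore shows
the machinery is correct and well calibrated under the stated generative
assumptions, not that real data meet those assumptions.

## Degenerate inputs and edge cases

All-zero tensors are refused by the solver; all-zero layers are refused by
max-normalization. Empty term sets, empty modules and oversized permutation
modules raise validation errors. Diseases with unmappable genes or terms are
dropped with log entries, never silently. Ties are broken lexicographically
on identifiers everywhere a ranking is materialized, so outputs are
deterministic under fixed seeds.

## Known limitations

* The continuous relaxation carries no optimality guarantee; restarts reduce
  but do not eliminate the chance of missing the heaviest subset. The
  brute-force oracle bounds this empirically at small n only.
* The per-layer weight threshold is an absolute number on the normalized
  scale; layers with very different densities may warrant per-layer
  thresholds, which the configuration allows but defaults do not set.
* Masking both endpoints forbids overlapping modules; biologically,
  overlapping disease modules exist and would require a different
  multiplicity scheme.
* The rewiring null conserves the weight multiset but not weight–topology
  correlations, with the hub-reconcentration caveat noted above.

## Problem sizes in the test and acceptance runs

Unit and property tests run on 10–60-node instances; recovery and null
checks run 20 extractions on 200 × 200 × 4 tensors and 50 rewired-null
repetitions of the same shape; permutation calibration uses 200 modules of
size 6 at 500 draws each on a 60-node reference network. These sizes were
chosen to exercise the asymptotic behavior of each statistic while keeping
the full suite around a minute of compute.
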