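# Methods

## Model and assumptions

Throughout, X is a set of n taxa and S = {Y₁, …, Y_k} a collection of
subsets of X (member sets may be empty or repeat; only the *induced*
c-tuples — size-c subsets contained in some Yᵢ — matter, and those are
kept duplicate-free). Trees are unrooted, binary, leaf-labeled; a
topology is identified with its set of non-trivial splits. Decisiveness
means: for every tree T on X, the restrictions T|Yᵢ characterize T
uniquely among all trees on X.

Two decision procedures are implemented:

* **Four-way partition checker** (`decisiveness`): S is decisive iff
  every partition of X into four non-empty blocks is covered by an
  induced quadruple with one member per block. The checker iterates
  partitions in a canonical order (restricted-growth strings with
  exactly four classes, so each unordered partition appears once and
  block order is by smallest element) and short-circuits at the first
  uncovered partition, which is returned as a deterministic witness.
  Complexity is exponential in n — inherent, since the problem is
  coNP-complete — so this checker is meant for small n and as the inner
  loop of exhaustive searches.
* **Coloring algorithm** (`traceability`): decides fixing taxon
  c-traceability in polynomial time. Induced tuples start white, cross
  tuples gray; a FIFO queue holds tuples whitened so far (initially all
  induced tuples in colex order). For each dequeued tuple C and each
  taxon x ∉ C, the c+1 tuples within C ∪ {x} form a complete clique of
  the (c−1)-overlap graph; if exactly one is gray, the clique taxon it
  lacks is its fixing taxon, and it is whitened, logged and enqueued.
  If zero are gray nothing changes; if two or more, no fixing taxon
  exists in that clique. The run returns a certificate (ordered log of
  (tuple, fixing taxon) steps) that can be replayed against the initial
  coloring; `TraceCertificate.replay` checks every step independently
  of the algorithm that produced it.

The final white/gray coloring is independent of processing order (the
whitening condition is monotone in the white set); the suite asserts
this by shuffling the queue and taxon scan with ten seeds rather than
assuming it. When several (C, x) pairs could whiten the same tuple, the
recorded fixing taxon is the first found in canonical scan order, so
certificates are deterministic for a given input.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| c | 4 | tuple size; 4 is the unrooted-tree case, 3 the rooted one |
| exhaustive guard | n ≤ 6 | subset sweeps over C(n,4) quadruples refuse larger n unless forced (C(15,·) ≈ 3·10⁴ subsets at n = 6; n = 7 already has 2³⁵) |
| oracle guard | n ≤ 6 (trees ≤ 7 leaves) | tree enumeration grows as (2m−5)!! |
| n_sim | 10 000 | sampled draws per (n, k) simulation cell |
| seed | none | root seed; each cell derives a substream from (seed, n, k), so cells are independently reproducible |

Rooted decisiveness is a count: it holds iff all C(n,3) triples are
induced. Fixing taxon 3-traceability does *not* imply it (three of the
four triples on four taxa are 3-traceable but not rooted-decisive), and
the command line prints a warning when routing `--rooted` queries.

## Exhaustive searches and the bitmask kernel

The subset sweeps (minimal decisive size, minimal traceable size,
maximal non-decisive size, maximal decisive-not-traceable size) and the
simulation share a private kernel that represents a quadruple family as
an integer bitmask over the C(n,4) quadruples in colex order. Per-
partition cover masks are precomputed once, so the partition check is a
sequence of AND tests; traceability is computed as a fixpoint over the
(c+1)-cliques — whiten any clique's unique gray vertex until nothing
changes — which coincides with the queue algorithm's outcome by the
order-independence property. Searches exploit monotonicity of both
properties under adding quadruples: minima are sought size-ascending,
maxima size-descending with early exit at the first admissible size.
At n = 6 the full 2¹⁵ classification takes well under a second.

## Constructions

* `star_construction(U, c, center)`: all C(n−1, c−1) tuples through one
  taxon; the center fixes every cross tuple, so the family is traceable
  — and this size is the exact minimum for traceability.
* `algorithm2(n)`: starts from the 9-quadruple family on {1..6} and,
  for each new taxon m = 7..n, adds every quadruple {1, a, b, m}. Taxon 1
  fixes everything through m, keeping the family decisive, while its
  size C(n−1,3) − 1 stays one below the traceability minimum.
* `algorithm3(n)`: starts from the 10 quadruples on {1..6} whose five
  missing quadruples form a 5-cycle in the overlap graph (each cross
  quadruple has two gray neighbors, hence no fixing taxon), and for each
  new taxon m adds all quadruples through m except {2,5,6,m}, {3,4,6,m},
  {4,5,6,m}. Size C(n,4) − 3n + 13; decisive, not traceable, and
  maximal: adding any single cross quadruple tips it into traceability.
  The 6-taxon seed is not spelled out anywhere as a list; it is pinned
  here by an exhaustive derivation (all 5-subsets of the 15 quadruples
  whose complement is decisive, non-traceable and maximal) that runs in
  the test suite, and frozen as `ALG3_BASE_CROSS`.

## Simulation study

`run_cell(n, k, …)` classifies families of k distinct quadruples by both
procedures and tabulates TP (traceable ∧ decisive), FN (decisive only)
and TN (non-decisive); (traceable ∧ ¬decisive) cannot occur and is
structurally absent. The admissible k range is
[⌈C(n,3)/4⌉ + 2, C(n,4) − n + 3]: below it no family is decisive, above
it all are traceable. At n = 6 every cell is enumerated exhaustively
(≤ 6435 subsets), so the whole contingency table is deterministic; for
n ≥ 7 cells are sampled — each draw shuffles the canonical quadruple
list with the cell's substream and takes a k-prefix, and drawn families
may repeat across draws (a with-replacement estimator over the family
space). Sampled estimates therefore carry Monte-Carlo error and are
checked for consistency, not equality.

Summaries report medians and interquartile ranges over k cells. TPR and
PREV are summarized over cells at or above the smallest k with a
decisive family (below it TPR is undefined and PREV identically zero);
NPV is defined on every admissible cell and is summarized over all of
them — the convention under which the published six-taxon row
(TPR 0.97 [0.71,1], NPV 1 [0.97,1], PREV 0.62 [0.36,0.83]) reproduces
exactly; restricting NPV like the others would give 0.98 [0.95,1].
Undefined metrics (zero denominators) are excluded; the even-count
median is the midpoint, and the IQR interpolation rule is configurable
(`quantile_method`, numpy's percentile methods) since no single
convention is canonical. k′ records, for decisive non-traceable
families, the input size plus the number of cross quadruples the
coloring still managed to resolve before stalling.

What the simulation emulates — and does not: it samples quadruple
families uniformly, which models taxon-sampling designs where every
4-subset is equally likely to be covered. Real multi-locus datasets
have highly structured coverage (nested, clade-biased, with member sets
much larger than 4), so the reported prevalence and power say nothing
quantitative about any particular empirical study; the implications and
bounds, being theorems, transfer regardless.

## Numerical and edge-case choices

* All counts and bounds are exact integer arithmetic; no floats outside
  the simulation proportions.
* Canonical orders everywhere: labels by universe index (numeric labels
  numerically), tuples and generated collections in colex order, so file
  output and certificates are reproducible byte-for-byte.
* Degenerate inputs: empty member sets are legal and contribute nothing;
  an empty collection on n ≥ c taxa is non-traceable (no white seed) and
  non-decisive for n ≥ 4. Taxa declared in the universe but absent from
  every member set are permitted; any quadruple containing such a taxon
  is cross and unresolvable, so such collections are never decisive for
  n ≥ 4 — permitting them is a deliberate choice, as the theory is
  usually stated with X = ⋃Yᵢ.
* The decisiveness lower bound is implemented as ⌈C(n,3)/4⌉ + 2. A
  frequently quoted tabulation drops the +2 (printing 5, 9, 14, 21, 30
  for n = 6..10); the derivation itself forces two extra duplicated
  triples, and its worked 6-taxon instance is 7, so the +2 form is used
  here and the discrepancy is flagged rather than silently reconciled.
* Newick is a boundary format only: reading goes through dendropy and
  rejects non-binary input (after suppressing a root bifurcation);
  writing reconstructs the nesting from the split set. The internal
  representation is always the split set, which makes topology equality
  and restriction pure set operations.

## Problem sizes in the test suite

The default suite keeps every exhaustive computation at the sizes where
it is exact and fast: full subset sweeps and the complete contingency
grid at n = 6, construction properties for n = 6..9, tree-oracle
equivalence exhaustively at n = 5 and on the 6-taxon fixtures,
tree-count checks up to 7 leaves, and sampled-mode consistency with
5 seeds × 300 draws (the study-scale 10 000 draws per cell is the
library default, not the test setting). Passing tests certify the
implementation on these grounds; they do not certify behavior on
structured empirical coverage patterns, and nothing beyond n = 10 has
been exercised.

## Known limitations

* The decisiveness checker is inherently exponential; beyond n ≈ 12–14
  the partition loop becomes impractical, and no ILP/FPT alternative is
  implemented (out of scope).
* `min_decisive_size_exhaustive` and friends are exact only under the
  n ≤ 6 guard; `force=True` is honest but slow.
* The maximality conjecture for decisive-not-traceable families is
  confirmed exhaustively only at n = 6.
* Sampled simulation rows are Monte-Carlo estimates; published sampled
  values for n ≥ 7 used unrecorded seeds and are reproducible only in
  distribution.
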