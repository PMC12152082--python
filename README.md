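# taxontrace

Supertree studies combine trees inferred for overlapping species sets
Y₁, …, Y_k into one tree on the union X of all taxa. Even when the input
trees are compatible, the supertree need not be unique — unless the
*taxon coverage pattern* itself guarantees it. A collection
S = {Y₁, …, Y_k} is **phylogenetically decisive** ("perfect taxon
sampling") when every compatible choice of input trees admits exactly one
supertree. `taxontrace` is a library and command-line tool for deciding
and exploring this property, aimed at phylogeneticists planning taxon
sampling and at combinatorialists studying the underlying set systems.

## The mathematics in brief

For unrooted binary trees, S is decisive iff it satisfies the
**four-way partition property (4WPP)**: for every partition of X into
four non-empty blocks X₁|X₂|X₃|X₄ there are taxa xᵢ ∈ Xᵢ with
{x₁,x₂,x₃,x₄} ⊆ Y_j for some j. Checking this directly means examining
all S₂(n,4) partitions, and the general decision problem is
coNP-complete.

`taxontrace` therefore also implements a polynomial-time recognizable
subclass. A quadruple C ∉ ⋃ᵢ C(Yᵢ,4) (a *cross quadruple*) has a
**fixing taxon** x ∉ C when all four quadruples (C \ {xᵢ}) ∪ {x} are
induced by S; the five quadruples within C ∪ {x} then force every
supertree to resolve C identically. Resolution iterates: resolved cross
quadruples may supply fixing taxa for others. S is **fixing taxon
traceable (FTT)** when iterated resolution whitens every cross
quadruple. FTT ⇒ decisive, and FTT is decidable in
O(n⁴ · max{k, n²}) time by an iterative coloring of the 3-overlap graph
K₅ⁿ (vertices: all quadruples; edges: pairs sharing three taxa). The
converse fails: a 9-quadruple family on six taxa is decisive with no
fixing taxon anywhere.

Closed-form thresholds bracket both properties (all evaluated exactly by
the `bounds` module): every family with k ≥ C(n,4) − n + 4 quadruples is
FTT and decisive; none with k < ⌈C(n,3)/4⌉ + 2 is decisive; FTT needs
k ≥ C(n−1,3); decisive families with C(n−1,3) − 1 quadruples exist for
every n ≥ 6; and the largest known decisive-but-not-FTT families have
C(n,4) − 3n + 13 quadruples.

## Worked example

The 11-quadruple collection on six taxa from the `fixtures()` map:

```python
import taxontrace as tt

S = tt.fixtures()["ex3.3"]
cross = tt.cross_ctuples(S, 4)
print("cross quadruples:", ", ".join(str(t) for t in cross))
cert = tt.trace(S)
print("traceable:", cert.traceable)
for step in cert.steps:
    print(f"  step {step.step_index}: {step.resolved_tuple} "
          f"resolved by taxon {step.fixing_taxon}")
print("decisive:", tt.is_decisive_unrooted(S).decisive)
```

prints

```
cross quadruples: {1,2,3,4}, {1,3,4,5}, {2,4,5,6}, {3,4,5,6}
traceable: True
  step 1: {2,4,5,6} resolved by taxon 1
  step 2: {3,4,5,6} resolved by taxon 2
  step 3: {1,2,3,4} resolved by taxon 6
  step 4: {1,3,4,5} resolved by taxon 6
decisive: True
```

Four of the fifteen quadruples on six taxa are uncovered; {2,4,5,6} and
{1,2,3,4} have fixing taxa outright, and whitening them lets the
remaining two inherit resolvability — so the collection guarantees a
unique supertree, and the certificate `cert.replay(S)` re-validates every
step. The same verdicts are available from the shell:

```
taxontrace construct fixture --name ex3.3 -o ex33.txt
taxontrace check ex33.txt
taxontrace bounds --n 6
```

the last of which prints the full threshold table for six taxa
(`f_n 13`, `ftt_min 10`, `decisive_lower 7`, `decisive_upper 9`, …).

Other entry points: `tt.decisive_by_definition` (ground truth by
enumerating all unrooted binary trees, n ≤ 6), `tt.count_supertrees`,
the extremal generators `tt.star_construction` / `tt.algorithm2` /
`tt.algorithm3`, and `tt.run_grid` / `tt.summarize` for the
FTT-vs-decisiveness contingency study (`taxontrace simulate` from the
shell, with CSV/JSON/plot output).

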