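# Methods

## The benchmarking problem

A serial-passage experiment that splits every culture in two once per day
and sequences a sample at every step defines its phylogeny by protocol:
after `d` days the samples form a complete binary tree with
`2^d - 1` nodes (255 for `d = 8`), of which `2^(d-1)` are leaves and the
rest are *sampled ancestors*. Naming samples by their split path (founder
`S`; daughters of `X` are `X1`, `X2`) makes ancestry the proper-prefix
relation on names, so the truth is known exactly without any inference.

Phylogenetic methods, however, return trees in which every sequence is a
leaf. An ancestral sequence ends up on a short — often zero-length, for
distance methods sometimes negative — branch adjacent to the internal node
it should occupy. For a single ancestor next to a bifurcation there are
exactly 3 such placements, all with identical likelihood/least-squares
merit; placements at distinct nodes are independent, so a fully occupied
binary tree with `k` internal nodes has `3^k` equally good leaf-only
resolutions, and a node occupied by *two* observed sequences (identical
genomes) has `(2·4-3)!! = 15`, the number of rooted bifurcating trees on 4
leaves. Bipartition-based distances (classic Robinson–Foulds) treat all of
these as far apart, which is why labeled-tree measures are needed.

## Collapsing

`collapse_fixed(tree, cutoff)` contracts every branch with length
`<= cutoff`, merging the child's names into the parent and splicing the
grandchildren in at the child's position; contraction runs to a fixpoint so
chains of short branches become one node with ≥ 3 names. "≤" is taken
literally: cutoff 0.0 removes zero-length *and* negative branches. The root
is never collapsed away (its branch length is meaningless) and the input is
never modified. Collapsing conserves the name multiset, is idempotent at a
fixed cutoff, and leaf count is non-increasing in the cutoff.

`collapse_adaptive(tree, target_leaves)` tries the tree's own distinct
branch lengths in ascending order as cutoffs and keeps the smallest that
leaves at most `target_leaves` leaves (the known leaf count of the
benchmark). Because collapsing everything always terminates in a single
node, any target ≥ 1 is reachable; the defensive warning branch for an
unreachable target cannot trigger in practice. Re-collapsing from the
original tree at each candidate is equivalent to incremental collapsing
(idempotence + monotonicity); the equivalence is asserted in the tests
rather than assumed.

## Similarity measures

Both scores use the *benchmark* tree's count as denominator, so they read
"fraction of the truth recovered"; this is explicit for the clade measure
and adopted for the relation measure by symmetry.

* **Parent–child relations.** Every branch from node `P` to child `C`
  yields all ordered pairs `(p, c)` with `p ∈ names(P)`, `c ∈ names(C)`;
  anonymous ends yield nothing. A true pair also counts as recovered when
  the inferred tree places both names on one collapsed node: co-location is
  the collapsed image of a correctly inferred zero-length branch, and
  penalizing it would punish correct inference. Co-location pairs are kept
  in a separate field of `RelationSet`, never mixed into the branch pairs.
* **Labeled clades.** Each internal node contributes the set of names on
  its strict descendants (names on internal descendants included, its own
  excluded); anonymous internal nodes contribute too. Matching is exact set
  equality with multiset semantics — duplicated identical clades in the
  truth each need their own match. On leaf-labeled trees this reduces to
  the leaf sets below internal nodes, which the tests cross-check against
  an independent dendropy traversal.

A true relation whose names are missing from the inferred tree counts as
unmatched (the benchmark setting compares equal name sets, so this case is
a deliberate, conservative extension).

## Resolution sampling and counting

`resolve_random` rebuilds each occupied internal node as a uniform random
rooted bifurcating topology over its "units" — one new leaf per occupant
name plus the node's (already resolved) child subtrees, kept atomic — via
stepwise insertion: the j-th unit attaches to one of the `2j - 3` branches
of the partial topology (the branch above the local root included). Each
topology arises from exactly one choice sequence, so the draw is uniform
over the `(2n-3)!!` possibilities; occupied nodes are processed in preorder
from a single seeded PCG64 stream, making runs reproducible. New branches
get length `extra_blen` (default 0), so collapsing at cutoff 0.0 inverts
the operation exactly — the round-trip identity the acceptance tests check
100 times over random trees, alongside an exhaustive-enumeration oracle on
trees with ≤ 3 occupied nodes. Occupied nodes must have exactly two
children; other shapes raise an error rather than guessing.

`count_resolutions` is the product over internal nodes of
`rooted_tree_count(m + c)` (`m` occupants, `c` children), which is `3^k`
for fully singly-occupied binary trees.

## Simulator

`simulate_experiment` draws a uniform founder genome, then walks the design
tree giving each child its parent's genome with `K ~ Poisson(mu)`
substitutions at distinct positions (no double hits within a branch;
across branches they can occur, so genome-wide diffs can undercount path
sums by the tiny homoplasy probability, which vanishes as the genome
grows). Mutation is modeled at the consensus level — one genome per node —
because a daily single-colony bottleneck fixes each lineage's consensus;
read-level noise is out of scope.

Defaults (chosen once, as the conditions the package is meant to emulate):

| parameter | default | meaning |
|---|---|---|
| `days`, `split` | 8, 2 | 255 samples, 128 leaves |
| `genome_length` | 100 000 bp | desk-scale; 4.6 Mb for realism |
| `mu` | 3.3 /genome/day | the rate the diff estimator reports on the real data (plate assay predicts ~5.4) |
| `at_to_gc_bias` | 0.9 | probability of an A→C / T→G transversion at a uniform A/T site (mutT spectrum; the exact bias is a free parameter) |
| `seq_success_prob` | 101/255 | partial sequencing success |
| `fixed_count` | off | exactly `round(mu)` mutations/day, an underdispersed variant |

Observation flags are i.i.d. Bernoulli, so the observed count is exactly
Binomial; the founder is *not* forced observed. Workflows that need the
founder (rate estimation) should pass `seq_success_prob=1.0` or an explicit
`observed_names` list containing it. What the simulator does **not**
reproduce: sequencing error, indels, recombination, selection, real
spectra beyond the single bias parameter, and the empirical underdispersion
of per-day mutation counts (available only through the fixed-count mode).
Tests passing on simulated data therefore certify the algorithms under the
stated model, not the behavior of any read-mapping pipeline on real reads.

## Rate estimation

`estimate_rate_per_day` counts genome positions differing from the founder
(skipping, and reporting, sites with non-ACGT symbols) and divides by the
isolate's age in days, defined as its sampling day minus the founder's
(day-1 names have age 1). The mean over non-founder isolates estimates
`mu`; parameter recovery within 3 standard errors across replicate seeds is
part of the acceptance suite at `mu ∈ {1, 3.3, 5}`. The dispersion index
(sample variance / sample mean, `ddof=1`) is reported with a unit-bin
histogram against the Poisson pmf at the observed mean. Note that because
rates are age-normalized averages, their dispersion index is below 1 even
for perfectly Poisson branch counts; the index ≈ 1 reference applies to
unit-age counts.

The plate-assay calculator normalizes mean colony counts by plated volume
(`fold = (mean_mutator/vol_mutator)/(mean_wildtype/vol_wildtype)`); with
the classic counts {9, 6, 15, 5} at 800 µL versus {170, 240, 180, 148} at
100 µL this gives ≈ 169-fold (printed summaries often round differently;
the function reports the exact normalized ratio and does not hard-code a
headline fold). Printed means use round-half-away-from-zero (8.75 → 8.8,
184.5 → 185). `expected_mutations_per_day(rate, minutes, fold)` is
`fold · rate · 1440/minutes`: 1×10⁻³ at 30 min gives ~0.05/day (wild
type); 164 × 10⁻³ at 44 min gives ~5.4/day (hypermutator). At ~5/day on a
4.6 Mb genome that is ~1×10⁻⁶ substitutions/site/day.

## Numerical and I/O choices

Branch lengths are stored exactly as parsed (no clamping of negatives) and
written with 6 significant digits; parse∘write is the identity to printed
precision. Multi-name nodes serialize as `"|"`-joined labels (delimiter
configurable) so collapsed trees pass through standard Newick parsers;
names may not contain the delimiter or Newick metacharacters. Trees are
rooted as written; no rerooting. Tree equality for tests is canonical-form
comparison insensitive to child order. Problem sizes in the test and
acceptance runs (100 kb genomes, 20 replicate seeds, 100 round-trip trees
at days 2–6) keep every check in seconds-to-a-few-minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Scores require rooted trees with a shared naming scheme; unrooted
  handling, quartet/path distances, and support-value-based collapsing are
  out of scope.
* `resolve_random` supports occupied nodes with exactly two children
  (the experiment's design shape), not general polytomies.
* The simulator's homoplasy is unmodeled in the truth tree (branch lengths
  are realized mutation counts, not observable diffs).
* Reproducing published benchmark scores of external read-mapping/SNP
  pipelines requires their raw reads and software and is explicitly not
  attempted.
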