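# sabench — benchmarking phylogenies against known trees with sampled ancestors

Serial-passage evolution experiments — and many disease outbreaks — produce
data sets in which some sequenced samples are the *direct ancestors* of
others. The true phylogeny then has observed sequences on internal nodes,
but standard phylogenetic methods place every sequence at a leaf, typically
hanging ancestral sequences on (near-)zero-length branches next to the node
where they belong. On a rooted bifurcating tree there are exactly **3**
equally good ways to do this per ancestral node, so a known tree with *k*
occupied internal nodes has **3^k** equally good leaf-only resolutions
(3^127 ≈ 3.9×10^60 for a 255-sample, 8-day binary-split experiment). Plain
Robinson–Foulds distance is useless under this ambiguity.

`sabench` implements the machinery needed to benchmark inferred
whole-genome phylogenies against such a known tree:

* **design** — the "ideal tree" implied by the schedule: daily splits in
  two, path-based names (S → S1, S2 → S11, S12, S21, S22, …), plus
  projection onto the subset of samples that were actually sequenced.
* **collapse** — contract every branch with length ≤ a cutoff (0.0 by
  default, negative lengths included) so leaves migrate onto internal
  nodes; or adaptively pick the smallest cutoff from the tree's own branch
  lengths that reaches a target leaf count.
* **compare** — two similarity measures on labeled trees: the fraction of
  correct parent–child relations (ordered name pairs at branch ends) and
  the fraction of correct labeled clades (all names strictly descendant
  from each internal node); plus uniform random resolution and exact
  counting of the ancestral-placement ambiguity.
* **simulate** — a generator emulating the in vitro experiment: Poisson
  mutations per genome per day on each branch, a mutT-hypermutator–style
  A:T→C:G–biased spectrum, and partial sequencing success; emits FASTA, the
  realized true tree, and per-sample metadata.
* **rates** — mutations/genome/day from whole-genome diffs to the founder
  divided by isolate age, dispersion versus the Poisson expectation, and
  Rifampicin plate-assay arithmetic (volume-normalized fold change,
  expected mutations/day = fold × rate/generation × 1440/generation-minutes).

## Worked example

```python
import sabench as sb

design = sb.ExperimentDesign(days=8, split=2)
truth = sb.build_design_tree(design)
print(truth.n_nodes, truth.n_leaves)      # 255 128
print(sb.count_resolutions(truth))        # 3**127 (~3.9e60)

# a phylogenetic method would return one of those resolutions:
inferred = sb.resolve_random(truth, seed=4)          # 255 leaves
collapsed = sb.collapse_fixed(inferred, 0.0).tree    # ancestors restored
print(sb.parent_child_score(collapsed, truth),
      sb.clade_score(collapsed, truth))   # 1.0 1.0

# simulate the experiment and recover the mutation rate
exp = sb.simulate_experiment(
    sb.SimulationConfig(days=8, mu=3.3, seq_success_prob=1.0, seed=7))
print(round(sb.estimate_rate_per_day(exp.sequences, "S").mean_rate, 2))  # 3.15
```

The scores read: every true parent→child branch and every true labeled
clade was recovered after collapsing. The recovered rate (3.15 for this
seed) estimates the simulator's 3.3 mutations/genome/day from the
genome-wide differences between each sample and the founder `S`.

The same pipeline is available from a shell:

```bash
sabench design-tree --days 8 -o ideal.nwk
sabench resolve -i ideal.nwk --seed 4 -o inferred.nwk
sabench compare --inferred inferred.nwk --truth ideal.nwk --collapse-cutoff 0.0
sabench simulate --days 8 --mu 3.3 --seq-success-prob 1.0 --seed 7 -o sim/
sabench rate-estimate --fasta sim/observed.fasta --root S --meta sim/metadata.tsv
```

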