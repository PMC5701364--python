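# Methods

## The model

`pte` treats a multi-sorter card sort as a weighted co-occurrence
network. Each sorter partitions the same n excerpts into piles; pile
labels carry no meaning across sorters, so the only cross-sorter signal
is co-assignment. The similarity score of an excerpt pair is the count
of sorters who co-piled it, and its conceptual distance is the
reciprocal 1/score. The reciprocal is a modelling choice, not a metric:
it maps the ordinal agreement scale (1..m sorters) onto path lengths so
that unanimous pairs are about m times "closer" than single-sorter
pairs. Pairs nobody co-piled have no edge at all; we deliberately avoid
an infinite-distance sentinel and let path algorithms treat such pairs
as unreachable (they contribute nothing to betweenness and make nodes
isolated rather than infinitely far).

Underlying assumptions worth keeping in mind:

- sorts are complete (every sorter places every excerpt exactly once);
  incomplete data is accepted only behind an explicit flag and then
  scores only observed co-assignments;
- sorters are exchangeable — the score is a plain count, so one
  idiosyncratic sorter contributes exactly one unit of similarity per
  pair;
- the instruction "at least two piles, no miscellaneous pile" binds
  the sorters, not the data, so the validator only warns about it.

## Community detection

Themes are communities found by Girvan–Newman edge removal: compute the
weighted edge betweenness of every edge (conceptual distances as path
lengths), delete the single highest edge, recompute, repeat until no
edges remain. Every deletion that splits a connected component records
one dendrogram level, so levels are strictly nested and end in
singletons.

Numerical and determinism choices:

- **Shortest-path ties.** Equal-length alternative paths share the
  count fractionally (standard dependency accumulation). Because
  distances are reciprocals of small integers, exactly-equal
  alternatives (1/2 + 1/2 vs 1) are common and floating-point sums of
  reciprocals are not exact, so two lengths are treated as equal when
  they differ by at most 1e−12 relative to 1 + the length.
- **Removal ties.** Edges within 1e−9 (relative) of the maximum
  betweenness are tied; the lexicographically smallest (min label,
  max label) edge is removed. Identical input therefore always
  produces an identical dendrogram — there is no randomness anywhere
  in the pipeline.
- **Performance.** Betweenness is recomputed only inside the component
  that lost an edge (shortest paths never cross components), using a
  numba-compiled Brandes accumulation over CSR arrays. This keeps a
  full dendrogram on a 40-node, ~400-edge network well under a second.

**Cut selection.** The dendrogram is cut at the level maximising
weighted modularity Q = Σ_c [W_in(c)/W − (S(c)/2W)²], with the *raw
similarity scores* (not distances) as edge strengths; earliest level
wins ties, and an explicit `k` override selects the first level with
exactly k communities. This is the one place the pipeline's weight
semantics split, and it is deliberate: betweenness asks "which tie
spans the largest conceptual gap?", a distance question, while
modularity asks "how much co-sorting agreement is kept inside groups?",
an affinity question. Feeding distances into modularity would reward
cutting exactly the ties most sorters agreed on. Since this choice
changes results, it is surfaced prominently here and in the CLI
defaults.

Size-1 communities in the selected level become *unassigned* excerpts:
items the sorters perceived as similar to different themes, reported
outside any group rather than forced into one. Group ids are assigned
in decreasing size (ties towards the smallest member label).

## Key quotes

Within each theme, the key quote by *closeness* minimises the mean
weighted shortest-path distance to the other members, computed on the
subgraph induced by the group — the quote competes only against its own
cluster, and edges to other themes cannot shorten within-theme paths.
The key quote by *betweenness* maximises unnormalised weighted node
betweenness on the full network, because bridging happens across
themes. Both scopes are configurable (`--closeness-scope`,
`--betweenness-scope`) since the opposite readings are defensible.
Centralities are unnormalised and endpoints are excluded; ties are
reported in full as sets, never broken.

## Preservation

A sorter's pile is preserved when all its excerpts landed in one final
group. Any pile containing an unassigned excerpt is unpreserved by
definition (that excerpt is in no group). By default the diagnostic
counts multi-excerpt piles only — singleton piles are trivially
coherent and would inflate the rate — with `count_singletons` exposing
the alternative reading. `low_preservation_flags` ranks sorters by
preserved/multi (or /all piles) ascending and returns those under a
threshold: candidates for qualitative follow-up, since low preservation
means the combined grouping kept little of that sorter's perspective.

## Synthetic data

The simulator plants K themes over n excerpts and corrupts each
sorter's copy independently: at most one merge of two random piles
(probability `p_merge`, skipped when it would leave fewer than two
piles), at most one split of a pile with ≥ 4 members (`p_split`, both
halves ≥ 2), then each excerpt moves to a uniformly random other pile
with probability `epsilon`. Defaults are n=40, m=8, K=4 — the scale of
the motivating study — with balanced theme sizes when none are given,
and p_merge=0.1, p_split=0.3, epsilon=0.1, chosen once so that
simulated panels show the qualitative behaviours observed in practice:
pile counts at or above the theme count (splits outnumber merges) and
cross-cutting excerpts that no theme retains. Randomness derives from
one root seed with an independent SeedSequence substream per sorter, so
datasets are byte-identical across runs and adding sorters never
perturbs earlier ones.

What the generator does *not* emulate: excerpt semantics (there is no
text model — "themes" are arbitrary labels), correlated sorter styles
(lumpers vs splitters beyond one merge/split each), reading-order or
fatigue effects, and partially nested theme structure. Passing recovery
tests therefore shows the pipeline recovers clean-to-moderately-noisy
planted partitions of this shape; it does not certify performance on
real panels whose disagreement is structured rather than uniform.

Recovery is scored with the adjusted Rand index (permutation-model
correction), with unassigned excerpts counted as singleton clusters so
that refusing to group anything scores near 0, not 1.

A property of the method worth knowing when interpreting simulation
results: with distance = 1/score as path length, strongly agreed edges
are shortest-path highways and can accumulate betweenness, so under
item-level noise the removal sequence sometimes peels well-connected
excerpts out of their own theme before all cross-theme ties are gone.
Recovery is perfect at zero noise and degrades steeply with epsilon;
that degradation is a property of the published algorithm (the igraph
routine the original analysis used behaves the same or worse on the
same networks), not of this implementation.

## Problem sizes used in the test suite

The randomized suites run at the scale the method targets: oracle
equivalence on 200 random graphs of ≤ 8 nodes against exhaustive
simple-path enumeration; exact recovery on 100 planted partitions with
n ∈ [6, 30], m ∈ [2, 8]; noise-response curves at n=40, m=8, K=4 with
200 replicates per epsilon ∈ {0, 0.1, 0.3}; preservation bookkeeping on
1000 random dataset/clustering pairs.

## Known limitations

- Modularity maximisation inherits the resolution limit; very small
  true themes attached by noise edges may be absorbed or left
  unassigned.
- The dendrogram only contains the partitions the removal sequence
  happens to pass through; the modularity optimum over *all* partitions
  can be better than every level (observed under heavy item noise).
- Betweenness recomputation is exact, not approximate; networks far
  beyond a few hundred excerpts will be slow.
- Alternative community algorithms (Louvain, label propagation, leading
  eigenvector) are out of scope, though the Clustering container does
  not care where a partition came from.
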