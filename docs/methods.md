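# Methods

This note documents the models and procedures `hubpanel` implements, the
conventions and defaults it pins down, what the synthetic generator does
and does not emulate, and the design choices that were genuinely open.

## Pipeline model

The package operates on an undirected simple graph of gene symbols.
Self-loops are dropped and duplicate edges collapsed (keeping the maximum
score) at read time; edges may carry a confidence score (STRING's 0–1000
combined score or a generic 0–1 weight), but **all analysis is
topological**: shortest paths are unweighted BFS paths and scores are used
only for thresholding at import. This matches how Cytoscape-style
centrality and clustering analyses of PPI networks are normally run.

Analysis is restricted to the main connected component. Betweenness,
stress and closeness are undefined or degenerate across components, and
restricting to the largest component is fixed in the pipeline rather than
left as a knob.

## Centralities

One Brandes sweep per source computes betweenness and stress together.
For each source the BFS shortest-path DAG is built with path counts σ;
backward accumulation yields the classical pair-dependency δ for
betweenness and, per node v, the number of DAG paths from v to its
descendants, which multiplied by σ(source→v) gives v's share of whole
shortest paths for stress. Summing over ordered sources counts each
unordered pair twice, so both totals are halved.

Conventions that tools disagree on, pinned here:

* pairs are unordered and endpoints never mediate their own pairs;
* betweenness is reported unnormalized (selection by rank is
  normalization-invariant); `normalized=True` divides by (n−1)(n−2)/2;
* stress counts each shortest path once (not once per direction), so
  stress and betweenness are on comparable pair scales;
* closeness is (n−1)/Σ_t d(v,t), in (0, 1] on a connected graph.

The implementation is validated against exhaustive shortest-path
enumeration on hundreds of small random graphs, against the subtree-pair
closed form on trees, and against networkx's independent betweenness
implementation on larger graphs.

## Hub and bottleneck selection

* Degree cutoff: mean + 2 SD of raw degrees, with the **population** SD
  (the node set is the entire population under study, not a sample);
  `population_sd=False` switches to the sample convention. The boundary is
  inclusive (degree ≥ cutoff): selection language of the form "highest
  degrees were selected" favors inclusion. Both choices are exposed and
  logged because neither convention is universal.
* Top-fraction sets (default 5% for betweenness, closeness, stress) take
  the ceil(fraction·n) highest values; ties at the boundary are all
  included rather than truncated by hidden ordering, so the set can exceed
  its nominal size (logged when it does).
* Bottleneck = top-fraction betweenness; hub-bottleneck = hub ∩
  bottleneck. Stress and closeness sets are corroborating report columns,
  not filters.

## MCODE-style complex detection

Follows the published MCODE scheme: vertex weight = k × density of the
highest k-core of the closed neighborhood N[v] (weight 0 below the degree
cutoff); greedy seeded expansion from the highest-weight unassigned node,
including neighbors whose weight is within `node_score_cutoff` (fraction,
default 0.2) of the seed's weight; haircut removes members with fewer than
two in-complex edges — iterated to a fixed point here, which keeps the
complex connected and of minimum internal degree ≥ 2; complexes whose
subgraph contains no k-core of order `k_core` are discarded; optional
fluff adds unassigned boundary nodes with neighborhood density above
`fluff_density_cutoff`. Scores are density × size. Parameter defaults are
the Cytoscape MCODE app defaults (degree cutoff 2, node score cutoff 0.2,
k-core 2, max depth 100, haircut on, fluff off). All ties anywhere (seed
order, ranking) are broken lexicographically, making the output a pure
function of the input graph and parameters.

## Enrichment

Upper-tail hypergeometric p per term (scipy), Benjamini–Hochberg q over
all tested terms (statsmodels; Bonferroni by flag), significance at
q ≤ α (default 0.05). Query genes outside the universe are dropped with a
logged count; the universe defaults to the union of term genes and can be
supplied explicitly (recommended — it changes N and therefore every p).

Significant terms are grouped by Cohen's kappa between their membership
indicator vectors restricted to the query's genes, merging pairs with
kappa ≥ 0.4 by single linkage and labelling each group by its most
significant member. The 0.4 threshold and the query-restricted domain are
the conventions of ClueGO-style term grouping; single linkage is a
deliberate simplification of that tool's iterative merging and is
documented as such.

## Synthetic data: what is emulated, and what is not

The generator produces every pipeline input with a planted-truth record,
at desk scale (seconds, one CPU):

* **Gene lists**: three lists of 232/143/132 symbols sharing exactly a
  17-gene core, otherwise disjoint — the shape of a three-disease
  comparison with a clean common core.
* **Network**: a preferential-attachment (Barabási–Albert, m = 2) main
  component of 300 nodes plus three smaller components (30/20/10), giving
  the four-component structure typical of seed-expanded PPI exports.
  Eight hubs are planted by adding edges to random background nodes until
  every planted hub clears the mean + 2 SD cutoff with margin and no
  other node does — verified arithmetically at construction, so exact hub
  recovery is a guarantee, not a probabilistic hope. Hubs are kept
  non-adjacent, and their added edges avoid module members, so their
  neighborhoods stay sparse (low MCODE weight) and the planted modules
  stay clean.
* **Complexes**: three modules (16/11/6 nodes at density 0.8) wired as
  connected random near-regular graphs and bridged to the background by
  two edges each. Regular wiring keeps the MCODE core-clustering weight
  homogeneous across members; with heterogeneous wiring the 20% expansion
  window recovers only each module's dense core, which is a property of
  the algorithm, not a bug.
* **Annotations**: the query is partitioned into 9 disjoint blocks; each
  block yields 2 enriched terms (block genes + 1 non-query filler), so
  within-block kappa is 1 and between-block kappa ≤ 0, giving exactly 9
  groups. Background terms receive a **deterministic chance-level** query
  overlap (floor(K·n/N)). This makes the planted negatives true negatives
  by construction: with randomly drawn background terms, BH at FDR 0.05
  admits ≈ 0.05·R false discoveries per run *by design*, and "exactly the
  planted terms are significant" would fail in a fixed fraction of seeds
  no matter how strong the signal. The `random_background=True` mode
  draws background terms uniformly and is the right mode for
  false-positive-rate simulations, where fluctuating overlap is the point.

What the generator does **not** emulate: realistic STRING confidence-score
distributions, correlated annotation hierarchies (GO's DAG), overlapping
complexes, or degree-dependent annotation bias. Passing recovery tests
therefore demonstrates algorithmic correctness under clean planted
conditions, not performance on real noisy annotation databases.

## Numerical choices and degenerate inputs

* Power-law fit: least squares on (log10 k, log10 count) with zero-count
  degrees omitted and isolated nodes excluded — the display convention of
  NetworkAnalyzer-style degree panels, not a maximum-likelihood
  (Clauset-style) tail fit; the fit needs ≥ 3 distinct degrees. The
  reported correlation is Pearson's r between observed and fitted counts
  on the original scale, defined as 1 when residuals vanish.
* Component ordering: by size, ties by lexicographically smallest member.
* Canonical edge key: lexicographically sorted pair; all writers emit
  sorted UTF-8/LF output, so every report is diffable and reruns are
  byte-identical (the determinism contract is tested end to end).
* Empty selections (no hub above cutoff, no significant term) are legal
  results, reported as such; grouping with zero significant terms is an
  error by contract.
* Problem sizes in tests and the acceptance script (300-node main
  component, 10-seed recovery batteries, 100-run null simulations,
  2000-node preferential-attachment graphs for the exponent interval) are
  the package's chosen desk-scale defaults; they complete in well under
  two minutes combined.

## Known limitations

* No identifier mapping: gene symbols are opaque uppercase strings;
  mixed-alias inputs will under-intersect.
* The seed→network expansion of web tools (e.g. STRING's neighborhood
  expansion inside Cytoscape) is modeled only generically by
  `expand(net, seeds, depth)`; reproducing any specific tool's export
  requires that tool's snapshot.
* MCODE here is the published algorithm, not a byte-compatible clone of
  the Cytoscape app (whose fluff stage permits overlapping complexes;
  overlap is disallowed here so that complex membership is a partition).
* Kappa grouping uses single linkage; long chains of moderately similar
  terms can merge groups that ClueGO's iterative scheme would keep apart.
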