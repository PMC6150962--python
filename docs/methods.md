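# Methods

## Model overview

`ppicomplex` treats complex detection as a supervised search over an
undirected PPI graph G = (V, E).  The method has two learned components: a
node-embedding model that maps every protein to a vector preserving its
network neighborhood, and two supervised models (a regression scorer over
topological features and a three-class classifier over pooled embedding
vectors) trained on a positive / intermediate / negative complex set.  The
assumptions are those of the underlying models: complexes are connected,
mostly locally dense regions whose members share network context, and known
complexes are informative about undiscovered ones.

## Node embeddings

Second-order biased random walks: from current node v, reached from previous
node t, neighbor x is drawn with unnormalized weight w(v,x)·α where α = 1/p
if x = t, 1 if x is adjacent to t, and 1/q otherwise (w ≡ 1 on unweighted
networks; the first step of a walk is weight-proportional over neighbors).
Each conditional distribution is stored as a Walker alias table, so a step
costs O(1).  Walks from isolated nodes truncate to the start node, and such
nodes receive no embedding (consumers fall back to the zero vector, which
cosine-scores 0 — "no evidence" — rather than erroring).

Defaults (changeable via `Node2VecParams`): p = 1, q = 8 (strongly local,
breadth-first-like exploration, which places structurally similar proteins
close together), r = 10 walks of length l = 10 per node, window k = 10,
dimension d = 64.  The skip-gram trainer is an in-house single-threaded SGD
with negative sampling (numba-compiled): 5 negatives drawn from the
unigram^0.75 distribution via an alias table, 5 epochs, learning rate
decaying linearly 0.025 → 1e-4, input vectors initialized uniformly in
±0.5/d, output vectors at zero.  Single-threaded corpus-order updates make
embeddings bit-reproducible for a fixed seed.

Cosine similarity is defined as 0 when either vector is zero.  Complex
vectors pool the member-embedding matrix Z column-wise; max pooling is the
default (it retains the globally salient coordinates of the member set),
with min and average as alternatives.

## Edge refinement

Each edge is weighted by the endpoint cosine similarity.  Filtering keeps
edges with weight ≥ the threshold (non-strict, so a threshold sweep aligns
with "edges kept" counts monotonically); augmentation adds, per node, the
single most similar non-neighbor when the similarity is strictly greater
than its threshold (strict, mirroring the asymmetric conventions of the two
operations' definitions).  Augmentation searches all non-neighbors exactly —
at desk scale (10^3–10^4 nodes) the O(|V|²·d) row-by-row scan is cheap and
avoids an approximate-nearest-neighbor dependency.  The combined operation
always filters first, then augments the filtered network; embeddings are
computed once on the original network and are not recomputed after
refinement.  Isolated nodes are kept after filtering (they simply never
seed the detector).

## Supervised detection

Training classes: known complexes (target 1.0), intermediate-quality
complexes (0.5) and uniformly random node sets (0.0; any draw identical to a
positive is rejected).  When no intermediate set is supplied the pipeline
fabricates one by resampling 30% of each positive's members — a stand-in
with the intended property of being better than random but worse than the
gold standard.  Negative counts default to one per positive.

The 11 features of a complex's induced subgraph: node count, edge count,
density, mean/variance/maximum internal degree, mean local clustering
coefficient, fraction of members in the largest connected component, mean
external degree, internal-edge ratio m/(m + boundary edges), and mean
internal edge weight (1.0 on unweighted networks, 0.0 for edgeless
subgraphs).  They cover the density, connectivity and separation axes
standard in complex-quality scoring; the extractor is pluggable.

The scorer regresses the targets on these features.  The default family is
ridge regression (α = 1) over standardized degree-2 polynomial features.
The choice is deliberate: greedy expansion needs a score that keeps rising
along the path from a small seed to a full-sized complex, which requires
size×density interaction terms.  Ordinary least squares on the raw features
— the simplest "regression model" — extrapolates pathologically on tiny
subgraphs: it scores 3-node cliques (density = clustering = 1) above
full-sized true complexes, so expansion stalls at triangles and recovery
collapses (F ≈ 0.1 versus ≈ 0.5–0.9 for the quadratic family on the same
fixtures).  Plain linear regression remains available (`model="linear"`),
and any sklearn-style regressor can be injected via `model_factory`.

Seeds are all nodes with degree strictly above the network mean 2|E|/|V|.
Expansion adds, per step, the frontier node giving the highest score
(ties → lexicographically smallest ID, so detection is deterministic), and
stops when the best gain is ≤ tol (default 1e-6) or the size cap is reached
(default: twice the largest positive).  Until the subgraph reaches the
minimum reportable size the best neighbor is added unconditionally:
regression scores on 1–2-node subgraphs are extrapolations far outside the
training distribution, and an overshoot there would otherwise freeze the
search below any size that could be reported.  Candidates smaller than
`min_size` and duplicate member sets are dropped.  `min_size` follows the
gold standard — the pipeline defaults to the size of the smallest positive
complex (3 for gold standards whose complexes start at 3) — since nothing
smaller than the smallest known complex is a credible candidate.

## Candidate classification

Each training complex and candidate becomes its pooled complex vector.  The
default classifier is a 1000-tree random forest (other settings at library
defaults, recorded in the run report); RBF-kernel SVM and L2 logistic
regression are available as comparators.  Only candidates predicted
"positive" are emitted; intermediate/negative predictions are logged.
Prediction counts per class appear in the run report.

## Evaluation

NA(p,q) = |V_p ∩ V_q|²/(|V_p|·|V_q|); a prediction matches a gold complex
when NA ≥ 0.25 (inclusive — NA is a ratio of small integers, so the
comparison is exact).  Matching is many-to-many: one gold complex can match
several predictions and vice versa.  Precision = matched predictions /
predictions, recall = matched gold / gold, F = 2PR/(P+R) with F = 0 when
P + R = 0 and P = 0 for an empty prediction list.

## Link prediction

⌊T·|E|⌋ edges are hidden, drawn uniformly among removable (non-bridge)
edges so the reduced network stays connected; on a disconnected input the
largest component is used with a warning.  For each hidden edge (u,v), 100
nodes not adjacent to u (and ≠ u, v) are sampled; hidden-edge partners other
than v remain eligible.  The true pair's score is ranked among the candidate
scores, ties receiving the mean rank of their block, so an uninformative
constant scorer lands at the analytic expectation (n_candidates + 2)/2 = 51
— this makes the random baseline testable.  Scorers: embedding cosine;
AdjustCD = 2|N_u ∩ N_v| / (max(|N_u|, N_avg) + max(|N_v|, N_avg)) with
N_avg the mean neighborhood size; the PE-measure
p(k)_uv = 1 − ∏_l (1 − p(k−1)_ul · p(k−1)_vl) over common neighbors l,
initialized at the adjacency indicator (the minimal start consistent with
the recursion) and iterated k = 2 times; and cosine over random unit
vectors as the baseline.

## Synthetic data

The generator plants n_complexes node sets (sizes uniform in
[size_min, size_max], disjoint unless overlap_fraction > 0) in a background
node set; pairs inside a common complex are connected with probability
p_within, all other pairs with p_background, and an optional
noise_edge_fraction·|E| extra uniform edges are added.  A planted-partition
design was chosen over LFR-style generators because the acceptance
properties need exact analytic control of the within/between densities
(background edges are excluded from within-complex pairs, so realized
internal density estimates p_within unbiasedly).  Defaults — 500 nodes, 20
complexes of 5–15 members, p_within = 0.8, p_background = 0.01, no noise or
overlap — are the fixture used throughout the test bench.

What the generator does *not* emulate: scale-free degree distributions,
assay-specific false-negative structure, core–attachment organization, and
heavily overlapping complexes.  Passing tests therefore demonstrate that the
machinery is correct and that the method recovers planted structure under
controlled noise, not that the reported operating points transfer to any
particular real interactome.

## Reproducibility and numerical choices

A single pipeline seed fans out to per-stage 31-bit seeds via CRC32 of
"stage:seed", so stages can be re-run independently yet reproducibly;
identical config + seed yields byte-identical predicted complex files.
Degenerate inputs are defined rather than fatal wherever a downstream
default exists (zero-vector cosine = 0, empty-subgraph mean edge weight = 0,
regular graphs yield no seeds with a warning); genuinely ambiguous inputs
(empty gold standard, missing training class, unembedded complex members in
a vector request) raise.

Problem sizes in the test bench are chosen to keep the full suite in a few
minutes on one CPU: the end-to-end recovery and link-prediction comparisons
run on the 500-node default fixture over 10 seeds; unit-level properties use
networks of 60–300 nodes.  The determinism check uses a 250-node fixture,
and the half-training recovery check a 300-node, 12-complex fixture (with
only a handful of planted complexes the quadratic scorer's training set
becomes too small to constrain it, which bounds how far that particular
check can be scaled down).

## Known limitations

- Candidate sets are not merged or deduplicated beyond exact equality, so
  several overlapping predictions of one complex inflate the prediction
  count; NA-based matching tolerates this but precision readings depend on
  it.
- The RF filter sees only pooled embedding vectors; on synthetic fixtures a
  small coherent background clique is nearly indistinguishable in that
  representation from a small true complex, so most precision comes from
  the detector, not the filter.
- Expansion only adds nodes; a seed that absorbs a wrong node early cannot
  shed it.
- The PE-measure's starting matrix is the adjacency indicator; other
  initializations would change absolute scores (though typically not
  rankings).
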