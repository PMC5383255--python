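# Methods

## Model

The package treats disease-gene identification as guilt-by-association
retrieval on a weighted interactome. Nodes are genes/proteins (opaque
string IDs); an undirected edge carries an integer confidence score
S ∈ [150, 999]. Two derived views of the same edge list are used: the
raw-score network for propagation, and the transformed network with
w(e) = 1000 − S for shortest paths, so that high-confidence interactions
are short. The two weights of an edge always sum to 1000.

**Propagation route.** The restart walk iterates
P_{t+1} = (1 − r)·A·P_t + r·P₀ from the uniform seed distribution, with
A the column-stochastic matrix A[i,j] = S(i,j)/Σₖ S(k,j). Column
normalization is applied to the *score-weighted* adjacency, not a
binarized one: edge confidence modulates how much mass flows across each
interaction. A note on orientation: the update applies the
column-stochastic matrix directly. Writing the same update with the
transpose of a column-normalized matrix — a formulation that circulates
in the applied literature — does not conserve probability mass on graphs
with heterogeneous weighted degrees; since the method's statistic is a
probability vector (asserted to sum to 1 at every iterate), the
mass-conserving orientation is the only internally consistent one and is
what this package implements. Convergence is declared when the L1 change
drops below the tolerance; a direct linear solve of
P = r(I − (1 − r)A)⁻¹P₀ serves as an independent oracle in the tests.

**Shortest-path route.** All minimum-weight paths between every unordered
seed pair (Dijkstra; integer weights keep tie detection exact). A
candidate's betweenness is the number of such paths containing it as an
inner node, seeds excluded. Two path modes exist because "the" shortest
path is ambiguous under ties: `all-ties` (default) counts every
minimum-weight path; `single` keeps one path per pair, the
lexicographically smallest node sequence, making runs bit-reproducible
under either mode. For the all-ties count the package also implements an
enumeration-free route — per-seed Dijkstra with path-multiplicity
counting, combining σ_s(v)·σ_t(v) wherever d_s(v) + d_t(v) = d_s(t) —
which the tests verify against explicit path enumeration; the permutation
test uses it for speed.

**Screens.** Comparison directions are deliberate and pinned by tests:
permuted statistic strictly greater than observed sets δᵢ = 1; p-value
strictly below 0.05 survives; MIS ≥ p_MIS survives (so a score exactly at
the threshold passes); MFS strictly above p_MFS survives. The screens are
pure set intersections, so their order cannot change the surviving set.

## Permutation null

Random seed sets are drawn uniformly without replacement from the whole
node universe, validated seeds included (an `exclude_seeds` flag restricts
the pool). The statistic is recomputed in full for every random set. Two
conventions make the null well defined for candidates:

* SP: a candidate absent from a permuted run's paths has betweenness 0.
* RWR: a candidate that is itself drawn into the permuted seed set
  contributes statistic 0 for that replicate. It is a seed of that run,
  and seeds are never candidates; its restart-held probability
  (≈ r/|S|, orders of magnitude above any candidate probability) is an
  artifact of the restart term, not a measure of network proximity.
  Without this rule every candidate would carry a baseline
  p ≈ |S|/|nodes| regardless of signal — negligible on a
  20,000-node interactome but fatal at benchmark scale.

Inside the jackknife the null is re-drawn per fold from a per-fold
derived seed. `n_perm` defaults to 100 during training (the null is
recomputed in every fold, so this is a cost concession) and to the
standard 1,000 for final identification runs.

## Training

Leave-one-out over the seed set: each fold runs the complete screened
pipeline on the remaining seeds and scores the retrieved set against the
single held-out gene (recall ∈ {0,1}; precision = hit/|retrieved|;
F1 with the 0/0 → 0 convention; F1-R = recall·F1). Fold metrics are
averaged per parameter combination — per-fold macro averaging, not
pooled counts. All other genes are assumed negative during training, so
the other held-out module genes a fold retrieves *depress* its measured
precision; the absolute F1-R values are therefore small by construction
and only their ranking matters.

Grids: pRWRp ∈ {1e-5, 2e-5, …, 1e-4} (step 1e-5 — the grid endpoints are
standard, the step is this package's choice and is configurable);
p_MIS ∈ {400, 700, 900}; p_MFS ∈ {0.0, 0.1, …, 0.9}. Every grid point is
a pure thresholding of per-fold statistics, so each fold's propagation,
permutation null, MIS and MFS are computed once and reused across the
whole grid; the tests verify this cache against an independent per-combo
re-run of the full pipeline. All tied optima are reported, and
`tied_outputs_coincide()` re-runs the final prediction at every tied
optimum to check the outputs agree — the consistency check applied when
the objective ties across thresholds.

## Enrichment-score vectors

The function screen needs per-gene vectors ES(g) of nonnegative term
scores; what "enrichment score" means is left open by the method's usual
presentations, so the scorer is pluggable and recorded in outputs:

* `neighborhood-hypergeometric` (default): ES(g)[t] is
  −log₁₀ of the hypergeometric upper-tail probability of the overlap
  between g's closed neighborhood ({g} plus direct interactors) and term
  t's gene set, in the network-node universe, floored at 0 (zero overlap
  scores exactly 0). This reads "enrichment" through the
  guilt-by-association lens: a term is informative for g if it is
  over-represented among g's interactors. The tail probability is floored
  at 1e-300 before the log, capping scores near 300.
* `indicator`: plain membership (1 if annotated), a transparent fallback
  used in tests.

Cosine association of two nonnegative vectors lies in [0, 1]; a gene with
an all-zero vector gets association 0 (logged), never an error.

## Synthetic benchmark

The generator emulates exactly the structure the method assumes: a 200-gene
network with a planted 20-gene module, within-module edges at p_in = 0.6
with scores uniform on [800, 999], background edges at p_out = 0.02 with
scores uniform on [150, 400] (bands chosen so the 400/700/900 MIS
thresholds discriminate module from background contacts), isolated nodes
repaired with one background edge so every gene is propagatable. Half the
module is designated seeds, half held-out truth. Annotations: 20 terms,
10 module-enriched (module genes annotated with probability 0.8,
background leak 0.05) and 10 background terms (rate 0.1 everywhere) —
values chosen once as a realistic degree of within-module annotation
coherence. Everything is a pure function of one RNG seed (default 12345).

What the benchmark does *not* emulate: scale-free degree structure, the
size of a real interactome (200 vs ~20,000 nodes), or realistic
annotation hierarchies. Two scale effects follow and bound what passing
tests show about genome-scale data. First, the pRWRp grid (1e-5…1e-4) is
calibrated to ~20,000-node probability mass; on 200 nodes every candidate
clears it, so the probability threshold is exercised logically but is not
selective. Second, seeds are 5% of benchmark nodes versus ~0.9% at full
scale, so random permutation sets frequently contain module genes or a
candidate's direct neighbors; weakly attached module genes then receive
genuinely marginal p-values (0.05–0.2), and the p < 0.05 screen — not the
propagation ranking — caps held-out recovery at 60–80% on the default
instance. On the same instance the shortest-path route returns an empty
putative set: the module is so dense and high-scoring that seed pairs are
directly connected (observed betweenness 1–14), while random seed sets
route *through* the module's cheap edges and exceed those counts. Both
are faithful consequences of the screens at benchmark scale, not
implementation artifacts; the propagation ranking itself separates the
module cleanly (every held-out gene outranks the background median).

## Numerical and design notes

* Node order is lexicographic everywhere; all vectors/matrices index by
  it, making runs independent of input-file line order and node labels
  (up to the order-dependence of lexicographic tie-breaks).
* Duplicate or reciprocal edge-list lines collapse to the unordered pair
  keeping the maximum score (STRING dumps list both directions); self-loops
  are dropped with a logged count.
* Candidate lists sort by descending statistic, ties by gene ID; TSV
  floats are rendered with a fixed format, so equal manifests give
  byte-identical outputs.
* The iteration guard (10,000 steps) turns non-convergent configurations
  into an explicit error carrying the last residual; with r ≥ 0.1 and the
  default tolerance, convergence takes well under 100 iterations.
* One master RNG seed fans out to per-stage seeds by hashing stage labels,
  so adding a stage never perturbs the draws of existing ones.
* Jackknife permutation p-values are recomputed inside every fold rather
  than reusing one observed-seed null: the fold's seed set differs, so its
  null does too.

## Known limitations

* Desk-scale networks make the permutation screen conservative (see
  above); on genome-scale inputs the same code paths apply unchanged but
  have not been validated here against a full interactome download.
* The neighborhood-hypergeometric scorer treats terms independently and
  ignores annotation hierarchy.
* `all-ties` path enumeration can be expensive on graphs with massive
  shortest-path degeneracy; the counting route avoids enumeration, and
  `single` mode bounds work per pair.
* No multiple-testing correction is applied to permutation p-values; the
  fixed 0.05 cut is part of the method's definition.
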