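# Methods

## The model

The object of study is a recipe corpus: an ordered list of records, each a
condition label and a set of ingredient tokens. The analysis treats a
recipe as an unordered set — quantities, preparations and within-recipe
repetition are ignored, because the statistic of interest is pairwise
co-use. The ingredient co-occurrence network has one node per ingredient
and an integer edge weight `W_ij` equal to the number of recipes containing
both endpoints. By default nodes are restricted to ingredients appearing in
at least two recipes (`min_recipes=2`); one-off ingredients contribute no
repeated-pair evidence and mostly add noise. Illustrative figures use
`min_recipes=1`.

### Weight normalization

Count weights are mapped onto `[ε, 1−ε]` by the affine transform

    W' = ε + (1 − 2ε) · (W − W_min) / (W_max − W_min)

with ε = 0.01 by default (admissible range 0 < ε < 0.5). The transform
preserves rank order and pins the extremes exactly at ε and 1 − ε, so a
threshold of 0 never removes the weakest links. The code uses this
arrangement of the formula rather than the algebraically identical
`((1−2ε)W + (2ε−1)W_min)/(W_max−W_min) + ε` because it lands the endpoints
exactly on ε and 1 − ε in floating point. When all weights are equal the
transform is undefined (zero denominator); every weight is then set to 0.5,
the midpoint of the target interval, which keeps thresholding semantics
intact: all edges survive thresholds below 0.5 and none above.

### Thresholding

For each threshold `t ∈ [0, 1)` an unweighted graph keeps the edges with
`W' > t` (strict: edges *at* the threshold are cut) at unit weight.
Isolated nodes are retained — they drive the fragmentation profile and the
consensus bookkeeping. The fragmentation profile records, for a candidate
list of thresholds (by default 0 plus every distinct normalized weight),
how many nodes keep at least one edge; it is non-increasing by
construction. Automatic schedule selection returns 0 plus every candidate
at which the nonisolated count strictly drops, truncated before the count
falls below `stop_min_nodes` (default 10). The stated reference schedule
for manuscript-scale corpora, `(0, 0.01, 0.15, 0.29, 0.43, 0.571)`, is
exported as a constant and can be passed explicitly; explicit schedules
bypass the selection rule entirely.

## Community detection

Quality function: Newman–Girvan modularity over all ordered node pairs
including `i = j`,

    q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j),

evaluated in practice per community as `Σ_c [e_c/m − (K_c/2m)²]` with `e_c`
internal links and `K_c` the community degree sum. The all-in-one partition
scores exactly 0, so the returned optimum is never negative.

The maximizer is a multi-restart spectral method:

- **Bisection.** For a group `g`, the generalized modularity matrix
  `B^(g) = B[g,g] − diag(row sums over g)` (with `B = A − kkᵀ/2m`) is
  formed; if its leading eigenvalue is ≤ 1e−10 the group is indivisible,
  otherwise nodes are split by the sign of the leading eigenvector after a
  uniform random perturbation of magnitude 1e−8 (which also assigns
  exactly-zero components randomly per restart). The gain of a split is
  `(1/4m) sᵀ B^(g) s`; a refined split with non-positive gain is rejected.
- **Kernighan–Lin refinement.** After each bisection, single nodes flip
  sides greedily in random order while the gain improves, never emptying a
  side.
- **Global tuning.** Single-node moves between any communities — including
  splitting off into a fresh singleton — accepted by best positive gain, in
  random node order, until a full pass makes no move.
- **Agglomeration.** Community pairs merge by best positive gain
  (best-improvement, not first-improvement) until no merge helps. Tuning
  and agglomeration alternate until neither changes anything.
- **Restarts.** `n_runs` independent runs (default 10,000, the protocol
  for manuscript-scale runs; tests use 10–200); even-numbered runs start
  from the recursive spectral bisection, odd-numbered runs start from
  random labels and rely on tuning/agglomeration. The random starts were
  added because on dense, noisy graphs the spectral start is nearly
  deterministic and all restarts can land in one basin; with them the
  optimizer attains the exhaustive optimum on 50/50 random 6–9-node test
  graphs and has not been observed below a Louvain baseline. The best
  partition over all runs is returned; identical seeds give identical
  output (per-run RNGs are spawned from one seed sequence, so the best over
  the first k runs is non-decreasing in k).

Eigenpairs use the dense symmetric solver up to 500 nodes and a sparse
iterative solver (tolerance 1e−9, max 10,000 iterations) above. Isolated
nodes bypass the optimizer as singleton communities; their `k_i = 0` terms
contribute nothing to q. Community ids are canonicalized by first-seen node
order so partitions compare stably.

An exhaustive enumerator over all set partitions (restricted-growth
strings, capped at 12 nodes) serves as the exactness oracle; ties break
toward fewer communities, then lexicographically smaller assignment.

## Consensus and core extraction

With one best partition per threshold (only the best-of-restarts partition
is tallied, not every restart), the co-occurrence matrix counts for each
pair the thresholds at which it shared a community; the diagonal records
presence (= T with isolated nodes retained). Core pairs are off-diagonal
entries equal to T; core groups are connected components of the core-pair
graph. Because an isolated-at-threshold node is a singleton there, "same
community at every threshold" is a genuine robustness statement.

No formula for *core single ingredients* exists beyond "read off the
matrix"; the implementation flags nodes in no core pair whose off-diagonal
row mass is in the top 5% (parameterizable), and labels the rule
non-canonical in the JSON output. It is a stand-in for expert judgment, not
a definition of the original selection.

Heat maps order the matrix by reverse Cuthill–McKee on the binarized
pattern (forward available by flag); since Cuthill–McKee is a heuristic,
the identity ordering is returned in the rare case the computed ordering
would increase bandwidth, so reordering never widens the band. The color
scale is linear: 0 → white, T → black.

Recipe ranking scores each recipe by core pairs fully contained plus core
singles present (a pair counts only with both members present), keeps
scores ≥ `min_score`, groups by descending score, and sorts alphabetically
within groups. Exclusion of unwanted ingredients or overlong recipes is
available but off by default, since such exclusions are judgment calls.

## Synthetic corpora

The generator emulates a manuscript-scale remedy collection: defaults of
400 recipes of 2–16 ingredients over a 300-token vocabulary in 10 modules
with `p_noise = 0.1` give a few thousand ingredient mentions with a mean
recipe length near 9 — the scale of a sizeable recipe book. Each recipe
draws a home module uniformly; each ingredient draw stays in the home
module with probability `1 − p_noise`, otherwise lands uniformly outside
it. At `hierarchy_depth=2` every module splits into two interleaved
submodules and within-module draws prefer the home submodule with
probability 0.75, planting the weight gradient (submodule > module >
background) that makes parent communities split as the threshold rises. An
optional handful of "ubiquitous" tokens (water/sugar-like: frequent,
structurally uninformative) can be appended to recipes with fixed
probability to produce right-skewed frequency distributions; it is off by
default. Generated tokens are synthetic (`m2_i05`) so tests never collide
with real ingredient names. The generator is a pure function of its design,
including the seed.

What the generator does *not* emulate: orthographic variation and synonymy
(the synonym table exists for real corpora but synthetic tokens need none),
quantities and preparations, condition-specific ingredient preferences, and
the empirical recipe-length and frequency distributions of any particular
manuscript (not published; the defaults are plausible stand-ins, not
calibrated fits). Passing recovery tests therefore demonstrates the
pipeline's correctness on block-structured corpora, not fidelity to any
particular historical text.

### Recovery study conditions

Planted-module recovery is validated at 3 modules × 8 ingredients, 45
recipes (15 per module), lengths 3–6, `p_noise = 0.05`: seed 1 recovers the
planted partition exactly (adjusted Rand index 1.0) and the 20-seed mean
ARI is ≥ 0.9. The recipe count matters and 15 recipes per module is the
deliberate choice: thresholding binarizes, so a count-1 noise edge weighs
as much as a count-12 within-module edge, and with several times more
recipes over the same 24-token vocabulary the cross-module link density
saturates to the point where the *true* modularity optimum of the
threshold-0 graph merges planted modules (verified by the exhaustive
oracle's small-graph analogue and by an independent Louvain baseline
finding the same higher-q merged partitions). That regime is a genuine
detectability limit of binarized modularity, not an optimizer failure;
recovery there is restored by raising the threshold, which is precisely the
point of the threshold sweep.

The nested fixture (2 modules × 2 submodules of 7, 240 recipes of length
3–5, submodule preference 0.75, `p_noise = 0.02`) yields 2 communities at
threshold 0 and the 4 planted submodules at threshold 0.4 (both at ARI 1.0
for the default seed), reproducing the community-splitting behaviour the
sweep is designed to reveal.

## Numerical choices and limitations

- Tolerances: eigenvalue positivity 1e−10; move/merge acceptance 1e−12;
  modularity comparisons in tests 1e−12 (analytic) / 1e−9 (oracle).
- Thresholds live in `[0, 1)`; a schedule must be strictly increasing.
- Degenerate inputs: empty corpus, edgeless network and all-equal weights
  are handled explicitly (error, warned singleton partition, constant 0.5).
- The optimizer is a heuristic: above the 12-node oracle cap there is no
  exactness guarantee, only the restart protocol. Modularity itself has a
  resolution limit; very small communities can be absorbed.
- Problem sizes in the test suite (networks of ≤ ~30 nodes, 10–200
  restarts, 20-seed recovery studies) are chosen so the full suite runs in
  well under a minute of optimizer time while still exercising every stage
  end to end; manuscript-scale runs (hundreds of nodes, 10,000 restarts)
  use the same code paths through the CLI.
- Statistical significance of co-occurrence counts is out of scope: the
  consensus count is a robustness measure across thresholds, not a p-value
  against a null model.
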