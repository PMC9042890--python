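# Methods

This note documents the model implemented by `twodea`, its assumptions,
the tunable parameters, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not show.

## Graph model and path semantics

The interaction map is a signed, typed digraph in reduced activity-flow
form: edges are triples `(source, relation, target)` with `relation ∈
{−1, +1}`.  Edges carry a regulatory class (`transcriptional`,
`catalytic`, `generic`) that determines which regulator set they populate:
transcriptional in-edges of a gene define its TF set, catalytic in-edges
of a metabolite its enzyme set (synthesis `+1`, consumption `−1`; consuming
enzymes are deliberately included).  Elements carry a biological type and
submap memberships; the submap neighbourhood of a phenotype `v` is the
union of members of all submaps containing `v`, minus `v`.

A path's type is the product of its edge signs.  Shortest paths are found
by a breadth-first search over `(node, sign)` states; a pair whose minimal-
length paths disagree in sign is *inconsistent*.  Inconsistent pairs carry
no usable direction, so they contribute **zero** wherever a formula
multiplies by the path type — the only sign-neutral choice, applied
uniformly.  Self-loops are rejected at load time (they would make
zero-length shortest paths ambiguous), and self-influence is never stored.

### Counted paths inside submaps

The phenotype influence base case needs "the number of paths to `v`" on
the submap subgraph, which is unbounded on cyclic submaps.  We count
*simple* paths (no node revisits) within the submap-induced subgraph,
capped at a configurable maximum length (`max_path_len`, default 8 edges).
The cap is a declared parameter of the method, exposed on
`phenotype_influence`, `count_paths` and `build_influence`.  Both the path
count through an element (`N_Pu`, counting the element as source or
intermediate) and the on-path element sets (`N_Vu`, including the source,
excluding the phenotype) use the same definition.

## Influence scores

All three contexts share the aggregation rule: an element outside the base
regulator set collects `I(k, v) · T(SP_{u,k}) / 2^L(SP_{u,k})` over base
regulators `k` at most **two edges** away (halving per step, minimum
weight 1/4).  The piecewise definition is exclusive: a base-set member
never receives the aggregated branch, even when its own base score is zero
(opposite parallel edges from the same source cancel to zero and produce
no entry — the map then asserts no net direct effect).

Boundedness is enforced differently per context, following the most literal
reading of each bound:

* transcriptional / catalytic: the aggregated sum is hard-clamped to
  `[−1, 1]`;
* phenotype: aggregated entries are magnitude-capped at the largest base
  magnitude, and the **whole finished column** (base + aggregated) is then
  divided by its maximum absolute value.  Normalizing after the full
  column is assembled (rather than after the base case only) was an open
  choice; it guarantees every nonempty column peaks at exactly 1.

## Enrichment statistics

For a sample's differentially changed elements (DCEs) with log2 fold
changes `FC` and an influence column `I`:

* `Level = Σ I·FC` — an exact, unclamped sum.  Because its scale depends
  on the DCE count, levels are normalized per phenotype by the maximum
  absolute level across samples (an all-zero phenotype stays zero).
* `Saturation = Σ_{DCE} |I| / Σ_V |I|` ∈ [0, 1]; undefined (reported
  missing, never 0/0) when the phenotype has no regulators.
* `ES = Σ |I·FC|·I·FC / (k + Σ I²·FC²)`.  Equivalently: project every
  point onto the diagonals (`x = FC·|I|`, `y = |FC|·I`), append baseline
  points of total x²-mass `k` on the x-axis as `(±√(k/2), 0)` — `k = 2`
  gives exactly `(1, 0)` and `(−1, 0)` — and take the least-squares slope
  through the origin.  This identity is verified to 1e-10 in the tests and
  implies `|ES| ≤ 1` for every `k ≥ 0`.
* Upstream: `Sensitivity = Σ I·FC / Σ|FC|` (+1 for a perfect positive
  target, −1 for a perfect counter-regulator), `Specificity =
  mean(1 − |I|)` over the non-DCE universe, and the adapted ES in which
  the fixed baseline `k` is replaced by the fold-change mass of DCEs the
  candidate does not regulate.  As printed, that mass is a *signed* FC sum
  which can zero or negate the denominator; the default sums `|FC|`,
  keeping the denominator positive and the score bounded.  A
  strict-as-printed mode is available (`strict_k=True`); a vanishing
  denominator then reports 0.
* The specificity universe is restricted to elements of the same
  biological type as the data (e.g. genes for transcriptomics) rather than
  the whole vertex set, to avoid inflating specificity with irrelevant
  element classes; it is configurable (`universe_types`).

## Permutation null and p-values

For each sample, `n` randomized DCE lists (default 1000) are drawn by
re-assigning element identities among map elements of the same biological
type, without replacement within a list, keeping every FC value in place —
so each randomized list has exactly the original FC multiset, stratified
by type.  The statistic (ES and/or Level) is recomputed for each list.

Because influence scores and fold changes need not be symmetric about
zero, a separate zero-centred half-normal is fitted to each sign direction
of the null by the method of moments (`σ̂² = mean of squared same-signed
values`); a direction with fewer than two values falls back to the other
direction's scale and is flagged.  The z-score uses the direction-matched
scale with mean 0, and the two-sided p-value is `2·P(Z > |z|)` evaluated by
the Maclaurin series of the normal CDF integral (terms accumulated until
below 1e-18), switching to the continued-fraction form of the Mills ratio
for `|z| > 4` to avoid catastrophic cancellation.  `|z|` is capped at 14,
flooring the p-value at ≈1.56e-44.

Benjamini–Hochberg FDR correction (via `statsmodels`) runs across all
enriched elements of a sample *before* any user filtering — the upstream
target-type filter is applied to already-adjusted results.  Upstream
output is ranked by |sensitivity| desc, then specificity desc, then id, a
deterministic ordering.

Four p-value modes are exposed downstream: `es`, `level`, `max_p`, `min_p`
(element-wise over the two statistics).  With `k_mode="adaptive"` the ES
baseline is set to the largest |FC| of the sample's DCE list; since
permutations preserve the FC multiset, the observed and randomized scores
share the same adaptive baseline by construction.

### Calibration behaviour

Under type-stratified random DCE sets, Level-based p-values reject at
close to the nominal rate (≈5% at α = 0.05 in the shipped calibration
experiment: 500 trials × 1000 permutations on a 200-node map).  ES-based
p-values are mildly **conservative** (≈3% at α = 0.05): the ES permutation
null is a bounded ratio statistic and is leptokurtic relative to the
fitted Gaussian half-distributions, so extreme quantiles are
overestimated.  This is a property of the Gaussian approximation itself,
not of the permutation machinery; users wanting exact nominal behaviour at
moderate significance levels should prefer the Level statistic or
`min_p`/`max_p` with that caveat in mind.

## Synthetic data

`make_network` emulates a curated map's composition at desk scale: a
transcriptional layer (1–3 TFs per gene), a catalytic layer (1–2 enzymes
per metabolite, synthesis or consumption), a sparse generic signalling
layer, and per-phenotype submaps whose members form a small acyclic
connected subgraph feeding the phenotype.  Defaults give ~50 nodes with
30% negative edges; every generated map passes validation and every
phenotype has curated regulators.  Generators are pure functions of
spec + seed.

`make_null_dces` draws identities independently of topology with
FC ~ N(0, 2) (log2 scale) and significant adjusted p by construction.
`make_planted_dces` plants an upstream regulator: responders are drawn
among the elements it influences **with probability proportional to
|influence|** — strong direct targets respond preferentially, as in a real
perturbation where direct targets shift most reliably — and receive
`FC = effect·sign(I) + noise` (defaults: effect 2, responder fraction 0.5,
noise σ 0.5); all other same-type elements appear with noise-only FC and
non-significant p, so default filtering removes them.  p-values are
synthetic placeholders satisfying the filter contract, not a model of a
real differential-expression test.

What passing tests on these fixtures show: the formulas, bounds,
permutation machinery, calibration and recovery behave as specified under
the stated generative assumptions.  What they do not show: behaviour under
correlated co-expression, realistic DE p-value distributions,
identifier-mapping noise, or the scale and curation biases of a real
disease map (the shipped maps are ~50–200 nodes; real maps are thousands).

## Problem sizes and determinism

Shipped experiments use deliberately modest sizes — 200-node maps, 500
calibration trials, 100 recovery replicates, 1000 permutations — chosen as
the package's own desk-scale defaults; all are parameters, not limits.
Every stochastic component (generators, permutation nulls, batch drivers)
takes an explicit seed and records it in its outputs; repeated runs with
the same seed are byte-identical.

## Known limitations

* The JSON/TSV map schema is this package's own documented stand-in for
  disease-map server dumps, whose field names are not standardized; an
  adapter may be needed for real exports.
* "Number of paths" on cyclic submaps is resolved by the simple-path cap
  described above; other conventions (e.g. walk counts) would give
  different phenotype base scores.
* ES-based p-values are conservative at moderate α (see calibration).
* The automated threshold-optimization and TF-reoccurrence probability
  analyses sometimes layered on top of this method are out of scope.
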