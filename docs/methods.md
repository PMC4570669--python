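# Methods

This note documents the models, estimators and design choices behind
`foldbridges`, and what the synthetic validation does and does not
establish about real structural-alignment surveys.

## Score calibration

Every alignment method scores domain pairs on its own scale and
orientation.  A similarity orientation means greater is more similar; a
distance orientation (e.g. an elastic metric between backbone curves) means
the opposite and is sign-flipped internally, so all downstream logic sees
"greater = more similar".

When a method emits several score columns, the calibrated column is the one
maximising the AUROC for discriminating fold siblings from unrelated pairs
(computed by concordant-pair counting with half-credit for ties; a constant
column scores 0.5 with a warning; ties between columns resolve in declared
column order).

The posterior P(F=1 | S > s̄) is estimated by counting, with no smoothing:

* priors — the proportions of sibling and unrelated pairs in the partition;
* conditionals — empirical survival proportions with *strict* inequality
  (score > s̄), matching the tail definition of the posterior.

Pairs are partitioned into `alpha_involved` (at least one all-α domain) and
`other`; each partition is calibrated independently, including its priors.
Computing priors within each partition keeps the two calibrations
self-contained; the alternative (global priors) would let one partition's
composition leak into the other's posterior scale.

Numerical conventions:

* At or beyond the joint maximum observed score both strict survivals
  vanish (0/0); evaluation there falls back to `>=` counting, so the
  top-scoring alignment in a separable sample receives posterior 1 rather
  than NaN.
* Scores below the observed support evaluate at the leftmost estimable
  point and trigger a warning.
* Threshold inversion uses a suffix rule: the cutoff for level p is the
  smallest observed score s̄ such that the posterior at *every* observed
  score ≥ s̄ reaches p.  This is well defined even where the raw
  posterior-versus-score curve is non-monotone in sparse regions, and
  reproduces a monotone threshold table without any smoothing.  A level no
  score attains yields an "unattainable" sentinel (NaN in exported tables).
* For distance-oriented methods exported cutoffs are upper limits, flagged
  in the `limit` column of the threshold table.

For a known generating mixture (truncated normals, see below) the
closed-form cutoff solves P(F=1 | S > s) = p via the analytic survival
functions; the empirical cutoff converges to it (observed absolute error
~0.006 score units at ~10⁵ pairs for p = 0.5).

## Network construction

The domain-level posterior array is collapsed to family, superfamily or
fold level by keeping, per group pair, the single cross-group alignment
with maximal posterior, with its domain pair as provenance.  Max-collapse
is associative, so collapsing domains → families → folds equals collapsing
directly to folds.

Static networks cut the collapsed array at posterior thresholds 0.5–0.9
(closed comparison: posterior ≥ t).  All groups remain nodes whether or not
they are connected; renderers may drop isolated nodes but analyses keep the
full universe.  The dynamic sweep walks a strictly decreasing grid (default
1.00 → 0.50, step 0.01) and annotates each edge with its birth threshold —
the highest grid value at which it appears.

Edge weights are similarity-type, per method: TM-scores verbatim where the
method emits them; for RMSD-reporting methods an approximate TM-score
TM = (L_aln/L̄) / (1 + (rmsd/d0(L̄))²) with d0(L) = 1.24(L−15)^⅓ − 1.8
(floored at 0.5 for very short chains), i.e. the canonical TM functional
with every residue deviation set to the reported RMSD and the mean domain
length as normalisation; for elastic-metric methods the reciprocal 1/d
(configurable).  Synthetic similarity methods use the score itself.

Consensus networks intersect the per-method edge sets at one threshold.
Because methods' weight scales differ, each method's weights are first
divided by that method's mean edge weight over its own network at the same
threshold and level, then averaged per edge.  The averaging population for
the mean is a genuine free choice; using the method's own network at the
consensus's threshold keeps the normalisation local to the comparison being
made.

## Network analysis

Distances are reciprocal-weight shortest paths (Dijkstra).  Degree is the
sum of incident weights over all nodes; closeness is the sum of reciprocal
distances within a node's component; betweenness uses Brandes' dependency
accumulation over unordered pairs, computed per component.  Path-length
ties are recognised within relative tolerance 1e-9 because lengths are
floating-point sums of reciprocals; with positive weights this only merges
genuinely equal-length path bundles.

Central folds are the top 30% per measure with boundary ties included
(deterministic and order-independent).  Peripheral folds are: bottom 30%
by closeness; at most one neighbour, by degree; zero betweenness, by
betweenness — the skewed empirical distributions of degree and betweenness
make fixed-rank bottom sets degenerate, hence the rule-based definitions.
Degree is ranked over all nodes; closeness and betweenness over connected
nodes pooled across components (recorded in output metadata).  Peripheral
sets exclude central members, keeping the two sets disjoint per measure.
Pivotal folds are those central under every measure in every network,
consensus included.

Louvain community detection runs on edge weights over connected nodes with
a fixed seed and 10 restarts, keeping the maximum-modularity partition
(Louvain is stochastic; restarts make the reported partition reproducible
and near-optimal — it attains the exhaustive-enumeration modularity maximum
on all two-clique test graphs up to 10 nodes).

Age analyses: |Δage| of every fold pair is binned by edge multiplicity
(0 = unconnected background, enumerated exhaustively — ~300k pairs at the
largest synthetic scale, no sampling needed).  Group age comparisons use
the two-sided Mann–Whitney U test, exact for small untied samples and
normal-approximated with tie correction otherwise; the central-versus-
peripheral report flags comparisons significant at α = 0.01 (configurable)
with the central mean older.  Comparisons with fewer than a configurable
minimum of folds per group (default 1; 5 in the validation suite, for
power) are reported as untested.

## Synthetic study conditions

Scores are drawn from truncated normals on [0, 1]: siblings N(0.60, 0.10),
unrelated N(0.25, 0.08), TM-score-like ranges; the distance method uses the
mirrored parameters.  Methods share a Gaussian-copula latent per pair
(correlation 0.6) with method-specific noise, so the same pair tends to
score high everywhere while each method keeps private noise.

Planted bridges are cross-fold domain pairs that score like *weak-to-
moderate* siblings: their draws map into the 2nd–60th percentile band of
the sibling distribution.  This matters: bridges are labelled "unrelated"
during calibration, and if they scored like top-tier siblings they would
dominate the unrelated tail and cap attainable posteriors below the
stringent levels — whereas real bridge alignments sit below typical
intra-fold scores.  Each bridge is visible to each method independently
with probability `method_agreement` (default 0.5), generating the
method-unique-edge phenomenon; 90% of bridges fall within one of five
planted communities (all-α, α/β, α+β, and the all-β class split into
sandwich-like and barrel-like halves).

Ages are uniform on [0, 1] except that a bridge seen by k methods
constrains its endpoints to |Δage| ≤ δ^(1+k) with δ the assortativity
budget (default 0.05): consensus bridges connect folds of nearly identical
age, method-unique bridges merely similar ones.  Bridged components share a
centre with per-fold offsets bounded by half the tightest incident
tolerance, reflected back into [0, 1] (reflection is contractive, so bounds
survive it); δ = 1 makes every constraint vacuous and all ages independent
uniforms, δ = 0 collapses a bridged component to a single age draw.

Three named conditions serve different analyses:

* the default (64 folds, 2–6 domains each, ~38k pairs) for pipeline runs
  and the central-age validation;
* `strong_community_spec` (60 folds × 5 domains, full method agreement,
  widely separated score populations) for community recovery — bridge
  carriers must stay well below sibling-pair counts or no posterior can
  reach 0.5;
* `age_study_spec` (768 folds × 2 domains, ~1.2M pairs, sparse bridges
  capped at two per fold) for the edge-multiplicity age gradient.  The cap
  is essential: per-edge constraints bound a connected component's age
  spread by δ × diameter, so a dense bridge graph would compress *all*
  bridged folds into one age neighbourhood and erase the uniform
  unconnected background.  At the default demo scale this compression is
  visible (the demo's multiplicity-bin medians are all tiny); meaningful
  gradient analyses use the sparse condition.

For the central-age validation, ages are planted against the pooled
percentile rank of all three centrality measures across the four method
networks.  Under uniform-random bridge placement the three peripheral rules
decouple (zero-betweenness nodes of a dense graph sit inside cliques;
bottom-closeness nodes of a fragmented graph are small-component members of
any degree), so a single-measure plant cannot drive all rules without also
simulating the hub-and-leaf topology of real fold networks — which the
generator deliberately does not attempt.

What passing these validations shows: the estimators recover structure they
are designed for, at realistic scales, under controlled noise.  What it
does not show: anything about the geometric fidelity of real alignment
scores, about SCOP annotation quality, or about the topology of the real
fold-space networks (the generator's bridge placement is random or
community-blocked, not preferential; its score distributions are smooth
parametric stand-ins).

## Coordinate QC

Domain quality filters mirror standard practice for alignment surveys:
drop structures with an ASTRAL aerospaci score below 0.4 (strictly less:
0.40 is retained), structures with only Cα atoms, and structures with a
chain break — consecutive Cα atoms strictly more than 4.3 Å apart, parsed
with Bio.PDB (first altloc, residue order as given).  Filtering is
idempotent and order-independent; missing aerospaci values are an error,
never a silent pass.  Sequence-identity filtering is treated as upstream
subset selection and not recomputed.

## Problem sizes and determinism

All validation suites run on one CPU in minutes: calibration convergence at
~10⁵ pairs × 10 seeds, community recovery at 60 folds × 10 seeds, the age
gradient at 768 folds × 10 seeds, the central-age calibration at 64 folds ×
20 seeds plus 200 label shuffles.  Every stochastic stage derives its
generator from one global seed through fixed purpose-keyed child seeds
(hierarchy, bridges, scores, ages, coordinates), so stages can be
regenerated independently and a fixed seed fixes every output bit for bit.
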