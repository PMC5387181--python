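# Methods

## Scope and model

neonet analyses weighted structural brain networks of the developing
(preterm/term neonatal) brain on a fixed 91-region parcellation.  Nodes
are grey-matter regions; an edge between regions *i* and *j* summarises
the white matter connecting them, with four weightings per connectome:

- **FS** — fraction of streamlines, `w_FS(i,j) = e_ij / Σ e_kl`, where
  `e_ij` is the streamline count and the denominator sums over all
  surviving unordered edges (each edge once).  The literature's
  double-index sum is ambiguous between counting each edge once or
  twice; either choice rescales FS globally by 2 and every
  normalised-weight analysis is invariant to it (tested), so the
  unordered convention was fixed and documented.
- **FA**, **NDI** — per-edge median fractional anisotropy / neurite
  density index, consumed as precomputed medians (computing medians
  along streamline trajectories is upstream tractography work, out of
  scope here).
- **1−ODI** (`ODI_C`) — fibre coherence.  ODI (dispersion) is what is
  stored; the coherence complement is computed at network-build time.

A **raw network** keeps edges with ≥ 5 streamlines; the FS denominator
is computed after this filter, since the raw network is defined as the
post-filter edge set.

## Topology measures

Geodesics use the `length = 1/weight` convention (unit lengths for
binary networks), isolated behind one function so alternatives such as
`−log w` are pluggable.  Conventions for degenerate cases:

- disconnected pairs contribute 0 to global efficiency (1/∞ = 0);
- characteristic path length averages finite distances only, so it
  stays finite on sparse thresholded graphs (disconnection is captured
  by efficiency, not by an infinite Lp);
- local efficiency of a node is the global efficiency of the subgraph
  induced on its neighbours (original weights); degree < 2 contributes 0;
- weighted clustering is the Onnela geometric-mean form with weights
  rescaled by the graph maximum; binary clustering is the triangle ratio;
- edge betweenness counts all co-minimal geodesics per node pair.
  Shortest paths and betweenness are delegated to scipy's Dijkstra and
  igraph's Brandes implementation respectively; both compare float path
  lengths exactly.  Structurally tied paths (identical sums of the same
  floats) tie exactly; accidental float ties have ~zero probability on
  continuous weights.  The test-suite oracle enumerates simple paths
  with a 1e-12 relative tie tolerance and agrees to 1e-9 on hundreds of
  random graphs.

## Density normalisation

Subjects differ in raw density (sparsity) and total strength, both of
which drive efficiency measures.  Three normalisations are provided:

1. **Cost-correction**: keep the `k = round(d·M)` edges with the most
   streamlines (M = 4095 possible edges), for every density `d` on the
   grid 0.05–0.50 in 0.01 steps (46 levels).  Rounding is half-up,
   keeping the achieved density within 1/M of target symmetrically.
   Ranking ties (equal counts) break by higher NDI, then lexicographic
   (i, j) — not prescribed by any source, chosen for determinism across
   runs and platforms.  Because one fixed ranking serves all densities,
   retained edge sets are nested along the grid.  The sweep is
   summarised per metric by **cost-integration** (the arithmetic mean
   over the grid), which refuses partial grids.  The grid's upper bound
   of 0.5 reflects the cohort's minimum raw density; the generator
   guarantees raw density ≥ 0.5 for every scan so the full sweep is
   always feasible.
2. **Normalised weights**: at each density, weights are divided by
   their sum (upper-triangle sum = 1), removing total-strength
   differences; metrics on these networks reflect pure weighted
   topology (rFS, rFA, rNDI, r(1−ODI)).
3. **Random equivalents**: Maslov–Sneppen double-edge swaps preserve
   every node's degree exactly; the original weight multiset is then
   permuted onto the rewired edges, so the strength distribution is
   preserved only approximately — the stated matching criteria are node
   count and degree distribution, and weight placement beyond that is a
   free choice made explicit here.  Graphs with no legal swap (e.g. a
   triangle, the unique graph on its degree sequence) are returned
   unchanged rather than erroring, which is what makes the null
   ensemble total.  Normalised path length α = Lp/⟨Lp_rand⟩ and
   clustering γ = Cp/⟨Cp_rand⟩ use 100 nulls by default (count not
   stated in the source literature; 100 gives ⟨·⟩ standard errors well
   below the effect sizes of interest).  The small-world coefficient
   defaults to the conventional σ = γ/α; the reciprocal α/γ form some
   reports print is available behind `printed_form=True` — we do not
   guess which was actually computed upstream.

## Core/local decomposition

At each density, edges are ranked by edge betweenness and the **core**
is the minimal prefix accounting for ≥ 50% of total betweenness; the
rest are **local** edges.  Betweenness ties are broken
lexicographically so the core is strictly minimal (removing its weakest
edge drops the share below the threshold); an alternative that includes
all boundary-tied edges is available (`include_boundary_ties=True`).
By default betweenness is computed with 1/count lengths from the
streamline counts — the quantity networks are thresholded and ranked by
— with binary and own-weight variants configurable, since the
weight/length convention of the original analysis is not stated.  An
all-tied betweenness vector (e.g. a complete graph, where every pair's
geodesic is its own edge) makes every edge core and flags the result.

## Minimum grid and edge-wise statistics

Each scan contributes a mask of its strongest 30% of connections by
streamline count (density 0.3, i.e. 1229 of 4095 edges); the **minimum
grid** is the intersection over scans — the backbone present in the
whole cohort.  Scans, not subjects, are the intersection unit when a
subject is scanned twice (the alternative — intersecting per-subject
unions — would admit edges absent from some sessions).

Within the grid, each edge's weight is associated with age at MRI (PMA
at scan) or with GA at birth by a **partial Spearman correlation**:

1. Covariate model: fixed effects sex (F=0, M=1), SGA, respiratory
   support, NEC (all 0/1) plus the *other* age variable (GA at birth
   when assessing maturation; age at MRI when assessing prematurity),
   with a subject-level random intercept for repeated scans, fit by
   REML.  Residuals are marginal (observed − fixed-effect fit).  With
   single scans per subject the model degenerates to OLS, applied in
   one vectorised pass over all edges (numerically identical to
   per-edge fits).  Constant covariate columns (e.g. no NEC case in a
   small cohort) are dropped as uninformative rather than allowed to
   make the design singular.
2. Both predictor and outcome are residualised (double
   residualisation); single residualisation of the outcome only is
   available behind a flag.  The mechanics of "partial Spearman
   controlled via LME" are not spelled out in the source literature;
   double residualisation is the standard partial-correlation
   construction.
3. Residuals are rank-correlated; p-values use the t approximation
   with the partial-correlation degrees of freedom n − 2 − k for k
   partialled covariates (a seeded permutation p is available).
4. Benjamini–Hochberg step-up at q = 0.05, with the family being
   exactly the grid's edges for one predictor and one weight kind — no
   correction across weight kinds, mirroring per-analysis reporting.

Relative (rFA/rNDI-style) edge weights for these analyses are taken at
the mask's own density 0.3, the one density the mask construction fixes.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not diffusion physics: no streamline geometry or image volumes are
simulated, and edge weights are drawn from explicit low-dimensional
models rather than tractography.  Defaults follow the published cohort
structure: 65 subjects, 8 scanned twice 3.5–8.7 weeks later, GA at
birth stratified 6/15/31/13 across extremely-preterm/very-preterm/
preterm/term bins (24–42 weeks), PMA at scan in 25–45 weeks, and
covariate prevalences SGA 29%, respiratory support 34%, NEC 11%,
twins 28%.

Edge model (one latent design per seed):

- each of the 4095 edges gets a long-tailed latent strength
  (lognormal, σ = 1.3); the top 54% by strength form an always-present
  **backbone** whose counts are ≥ 5, guaranteeing raw density ≥ 0.5;
- non-backbone edges appear with an age-dependent logistic probability
  (slope −0.17/week), so raw density falls with PMA; their counts are
  drawn so that a fraction lands under the 5-streamline filter,
  keeping the raw-network filter non-trivial.  Realised raw densities
  span ≈ 0.57–0.77, within the reported 0.55–0.88 band, and correlate
  with PMA at ρ ≈ −0.98;
- FA and NDI increase with PMA (0.008 and 0.012 per week), ODI
  increases (0.006/week) so coherence 1−ODI decreases; per-edge noise
  SD 0.03; all values clipped to (0, 1);
- the top 10% of edges by strength are the designed **core**, given
  elevated baseline NDI (0.45–0.65 vs 0.20–0.50) as strong early-
  maturing pathways; GA at birth modulates NDI only on the remaining
  **local** edges (+0.005/week-of-GA).  The elevated core baseline is
  what lets the relative-weight (rNDI) core/local dissociation appear:
  unit-sum normalisation divides by a total that grows with GA through
  the local edges, so core rNDI falls with GA while local rNDI rises;
- covariates add small NDI shifts (sex +0.008, SGA −0.010, respiratory
  support −0.008, NEC −0.012) so covariate control is testable.

Effect sizes are calibrated to the signs and rough magnitudes of the
published cohort-level correlations; exact ρ values depend on the
unreleased imaging data and are not reproduction targets.  All draws
descend from one `SeedSequence(config.seed)`, so cohorts are pure
functions of their configuration.

What passing tests show — and do not: recovery tests demonstrate that
the pipeline detects the *kind* of structure it is designed for under
a favourable, correctly-specified generative model with independent
Gaussian edge noise.  Real connectomes have spatially correlated
noise, motion artefacts, parcellation and tractography biases, and
non-linear age trajectories, none of which the generator emulates; the
tests validate the machinery, not the biology.

## Problem sizes in the test and acceptance runs

The validation suite uses the full 73-scan cohort for mask, grid and
recovery checks; 100 generator replicates for the age-trend study; 200
simulated 65-scan replicates (100 signal + 400 null edges) for FDR
calibration; 200 random ≤ 7-node graphs against brute-force metric
oracles; and a reduced 10-level density grid (step 0.05) for sweep-based
recovery demonstrations, chosen because cost-integration is a plain
mean and the 46-level grid adds resolution, not information, to a sign
check.

## Known limitations

- Strength preservation in random equivalents is approximate (weight
  multiset permutation), as discussed above.
- Mixed-model residualisation fits one model per edge when repeats are
  present; a full multivariate mixed model (shared variance components
  across edges) is not attempted.
- The betweenness core depends on the chosen length convention;
  results are reported for the count-based default.
- The generator's density and grid sizes bracket but do not exactly
  match the published cohort (grid ≈ 350–400 edges vs 505 reported);
  downstream checks are sign- and calibration-based, not tied to grid
  size.
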