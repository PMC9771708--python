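# Methods

This note documents the statistical machinery implemented in `ventnet`, the
defaults it ships with, and the choices made where the methods literature
leaves room.

## Input model

The unit of analysis is a binary site-by-species occurrence matrix.  A cell
of 1 records an observation; a cell of 0 means *not recorded*, never
"confirmed absent" — deep-sea survey effort is too uneven for true absences.
No imputation is performed anywhere.  Loading rejects duplicate identifiers,
non-binary cells, and empty rows or columns; blank cells may be read as
absences behind an explicit flag.  File order of sites and species is
preserved, and permutation-sensitive outputs (eigenvectors, dendrograms) are
always reported against identifiers, not positions.

## Similarity network and percolation threshold

Pairwise Sørensen dissimilarity is `D = (b+c)/(2a+b+c)`, computed
vectorised as `D = 1 − 2a/(r_i + r_j)`.  The network places an edge wherever
two sites share at least one species, weighted by `S = 1 − D`.  Pairs with
`S = 0` carry *no* edge: absence of shared species is no evidence of a
connection, and it is not an edge of weight zero.

The percolation threshold scan removes edges in descending dissimilarity
(ties removed together) and evaluates the Molloy–Reed ratio
`κ = ⟨k²⟩/⟨k⟩` over **all** nodes after each step; `D_p` is the
dissimilarity of the first removal at which `κ < 2`.  If the intact network
already sits below `κ = 2` the network is at percolation immediately and
`D_p` is the largest edge dissimilarity present; if `κ` never falls below 2,
`D_p = 1`.  Retention is strict (`D < D_p`): edges exactly at the threshold
are removed, consistent with the scan having reached them.  Isolated nodes
are always retained.  An alternative criterion — the smallest cutoff that
leaves a single connected component — is available
(`percolation_threshold(..., criterion="giant-component")`).

Betweenness centrality is computed on the thresholded network with edge cost
`1 − S`, so geodesics follow chains of high similarity; hop-count
betweenness is available (`weights="none"`) because the weighting convention
behind published per-site values is not fixed by the method itself.  Both
conventions are exposed; the package does not promise decimal agreement with
any particular published betweenness column.

## SIMPROF

Group-average (UPGMA) linkage is the default dendrogram; complete and single
linkage are options.  Agglomeration is delegated to
`scipy.cluster.hierarchy.linkage`, whose tie-handling is deterministic;
exact ties are measure-zero on real-valued Sørensen input.

For a node with ≥ 3 leaves, the similarity profile is the sorted vector of
the `n(n−1)/2` pairwise similarities.  The expected profile is the mean
sorted profile over `n_perm_expected = 1000` permutations in which each
species column is shuffled independently across the node's sites;
`n_perm_null = 999` further permutations give the null distribution of
`π = Σ_k |s_(k) − s̄_(k)|` and `p = (1 + #{π_null ≥ π_obs})/(1 + 999)`.
The published "1000 permutations" does not specify the expected/null split;
1000 + 999 with the +1 correction keeps the test exact.  Traversal is
top-down: a significant node (p ≤ α = 0.05) is opened, a non-significant
node terminates as a flat group.  Groups of fewer than three sites are
untestable (one pairwise similarity at most) and terminate as groups.  No
multiplicity correction is applied across the sequential tests — stopping is
hierarchical, which is the method's standard behaviour.  A single seeded RNG
stream is consumed in pre-order so a (matrix, tree, seed) triple is fully
reproducible.

## Bipartite modularity and cartography

The two-mode graph links each species to the sites where it occurs.  Sites
and species are co-assigned to modules by maximising the joint
Newman–Girvan modularity `M = Σ_s [l_s/L − (d_s/2L)²]`; this is the default
because ecological modules are expected to contain both node classes.
Barber's degree-constrained bipartite null
`M = Σ_s [l_s/L − d_s^site d_s^species / L²]` is available via
`null="bipartite"`; which null produced any given published partition is
generally not recoverable, so both are implemented and the joint form is the
default.

Maximisation is simulated annealing with the schedule: per temperature,
`f·N²` single-node reassignments and `f·N` collective proposals (merge of
two random modules, or a split seeded by random bisection and refined by a
short bounded greedy exchange over the module's members), each accepted with
probability `min(1, exp(ΔM/T))`; then `T ← c·T` with `c = 0.995` and
`f = 1`.  The initial temperature is calibrated from a 200-move probe so
that ≈ 95% of worsening single-node moves would be accepted at the start.
Termination: `T < 1e-6`, or early exit once the chain is *frozen* — ten
consecutive temperatures with no improvement of the best-seen `M` while at
most 2% of worsening proposals are being accepted.  The freeze condition
matters: a pure "no new best for ten temperatures" rule trips during the hot
random-walk phase, where new records become rare long before convergence.
Ten independent restarts are run by default and the best partition returned;
it is additionally floored by three deterministic baselines (all-singleton,
single-module, connected-components), so the reported `M` is never below
`0` and never below the trivial optima.  The inner loop is numba-compiled,
which keeps the published-style schedule affordable (~2 s per restart at
N ≈ 150 nodes).

Cartography: within-module degree z-score `z_i` uses the population
standard deviation over the module's members; modules whose members all
have equal internal degree give `z = 0`.  Participation is
`P_i = 1 − Σ_s (k_is/k_i)²`.  Role thresholds are `z = 2.5` and `P = 0.62`;
boundary values are assigned to the non-hub / non-connector side (strict
inequalities in the source taxonomy leave the boundary unassigned; closing
it downward is the conservative reading).  Nodes with `P = 0` are flagged
ultra-peripheral.  A species is endemic to a module when every site it links
to belongs to that module; sharing between module pairs is tabulated both by
the species' own module label ("outreach") and irrespective of it.

## Spatial drivers

Geodesics are haversine great-circle distances with Earth radius 6371.0 km.

dbMEM: the distance matrix is truncated at `t` (entries above `t` become
`4t`), Gower-centred, and eigendecomposed.  Eigenvalue positivity is judged
relative to the spectral magnitude (`λ > 1e-9 · max|λ|`) because the
spectrum scales with the squared truncation distance.  Retained eigenvectors
are re-centred (near-zero eigenvectors can rotate slightly with the exact
zero "constant" eigenvector) and scaled by `√λ`, with a deterministic sign
convention.  The default retention additionally requires Moran's I above its
null expectation `−1/(n−1)` under the within-threshold connectivity — the
standard dbMEM convention, which models positive spatial autocorrelation.
Retaining *all* positive-eigenvalue vectors (`retain="positive-eigenvalue"`)
is available, but at metacommunity sample sizes (n ≈ 36) it saturates the
variance-partition design matrix (n − m − 1 ≈ 1) and renders the adjusted-R²
decomposition meaningless, which is why it is not the default.

Thresholds: `t_broad` is the longest minimum-spanning-tree edge — the
smallest truncation keeping all sites connected.  `t_fine` is just below
(factor `1 − 1e-6`) the smallest distance connecting the focal region (by
default the Okinawa Trough; a set of region labels is accepted) to the rest,
so the fine basis treats that region as spatially self-contained.  By the
MST cut property `t_fine < t_broad` always holds.

Variance partitioning: the response is the set of positive-eigenvalue
principal-coordinate axes of the Sørensen dissimilarity (distance-based
RDA); negative-eigenvalue axes are dropped.  Each of the seven unions of
{environment, fine dbMEM, broad dbMEM} is fit by multivariate least squares
with intercept; `R²` is the explained share of the total (centred) sum of
squares, adjusted by Ezekiel's formula
`R²adj = 1 − (1−R²)(n−1)/(n−m−1)`; unique and shared fractions follow by
inclusion–exclusion.  Individual fractions may legitimately be negative; the
seven fractions sum to the full-model adjusted R², and with the residual to
1 (both held to 1e-9 in tests, and cross-checked against `vegan::varpart`
on a small dataset).  A union with `n − m − 1 ≤ 0` raises an
"over-parameterized" error.  Environment enters as standardized depth plus
dummy-coded tectonic setting.

Module membership is regressed (dummy-coded response) on environment plus
the broad basis; the constrained proportion is reported both raw and
Ezekiel-adjusted, since either convention can stand behind a published
percentage.  The companion one-way MANOVA uses module as the factor and
(depth, tectonic dummies, broad MEM scores) as responses, reporting Wilks'
Λ with Rao's F approximation for the responses jointly and per block.
Depth's spatial autocorrelation is reported via a distance-band Moran's I
permutation test before depth is offered as a predictor; nothing is dropped
automatically.

## Synthetic metacommunity generator

The generator plants: `B` modules of sites sharing a species pool (cell
probability `p_in` inside a block, `p_out` outside), connector species with
`p_in` in exactly two adjacent modules and nothing elsewhere, outlier sites
with ~5 species of which all but one are private, coordinates jittered
≤ 150 km around module centres ≥ 1000 km apart along an arc,
module-correlated depth (Normal with σ = 150 m, truncated positive; outliers
markedly shallow), and per-module tectonic settings with 10% flips.  Empty
rows/columns are redrawn.  Each generated object draws from an RNG stream
keyed by (seed, object-name), so outputs are bit-reproducible and adding a
new output never perturbs existing ones.

The *paperlike* preset fixes study-scale conditions: three modules with
(12, 14, 8) sites and (50, 30, 21) pool species, 8 connectors, 2 outliers —
36 sites and ≈ 117 species — with `p_in = 0.35`, `p_out = 0.01`, chosen once
to land mean per-site richness near 15, the scale typical of curated vent
occurrence data.

What the generator does not emulate: uneven survey effort, taxonomic error,
within-module spatial gradients, and dispersal-driven distance decay beyond
the block structure.  Tests passing on synthetic data therefore validate the
algorithms' behaviour under the assumed model, not robustness to survey
artefacts in field data.

## Problem sizes and runtime

The test suite runs at deliberately modest sizes: brute-force betweenness
oracles on ≤ 7-node graphs (20 seeded instances), exhaustive-partition
modularity oracles on 8-node graphs (Bell number 4140), planted-recovery at
3 × 8 sites × 20 species/module over 10 seeds, SIMPROF type-I calibration on
200 null 12 × 25 matrices with 200 + 199 permutations, and a full pipeline
pass on the 36-site preset.  `scripts/acceptance.py` runs the paperlike
preset at the published permutation (1000 + 999) and restart (10) settings
in roughly half a minute on one CPU.

## Known limitations

- Percolation and SIMPROF results on presence-only data inherit the
  sampling biases of the occurrence records; a poorly surveyed site is
  indistinguishable from a genuinely species-poor one.
- The annealer is stochastic; module *counts* and compositions are stable
  across restarts on well-separated data, but decimal values of z and P
  depend on the found partition.
- dbMEM treats geodesic proximity as the only spatial structure; ocean
  currents and topographic barriers that decouple nearby sites are invisible
  to it.
- Variance partitioning at n ≈ 36 sites has little adjusted-R² headroom;
  fractions for individual predictor sets carry wide sampling error even
  when the total is stable.
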