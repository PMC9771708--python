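# ventnet

Species-assemblage network analysis for spatially fragmented metacommunities,
built around the hydrothermal-vent fields of the Northwest Pacific
(Okinawa Trough, Izu-Bonin and Mariana arcs and back-arc basins).

Hydrothermal vents are island-like habitat patches connected only by larval
dispersal.  Given a binary site-by-species occurrence matrix and per-site
metadata (coordinates, depth, tectonic setting), `ventnet` quantifies the
structure of that connectivity with two complementary networks and a set of
driver analyses:

1. **Similarity network** — sites as nodes, edges weighted by Sørensen
   similarity `S = 2a / (2a + b + c)` (`a` shared species, `b`, `c` unique to
   either site).  Weak links are pruned at the network's *percolation
   threshold*: edges are removed in descending dissimilarity until the
   Molloy–Reed ratio `⟨k²⟩/⟨k⟩` drops below 2 (the point where a random graph
   with this degree sequence loses its giant component).  Node importance is
   scored by betweenness centrality on dissimilarity-weighted geodesics.
2. **SIMPROF clustering** — UPGMA dendrogram on Sørensen dissimilarities with
   similarity-profile permutation tests (`π = Σ_k |s_(k) − s̄_(k)|`, 1000
   permutations, α = 0.05) so that clustering stops at groups with no
   internal assemblage structure.
3. **Bipartite cartography** — the two-mode site–species graph is partitioned
   by simulated-annealing maximisation of modularity
   `M = Σ_s [l_s/L − (d_s/2L)²]`; every node gets a within-module degree
   z-score `z_i`, a participation coefficient `P_i = 1 − Σ_s (k_is/k_i)²`,
   and a cartographic role (peripheral / module hub / connector / network
   hub, thresholds z = 2.5 and P = 0.62), plus per-module endemism and
   species-sharing summaries.
4. **Spatial & environmental drivers** — distance-based Moran's Eigenvector
   Maps (dbMEM) at a fine and a broad truncation scale, variance partitioning
   of β-diversity (distance-based RDA with Ezekiel-adjusted R²) over
   {environment, fine dbMEM, broad dbMEM}, and redundancy/MANOVA analysis of
   module membership.

A synthetic-metacommunity generator with planted module structure, connector
species, outlier sites and module-correlated covariates makes every stage
testable end-to-end without downloading anything; the published per-site
metadata table (36 vent fields) is bundled for the spatial computations.

## Worked example

Generate a study-scale synthetic metacommunity (36 sites, 117 species, three
planted sub-regions plus two outliers) and run the stages:

```bash
$ ventnet synth --seed 1 --out demo
wrote 36 sites x 117 species to demo

$ ventnet simnet --matrix demo/presence_matrix.csv --out demo/simnet
percolation threshold D_p = 0.5172

$ ventnet simprof --matrix demo/presence_matrix.csv --seed 42 --out demo/simprof
5 SIMPROF groups at alpha=0.05

$ ventnet modules --matrix demo/presence_matrix.csv --seed 42 --restarts 5 --out demo/modules
11 modules, modularity M = 0.5031

$ ventnet drivers --matrix demo/presence_matrix.csv --meta demo/site_metadata.csv \
      --okinawa-region basin-1 --out demo/drivers
t_fine=1165.7 km t_broad=1165.7 km total explained=0.319
```

Reading the numbers: the similarity network of this synthetic region
fragments at a Sørensen dissimilarity of 0.52 — pairs less similar than that
are "weak" links whose removal breaks the giant component.  SIMPROF finds 5
statistically distinct assemblage groups.  The bipartite partition reaches a
modularity of 0.50; of its 11 modules, the large ones carry the three planted
sub-regions (plus outliers), while the remainder are small species-only
modules of scattered low-prevalence species.  The two dbMEM truncations
differ only marginally in kilometres (the fine threshold sits just below the
distance that connects the first basin to the rest, which here is also the
longest minimum-spanning-tree edge), but the fine basis treats that basin as
spatially decoupled; environment plus space explain 32% of the assemblage
variance under this generator's noise level.  Full per-site tables, GraphML
networks and CSV summaries are written to the output directories, and
`ventnet run --config run.yaml` executes all stages in one pass with a JSON
run manifest.

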