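# Methods

## The model

`patchconn` models structural habitat connectivity under a functional
assumption: organisms (here, grassland plants via seed or pollen) can move
between two habitat patches if and only if the minimum edge-to-edge
Euclidean distance between the polygons is at most a dispersal threshold
`d`.  For each `d` the patch mosaic becomes an undirected, unweighted graph;
all indices are computed on that graph.  The threshold comparison is
inclusive (`distance <= d`): only links *exceeding* the threshold are
removed.  The default threshold set {2, 20, 44, 100, 1000} m spans poorly
dispersed species (a few meters), typical abiotic dispersal (~44 m),
well-dispersed species (~100 m) and pollen movement (~1000 m).

Edge-to-edge distance (not centroid distance) is the default convention:
centroid distance would disconnect large adjacent patches whose boundaries
touch.  A `method="centroid"` switch exists for comparison.  Patches that
touch or overlap get distance 0 and are linked at every threshold, but they
are never merged — the source map's patch delineation is preserved.
Distances are computed once at the largest threshold of interest (an STR
packed R-tree prunes far-apart pairs) and reused for every smaller
threshold, which is valid because smaller thresholds only remove links.

## Indices

With patch areas `a_i` (internally m², reported in ha) and shortest-path
link counts `nl_ij`:

- **NL, NC** — link and component counts; higher NL and lower NC mean a
  better-connected system.
- **Area-covering component count** — the smallest number of largest
  components whose summed area *strictly* exceeds a fraction `p` (default
  0.5) of total habitat area.  When patch sizes are strongly right-skewed,
  NC alone misleads: thousands of tiny components can coexist with one
  component holding most of the habitat.  Ties in component area are broken
  by component index, deterministically.
- **IIC** — `Σ_ij a_i a_j / (1 + nl_ij)` over ordered pairs including
  `i = j`; unreachable pairs contribute exactly 0 (no capped penalty).  The
  numerator (ha²) is primary; dividing by `A_L²` is optional because every
  downstream quantity is a ratio of numerators and `A_L` cancels.  Supplying
  `A_L` smaller than the habitat area triggers a warning, not an error.

## Importance and its partition

`dIIC_k = 100·(IIC − IIC(G−k))/IIC` where `G−k` removes patch k and its
links.  It is computed from pair terms, not by brute-force recomputation:

- `intra_k = 100·a_k²/IICnum`
- `flux_k = 100·2·Σ_{j≠k} a_k a_j/(1+nl_kj)/IICnum`
- `connector_k = 100·Σ_{i,j≠k} a_i a_j [1/(1+nl_ij) − 1/(1+nl'_ij)]/IICnum`

with `nl'` the link counts after removal (pairs severed entirely contribute
their whole original term).  The three fractions sum to dIIC exactly; the
test suite verifies the identity and the equivalence with a from-scratch
removal oracle at 1e-9 relative tolerance on a random-graph suite.

Ranking is by descending dIIC with ties broken by descending area and then
ascending id, so outputs are reproducible.  `normalized_rank` is
`dIIC_k / max_k dIIC`, mapping importance onto [0, 1]; the literature's
exact normalization convention varies, and this choice keeps the ordering
of dIIC while anchoring the most important patch at 1.

### Computational strategy for connector

Removing k only changes `nl_ij` for pairs whose **every** shortest path
passes through k.  Three exact reductions make the node-removal sweep
feasible on thousands of patches without per-node whole-graph searches:

1. *Neighborhood test.*  Any shortest path with interior node k steps
   h1–k–h2 through neighbors at mutual link distance 2.  If every such
   neighbor pair has a second common neighbor (an entry of A² greater
   than 1), every path through k reroutes at equal length, so
   `connector_k = 0` with no further work.  In dense graphs this eliminates
   most nodes.
2. *Path-count factorization.*  All-pairs shortest-path counts `sigma` are
   computed once per component by level-wise recursion
   (`sigma_ij = Σ_{h∈N(j), nl_ih = nl_ij−1} sigma_ih`).  A pair (i, j) is
   affected by k iff `nl_ik + nl_kj = nl_ij` and
   `sigma_ik·sigma_kj = sigma_ij`.  Counts are held as float64 and the
   equality allows 1e-9 relative slack: accumulated rounding stays several
   orders of magnitude below it, and a false positive merely triggers a
   redundant search while the distances used for the result are always
   recomputed exactly.
3. *Severance shortcut.*  Affected pairs that land in different connected
   components of `G−k` lose their whole term; only rows with affected pairs
   inside a surviving component are re-searched by BFS.

Unreachable pairs are represented explicitly (`None`/masked), never as a
large finite distance.

## Fraction profile

For each patch with `dIIC > 0`, the three fractions are recast as shares of
that patch's own dIIC (summing to 100 %); the unweighted mean share per
threshold is reported.  Patches with `dIIC = 0` have no defined shares and
are excluded (possible only in degenerate equal-term cases).  On skewed
landscapes the profile shifts from intra-dominance at 2 m (no links — the
index reduces to patch area) to flux-dominance at 1000 m, with connector
peaking at intermediate thresholds.

## Prioritization and per-capita analysis

`top_fraction` selects the `ceil(q·n)` highest-dIIC patches (default
q = 0.2) under the deterministic rank.  The correlation matrix is Spearman
rho with average ranks for ties and two-sided p-values among area, dIIC and
the three fractions; entries with `p >= alpha` (default 0.05) or undefined
(constant column) are masked as absent in the significance-masked view,
while the full matrix stays available.

District grassland area is assigned by geometric intersection — a patch
straddling a boundary credits each district with its exact share, so
district areas are additive to machine precision.  Districts with zero
population are flagged undefined and excluded from the density relation,
which is reported as Spearman rho plus an OLS slope on log10 values
(descriptive only; no inferential model).

## Synthetic landscape

The generator emulates the statistical structure of a ~300 km² Central
European city's grassland mosaic; it makes the full pipeline testable with
no external data.  Defaults, chosen once from the emulated system:

| parameter | default | why |
|---|---|---|
| n_patches | 2,442 | the emulated mosaic's patch count |
| extent | 20 × 20 km | slightly above the city footprint so non-overlapping square placement of ~12,000 ha is feasible |
| size law | lognormal, median 0.4 ha, sigma 2.3 | matches the printed median and places the maximum order statistic near the printed 1,179 ha maximum |
| truncation | [0.003, 1,179] ha | printed min/max; the floor doubles as the map-resolution floor |
| barrier | 200-m horizontal strip | a river wide enough to sever all plant-dispersal links (every `d <= 100` m) while pollen-scale links (1000 m) can cross |
| districts | 6×6 grid, exponential radial density scaled to [83.1, 14,025] people/km² | the emulated city's printed density extremes |
| clustering | 0 (uniform placement) | no clustering statistics are available for the emulated mosaic; the knob exists but has no data-derived default |

Sizes come from the truncated lognormal by inverse-CDF sampling (exact
truncation, deterministic per seed).  Placement is rejection sampling,
largest patch first, against a uniform-grid spatial hash; overlap with
another patch, the barrier strip or the extent boundary rejects a
candidate, and 1,000 failed attempts for one patch raise an error rather
than silently overlapping.  Patch shapes are axis-aligned squares: no index
depends on shape, only on areas and edge-to-edge distances.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real patches are irregular and elongated (road
verges), spatially clustered along street networks, and their sizes are
spatially autocorrelated (large peripheral meadows beget large neighbors).
One measurable consequence: on the uniform default landscape the Spearman
correlation between patch area and dIIC dips to ~0.78 at the 100-m
threshold (it exceeds 0.89 at 2, 20, 44 and 1000 m), because uniform
placement puts the 100-m graph in a percolation regime where a small
patch's cluster membership — and hence its flux — is spatially random.  In
the real mosaic's clustered geometry the area–importance correlation stays
high at every threshold.

## Numerical choices

- Areas m² internally, ha in all outputs (1 ha = 10⁴ m²); IIC numerators in
  ha².
- Conefor-style node (`id TAB area`) and connection (`id TAB id TAB dist`)
  files carry 8 significant digits so a write/read cycle preserves values
  to better than 1e-6 relative.
- GeoJSON output keys are sorted so reruns are byte-identical.
- Geometry repair uses `make_valid` (covered region preserved; stray
  lower-dimensional pieces discarded); clipping is by intersection with the
  boundary, dropping patches that fall entirely outside.
- Without a CRS library, geographic coordinates are refused only when the
  file *declares* a geographic CRS; RFC 7946 GeoJSON carries no CRS member,
  so callers are responsible for supplying projected data in meters.
- The `sweep` report asserts NL monotone non-decreasing and NC monotone
  non-increasing across thresholds at report time — a cheap end-to-end
  sanity check that the edge list and pruning are consistent.

## Problem sizes

The default test and reproduction runs use the full 2,442-patch landscape
for the threshold sweep (the 1000-m importance table is the dominant cost,
a few minutes on one CPU) and 100 random graphs of up to 60 nodes for the
oracle-equivalence suites.

## Known limitations

- Binary threshold graphs only; no probability-weighted connectivity (PC
  index), betweenness or circuit-theory metrics.
- No CRS reprojection; inputs must already be projected in meters.
- Shapefile input is not supported; convert to GeoJSON first.
- The per-capita analysis is descriptive (correlation and slope), not an
  inferential model of the density–greenery relation.
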