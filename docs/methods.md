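# Methods

This note documents the models, conventions and numerical choices behind
`circuitshift`, and what the synthetic test landscape does and does not
establish about behaviour on real data.

## Suitability modelling

Occurrence records are thinned to one presence per grid cell (row-major
deterministic order) and complemented with pseudo-absences drawn uniformly
without replacement from non-presence cells, default three per presence.
No exclusion buffer is applied around presences: background points may sit
in cells adjacent to presences.

Cross-validation uses spatial blocking: the extent is tessellated with
hexagons sized so that roughly `n_blocks` (default 40) hexes tile it, and
each occupied hexagon is allocated uniformly at random to one of
`n_folds` (default 5) folds. All records of a block share its fold, which
keeps evaluation folds geographically separated and limits the optimism
that spatial autocorrelation induces in random splits. Block-to-fold
allocation is uniform rather than balanced; with ~40 occupied blocks and
5 folds an empty fold is possible in principle, and such folds are simply
skipped during ensemble fitting.

The native learner is a binomial GLM with logit link, linear plus
optional squared terms, no interactions, fitted by iteratively reweighted
least squares (convergence: log-likelihood change < 1e-8 or 100 sweeps).
The normal equations are solved by least squares so rank-deficient
designs (e.g. a constant predictor) degrade gracefully instead of
erroring. Perfect separation is detected from the fitted probabilities
(every presence above 0.99 and every absence below 0.01); separated or
non-converged fits are refitted with a ridge penalty of 1e-6 and flagged.
Other learner families (random forest, MaxEnt-style models, FDA) can be
plugged in through the `FittedLearner` contract — a layer-name list and a
`predict` map to probabilities — but are deliberately not bundled: they
are standard library components, not part of this package's contribution.

Evaluation reports ROC-AUC in the rank (Mann–Whitney) formulation with
mid-rank tie correction, and TSS = max over observed prediction
thresholds of (sensitivity + specificity − 1), with "presence" voted when
probability ≥ threshold (ties at the threshold vote presence). Members
with ROC-AUC ≥ 0.70 are retained; the committee average is the fraction
of retained members voting presence after binarising each at its own
TSS-maximising threshold, so committee outputs live on the lattice
{0, 1/m, …, 1}. A TSS-weighted mean ensemble is available as an
alternative. In the orchestrated pipeline, if no member clears the
retention bar the single best member is kept so projection stays defined;
the library-level ensemble functions instead raise, since silently empty
ensembles are an analysis error.

Projection applies the ensemble to a scenario's predictor stack (climate
layers vary by scenario; distance-to-feature, topographic position and
landcover are held fixed). Extrapolation is flagged by an in-range count:
per cell, the number of climate predictors whose scenario value lies
inside the training min–max range. The continuous environmental
similarity statistic is intentionally not implemented; the count map is
the variant used downstream.

## Predictor preparation

* **Distance to features** is the shortest-path distance on the
  8-neighbour lattice (orthogonal step = cell size, diagonal = √2 ×
  cell size), computed by a two-pass chamfer sweep, which is exact on an
  obstacle-free grid; a Dijkstra oracle in the test suite confirms
  equivalence. Euclidean distance is deliberately not used — the
  eight-direction metric is the one raster GIS distance tools implement.
* **Topographic position index** is cell elevation minus the mean of a
  (2r+1)² focal window, truncated (not padded) at edges, computed with
  summed-area tables.
* **Aggregation** to coarser resolution takes block means (continuous) or
  block modes (categorical, smallest code wins ties); non-divisible
  dimensions are padded with nodata and nodata cells are excluded from
  block statistics.
* **Collinearity screening** is a greedy scan in a caller-supplied
  priority order (the ecological-preference ranking): a layer is kept iff
  its absolute Pearson correlation with every already-kept layer is
  ≤ 0.70, computed on listwise-complete cells. Listwise rather than
  pairwise completion was chosen for a single, consistent cell set across
  all correlations.

## Resistance transform

`R(h) = 100 − 99·(1 − e^(−c·h)) / (1 − e^(−c))` with suitability
`h ∈ [0, 1]` and exponent magnitude `c > 0`. The transform is exact at the
endpoints (R(1) = 1, R(0) = 100), strictly decreasing in `h`, pointwise
non-increasing in `c` at fixed `h`, and approaches the linear map
`100 − 99·h` as `c → 0`. The routine exponent set is
{0.25, 0.5, 1, 2, 4, 8, 16, 32}: small `c` keeps resistance high until
suitability is near 1 (species reluctant to leave suitable habitat);
large `c` collapses resistance quickly (vagile species). The [1, 100]
range is a convention, not a calibration; no telemetry or genetic
calibration is attempted.

## Circuit solver

Valid cells are nodes; 8-neighbour pairs carry conductance
`(1/Rᵢ + 1/Rⱼ)/2`, divided by √2 for diagonals — the standard raster
circuit-model convention. For one source/target pair, one unit of current
is injected and withdrawn and the graph-Laplacian system is solved; the
singular system is grounded at one node (sparse LU on the reduced
matrix), and because currents are invariant to the grounding choice a
single factorisation is reused for all pairs of a terminal set — 300
triangular solves instead of 300 factorisations. Per-cell current is half
the sum of absolute incident edge currents, with source and target set to
the injected unit, so a straight series chain reads 1.0 at every cell.
Correctness is pinned by tests: equivalence with a dense minimum-norm
oracle to 1e-8 on fixtures up to 12×12, Kirchhoff conservation < 1e-8 at
non-terminal nodes, reciprocity, Rayleigh monotonicity, and invariance of
currents under global resistance rescaling.

Omnidirectional maps use `n` terminals (default 25 → 300 pairs) placed at
equal perimeter-arc spacing from a seeded random rotational offset on the
outermost ring of the **buffered** raster. The buffer, of width
`ceil(fraction × max(rows, cols))` cells (fraction default 0.20), is
filled by sampling with replacement from the core's own resistance
distribution, which keeps node-adjacency artefacts outside the study area
without biasing resistance. The accumulated map is divided by the map of
an all-ones resistance raster with identical shape and terminals (cells
with null current below 1e-12 become nodata); the null raster is uniform
everywhere, buffer included. After normalisation the buffer is cropped.

## Scenario standardisation and the network

Species maps are stacked by cellwise summation (nodata propagates). Each
scenario is standardised by the reference scenario's mean and standard
deviation with **population** (N) denominators, so the reference
standardises to mean 0, sd 1 exactly — the property the acceptance script
verifies. Summary statistics use population moments; kurtosis is reported
as excess kurtosis (normal = 0). Inter-scenario agreement is Pearson
correlation over jointly valid cells.

The top-decile mask selects exactly `ceil(0.1 · N)` valid cells — the
highest-valued, with ties broken by row-major order — rather than
thresholding at a percentile value, so every scenario's mask covers the
same amount of space even on heavily tied surfaces. Masks are computed on
core-extent cells only (the buffer is cropped before any decile logic).
Classification over the three scenario masks: membership in all three →
permanent; current & 2050 only, or 2050 & 2090 only → stepping stones
(retained regardless of adjacency to permanent cells); any single period,
or current & 2090 without 2050 → impermanent and excluded; none → outside.

## Zonal reporting

Areas are cell counts × cell area in hectares; zones are pre-rasterised,
so no polygon clipping is performed. Zone ranking is dense (ties share a
rank, the next distinct proportion takes the next rank). Conservation is
exact in cell counts: zone-table and landcover-table totals equal the
network area, and the test suite asserts it.

## Synthetic landscapes

The generators produce the statistical structure the analysis assumes:
Gaussian-blurred white noise plus a north–south linear gradient for
climate (autocorrelation range ≈ one tenth of the short grid side);
additive per-layer scenario shifts (default 1.5 units per scenario step
in the pipeline) emulating progressive warming; equal-frequency
thresholded smooth fields for clumped landcover and for blob-shaped
protection masks; Bresenham polylines spanning the grid for linear
features; Voronoi partitions for zones; and presences sampled without
replacement with probability proportional to a known logistic model, at
cell centres. All generators are bit-reproducible under a fixed seed.

What they do **not** emulate: anisotropic or long-range climate
structure, realistic landcover class composition, observation bias in
occurrence records (records are an unbiased sample of the true
suitability surface), coastline/nodata geometry, or realistic
prevalences. Passing tests therefore demonstrate that the machinery is
correct and recovers known structure under its own assumptions — not that
any particular real landscape's numbers would be reproduced.

## Orchestration, sizes and determinism

The pipeline runs five stages (sdm → resistance → circuit → network →
zonal) from a validated plan; the full design enumerates one solver run
per species × scenario (15 × 3 = 45) with C(25,2) = 300 pairwise solves
each. A single master seed expands into per-stage, per-species sub-seeds
via `SeedSequence([master, crc32(stage), index])`, all below 2³¹, so any
stage can be rerun in isolation. A JSON manifest records the seed, the
completed stages and a SHA-256 checksum per output file; reruns with the
same seeds are byte-identical, and a failed stage aborts with the stage
named while retaining earlier outputs.

Demonstration runs and the test suite use compact problem sizes (grids of
28–64 cells per side, 2–3 species, 6–25 terminals) chosen so the full
suite and pipeline execute in seconds while still exercising every code
path at realistic parameter settings; all defaults (25 nodes, 20% buffer,
ratio 3, ROC 0.70, decile 0.9) match the full-scale design.

## Known limitations

* Only the logistic learner ships; ensemble diversity in practice comes
  from fold-wise refits, not model families.
* The committee tie rule (probability exactly at threshold votes
  presence) and the ≥ 0.70 ROC retention boundary are conventions where
  common practice is ambiguous; both are explicit and tested.
* The solver targets lattices of up to roughly 10⁵ nodes on one CPU
  (sparse LU); national-scale hectare grids would need an iterative
  preconditioned solver, which is out of scope.
* Hexagonal blocking assigns blocks to folds uniformly at random, not by
  balanced allocation; fold sizes can be uneven at small record counts.
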