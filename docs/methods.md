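# Methods

## Colour space

A fragment's colour is its N-channel intensity profile after background
subtraction and per-channel max scaling, L2-normalized onto the
nonnegative orthant of the unit hypersphere; the pre-normalization
Euclidean norm is kept as the fragment's *magnitude* (brightness on a 0-1
scale after max scaling). Hue similarity is plain Euclidean distance `d`;
the maximum distance between two nonnegative unit vectors is √2, which
puts the working threshold Th(d) ≈ 0.2 at about 14% of the full scale.

L2 was chosen as the normalization: "vector-normalized" conventionally
means unit Euclidean norm, and the Th(d) scale is consistent with it. L1
(simplex) normalization is available as a config switch
(`vector_normalize(..., norm="l1")`) for users who prefer compositional
coordinates; all downstream machinery is norm-agnostic.

Cluster centroids are magnitude-weighted means of member vectors and are
deliberately **not** re-projected onto the sphere: centroid update is
position averaging, and point-to-centroid distances use the raw mean
(whose norm is ≤ 1). All-zero vectors are representable (magnitude 0) so
quality control can drop them explicitly instead of crashing.

## Detector linearity correction

Hybrid photon-counting detectors undercount at high flux. The correction
maps measured intensity x to true intensity with

    y = a·x + b·(e^{c·x} − 1),

which fixes 0 and is strictly increasing for a > 0, b, c ≥ 0. Reference
coefficients for the hardware the defaults were derived on are
a = 0.9838, b = 1.1044, c = 0.001 with a saturation cutoff of 7000
counts; voxels above the cutoff are set to NaN and excluded from every
downstream mean. `fit_linearity` estimates the coefficients from a
laser-power series: per-pixel straight-line fits over the trusted
low-power range extrapolate predicted (true) intensities at all powers,
and the pooled (measured, predicted) pairs are fit by least squares.
Because even the "linear" range carries residual nonlinearity, the slopes
are re-estimated from corrected values and the curve re-fit (three
rounds), which removes most of the bias in (a, b, c); recovery on
synthetic detectors is within 2%. One coefficient triple is fitted per
detector (pooled pixels), not per pixel.

## Spectral unmixing

Unmixing is solved independently per excitation group, mirroring the
acquisition scheme (e.g. three channels at 405 nm, two at 488 nm, two at
552 nm); cross-laser bleed-through is assumed zero. Each fluorophore's
reference column is its mean background-subtracted foreground intensity
per in-group channel, L1-normalized. Foreground is the brightest 10% of
voxels by rank (configurable percentile); background is the per-channel
median of the remaining voxels. Per voxel, `M·u ≈ s` is solved by
unconstrained least squares with negative abundances clipped to zero
(default) or by NNLS (`method="nnls"`); for the square systems produced by
the group layout, clipping is cheap and matches NNLS except at voxels
dominated by noise. NaN (saturated) voxels propagate to all fluorophores
of their group.

## Traces and fragments

SWC (7-column, '#' comments) is the interchange format; each connected
component becomes one trace. Fragments are maximal unbranched runs:
splitting duplicates branch points as endpoints of every incident
fragment, so fragment edges partition the tree's non-soma edges exactly.
Soma samples (SWC type 1) are excluded — soma signals exceed the
detectors' linear range and their hue is unreliable.

A fragment's voxel footprint is the union of spheres (per-point radius,
minimum one voxel across) along the polyline, with coordinates in µm
mapped through the voxel size; channel means are taken over that set,
excluding NaNs. Arc-length subdivision cuts consecutive pieces of the
requested length; a trailing remainder shorter than half a piece is merged
into the previous piece, otherwise kept. Point recentring (for traces that
ride a neurite's edge) iterates a local intensity-centroid step on the
channel-max image, with total displacement capped at the search radius.

## Quality control

Stage order: channel S/N screen → minimum length → minimum brightness →
colour-change splitting → final colour vectors. Defaults: S/N ≥ 2.5
computed over the 80th-100th percentile band of fragment intensities
against the background median (the source material gives both 2.5 and a
stricter 3.0; 2.5 is the default, configurable); minimum length and
minimum magnitude are determined from the data by default, with ~5 µm and
~0.1 the typical outcomes on 7-colour cortical dendrites; colour-change
split at d > 0.3 between adjacent minimum-length pieces.

The minimum length is the smallest grid value whose sub-fragment-to-parent
colour distances have median ≤ 0.1 (median chosen for robustness over an
unstated aggregate; configurable). The minimum magnitude is the smallest
cutoff at which fewer than 5% of minimum-length pieces are "inaccurate"
(d > 0.2 from their parent), with piece magnitudes expressed relative to
the brightest piece so the cutoff lives on the same 0-1 scale as final
magnitudes. Sub-minimum pieces produced by colour splitting are removed by
a second pass of the length filter, so every surviving vector satisfies
both thresholds.

Dropped channels shrink the vector dimension rather than zero-filling
(zero-filled dead channels would distort distances). The per-channel max
used in the final scaling is taken over the analysed fragment set of the
whole dataset, not per image, so jointly processed multi-volume datasets
share one colour scale. The analyses that compare colours within a
fragment family (length, brightness, splitting) subtract the global
per-channel median as background first; the shared max scaling cancels
within a family and is omitted there.

## dCrawler

Point-driven crawl in input order (the narration "the first data point
will be the first cluster" fixes the seed; a descending-magnitude order is
available as an option for users who want bright, reliable seeds).
Centroids update incrementally after every accretion. The adjust phase
recomputes centroids from the incoming assignment before the first
reassignment — the preceding merge may have evicted points without
updating survivors' centroids — then iterates
reassign-to-nearest/recompute to a fixed point (cap 100 iterations).
Merge fuses the closest centroid pair first and repeats while any pair is
within the merge threshold; eviction afterwards compares against the
undecayed Th(d). Convergence is exact equality of consecutive assignment
vectors with no unassigned points; from loop 21 the merge threshold decays
by 0.99 per loop, so termination is guaranteed (hard cap 1000 loops). At
convergence every point is within Th(d) of its centroid and centroids are
pairwise separated beyond the final merge threshold — both are asserted in
the test suite over random datasets. Equidistant ties go to the lower
cluster id, making runs deterministic for a fixed input order.

## Evaluation

Per-neuron confusion counts are fragment-level (not length-weighted,
matching the fragment-level definition; a length-weighted variant would be
a straightforward extension): the best cluster for a neuron is the one
containing most of its fragments (ties to the lower cluster id), and
F1 = 2PR/(P+R) with 0 where undefined. The Th(d) scan uses a uniform grid
(default step 0.025 over 0.05-1.0) with ties to the smaller threshold.
"% reconstructed" rasterizes ground-truth and predicted traces on a voxel
grid, dilates the predictions (default 10 px) to forgive small
misalignments, and reports 100·|GT ∩ dilated(pred)|/|GT|.

## Labelling simulations

Copy numbers per cell and colour follow Poisson(λ) truncated at 50.
The default sampler ("quota") fits the truncated pmf to the cohort size —
each copy number receives a largest-remainder-rounded quota of cells — and
shuffles the assignment independently per channel; this pins the
per-channel composition exactly, which matters in small cohorts.
Independent per-cell Poisson draws are available as `sampling="poisson"`;
the two agree in distribution for large cohorts. Cells with zero copies of
every colour are unlabelled and invisible, so they are replaced by
labelled rows from fresh draws; at λ = 2 over 7 channels the all-zero
probability is e⁻¹⁴ and this choice is numerically irrelevant, but it
matters at λ ≤ 0.2. Expression level equals copy count (no per-copy
brightness variance).

*Percent discriminable* is the fraction of unordered pairs with
d > Th(d), computed with chunked matrix products (no O(n²) memory).
*Percent unique* runs Monte-Carlo cohorts (default 200) and reports the
mean and SD of the per-cohort fraction of cells with no neighbour within
Th(d). The *noise model* perturbs each normalized vector with per-channel
Gaussian noise (clipped at 0, re-normalized), sets Th(d) to the 95th
percentile of noisy-to-true distances, and scores the true vectors at that
threshold. Noise is injected on the normalized vector (not the raw
counts); with the derived-threshold rule the alternative mainly rescales
Th(d) and the reported discriminability moves by well under a point at
SD 0.1.

## Phantom generator

The phantom emulates the imaging conditions at toy scale: neuron colours
from the labelling model; skeletons as persistent random walks (direction
diffusing on the unit sphere, reflecting off the volume walls, optional
side branch); rendering as sphere-union tubes convolved with a separable
Gaussian PSF over a constant background, with optional Poisson-like noise
and per-fragment colour jitter. Ground-truth traces, fragment labels, and
true colours are returned alongside the image, and everything is
reproducible from the seed. A hybrid-fragment fixture concatenates two
coloured fibres with a sharp boundary for exercising colour-change
splitting.

What the phantom does **not** model: realistic morphologies, non-uniform
autofluorescence, chromatic aberration, depth-dependent scattering, or
tracing errors other than colour hybrids. Passing end-to-end tests
therefore demonstrates the pipeline's correctness and its noise behaviour
under controlled conditions, not performance on real tissue.

## Problem sizes

The test suite runs phantoms of 2-20 neurons in volumes up to
20×96×96 voxels, pairwise statistics on up to 10,000 simulated cells, and
Monte-Carlo uniqueness over 200 cohorts — the same cohort and pair counts
as the published simulations, which are fast; the imaging-scale components
are exercised at phantom scale. The acceptance script uses 10,000 cells
and 200 cohorts throughout.

## Known limitations

- Crawl-order sensitivity: dCrawler's result can depend on input order for
  ambiguous geometries; on structured data the adjusted Rand index across
  orders is ≥ 0.95 (regression-tested), but pathological configurations
  can flip boundary points.
- The S/N screen needs ≥ 10 fragments for a stable percentile estimate.
- `percent_reconstructed` rasterizes at fragment radius; sub-voxel trace
  misalignment below the dilation radius is invisible to it.
- Chromatic aberration is not corrected anywhere in the pipeline: users
  with aberrated stacks should correct them upstream and feed corrected
  TIFFs to `unmix`/`extract`.
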