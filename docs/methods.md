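# Methods

## The Retinotopy Index

The central quantity is an inversion-count statistic for a mapping of
one point set between two metric spaces. For reference point *i*, the
remaining N−1 points are ranked by distance to *i* in each space; the
two rankings are permutations of one another and S_i is the number of
adjacent transpositions (bubble-sort swaps, equivalently discordant
pairs) separating them, computed by merge-counting in O(n log n) and
cross-checked in the tests against an O(n²) bubble-sort oracle. With
A = (N−1)(N−2)/4 — the mean inversion count of a uniformly random
permutation, i.e. half the maximum (N−1)(N−2)/2 by the symmetry pairing
every permutation with its reversal — the per-point index is
RI_i = 1 − S_i/A and the population RI is the mean over all reference
points. RI is 1 for any similarity transform, −1 when every ranking is
exactly reversed, 0 in expectation for random mappings, and for
tie-free rankings RI_i equals Kendall's τ-a between the distance-rank
vectors.

Numerical choices:

- **Ties.** Exactly equal distances are ordered by ascending id,
  identically in both spaces, so exact ties never contribute spurious
  inversions; tie positions are flagged on the rank list. With
  continuous coordinates ties are measure-zero.
- **Significance.** `ri_significance` tests the per-point RI population
  against zero with a two-sided Wilcoxon signed-rank test by default; a
  `null_sample` argument switches to a Mann–Whitney U test against the
  RIs of matched randomized mappings. Per-point RIs of one mapping share
  points and are mutually dependent, so both p-values are approximate —
  they are reported as conventional summaries, and conclusions should
  rest on comparisons with explicit null mappings.
- **Metrics.** A `PointMapping` accepts coordinates with a pdist metric
  name, great-circle degrees for (lon, lat) input, a callable, or a
  precomputed distance matrix — the last is how the synapse-cloud
  distance feeds the same RI core. N ≥ 3 is required (A vanishes below
  that).

## Eye coordinates

One eye's field of view is a spherical lune, longitude ∈ [−90°, +90°],
latitude ∈ [−10°, +160°], with longitude the azimuth of the standard
spherical parameterization. Latitudes above 90° wrap over the pole;
functions returning eye coordinates produce the canonical (wrapped)
representation there, which matters only within ~2° of the pole.
Distances between eye positions are great-circle degrees; receptive
fields are evaluated in planar lon/lat degrees by default (the maps are
flattened lune plots) with a great-circle variant behind a flag.

## Null mappings and the idealized glomerulus projection

`full_randomize` permutes point identities uniformly; `block_randomize`
tiles the bounding rectangle (anchored at its minimum corner, partial
edge blocks allowed) and permutes within blocks, interpolating between
the identity (one point per block) and full randomization (one block).
The idealized 1-D projection puts eye points on the unit sphere, rotates
by the axis angle about the lobula mid-point (longitude 73°, latitude
0°) and reads the new azimuths, so angle 0° returns raw longitudes
(the anterior–posterior axis) and angles are taken modulo 180°. The
sweep default is 0°–170° in 10° steps. After projection the 1-D space
uses absolute scalar difference.

## Skeleton geometry

Coordinates are nm throughout; no implicit unit conversion. Skeletons
are single-rooted trees validated for cycles and dangling parents.
Resampling places nodes at ~uniform arclength (default 400 nm) along
every unbranched segment, preserving branch points and leaves; segment
interval counts are rounded, so total cable length is preserved to
within one spacing unit per path. Cross-section positions are per-neuron
centroids of nodes within a closed slab [−t/2, +t/2] (default t = 1 µm)
about the plane, optionally normalized by the similarity transform
(rotation + uniform scale, no reflection) sending a reference neuron
pair to (0,0) and (0,1) — which removes any rigid motion of the scene.

The glomerulus long axis is the first principal component of the
presynapse cloud (origin at the centroid, deterministic sign, flagged
near-isotropic when the top two eigenvalues are within 5%); PCA is the
canonical elongation axis and is validated on synthetic cylinders to
within 2°. The glomerulus volume is the convex hull of the presynapses
with an approximate radial dilation margin. Axon tips are the mean of
the ⌈0.1 n⌉ nodes farthest from the entry node by geodesic
(along-skeleton) distance — robust to curled axons; Euclidean distance
is available behind a flag. Compartments split the projected presynapses
into k (default 10) equal-count bins by sorted rank, boundary ties going
to the lower compartment; boundaries are reported at the j/k quantiles.

## Connectivity statistics

The distance-weighted shuffle test asks whether neuron–neuron synapses
prefer eye-coordinate neighbors: per presynaptic neuron, the observed
statistic is the synapse-count-weighted mean of great-circle distances
to its partners' dendrite centers; the null permutes each neuron's
partner distances with counts fixed, so the non-uniform density of
dendrite centers is preserved in the null. The p-value is one-sided for
smaller observed distances with ties counted at half weight (mid-p):
a permutation-invariant statistic (uniform counts) then yields p = 0.5
rather than an artificial extreme.

The presynapse distance between neurons A and B pools the nearest-
neighbor distances from every presynapse of A into B's cloud and vice
versa and takes the mean; it is symmetric with d(A,A)=0 but does **not**
satisfy the triangle inequality, which the RI machinery never needs.
Target-proximity profiles slice the glomerulus into 80 consecutive 1 µm
slabs (centered on the presynapse extent by default); within each slice
every projection neuron is reduced to one position (the centroid of its
in-slice nodes — the pruning step) and the mean over neuron × target
node pairs is reported per group, with target-absent slices as missing
rather than zero. Synapse density per cable assigns synapses to the
nearest node and edge length to the slice of the edge midpoint, so
totals are conserved under re-slicing.

## Eye mapping

A quadratic height field over the principal frame of all dendrite nodes
is fit by least squares (≥ 6 points, rms residual reported). The
surface-to-lune map — not uniquely determined by any physical
constraint — is geodesic-polar about the eye-center reference: a query's
radial arclength along the surface and its tangent angle relative to the
direction of the central-meridian reference are replayed on the sphere
from the lune center, with the radial scale pinned so the meridian
reference lands at its known eye position (and hence on longitude 0).
Radial arclengths are integrated along the surface image of straight
frame-plane segments, an approximation to true surface geodesics that is
accurate for gently curved sheets; round-trip tests on a synthetic
spherical embedding bound the interior error below 1°. The handedness of
the angular coordinate is a flag (the two hemispheres are mirror
images). Queries more than 3× the fit residual off-surface raise a
warning; off-surface references are errors.

## Receptive fields

An anatomical RF places one isotropic Gaussian per neuron at its eye
center, height proportional to its synapse count onto the target, and
sums them. "Half-width" is read as half-width at half-maximum, so
σ = half_width/√(2 ln 2) with a 30° default (≈ the mean dendritic arbor
radius); the conversion is configurable. Absolute field values are
arbitrary units — contours and argmax positions, the quantities actually
compared, are scale-invariant. Contours are fraction-of-peak level sets
from bilinear-interpolated marching squares on a 1° grid, flagged open
when clipped at the lune boundary. Compartment RFs reuse the same
construction with per-neuron presynapse counts restricted to one
compartment, so the compartment fields sum exactly to the whole-
population field.

## Imaging summaries

ΔF/F = (F − F₀)/F₀ with F₀ the 10th percentile of a 300-frame centered
window, truncated (not padded) at trace edges; an epoch mode uses one
global percentile for stimulation-protocol baselines. Per-fly responses
are normalized by that fly's 98th percentile across all stimuli,
removing per-animal gain. Functional RFs take per-location, per-fly peak
responses, test each location with a one-sided one-sample t-test against
zero, control the set with Benjamini–Hochberg FDR at α = 0.05, and
interpolate means linearly onto the eye grid for the 60%-of-peak
contour. Zero-variance locations get p = 1 (mean ≤ 0) or p = 0
(mean > 0) by continuity. Tuning comparison regresses log-peaks of one
cell type on another's (slope 1 = inherited tuning); the bilateral test
is a two-sided paired t-test on per-fly peaks with the effect direction
reported.

## Synthetic connectome generator

The generator emulates the study conditions: 65 neurons drawn from a
jittered 6×11 lattice spanning the lune (jitter sd 3°), longitudes
compressed toward the visual midline by a power warp (exponent 1.3)
reflecting the higher dendrite density there; a cylindrical glomerulus
(length 40 µm, radius 5 µm) entered 120 µm from the lobula sheet
(400 nm per eye degree, sheet at z = 0). Each axon's extent along the
glomerulus axis is set by re-ranking a convex mixture of its
(coupling-weighted) latitude rank and a random rank — `scramble` ∈ [0,1]
interpolates cleanly between RI ≈ 1 and E[RI] = 0, and
`axis_coupling` ∈ [−1,1] sets how strongly (and in which direction)
latitude orders the axis. Presynapses (80 per neuron) are uniform along
the distal 15 µm terminal stretch of each axon with 500 nm radial
jitter: synapses sit on the terminal arborization, and this is what
lets the compartment-level analyses see the axial ordering — clouds
spread along the whole axon from the entry would overlap almost
completely. Neuron–neuron synapse counts are Poisson with rate
4.5·exp(−d/20°) in great-circle eye distance (≈ 2,000 synapses total at
defaults); target synapse budgets (912/428/207 at defaults, matching the
order of strongly-to-weakly connected glomerulus interneurons) are
multinomial over neurons with Gaussian RF weights in planar eye degrees.
Calcium traces are baseline + gain·rf(center)·shape(t) + noise with a
linear rise peaking at the epoch end and an exponential decay, so the
noiseless peak ΔF/F is exactly gain·rf/F₀.

All randomness flows from one seed through named substreams
(SeedSequence keyed by component name), so identical config + seed is
byte-identical and adding one component never perturbs another.

What the generator does *not* emulate: real dendrite morphology (a
5-node star stands in), axon tortuosity and branching in the glomerulus,
polyadic synapse geometry, mixed excitatory/inhibitory interactions, or
imaging artifacts (motion, bleaching, indicator nonlinearity). Passing
tests therefore demonstrate correctness of the statistics under the
assumed generative structure, not robustness to every property of real
reconstructions.

## Problem sizes and known limitations

The test suite runs the Monte-Carlo checks at the sizes stated in the
tests themselves (e.g. 1,000 random 66-point permutations for null
calibration, 100 seeds for scramble monotonicity and the
compartment-vs-control comparison, 1,000 replicates for the FDR null) —
sizes chosen so that sampling error is well below the effect being
checked. The RI p-values ignore the dependence between per-point values;
the block-randomized RI depends on the (unspecified) block layout and is
treated as a qualitative band (0 < RI < 1, monotone in block size)
rather than a point value; the eye map's geodesic-polar construction is
one defensible choice among several and is isolated behind a single
interface so alternatives can be swapped.
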