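# Methods

This note documents the models, numerical choices, and limitations behind
clawmorph's three analysis chains, and what the synthetic-data tests do and
do not establish about real data.

## Superimposition

Configurations are K ordered 2-D landmarks per specimen (the shipped scheme
uses K = 16: four fixed anatomical landmarks and twelve outline
semi-landmarks). Generalized Procrustes analysis first translates each
configuration's centroid to the origin and scales its centroid size (root
summed squared distance to the centroid) to one, then iterates: rotate every
configuration onto the current consensus with the planar closed-form
rotation (reflections are never fitted — left and right elements must be
mirrored at I/O, where a `flip_y` option exists for image-origin data), and
replace the consensus by the aligned mean. Convergence is declared when the
consensus displacement falls below 1e-8 (maximum 100 outer iterations); the
procedure is fully deterministic.

Semi-landmarks slide along the chord through their (before, after)
neighbors, re-estimated each outer iteration. Two criteria are offered:

- **minimum bending energy** (default, the convention of the mainstream
  morphometrics toolchain): all sliding amounts of one specimen are solved
  jointly from the quadratic form of the thin-plate-spline bending-energy
  matrix of the consensus;
- **minimum Procrustes distance**: each semi-landmark independently projects
  its residual to the consensus onto its tangent.

Two non-obvious choices stabilize sliding. First, sliding amounts are
re-computed each outer iteration *from the originally digitized positions*
rather than from already-slid ones; cumulative re-sliding otherwise drifts
along the outline. Second, the across-specimen mean sliding amount is
subtracted per semi-landmark: a common slide of every specimen along the
curve is a gauge mode (it drags the consensus with it and changes nothing
identifiable), and removing it anchors the parameterization to the average
digitized spacing. Only relative spacing differences between specimens —
the thing sliding exists to remove — are affected by what remains.

After convergence the joint orientation is canonicalized (consensus major
axis along x, first landmark on the positive side), which makes aligned
coordinates invariant to arbitrary rotation/translation/scaling of the
input batch. Coordinates are then orthogonally projected to the tangent
space at the consensus, the standard linearization before PCA. The reported
consensus is the arithmetic mean of the aligned shapes (centroid size
marginally below one); the unit-size version exists only as the internal
iteration reference.

## Shape space

PCA uses the covariance matrix (n−1 divisor) of the flattened aligned
coordinates via symmetric eigendecomposition; components below 1e-12 of the
leading eigenvalue are dropped (at most min(n−1, 2K−4) shape dimensions
survive the similarity constraints). Scores are in dimensionless tangent
(Procrustes) units. Eigenvector signs are arbitrary, so `orient_axes` flips
each component to correlate non-negatively with a per-specimen statistic —
by default the tip-to-proximal chord of the back-projected shape, so that
high PC1 reads as claw elongation; the operation is idempotent and touches
signs only. Thin-plate-spline warps visualize morphospace positions by
interpolating the consensus landmarks onto a back-projected target and
deforming a rectangular grid; the bending-energy functional is exactly zero
for affine displacements.

## Lever mechanics

The ungual is a class-3 lever: MA = sin(θ+δ)·d/a, DFT = h/b, hypothesized
output = MA·DFT (see README for symbol definitions). Angles are stored in
degrees in all files and converted internally; θ+δ must lie in (0°, 180°).
MA is maximal at θ+δ = 90° and invariant to common rescaling of d and a;
the scores table satisfies output = MA·DFT row-wise exactly.

The DFT denominator is the tubercle base-segment length, which makes the
ratio dimensionless and of order 0.1–0.3 for realistic tubercles; an
alternative normalizer (e.g. ungual proximal height) can be supplied where
a different convention is needed. For the landmark-derived path
(`measure_levers_from_landmarks`) the fulcrum, tip, tubercle apex and base
landmarks are user-designated, and the input-force direction is either an
explicit vector/angle or defaults to the flexor-tendon approximation
(parallel to the ventral border immediately proximal to the tubercle). The
dimensionless outputs (θ, δ, DFT) are rigid-motion and scale invariant;
lengths scale linearly.

## Comparative statistics

SMA regression: slope = sign(r)·sd(y)/sd(x), line through the centroid;
significance is reported as the Pearson correlation test with n−2 df (the
convention of the standard SMA toolchain). Residuals default to the
vertical (y) convention, with signed perpendicular residuals by flag.
Welch's t-test uses the unequal-variance statistic with
Welch–Satterthwaite df (scipy backend); two identical constant groups
return t = 0, p = 1 rather than an error. Quartiles use linear
interpolation between order statistics — hinge-based boxplot conventions
will differ slightly. All tests are two-sided and uncorrected.

## Parsimony

Matrices come from TNT xread or a NEXUS CHARACTERS/DATA block; '?' is
missing, '−' (inapplicable) is scored as missing (the standard
non-hierarchical treatment), and bracketed cells are polymorphic with
any-of semantics: a leaf may realize any member state at no cost.
User-facing character lists (ordered/excluded) are 1-based; TNT on-disk
ccode numbering is 0-based by convention and translated at parse time
(`tnt_zero_based` flag, since published character lists sometimes follow
the 1-based prose numbering instead).

Unordered characters are optimized with Fitch set operations (bitmask
vectorized across characters). Ordered (additive) characters use a Sankoff
dynamic program with linear cost over the observed state range rather than
Farris intervals: the interval relaxation can let a polymorphic leaf
realize an intermediate state it does not contain, whereas the DP leaf-cost
initialization is exact; both routes agree on non-polymorphic data and the
DP is verified against an exhaustive-assignment oracle. Per-character
minima M use the observed range (ordered) or one less than the minimum
hitting set of the cell state-sets (unordered, exact); star-tree maxima G
minimize total distance to a single central state. CI = M/S and
RI = (G−S)/(G−M) are ensemble sums over all active characters, including
uninformative ones; S = 0 (CI) and G = M (RI) degenerate cases report 1.0
with a flag.

Search follows the classic heuristic: random-addition Wagner builds
(stepwise insertion on the length-minimizing branch, ties broken by one
seeded generator) followed by NNI, SPR, or TBR hill climbing, holding up to
`hold` equally parsimonious trees per replicate and pooling distinct
topologies (by bipartition set) across replicates. Desk-scale defaults are
100 replicates, hold 10, TBR. Exhaustive topology enumeration is available
for ≤ ~8 taxa and serves as the search-adequacy oracle. Consensus trees
retain bipartitions present in all (strict) or a strict majority
(> threshold, default 0.5) of inputs, annotated with clade frequencies.
The count of most parsimonious trees depends on the zero-length-branch
collapsing rule of the producing program and is deliberately not a
quantity this package tries to match across implementations.

## Synthetic data

Claw outlines are two concentric circular arcs (dorsal radius 1, ventral
radius set by solving the elongation constraint with Brent's method)
spanning `curvature` degrees, a triangular flexor-tubercle bump of
prominence h/b on the ventral margin, and an articular extension of the
proximoventral process. Circular arcs were chosen over more anatomical
outline families because the lever geometry stays analytic: the generated
DFT equals `tubercle_prominence` exactly and the a/d ratio is monotone in
elongation. Elongation has a curvature-dependent geometric floor
(`minimum_elongation`); per-specimen lognormal parameter jitter (default
8% relative SD) is clamped to stay inside it. Landmark noise is isotropic
Gaussian, added after outline sampling; lever measurements come from the
noiseless geometry. Group presets — basal: curvature 140°, elongation 1.6,
prominence 0.30; derived: curvature 100°, elongation 2.6, prominence 0.12;
n = 10 per group; noise 0.01 Procrustes units — emulate the
basal-vs-derived therizinosaur contrast, with the derived DFT preset inside
the 0.11–0.13 band reported for derived taxa.

Character matrices evolve on a known binary tree from state 0 at an
arbitrary root, changing on each branch with probability `change_prob`
(unordered: uniform different state; ordered: ±1 clamped), then masking
cells to missing. Recovery experiments use the `exactly_one_change`
construction (every character changes once on a uniformly chosen branch):
it guarantees the true tree is most parsimonious with S = nchar and
CI = RI = 1, which is the ground truth a recovery rate needs. Under
stochastic sprinkling, multiple hits and masked cells make the parsimony
length fall below the realized change count almost surely, so "length
equals true changes" is only a meaningful target under the homoplasy-free
construction.

What passing synthetic tests establish: the estimators recover the
generating parameters of data satisfying their own assumptions (isotropic
landmark noise, homology of semi-landmark arcs, independent characters, no
directional taphonomic distortion). They do not establish robustness to
correlated digitization error, outline homology violations, or character
correlation — all present in real fossil data.

## Problem sizes

Default experiment scales — 20 specimens × 16 landmarks for the
morphometrics chain; 8-taxon, 60-character matrices (50 replicates) for
recovery; 6-taxon matrices for exhaustive-oracle comparisons; 2,000
simulations for the Welch calibration — were chosen so the full suite and
the acceptance script each complete in well under a minute while leaving
the statistical assertions comfortable margins. Search scale on published
matrices (hundreds of replicates on 79 × 356) is a config choice
(`--reps`), not a code limit.
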