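# Methods

This note documents the models, conventions and numerical choices behind
`avpconn`, and what the synthetic benchmark does and does not establish.

## Scope and data model

The package analyses EM-connectome exports: a synapse table (presynaptic
id, postsynaptic id, 3-D cleft position, detection confidence score) and a
neuron annotation table (id, cell class, hemisphere).  All geometry is
carried in nanometres; identifiers are opaque strings.  Voxel input is
converted to nm exactly once, at read time, via a per-axis scale in the
reader — downstream code never mixes unit conventions.  Contacts onto the
background segmentation are encoded with the reserved partner id `"0"` and
survive reading, so raw counts remain auditable; they are removed only by
the explicit filter.

## Synapse filtering and weight matrices

A contact enters any connectivity analysis only if its cleft confidence
score is at least 50, it is not an autapse, and neither partner is the
background sentinel.  Filtering is idempotent and order-preserving.

The individual weight of a connection inside a region is the filtered
synapse count from pre to post divided by the postsynaptic neuron's total
regional synapse count.  "Total" is read as total *input* synapses by
default, because the quantity expresses fractional input weight; a config
switch (`denominator_side="both"`) counts input+output instead, since the
source convention is ambiguous.  Postsynaptic neurons with fewer than five
regional connections are dropped from matrices (they otherwise produce
extreme weights from tiny denominators).  Outlier exclusion is an explicit
id-list parameter, never hard-coded.  Type-level weights aggregate all
neurons per type before normalizing by the postsynaptic type's regional
total; a type with zero regional synapses reports 0 with a warning rather
than NaN.

Matrix rows are ordered retinotopically for display: neurons group by their
strongest TuBu partner, groups order by that TuBu's dorsal–ventral
position, and within a group neurons sort by descending synapse count with
that TuBu (ties by id).

## Region membership

Neuropil boundaries are convex vertex sets; membership is tested with a
Delaunay tessellation of the vertices, which agrees exactly with the
half-space test on the convex hull facets (the test suite enforces this
equivalence on random hulls).  A hull may name a second hull whose interior
is subtracted, for tessellations that swallow part of a neighbouring
neuropil.  Coplanar vertex sets are rejected.

## Medulla columns, layers and the eye map

Each medulla column is anchored by one columnar neuron spanning the
distal–proximal axis.  The column axis is the first principal component of
the anchor's synapse cloud; PCA sign is disambiguated by a caller-supplied
proximal reference point (the deep end of the shared axis in the synthetic
data, the medulla centroid in real data).  Clouds that are coincident or
exactly collinear are rejected; a leading-eigenvalue ratio below 1.2
triggers an ill-defined-axis warning.  Depth bounds are the 3rd and 97th
percentiles (linear interpolation between order statistics — the percentile
convention is not dictated by the source material) of the projections.

Layers M1–M10 are fixed half-open fractional intervals of the
distal–proximal axis covering [−3.9 %, 102.2 %], with the terminal edge
closed (edge ownership is an implementation choice; the printed bounds only
touch).

Equatorial columns are those with 7 or 8 photoreceptors (6 elsewhere).
Columns map to ommatidial viewing directions by aligning the two hexagonal
lattices in axial coordinates: integer offsets are searched with the
constraint that equator rows coincide, in both mirror orientations, and the
assignment minimizing the total number of unmatched points wins.  Tie-break
order: unmirrored orientation first (a mirror is unidentifiable on a
mirror-symmetric field), then smallest offset magnitude, then lexicographic
offset.  The search matches an exhaustive oracle on lattices up to 15×15.

## MeTu classification

Feature vectors concatenate an upstream block (summed input weight from
each medulla input type) and a downstream block (summed output weight to
each tubercle partner type).  The upstream type list is the union, over
coarse groups, of each group's five strongest input types by mean weight;
groups default to each neuron's dominant tubercle partner type, which
mirrors how the named classes are anchored anatomically and keeps the
selected type set stable.

Two unsupervised modes are provided: an agglomerative dendrogram (average
linkage on correlation distance, cut at a height or cluster count;
deterministic) and a seeded 2-D nonlinear embedding (UMAP) with
density-based grouping.  Constant feature matrices collapse to a single
cluster with a warning; zero-variance rows are treated as maximally distant
rather than propagating NaN.

The explicit threshold rules are implemented as a pure function of counts:
class from the AOTUsu subregion holding the axonal synapses (posterior
lateral → MeTu1, posterior central → MeTu2, anterior → MeTu3, medial →
MeTu4; no axonal synapses → "incomplete"); MeTu3a iff MeTu3 with ≤ 13 Mi15
synapses; MeTu4d iff MeTu4 with < 15 lobula pre+post synapses; remaining
MeTu4 and MeTu2/MeTu3 splits by dominant TuBu partner.

## Morphometrics

Dendritic spans are fitted with a maximum-likelihood 2-D Gaussian (mean and
covariance, weighted where weights are given); the reported ellipse is the
k-sigma contour with k = 1 by default (the contour level is exposed because
the source convention is unstated).  Angles are measured from the
dorsal–ventral (vertical) axis of the projection plane, mapped to [0, 180);
the fit is rotation-equivariant and the ratio is ≥ 1 by construction.
Points are projected to the plane orthogonal to the local column-axis
average.

Orientation uniformity uses the axial Rayleigh test: angles are doubled,
R̄ is the resultant length, z = nR̄², and p = e^(−z)·(1 + (2z − z²)/(4n))
clamped to (0, 1].  The type-I error at α = 0.05 calibrates to 0.05 ± 0.01
at n = 100 (checked over 10,000 simulations) and power grows monotonically
with von Mises concentration.

Annulus density profiles use concentric equal-area annuli (default
314.15 µm²; outer radii r_k = √(kA/π)) around the Gaussian centroid.
Retinotopy pairs each neuron's dendritic centroid on the medulla
anterior–posterior axis with its axonal centroid on the target
dorsal–ventral axis and reports the Spearman rank correlation.  Columns
spanned assigns each synapse to the column with the nearest axis
(perpendicular distance, ties to the lexicographically smaller column id).

## Receptive-field back-tracing

Occupancy of MeTu *m* at column *c* is the fraction of *m*'s presynaptic
medulla sites nearest *c* ("nearest" again as perpendicular distance to the
column axis).  Presynaptic sites follow the literal source convention; a
switch substitutes dendritic postsynaptic sites, arguably the anatomically
intended quantity for a dendritic footprint.  The direct value of column
*c* for an ER neuron is Σ_b Σ_m w(b→ER)·w(m→b)·occ(m,c); the indirect value
routes through the bilateral TuTu neurons.  The AOTU046-mediated path is
not traced (its transmitter, hence sign, is unresolved).  Direct and
indirect values are reported separately and never summed.  Because
occupancies are normalized, Σ_c D(c) equals the total branch weight
Σ_b w(b→ER)·Σ_m w(m→b); this conservation identity is enforced at 1e-9 on
every fixture.

A column counts as covered when its direct value exceeds a threshold that
defaults to exactly 0 (no threshold is stated for the source's covered-
column counts).  Field outlines are unions of hexagonal cells in eye
coordinates, with the hexagon size derived from the median nearest-
neighbour ommatidial spacing.

## Stimulus-response analysis

ΔF/F is computed from raw fluorescence by per-frame subtraction of an
empty-ROI control, with F0 the mean of the lowest decile of the subtracted
series (F0 ≤ 0 is an error).  The per-trial response to a stimulus is the
mean ΔF/F during the 1-s stimulation window *minus* the mean during the
500-ms pre-stimulus baseline.  The source text describes the subtraction in
the opposite order, which would make excitatory responses negative; the
stimulus-minus-baseline convention is used here so that reported responses
match the sign of the published traces.  A position is responsive when the
paired signed-rank test across trials gives p ≤ 0.05 (exact null
distribution up to 25 trials, normal approximation beyond) *and* the mean
response exceeds the empty-control response.  Note the exact test cannot
reach p ≤ 0.05 with fewer than six trials.

The stimulus layout is 38 non-overlapping 18°×18° squares in staggered rows
of 8/7/8/7/8, spanning 144° of azimuth and 90° of elevation.  For the
contour ellipse, mean responses are interpolated with a thin-plate-spline
surface onto a 1° raster (clipped at zero), the iso-contour at 20 % of the
maximum is extracted, and the largest closed contour's enclosed region is
summarized by its second moments (a filled ellipse with semi-axes a, b has
moment eigenvalues a²/4, b²/4 — the regionprops convention).  The smooth
surface reconstruction was chosen over piecewise-linear interpolation
because the latter systematically broadens profiles near the 18° sampling
scale; even so, features with sigma below about half the stimulus spacing
cannot be recovered faithfully, and the 20 % contour must close inside the
stimulated field.

## Synthetic connectome

The generator emulates the statistical structure the analyses rely on —
not anatomy.  Defaults: a hexagonal lattice of side 11 (331 columns, 5 µm
pitch, 40 µm column depth) with one anchor neuron per column; ten MeTu-like
subtypes with 50 neurons each; per-neuron contact counts of 120 dendritic,
40 presynaptic-medulla, 30 axonal and 10 TuTu contacts (25 lobula contacts
for the three lobula-projecting subtypes); MeTu→TuBu convergence 10 and
TuBu→ER divergence 2; positional jitter 300 nm; 5 % of contacts degraded
below the cleft threshold, plus 20 background contacts and 5 autapses.
Contact bookkeeping is exact, so the total table length is checkable.

Input partners are drawn from per-subtype Dirichlet fingerprints over 16
medulla input types (concentration 0.3), with the structural constraints
the threshold rules rely on (no Mi15 input for the MeTu3a-like subtype,
prominent Mi15 for MeTu3b/c-like, dominant Dm2 for MeTu1-like).  Dendritic
clouds follow planted 2-D Gaussian spans: the MeTu1-like channel is
vertically elongated (ratio 3) and wired to TuBu by azimuth bin only, so
its ER fields are vertical stripes; the MeTu3c-like channel has
near-isotropic spans (ratio 1.2) and converges onto compact 2-D patches
(k-means on dendritic centres), so its ER fields are patches.  All axons
follow a planted strictly monotone anterior-posterior-to-dorsal-ventral
map.  One lattice row carries 7–8 photoreceptor counts (the equator); all
others 6.

Because single-ER field ellipses scatter (a patch at the lattice margin can
be elongated by the hexagon's corners), the vertical-vs-tiling contrast is
evaluated on the *median* ratio per channel, the same population-level
comparison used for the physiological receptive-field contrast it mirrors.

What the benchmark does **not** show: realistic morphologies, left/right
asymmetries, reconstruction noise beyond positional jitter and cleft-score
degradation, non-convex neuropils, or biological variability in fingerprint
composition.  Passing tests establish the correctness and calibration of
the *analysis*, not anatomical claims.

## Problem sizes and runtime

The default benchmark (331 columns, 500 MeTu, ~129k contacts) analyses end
to end in a few seconds; the full test suite runs in well under a minute,
and the acceptance script (including 10,000 Rayleigh calibration runs, 100
back-tracing oracle fixtures and 100 lattice-alignment trials) in a few
seconds.  These sizes were chosen as the smallest at which every recovery
claim is statistically meaningful.

## Known limitations

* Convex hulls only; real neuropils are mildly non-convex.
* The angle reference (0° = dorsal–ventral axis) and handedness are this
  package's convention; published angle histograms may use another zero.
* A published orientation statistic of z = 0.345 alongside
  p ≈ 2×10⁻¹³ is inconsistent with z = nR̄² (0.345 is plausibly R̄ itself);
  the implementation reports n, R̄, z and p so either reading can be
  checked.
* The embedding mode (UMAP + DBSCAN) is reproducible per seed but its
  grouping is qualitative; quantitative recovery claims use the
  deterministic dendrogram mode.
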