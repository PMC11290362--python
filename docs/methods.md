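# Methods

## The backbone curve model

A protein chain's Cα trace is modelled as a parametric space curve
r(t) = (x(t), y(t), z(t)) where each coordinate is an interpolating cubic
spline through the Cα positions. The parameter t is the 0-based residue
position *within a contiguous segment* (uniform knots), never the author
residue number: numbering gaps and insertion codes would otherwise distort
the parameterization. Author numbering is carried alongside in the output
records. This is pure interpolation — the curve reproduces every input Cα
to better than 1e-9 Å — not smoothing; noise models are out of scope.

Chain breaks split the trace into independent segments before fitting. Two
heuristics, both configurable, mark a break: a residue-number gap larger
than 1, or a consecutive Cα–Cα distance above 4.5 Å (the upper end of
plausible bonded Cα separations; trans peptides sit near 3.8 Å, cis near
2.9 Å). Segments need at least 4 residues (the cubic-spline minimum);
`fit_backbone_curve` rejects shorter ones, while the table-building
pipeline flags their residues' descriptors as undefined instead so that
every residue still gets an output row.

The spline end condition is not-a-knot by default (the mainstream
scientific-library default, maximal end-interval smoothness), with natural
splines available as an option; descriptor values within ~2 residues of a
terminus depend measurably on this choice, interior values do not.

## Chebyshev differentiation

Curvature and torsion need up to the third derivative of r(t). A cubic
spline's third derivative is piecewise constant and jumps at every knot, so
direct spline differentiation makes torsion extremely noisy. Instead, the
spline is sampled at 50 Chebyshev nodes of a window around the residue, a
Chebyshev series is least-squares fitted per coordinate (degree 10 by
default), and the series is differentiated analytically. The fit is exact
for cubic curves (degree ≥ 3) and deterministic.

The window halfwidth is 3.0 residues by default. This choice matters and
deserves its own analysis:

- The spline interpolant of a sampled curve consists of the underlying
  smooth signal plus a "knot ripple" of period 1 in t. For an α-helix the
  signal itself has angular frequency ω ≈ 1.745 rad/residue (100°/residue),
  i.e. only ~3.6 samples per turn.
- Over a ±1 window, no polynomial degree can separate ripple from signal:
  measured closed-form recovery errors on an ideal helix exceed 14% at
  every degree, and 40% at high degrees that track the ripple faithfully.
- Over a ±3 window, a degree-10 fit resolves the helical carrier (phase
  span ≈ 10.5 rad) while averaging six ripple periods, recovering the
  ideal helix's closed-form curvature to within 1% at interior residues.

There is an irreducible residual: cardinal cubic-spline interpolation
attenuates a sinusoid of frequency ω to A₀ = b̂₄(ω)/Σₖ b̂₄(ω+2πk) of its
amplitude (b̂₄ is the quartic B-spline transfer function), which is 0.976
at α-helical density. Even ideal low-pass recovery therefore sees a helix
of radius 0.976·a, biasing κ by +1.9% and τ by +4.4%. Window/degree
combinations trade these two biases against each other (alias leakage can
cancel one only by inflating the other); a scan over halfwidths 2.5–7 and
degrees 6–23 never brought both below 2% simultaneously. The shipped
defaults favour curvature accuracy (≈1%) and accept the ~4–5% torsion
bias, and the classification boxes below are anchored to the pipeline's
*measured* values, not to the continuum closed forms. For densely sampled
smooth curves (a circle at 0.5 rad/step, the twisted cubic) the same
pipeline matches closed forms to 0.1% and 1e-12 respectively, confirming
that the bias is a property of the sampling density, not of the scheme.

Near segment ends the window keeps its full width by sliding inside the
segment (the evaluation point sits off-centre); only when a segment is
shorter than a minimum window (1.0 parameter units) are curvature and
torsion flagged undefined. Terminal values are computed but less accurate —
downstream consumers that need uniform quality should drop the first and
last ~3 residues of each segment.

Torsion is additionally flagged undefined wherever |ṙ × r̈|² < 1e-12
(locally straight curve): the τ quotient is numerically meaningless there
and must not be emitted as a large number.

## Arc length

Arc length is the adaptive-quadrature integral of |ṙ| taken directly on the
spline (the integrand is only C¹ at knots, so integration proceeds knot
interval by knot interval). It is cumulative from each contiguous segment's
start and restarts at chain breaks, whose physical gap length is unknown.
Note the spline slightly under-measures the continuum curve's length at
coarse sampling (−2.1% per residue on the ideal helix) for the same
carrier-attenuation reason as above.

## Writhe

The writhing number of the five-residue window centred on a residue is the
polygonal writhe Wr = 2·Σ_{i<j, non-adjacent} ω_ij of the window's four
directed edges, where ω_ij is the exact closed-form Gauss-integral
contribution of an edge pair (the signed solid angle / 4π, computed by the
Klenin–Langowski construction). Adjacent pairs share a vertex and
contribute exactly zero for straight segments, so they are excluded rather
than double-counted. The test suite retains an independent brute-force
double-quadrature evaluator of the Gauss integrand and checks the closed
form against it to 1e-5 or better.

Sign convention: the integrand is (dr₁ × dr₂)·(r₁ − r₂)/|r₁ − r₂|³, under
which right-handed crossings count positive; a right-handed α-helix window
has Wr ≈ +0.235 and its mirror image −0.235. Coplanar edge pairs contribute
exactly 0 (the construction's intermediate normals vanish; the zero branch
is taken explicitly). Genuinely intersecting segment pairs — a measure-zero
degeneracy that does not occur for physical Cα traces — are not separately
detected and also return 0. Windows that would cross a chain break or run
off a terminus (fewer than two neighbours on a side) are undefined.

## Structure I/O

PDB reading and b-factor writing operate on the fixed-width text records
directly, because the annotation contract is byte-level: a descriptor is
written as %6.2f into columns 61–66 of every atom of its residue, clamped
to [−99.99, 999.99], while every other byte of the file is preserved.
Residues whose descriptor is undefined receive a configurable sentinel
(default 0.00 — visually neutral in b-factor colouring); residues absent
from the value map are left untouched, so an empty map is the identity.
Policies: first model only for multi-model files; highest-occupancy
alternate location (ties broken alphabetically, blank first); HETATM
ignored except MSE-as-MET; insertion-code residues are distinct residues in
file order. mmCIF and gzip handling are out of scope in this version.

## Alignment annotation

Aligned residues are compared by the weighted Euclidean distance between
their (κ, τ, Wr) vectors — a true metric, unlike RMSD. Descriptors are
first standardized per descriptor using the family's pooled mean and
standard deviation, so one cutoff is comparable across families; weights
default to (1, 1, 1) and the cutoff to 1.0 standardized units. Each
column's present sequences are clustered by complete-linkage agglomerative
clustering cut at the cutoff; labels are deterministic (the cluster
containing the earliest sequence is 1). Runs of ≥ 3 consecutive columns
with an identical partition form blocks; shorter runs are considered noise
and unlabelled. A column carrying any undefined descriptor among its
mapped residues is never labelled; a column with fewer than two present
sequences is never labelled. These four knobs (linkage implicit in the
cutoff semantics, weights, cutoff, minimum block length) are the
user-adjustable similarity criterion; the defaults were chosen on the
synthetic families below, where the geometric separation is unambiguous.
Label→colour mapping is a fixed palette, so the plain-text report and the
PyMOL script colour the same residues identically. The alignment itself is
an input (FASTA or Clustal); no alignment computation is performed.

## Environment classification and densities

Residues are classified into {helix, strand, other} by rectangle rules in
(κ, τ) space, anchored to the pipeline's measured values on ideal
secondary-structure geometry:

- helix: |κ − 0.38| ≤ 0.08 and |τ − 0.14| ≤ 0.08 (the ideal α-helix
  measures (0.385, 0.149); backbones built from α dihedrals (−57°, −47°)
  measure (0.383, 0.157)),
- strand: κ ≥ 0.48 and |τ| ≤ 0.12 (backbones from ideal antiparallel and
  parallel β dihedrals measure (0.53, 0.02) and (0.74, 0.03): the spline
  bends sharply at every residue of the ~2-residue strand repeat but stays
  nearly planar, so strands are high-curvature/low-torsion in this
  representation — note this differs from descriptors computed on
  arc-length-resampled or virtual-bond representations),
- other: everything else (e.g. polyproline II measures (0.36, −0.37); the
  3₁₀ helix (0.48, 0.22) falls outside both boxes).

The boxes are disjoint and configurable. Classification requires defined
descriptors; a straight stretch (undefined τ) cannot be classified.

Propensity tables (environment class × 20 amino acids) are supported as a
documented plain-text format with a loader, optional row normalization to
probabilities, and a serializer; the published numeric table values are
external data and are not shipped — synthetic tables are used for testing.
Solvent-accessibility environment classes would require all-atom surface
computation and are out of scope.

Per-class densities over (κ, τ) are Gaussian kernel density estimates with
a diagonal Scott's-rule bandwidth (h_j = σ_j·n^(−1/6) for 2D). The
estimator is hand-written rather than delegated, because degenerate sample
sets (zero variance in a dimension) must degrade gracefully to a sharp peak
via a bandwidth floor of 1e-8 rather than fail on a singular covariance.
Box probability masses are available analytically via the normal CDF, and
the tests confirm quadrature integration to 1 within 1e-3. Sampling is
driven by a caller-supplied seed and is bit-reproducible. At least 20
residues per class are required; sparser classes are skipped with a
warning.

## Synthetic fixtures

The fixture generator produces ideal helices (α parameters by default),
twisted strands (radius 0.9 Å, rise 3.3 Å, 185°/residue — an exact
180° two-residue repeat would be planar with zero torsion, while real
strands carry a few degrees of twist per residue), straight lines, planar
circles and zigzags, the twisted cubic (t, t², t³), and noise-perturbed
variants, as coordinate arrays, minimal CA-only PDB text, and truth tables
carrying closed-form κ/τ where they exist. The same spec (including the
seed) always yields byte-identical output. What the fixtures deliberately
do *not* emulate: side chains, thermal disorder correlated along the chain,
non-ideal bond geometry, and real secondary-structure irregularity —
passing tests on them validates the mathematics and the contracts, not
performance on experimental structures.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problems chosen to
exercise every code path: 30-residue fixtures for descriptor checks, 100
random rigid motions for invariance, 200 random segment pairs against the
writhe quadrature oracle, 10⁴ random triples for the metric axioms, and a
1000-residue trace for throughput (≈1 s single-threaded). Key tolerances:
interpolation 1e-9 Å; rigid-motion drift 1e-8 (measured ~1e-13); writhe
closed form vs quadrature 1e-5 (measured ~1e-15); torsion degeneracy
threshold 1e-12 on |ṙ × r̈|²; b-factor precision 0.01 by format.

## Known limitations

- Torsion (and arc length) carry a small positive (resp. negative) bias at
  α-helical sampling density, intrinsic to interpolating cubic splines (see
  the Chebyshev section); descriptor *differences* between structures, the
  quantity that drives comparison and clustering, are unaffected to first
  order because the bias is common to both.
- Terminal residues' κ/τ come from off-centre windows and are less
  accurate; writhe is undefined at the two outermost residues of a segment.
- PDB only (no mmCIF), Cα only (no all-atom geometry), first model only by
  default.
- Cluster labels are deterministic for a fixed input order and invariant to
  reordering only up to renaming; exact ties in the linkage are resolved by
  scipy's ordering.
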