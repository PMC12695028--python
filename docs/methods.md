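# Methods

`heterodont` quantifies dental shape variation in shark-like dentitions
at three nested levels — sub-tooth features, single teeth, and whole
tooth rows — and relates the resulting descriptors to genetic distance
and ecological traits.  This note documents the models, the numerical
choices, and what the synthetic study conditions do and do not show.

## Outlines and preprocessing

A tooth is represented by the open 2D outline of its upper (functional)
crown, ordered mesial→distal; the first and last points are the
baseline termini.  Outlines are resampled to 1000 points at equal
arc-length spacing (linear interpolation along the polyline; endpoints
preserved).  Resampling of an outline that is already uniform within
0.1% of its spacing is the identity: re-interpolating such an outline
would move points by no more than that spacing error while accumulating
corner-cutting drift, so the operation is made exactly idempotent.

The centroid is the arithmetic mean of the resampled points, matching
the point-based distance formulas.  Size normalization is either to
unit outline length or to unit area of the polygon closed by the
straight baseline segment.

Crown/base segmentation of a full tooth outline applies, in order:
explicit annotated termini (a metadata channel — the material-transition
criterion cannot be derived from coordinates alone); the lowest concave
lateral point on each side of the apex, with concavity read from the
sign of the cross product of successive edges on a window-5
moving-average smoothing; else the most distant point pair in the lower
half of the bounding box.  The arc containing the apex is kept.

## Pairwise distance measures

Six measures capture complementary aspects of shape difference:

* **EMD** — sum of the two directed mean nearest-point distances.
* **HED** — twice the mean positionwise distance at equal point counts;
  with unequal counts, points are matched at the nearest relative
  position (`k = argmin_j |i/n_i − j/n_j|`) and the two directed means
  are summed.
* **SAO** — area-overlap similarity `2|A∩B| / (|A|+|B|)` over pixel
  sets.  The raster covers the joint extent of the pre-alignment pair,
  discretized into 100 units per axis with a 25% margin per side so
  transformed shapes stay on-grid; a pixel belongs to a shape iff its
  center lies inside the baseline-closed polygon (shapely point-in-
  polygon).  The pipeline stores the distance `1 − SAO` so all six
  measures average coherently.
* **DFD** — Euclidean distance between cosine-Fourier coefficients.
  Coordinate series x(t), y(t) are expanded with the orthonormal
  type-II DCT; "24 harmonics" means the first 24 non-DC coefficients
  per axis.  DC terms (translation) are excluded.
* **OAD** — outlines are reduced to 100 equidistant points; the
  interior angle (in [0, π]) at each of the 98 interior points is
  accumulated into a cumulative angle function anchored to start at 0;
  OAD is the discrete integral of the absolute gap between two such
  functions.
* **ADD** — Euclidean distance between the non-DC DCT coefficients of
  the two anchored angle functions.

Mean shapes average full-rank DCT coefficients and reconstruct.

### Superimposition

EMD, HED, and SAO are evaluated at the optimum of a bounded
partial-Procrustes search: rotation within ±π/8, shift within ±10% of
the bounding-box diagonal per axis, size change within ±25%, run under
both size-normalization modes with the lower minimum kept.  The default
grid uses 17 rotation × 9×9 shift × 11 scale steps plus one local
refinement pass at a quarter step; all counts are configurable
(`GridSpec`).  DFD, OAD, and ADD are computed on centered,
length-normalized outlines without the search.

The size change `s` is split evenly between the shapes (reference at
1/√s, candidate at √s; the relative size range is unchanged).  A
unilateral scale would multiply the measured residual itself by up to
the scale bound and make `d(a,b)` and `d(b,a)` differ by ~25%
independent of grid fineness.  For the homogeneous measures the split
is folded back algebraically onto fixed reference points
(`d(a/r, r·R·b + t) = d(a, s·R·b + r·t)/r`); SAO caches reference masks
per scale value.  Residual order-dependence is bounded by
`heterodont.align.symmetry_tolerance`: one scale-grid step plus the
inversion deficit of the bounded scale range (`1/0.75 − 1.25 ≈ 0.083`
relative), plus a small absolute term for rasterization noise.

## Heterodonty statistics

With `d` a chosen distance measure over teeth:

* `HMS = Σ_i (d(i,i−1) + d(i,i+1)) / 2n` — sequential monognathic
  heterodonty; missing-neighbor terms at the row ends are skipped while
  the 2n denominator is kept, so a homogeneous row of sequential
  distance δ scores δ(n−1)/n.
* `HMT = Σ_i Σ_j d(i,j) / n²` — total monognathic heterodonty,
  diagonal zeros included.
* `HDG` — teeth matched across jaws at the nearest relative position;
  the two directed mean distances are summed (a uniform cross-jaw
  distance δ gives HDG = 2δ).
* `HMX` — the within-jaw maximum; `HMX ≥ HMT` always.

Row-level statistics are averaged over the two jaws.  The cross-species
phenotypic distance DP applies the HDG-style matching within like jaws
and averages the two per-jaw values.

Species-level aggregation normalizes each (statistic, measure) column
to [0, 1] over the species set, then averages the six measures —
normalization first, because the measures live on incommensurable
scales.  Derived ratios (graduality HMX/HMS and HDG/HMT) are formed
within each measure, where the scale cancels, and then averaged; the
outline-based (EMD, HED, SAO) versus angle-based (OAD, ADD) contrast is
reported per statistic on normalized values.

## Single-tooth complexity

Ten measures per crown (per-species value = mean over all teeth of both
jaws):

* **CUSP1/CUSP2** — local maxima of distance from the baseline are apex
  candidates; a cusp is major iff its topographic prominence (drop to
  the higher of its two cols) reaches 2% of the outline length, with
  the largest cusp always major; the rest are minor cusplets.  The
  serration criterion is subsumed by the prominence rule — a visual
  criterion is not computable from coordinates.
* **OAR** — outline length / baseline-closed area (scales as 1/size;
  computed on the length-normalized outline).
* **OCR** — outline length divided by the square root of the *sum* of
  point-to-centroid distances, as defined; the value depends on the
  fixed n = 1000 resampling and is only comparable at that resolution.
* **OIR** — escribed/inscribed circle area ratio, capped at 25.  The
  reciprocal reading (inscribed/escribed) is bounded by 1 and could
  never reach the cap, so the ratio is taken escribed over inscribed.
  Circles via shapely `minimum_bounding_radius` and
  `maximum_inscribed_circle` (tolerance 1e-7 of the crown extent).
* **DFS** — total |coefficient| mass over both axes and 24 non-DC
  harmonics, computed at unit *centroid size* (RMS distance to the
  centroid).  Unit outline length would shrink strongly undulating
  crowns and invert the expected response of coefficient mass to added
  cusps; centroid size is the conventional shape-space scale.
* **ANS/ASC/AND** — over the resolution ladder
  `n_R = 1000/(5·2^(R−1))`, rounded half-up to {200, 100, 50, 25, 13,
  6} (resolutions below 3 points are dropped): ANS is the mean over
  resolutions of Σ|angle − π|; ASC the mean signed difference between
  successive resolutions (an `absolute` flag is available); AND the
  mean absolute pairwise angle difference over interior points,
  normalized by (n_R − 2)² ordered pairs — without the absolute value
  the pairwise differences cancel identically.
* **OPC** — inter-point vectors are assigned to circular sectors;
  maximal runs of constant sector are counted and averaged over
  partitions {2, 4, 8}, rotation offsets {0, half-sector} (plus a
  quarter-sector offset for partition 2), and the resolution ladder.
  A straight line scores exactly 1.

`Cx_combined` sums the globally min-max-normalized species values of
all ten measures (bounds 0 and 10); pooled groups sum the normalized
excentricity measures (OCR, OAR, OIR), the angle measures (ANS, ASC,
AND, OPC), and the Fourier measure.  `cusp_ratio` is CUSP2/CUSP1 with
the convention 0 when CUSP1 = 0.

## Genetic distances and the divergence scan

K2P distances, `d = −½ ln((1−2P−Q)√(1−2Q))`, use pairwise deletion of
gapped/ambiguous sites; saturated pairs raise an error.  Trees come
from Saitou–Nei neighbor joining (scikit-bio; negative branch lengths
set to zero), which reproduces additive input exactly; a ready-made
Newick tree can be supplied instead.  Patristic distances, min-max
normalized over all species pairs, give dG ∈ [0, 1].

The divergence scan orders all species pairs by dG (ties broken by
species names), forms per-trait absolute differences, and slides two
100-pair windows at a configurable rank offset (0 or 200 by default) in
steps of 1.  Each window pair is tested with a one-sided two-sample
Wilcoxon/Mann–Whitney test (normal approximation with tie correction;
alternative: larger differences in the higher-dG window).  Windows are
half-open spans of exactly `window` ranks.  No multiple-testing
correction is applied across windows.  P-values are reported against
both window anchors (dG of the top pair of the lower set, and of the
bottom pair of the upper set).  Per-window taxonomic composition
fractions (same family / order / superorder / different superorders)
annotate the same ordering.

## Synthetic study conditions

The generator produces crowns on a unit baseline: a sinusoidal dome
carries `n_major_cusps` raised-cosine cusps whose supports tile the
crown, plus narrow cusplets on the flanks whose width is chosen steep
enough to puncture the local slope while their prominence stays below
the 2% col threshold (so they count as minor).  Asymmetry is a
horizontal shear (leaving baseline-distance extrema intact), elongation
the height/width ratio, and corner rounding a Gaussian smoothing of the
height profile.  Dentitions apply parameter gradients along the row
(mesial fraction 0 → distal fraction 1), a parameter offset to the
lower jaw, and seeded Gaussian noise on shape parameters — never on
individual points, so resampling invariants hold.  Zero gradient and
zero offset give bitwise-identical teeth (exact homodonty null).

Sequences evolve under K2P along a given tree, with `kappa` the
transition/transversion *event* ratio (α/2β), so the empirical ts/tv
count ratio converges to kappa on short branches.  Trait tables are
either independent of dG or have expected difference increasing in dG.

What the synthetic conditions do not emulate: digitization noise and
point-correspondence error of hand-traced outlines, within-species
variation (sex, age, tooth replacement), overlapping or damaged teeth,
alignment/trimming artifacts in real multi-marker matrices, and
non-K2P sequence evolution.  Passing tests therefore validate the
computational pipeline and its ground-truth recovery, not the
biological conclusions reachable from any particular real dataset.

## Problem sizes and tolerances

Synthetic validation runs use reduced sizes chosen to keep the full
suite in a few CPU-minutes while leaving the logic untouched: 64-point
outlines and a coarse search grid (3–5 steps per axis, no refinement)
for distance batteries and gradient recovery; 100k sites on 8-leaf
trees for the phylogenetic round trip (pairwise estimates and inferred
patristic distances within 3 analytic standard errors); 30–50 taxa for
the scan fixtures.  The null calibration of the windowed test reports
the mean rejection fraction over 20 independent trait draws because
overlapping windows make a single draw's fraction highly autocorrelated
(roughly one effectively independent block per window length).
Closed-form checks (rectangle OIR = 5, semicircle OAR = 2, straight-
line OPC = 1, K2P at P = 0.1/Q = 0.05, three-leaf NJ) are exact to
their stated numerical tolerances.

## Known limitations

* The grid search is exhaustive within its bounds but the bounds
  themselves (±π/8, ±10%, ±25%) are assumptions inherited from the
  measurement protocol; outlines differing by larger rigid motions are
  not brought into register.
* Aligned distances are order-symmetric only within
  `symmetry_tolerance`; the bounded, linearly gridded scale axis is the
  irreducible cause.
* OCR is resolution-bound by construction; values from different
  resamplings are not comparable.
* Segmentation rule 1 (material transition) requires annotation;
  rules 2–3 are geometric surrogates.
* `dG` is a dataset-relative quantity; values are not comparable across
  different species sets.
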