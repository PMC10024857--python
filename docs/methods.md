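# Methods

## Scope and model

`cycihc` analyzes cyclic chromogenic multiplex IHC: one tissue section,
stained and imaged once per antibody with a soluble red chromogen over a
hematoxylin counterstain, the chromogen removed between rounds.  The
computational model has four layers — stain arithmetic, geometric
alignment, per-object marker logic, and spatial statistics — plus a
forward-model phantom generator that closes the loop for testing.

## Stain arithmetic

Transmitted-light imaging is multiplicative, so intensities are converted
to optical density, `OD = -log10(I / I0)` per RGB sample, where `I0` is the
white point.  Intensities are floored at one intensity level before the
log (and capped at `I0`), which keeps saturated-dark pixels finite and
leaves the transform exact and strictly monotone everywhere else; an
additive dark guard was rejected because it biases the OD of every pixel.

Each stain is a unit vector of RGB absorption coefficients.  The shipped
defaults are the hematoxylin direction in common use for brightfield
deconvolution, `(0.650, 0.704, 0.286)` normalized, and a red-chromogen
direction `(0.15, 0.75, 0.64)` normalized (red chromogens transmit red, so
absorption sits in green/blue).  No published vectors exist for the exact
AMEC-red/hematoxylin pair as scanned by any particular instrument, and the
proprietary software used in the source workflow does not disclose its
color model, so for real slides the vectors must come either from the YAML
stain config or from `estimate_stain_vector` (first principal direction of
OD vectors in a single-stain ROI, sign-fixed to the non-negative octant,
minimum 50 stained pixels).  The synthetic renderer uses the same default
vectors, which is what makes its scenes exactly invertible.

Deconvolution is the per-pixel least-squares projection onto the stain
basis via the pseudo-inverse; a two-stain basis is completed with the unit
cross product so the system is square.  Negative densities (noise outside
the physical cone) are clipped to zero rather than re-balanced — the
simplest contract — and the clipped fraction per stain is reported in QC.
On forward-mixed fields without clipping the inversion is exact to 1e-6 OD
(tested against an independently written forward model).

## Registration and the stack

Only the counterstain is present in every round, so round-to-reference
transforms are estimated on the hematoxylin density channel; the reference
is round 1, matching staining-order semantics.  The default model is rigid
(rotation + translation): the same physical section is re-coverslipped and
re-scanned, so deformation is small.  Estimation is a two-stage search:

1. **Coarse**: a grid of candidate rotations (±6° in 1.5° steps) on 4×
   decimated images, each resolved to a translation by phase correlation;
   the candidate with the best normalized cross-correlation (NCC) seeds
   stage 2.  Phase correlation alone loses the peak beyond ~2–3° of
   rotation, which this grid repairs.
2. **Refine**: Powell minimization of negative masked NCC over (angle,
   row-shift, col-shift) at full resolution, linear interpolation, with
   out-of-field pixels excluded by a validity mask.

An `affine` mode re-optimizes all six parameters from the rigid optimum;
`deformable` adds a B-spline free-form refinement (SimpleITK, correlation
metric, L-BFGS-B) and returns a dense displacement field.  On phantom
scenes the rigid estimator recovers transforms to ≲0.15 px and ≲0.01°
across the full configured misalignment range (shifts to 30 px, rotations
to 5°).  A configurable similarity floor (NCC 0.2) turns silent
misregistration into an explicit error.

Warping is linear interpolation onto the reference grid; pixels sampled
from outside the moving field are zero-filled and removed from the validity
mask, and the stack's validity is the conjunction over rounds.  Every area
fraction downstream is computed inside that mask so border strips never
inflate statistics.  `compose_stack` emits one channel per antibody round
plus the reference round's counterstain — N+1 channels, names fixed by
provenance, content independent of the order rounds are supplied.

## De-stain QC

The positivity threshold defaults to Otsu computed on the *pre-removal*
density restricted to pixels above a background floor (0.1 OD).  Two
reasons: (i) stained pixels are a small minority, so whole-histogram Otsu
collapses toward the noise cluster; (ii) a threshold near half the stain
amplitude makes thresholded areas insensitive to the sub-pixel blur that
resampling introduces, which matters when pre and post images are compared
across a registration.  If the stained histogram is near-unimodal (uniform
blobs), Otsu would split the mode itself; the threshold then falls back to
half the 99th-percentile amplitude.  The de-stained image is never
thresholded on its own histogram — it is near-blank by construction.

`residual_stain` warps post onto pre, then reports the residual percentage
within the pre-positive region (share of originally positive pixels still
positive), plus the whole-tissue post area fraction.  Both are reported
because the two denominators answer different questions — re-development of
the same structures vs. any staining anywhere — and it is genuinely
ambiguous which convention a given lab's numbers use.  A per-tile (256 px)
residual map exposes spatially non-uniform blocking.

## Objects and the gate

Cells are 8-connected components of the thresholded IBA1 channel, with
areas converted to µm² and a 40 µm² minimum-size exclusion so that severed
process fragments and oblique cuts are not counted as cells.  Touching
cells are not split: the phantom guarantees separability and a watershed
would add an untestable degree of freedom (it can be layered on by the
caller).  Plaques and tangles come from their own channels with a minimum
*equivalent diameter* of 100 µm by default; the size rule could also be
read as a minimum area, so the knob (`pathology_min_diameter_um`) is
exposed and documented with the conversion `2·sqrt(area/π)`.

Marker positivity per object uses a fractional-overlap rule: marker m is
positive iff ≥ 25% of the object's pixels exceed that channel's threshold.
This is robust to partial-volume edges and misregistration residue; mean
densities and positive fractions are stored per object so a mean-density
rule can be applied post hoc.

The gate is an ordered rule table evaluated top-down, so every one of the
2^7 possible vectors receives exactly one label (enumerated in tests):

1. IBA1− → `non_microglia`
2. GFAP+ → `gfap_conflict` (control marker: a microglia-marker-positive
   object co-staining for the astrocyte marker is a segmentation or
   bleed-through artifact, quarantined rather than classified)
3. P2Y12+ → `IBA1+P2Y12+` (homeostatic; TMEM119 is collapsed into this
   class because TMEM119+ cells are almost always P2Y12+ and TMEM119 adds
   no unique population)
4. Ferritin+ & CD68+ → `IBA1+Ferritin+CD68+`
5. Ferritin+ → `IBA1+Ferritin+`
6. CD68+ → `IBA1+CD68+`
7. otherwise → `IBA1-only`

CD45 is recorded per object but not used for assignment: its low/high
split does not isolate a unique microglia population.

## Proximity and association

Distances are measured from the cell centroid to the pathology boundary
(zero inside), the convention typical of proximity modules and the robust
choice for small cells; a boundary-to-boundary variant backs the
touching/association statistics.  Each cell is attributed to its single
nearest pathology object; if that distance is within the 100 µm radius the
cell lands in that object's kind-specific profile (20 µm bins by default —
a round divisor of the radius; widths are configurable because published
profiles rarely state theirs).  Nearest-object attribution prevents a cell
sitting between a plaque and a tangle from being counted twice in
profiles; association summaries deliberately count per kind independently.
Both row-normalized (per-bin composition) and column-normalized
(per-phenotype distribution) percentages are emitted, since either
normalization is defensible for stacked profile plots.

"Touching" means boundary-to-boundary distance ≤ `touch_tolerance_um`
(default 0 = overlap/contact).  The primary split counts each cell once
with priority pathology > vessel > none; vessel masks cannot be derived
from the stain panel, so they are supplied externally, and when absent the
vessel fraction is reported as *not computed* rather than zero.

## The phantom generator

`SceneConfig`/`Scene` emulate a gray-matter field: microglia as soma disks
(radius 3.8–5.2 µm, hence soma areas of 45–85 µm², straddling the 40 µm²
exclusion realistically) with 2–4 thin processes (6–10 µm); plaques and
tangles as unions of jittered disks (default equivalent diameters ~125 µm
and ~117 µm, above the 100 µm rule) plus deliberate sub-exclusion amyloid
speckles and detached process fragments to exercise both size filters;
hematoxylin nuclei at every cell plus filler nuclei and a faint tissue
background.  Default mixture over the five phenotypes is
(0.45, 0.25, 0.10, 0.12, 0.08) in the order homeostatic, IBA1-only,
Ferritin, Ferritin+CD68, CD68 — most-to-least prevalent as observed in
aged human gray matter, with 80% of homeostatic cells TMEM119+ and CD45
present on 80% of all cells.  Reactive phenotypes are placed with a
plaque-attraction weight `1 + a·exp(-d/30 µm)` (a = 6 for the
triple-positive class, 1.5 for the other reactive classes, −0.8 for
homeostatic), reproducing the toward/away polarization; optional per-
phenotype `touching_fractions` pin cells onto plaque boundaries for
association tests.

Rendering is the exact forward model: per-round chromogen density (that
round's positive cells, plus optionally a retained-stain subset of earlier
rounds), mixed with hematoxylin through the stain matrix, warped by a known
rigid misalignment (defaults: |shift| ≤ 8 px, |rot| ≤ 2°; re-coverslipped
de-stained images get a smaller fresh misalignment), degraded by additive
Gaussian OD noise (σ = 0.01, the scale of scanner noise after
quantization; an optional Poisson intensity toggle exists) and quantized to
8-bit.  Retention is *pixel-fraction* retention: whole render units are
kept until the configured fraction of that round's positive pixels is
reached, so a 20% setting reads out as ~20% residual under the pixel-based
QC statistic, and nested subsets model carry-over across multiple rounds.
All randomness derives from the seed through fixed substreams, so renders
are bit-reproducible and independent of call order.

What the phantom does **not** model: real tissue texture, lipofuscin and
other pigments, uneven illumination, chromatic scanner aberrations,
overlapping/touching cells (by default), antibody-affinity variation, or
true plaque morphology.  Passing tests therefore demonstrate correctness
of the *computational* chain under a faithful forward model — they do not
certify staining chemistry or segmentation performance on real slides,
where thresholds and stain vectors must be re-estimated.

## Numerical choices and problem sizes

* Dark guard: intensity floor of 1 level (≙ OD ceiling ~2.4 at 8-bit).
* Deconvolution clip fraction is reported, never silently discarded.
* Otsu background floor 0.1 OD ≈ 6σ of deconvolved acquisition noise at
  σ_OD = 0.01, so blank channels produce zero positives.
* Registration: NCC needs ≥ 16 valid pixels; Powell tolerances 1e-4
  (parameters) / 1e-8 (function); similarity floor 0.2.
* Bin edges are half-open `[lo, hi)` with the outermost edge inclusive, so
  a cell exactly at the radius is binned, one beyond it is excluded.
* Test and acceptance scenes use 300–600 µm fields at 1 µm/px with 12–150
  cells, and geometry-only scenes up to 2400 µm with 700–800 cells for the
  statistical recovery checks — sizes chosen so the full simulation chain
  (including nine registrations per scene) stays comfortable on a single
  CPU while leaving every size rule and bound non-trivial.

## Known limitations

* No whole-slide tiling or pyramid support: single-field processing.
* No cross-section (z-adjacent slide) registration; the multiplex-vs-single
  comparison is same-scene by construction, whereas real single-stain
  controls sit on neighboring sections.
* Exact numeric parity with proprietary slide-analysis suites is not
  attempted: their stain vectors and thresholding rules are unpublished.
* The deformable mode is a thin refinement layer and is exercised only by
  smoke tests; rigid covers the re-imaged single-section use case.
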