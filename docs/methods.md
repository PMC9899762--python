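# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. It is the companion to the code; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Morphometry of annotated capillary profiles

A capillary cross-section is an annotation bundle in a µm coordinate system
(y increasing downward, the image convention): closed simple polygons for the
abluminal membrane, the lumen, and the inner/outer faces of the basal lamina
(BL); polygons for pericyte processes; open polylines for pericyte/astrocyte
adhesion arcs and tight junctions (TJ); (area, count) pairs for pinocytic
vesicle fields; and an optional grayscale intensity image aligned through an
origin offset and pixel size. Annotation vertices are polygon vertices, not
pixel centers; areas use the shoelace formula and perimeters summed edge
lengths (both via shapely).

**Shape descriptors.** Circularity is `4π·area/perimeter²` (1 for a circle,
→ 0 for elongated shapes). Roundness is `4·area/(π·major²)`, the inverse
aspect ratio of the fitted ellipse; "major" is taken from the
moment-matching ellipse — the eigen-decomposition of the region's normalized
second central moments, computed in closed form from the polygon (Green's
theorem), matching the convention of standard particle-analysis software
(for covariance eigenvalue λ₁ the major axis is 4√λ₁). Digitized circles can
overshoot 1 by perimeter-estimation bias; values are clamped at 1 after
asserting they do not exceed 1.02.

**Volume fractions.** Endothelium area is defined as capillary − lumen area,
so lumen and endothelium volume fractions sum to 1 exactly on every profile.
Group-mean fractions are nevertheless averaged independently in the report
layer: means of ratios over (potentially different) profile subsets need not
sum to 1 in aggregate, and the report reproduces that honest behavior rather
than renormalizing.

**GOIA basal-lamina thickness.** A square grid (default pitch 0.5 µm,
aligned to the coordinate origin) is intersected with the inner BL face;
at each crossing, thickness is the distance to the outer face along the
local outward normal of the inner face. Crossings within 0.25 µm of a
pericyte adhesion arc are excluded, since the BL thins where a pericyte is
interposed; the 0.25 µm default operationalizes "adjacent" and is
configurable. At least 3 admissible crossings are required (error
otherwise, naming the profile); exactly coincident faces return 0 rather
than erroring, for continuity at the degenerate boundary. On smooth annuli
the grid estimate agrees with a dense (10⁴-point) normal-distance oracle to
well under 5% (tested); on the generator's parallel-curve annuli the error
is ~10⁻⁸ µm.

**Other parameters.** TJ tortuosity divides the junction's arc length by
the diagonal of its axis-aligned bounding rectangle — note this makes
tortuosity the one statistic that is *not* rotation invariant, asserted and
accepted as part of the definition. Vesicle density pools 3–5 fields:
Σcounts/Σareas. Pericyte areas of multiple processes are summed; coverage
divides summed adhesion arc length by the BL circumference, for which the
**outer** BL face perimeter is used (adhesion arcs lie on the parenchymal
face; configurable). The electron-lucent "hole" area thresholds the
intensity image (Otsu on the perivascular band by default, overridable by a
fixed grey level), labels 8-connected components, and sums those
intersecting the band from the abluminal contour to 2 µm outside it
(band width configurable).

Two guards make the hole measurement robust: (i) Otsu's histogram optimum
is refined by an intermeans (isodata) fixed-point iteration, because on
strongly bimodal data with an empty gap every bin between the modes ties
and the 256-bin argmax can land inside a class; (ii) the threshold is
accepted only if the separated class means differ by more than 5 background
standard deviations — an image with no unequivocally bright pixels reports
0, not a noise split.

**Inclusion.** A profile enters analysis when it is a cross-section lined
by at most two endothelial cells, free of blood cells or plasma, and
without an endothelial or pericyte nucleus in frame (nucleus-bearing images
generate extreme measurements and are too infrequent to sample adequately).

## Phantom generator

The generator emulates the study's inputs with known ground truth; its
defaults are the study conditions (three groups, per-parameter mean ± SD of
the group table, 4 animals × 10 profiles, 0.02 µm pixels, 3–5 vesicle
fields of ~1 µm²).

- **Contours** are Fourier-perturbed ellipses: a random-aspect ellipse
  radius function modulated by cosine harmonics k = 2–4 with amplitudes
  ∝ 1/k² (stronger irregularity for the SAH group), rotated randomly and
  uniformly rescaled so the enclosed area equals the drawn value exactly.
  The lumen is the same shape scaled about the centroid by √(lumen
  fraction), making the area ratio exact and containment automatic. The BL
  outer face is the parallel curve of the abluminal contour at the drawn
  thickness, so the normal-distance thickness is exact by construction.
- **Sampling** uses truncated normals at the physical bounds (areas ≥ 0,
  fractions in (0,1), tortuosity ≥ 1) with the location *moment-matched*
  so the truncated mean equals the requested mean: plain truncation at a
  bound within ~2 SD of the mean (e.g. tortuosity 1.25 ± 0.16 at the bound
  1) would otherwise shift the realized group mean by more than the
  recovery tolerance. Adhesion lengths and hole area are drawn *after* the
  contour exists, truncated at what it can host (an arc cannot exceed the
  BL circumference; a hole cannot exceed ~80% of the perivascular band),
  which keeps group means unbiased without rejection coupling to capillary
  size. Rare residual infeasibilities trigger a bounded redraw.
- **Adhesion arcs** are sub-arcs of the outer BL ring placed by arc length,
  so the summed drawn length is exact. **TJ polylines** are sawtooth paths:
  with n teeth in a w × h box the length is √(w² + n²h²) and the diagonal
  √(w² + h²); h is solved so the tortuosity is hit exactly (a target of 1
  degenerates to a straight segment); the polyline is translated but not
  rotated, because the definition's bounding box is axis-aligned.
- **Holes** are painted into the intensity image as bright pixels
  (default 3000 on a background of 100 ± 15 grey levels) swept in angular
  order through the band outside the BL until exactly round(area/px²)
  pixels are set, so the painted area is the ground truth to within half a
  pixel. **Vesicle counts** are Poisson at the drawn density; ground truth
  records the realized pooled density.
- **Determinism**: each (seed, animal, profile) triple seeds an independent
  generator stream (entropy-pooled, not spawn-keyed: sequential spawn keys
  showed measurable cross-stream correlation in early outputs, inflating
  the dispersion of per-seed means by ~35%). Identical configuration and
  seed reproduce annotation files byte for byte.

A record-level fast path (`draw_record_table`) emits the drawn parameter
values without building geometry. The geometric pipeline reproduces drawn
values essentially exactly (round-trip errors ≤ 10⁻⁶, most ≤ 10⁻⁹; verified
by tests), so value-only analyses — notably the 50-replicate power
simulation — run on the fast path with the same scientific content.

**What the phantoms do not emulate:** TEM texture, segmentation ambiguity,
annotator variability, partial-volume effects, correlated parameters within
an animal (draws are i.i.d. across profiles), or staining chemistry.
Passing recovery tests therefore demonstrates the *measurement* chain is
correct and unbiased given annotations, not that annotations of real
micrographs would be error-free.

## Colocalization

Costes-style automatic thresholding: the a–b relation is an orthogonal
regression computed on standardized intensities and back-transformed
(equivalently the geometric-mean slope sign(r)·sd_b/sd_a). The
standardized form is used instead of raw total least squares because raw
TLS is not equivariant under per-channel gain, and gain invariance of the
thresholds (T scaling with the channel) is a property we require and test.
The threshold T_a descends a candidate grid — integer grey levels for
integer data, 256 quantiles for float data — with T_b = slope·T_a +
intercept, and the first candidate at which the Pearson correlation of
voxels below *both* thresholds is ≤ 0 wins; a minimum below-threshold
population of 20 voxels is required for a stable estimate. If the scan
exhausts the grid (e.g. perfectly correlated channels), the threshold falls
just below the minimum intensity, everything is colocalized, and a warning
flag is set. Voxels where both channels are zero are excluded from the
regression (empty space inflates correlation).

Reported statistics: percent of material colocalized per channel
(100·Σ intensity over colocalized voxels / total), Pearson's r over the
colocalized voxels, a whole-stack r for transparency, and the study's
classification `correlated ⇔ r ≥ 0.5` (boundary inclusive). An empty
colocalized set reports 0%, an undefined (NaN) r, and `correlated = False`.
Object-based (spot) colocalization is deliberately not implemented.

The volume generator has two regimes. With `coloc_fraction = 1` both
channels mix a shared smoothed Gaussian field with independent fields in
proportions solved from the target ρ (corr = ±α²/(α²+β²), α² = |ρ|), so
the whole-stack empirical r hits ρ directly — used to test r estimation.
With `coloc_fraction < 1` signal occupies sparse supports over a dark
background: a shared support carrying the ρ-correlated pair plus one
private support per channel, sized so the shared support holds the
requested fraction of each channel's mass — the regime Costes thresholding
is designed for, where %MC recovers the generating fraction (±10 points at
64×64×32) and ρ applies to the colocalized voxels. Negative ρ is supported
only in the mixture regime.

## Molecular quantification

ΔΔCT follows the comparative-CT method with amplification efficiency fixed
at 2 and no efficiency correction: ΔCT = CT_gene − CT_ref per sample;
ΔΔCT subtracts the control group's arithmetic-mean ΔCT per gene
(equivalently, the geometric mean of control folds is 1); expression is
2^−ΔΔCT. Densitometry subtracts the mean of the backgrounds measured above
and beneath each band (mean chosen as the combiner; floored at 0),
normalizes against the loading-control intensity, and divides by the mean
normalized value of control samples on the *same membrane*, cancelling
per-membrane gain exactly (tested). Zymogram activity treats clear digested
bands as intensity minima: Σ max(background − intensity, 0) over the band
window, optionally divided by a parallel-gel loading value (normalization
optional because quantitative use of the load gel is a per-study choice).

## Statistics

Grading sums six basal-brain segment scores of 0–3 (range 0–18); animals
below the inclusion grade (default 8) are excluded. Profiles are averaged
to animal-level means per parameter (missing values excluded pairwise); the
animal is the statistical unit throughout. Group comparison is classical
one-way ANOVA per parameter plus pairwise Welch t-tests adjusted by
Benjamini–Hochberg FDR across the three comparisons of that parameter; the
two-stage Benjamini–Krieger–Yekutieli variant (`fdr_tsbky`) and pooling the
family across parameters are available behind flags, since the exact
post-hoc scheme of the original analysis is not specified and BH per
parameter is the conservative, reproducible baseline. Two all-constant
groups compare with p = 1 when equal and p = 0 when different (the t
statistic is undefined there; the limit is taken instead so one degenerate
comparison cannot poison the adjustment family with NaN). Star flags encode
*which* comparison is significant at q < 0.05, not a significance tier —
*** does not mean "more significant" than *.

## Problem sizes

Recovery runs use 100–200 phantom profiles per condition at fixed seeds
(group-mean tolerance 2 SE, or the documented explicit tolerances); the
power simulation uses 50 replicates of 3 groups × 4 animals × 10 profiles;
colocalization checks use 64×64×32 to 64³ voxel volumes over up to 20
seeds. These sizes keep every statistical check comfortably resolved while
the full suite runs in about a minute.
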