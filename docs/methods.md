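# Methods

## Overview

`ki67quant` quantifies nuclear Ki-67 immunohistochemistry globally, across a
whole stained tumour section, instead of within a single manually chosen
field. The pipeline takes an RGB brightfield image with known physical pixel
size (default 0.23 µm/pixel, a 40× whole-slide scan), a region-of-interest
annotation (tumour outline minus exclusions), and produces per-slide
proliferation metrics, a hotspot analysis, and — across many slides — the
cohort-level statistics used to relate those metrics to grading, manual
hotspot counts, and survival.

## Stain model

Brightfield absorbance is modelled with Beer–Lambert: per channel,

    OD_c = −log10((I_c + 1) / (bg_c + 1)),     bg = 255 by default,

clamped below at 0. The +1 offset bounds the OD at pixel value 0 without a
special case. The OD vector of each pixel is unmixed into hematoxylin, DAB,
and residual contributions by solving the 3×3 linear system defined by the
stain basis; negative coefficients are clamped to 0. The default basis is
the Ruifrok–Johansen H-DAB pair, with the residual direction taken as the
per-channel complement √(1 − h² − d²), renormalised — this keeps all three
basis vectors non-negative, unlike the raw cross product. The basis is
configurable (nine reals, row-normalised on load) because the true vectors
of any given scanner/stainer combination are never exactly the published
ones.

DAB amounts are re-expressed on a 0–255 *pseudo-intensity* scale,

    v = 255 · 10^(−OD_DAB),

so 255 is unstained white and OD 1 maps to 25.5 — a dense dark-brown floor
of ≈25. Values are kept real until per-nucleus averaging. This inverse
scale is what the four-band classification is defined on.

## Nucleus detection and classification

The detector is a deliberately classical stand-in with explicit,
documented parameters (commercial detectors in this space are deep-learning
black boxes):

1. combined nuclear OD = hematoxylin + DAB;
2. Gaussian smoothing, σ = 0.5 µm;
3. threshold at combined OD 0.15; hole filling;
4. distance-transform watershed to split touching objects (seed peaks at
   least 1.5 µm apart);
5. restriction of each object to its unsmoothed-OD support — smoothing
   dilates objects into a pale halo which would otherwise contaminate the
   intensity measurement;
6. area gate 8–150 µm².

Each object's **central mean DAB** is the mean pseudo-intensity over its
central 25–75% pixels: pixels are ranked by Euclidean distance to the
object boundary and the outermost and innermost quartiles of ranks are
discarded (ties broken by pixel index, so the band is deterministic).
Excluding the rim suppresses edge artefacts and partial-volume background;
excluding the core suppresses chromatin-clearing highlights. Objects of ≤4
pixels are used whole. The 25–75% band is interpreted as a distance-rank
annulus; an intensity-percentile trim would be a defensible alternative but
the annulus matches the stated purpose (edge artefact suppression).

Classification bands on the central mean (half-open from below):

| class    | pseudo-intensity |
|----------|------------------|
| strong   | [0, 70)          |
| moderate | [70, 120)        |
| weak     | [120, 170]       |
| negative | (170, 255]       |

The printed band edges overlap (120 and 170 each appear in two bands); the
convention above keeps the strict inequalities for strong and negative and
assigns each boundary to exactly one class, so every value in [0, 255] maps
to exactly one class. All nuclei inside the ROI are assessed, with no
neoplastic/non-neoplastic discrimination — Ki-67 is not tumour-specific, and
the quality scores (below) are how unreliable slides are flagged.

## ROI and area

Annotations are GeoJSON polygon features in pixel coordinates with a `role`
of `tumour` or `exclusion` (exclusion categories: adnexa, vessel, adipose,
lymphoid, artefact, ulcer). Pixel (i, j) occupies the unit square with
centre (j+0.5, i+0.5); the analysis mask is rasterized with a
pixel-centre-in-polygon rule, overlapping exclusions are unioned before
subtraction, and the assessed area is the true-pixel count × (µm/px)²/10⁶
mm². A nucleus belongs to the ROI iff the mask is true at its centroid
pixel — centroid membership keeps "counts per mm² of tumour tissue"
well-defined and order-independent. Self-intersecting rings and annotation
files without a tumour polygon are rejected.

## Slide metrics

Over the assessed nuclei: the proliferation index PI = 100·positive/total
(%), the H-score = 1·%weak + 2·%moderate + 3·%strong with percentages over
*all* assessed nuclei (range 0–300, so PI ≤ H ≤ 3·PI always), and the
densities of positive and strongly positive nuclei per mm² of assessed
tissue. A slide with no assessed nuclei reports PI = H = 0 with a warning
rather than NaN. Strong density is tracked separately because strongly
stained nuclei are the best available proxy for tumour-cell proliferation
when weak/moderate staining is contributed by reactive cells.

Slide quality is scored 0/1/2 on three axes from caller-supplied fractions
(the underlying judgement is a pathologist's, so the package scores the
fractions rather than estimating them): tissue assessability (2 if >90%,
1 if 50–90%, 0 if <50%), inflammatory-cell fraction (2 if <1%, 1 if 1–10%,
0 if >10%), and unlabelled-nucleus fraction (same cuts). Boundary values
(1%, 10%, 90%) fall to the middle score, since the outer categories are
defined by strict inequalities.

## Hotspot analysis

The hotspot is the fixed-area window — 0.3125 mm², the conventional manual
counting frame — containing the most Ki-67-positive centroids. Only the
area of that frame is conventional; the shape is not, so a square of side
√0.3125 mm = 559.02 µm is used. Membership is half-open
(x ∈ [x0, x0+s), y ∈ [y0, y0+s)); the search enumerates every window
anchored at a pair of nucleus coordinates, a candidate set that provably
contains a maximizer, optionally augmented with a coarse stride grid. Ties
go to the smallest (y0, x0). Windows may overhang the ROI bounding box;
clamping would break provable maximality. With no positives the count is 0
at the ROI corner.

Derived quantities: hotspot density = count/0.3125 per mm²; the Webster
dichotomization (high iff count > 23, the established prognostic cutoff);
and the **proliferation factor** = hotspot positive density / global strong
density — undefined when the global strong density is 0 — expressing how
many times more proliferative the hotspot is than the section overall. The
orientation (hotspot over global, values ≥ 1) is chosen so the factor reads
as the fold *excess* of the hotspot.

## Cohort statistics

Slides join cohort metadata on `slide_id`. The layer reproduces standard
exploratory practice for this kind of biomarker series:

* exclusion of slides with marked inflammation (quality score 0) and
  signed fold changes of cohort means before/after exclusion
  (magnitude max/min to 2 decimals, negative when the excluded-subset mean
  is lower, +1.00 when equal);
* category summaries (manual hotspot low/high; PI ≤ 15% and ≥ 30%) with
  integer percentages rounded half away from zero;
* Wilcoxon rank-sum for two groups — exact by full enumeration of label
  assignments when both groups have ≤ 8 observations, normal approximation
  with tie correction otherwise — and Kruskal–Wallis for three;
* Spearman correlation with average ranks for ties;
* univariable Cox proportional hazards per metric (lifelines, Efron tie
  handling — survival times have day granularity, so ties are expected),
  reporting the HR per unit with a 95% Wald CI; a constant metric returns
  HR 1 and non-convergence is flagged, not raised;
* Kaplan–Meier curves after dichotomizing a metric at its median, with
  values equal to the threshold going to the low group ("high" means
  strictly above the median); a one-sided split is flagged;
* an inter-protocol comparison of pooled per-nucleus intensities of
  positive nuclei (rank-sum p plus the absolute difference of group means).

Two censoring rules are exposed (`all-deaths`, `mct-only`) because both
all-cause and disease-specific survival are legitimate readings of the
outcome data. No multiple-testing correction is applied by default —
p-values are exploratory — with Benjamini–Hochberg available as an option.

## Synthetic slides and cohorts

The generator exists so every stage can be validated against planted ground
truth. Nuclei are hard disks composited in OD space: hematoxylin OD 0.55
plus a DAB OD of −log10(v/255) for a planted pseudo-intensity v, so the
rendered central mean equals v up to 8-bit quantisation (±2 units). Planted
intensities are drawn uniformly from per-class bands that sit strictly
inside the classification bands with a ≥ 5-unit guard margin — so planted
classes are recoverable exactly; class membership follows the requested
quotas exactly (largest-remainder apportionment); positions are uniform or
cluster-enriched, non-overlapping by rejection sampling (gap ≥ 1.5 µm, 100
retries per nucleus, then an error naming the packing limit); inflammatory
infiltration is emulated as extra small weak-band nuclei (granulocytes show
weak or no Ki-67 signal) flagged in the ground truth; and
`plant_hotspot` routes a chosen number of positives into one window,
refusing configurations whose remainder could form a rival hotspot. One
private random stream per slide makes outputs bit-identical under a fixed
seed. The planted slide summary is computed with the same formulas as the
pipeline summary, so the two agree by construction on the ground-truth
table.

The default test geometry for dense slides is 3000×3000 px (690 µm square,
≈0.48 mm²) with 5000 nuclei of radius 1.8–2.6 µm — about 10,500 nuclei/mm²,
a cellularity above that of most real sections, chosen to stress the
watershed and keep runtimes in seconds per slide.

What the generator does **not** emulate: stain texture and chromatin
structure, scanner noise and compression, anisotropic nuclei, overlapping
nuclei (real sections have them; the detector's watershed is only exercised
on mild planted overlaps), ulceration, and tissue folds. Passing the
plant/recover suites therefore demonstrates correctness of the measurement
conventions and the pipeline plumbing — not detector performance on real
histology, which the classical stand-in does not claim.

Survival cohorts are simulated with a standard-normal metric and
exponential event times with hazard h₀·exp(β·metric), administratively
censored, so the true HR per metric unit is exp(β); the Cox recovery suite
uses h₀ = 0.001/day and 5-year censoring (≈80% events).

## Numerical choices and degenerate inputs

* OD separation is an exact 3×3 solve (basis condition number must be
  < 10⁶, else an error naming the bound).
* Pseudo-intensities stay floating point until export; exported TSV rounds
  metrics to 1 decimal (a repository convention) and the proliferation
  factor to 2.
* Empty ROI masks yield a zero-count row and a warning, not an exception;
  empty slides define PI = H = 0.
* The hotspot tie-break, central-pixel ordering, and largest-remainder ties
  are all deterministic, so reruns are byte-identical.

## Limitations

The detector is classical and tuned for clean, well-separated nuclei; on
real tissue it will under-segment dense sheets and is not a substitute for
a learned detector. Stain vectors are fixed per run rather than estimated
per slide. Quality scores require caller-supplied fractions. Cohort-level
statistics are exploratory by design; the package deliberately does not
search for prognostic thresholds.
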