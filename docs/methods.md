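# Methods

## Problem and model

A late frost kills part of a winter-wheat seedling canopy; the surviving
green fraction of the ground, seen from straight above, is a direct and
cheap severity readout. The package models a plot photo as a mixture of
three pixel populations — green tissue, soil/shadow, and withered
(straw-to-white) tissue — and estimates three quantities per image:

1. **Vegetation coverage** `VC = 100 · |plant mask| / |image|` (percent).
2. **Frost grade**, an ordinal severity class from coverage intervals.
3. **Withered-leaf fraction**, the share of image pixels that are
   desiccated yellow-white tissue.

The core assumption is chromatic separability: on sum-normalized channels,
green tissue has strictly positive excess-vegetation index
`ExV = 3g − 2.4r − b`, while soil, shadow and straw sit at or below zero.
Illumination intensity largely cancels in the normalization, which is why
the method tolerates the narrow brightness variation of controlled
acquisition but is *not* designed for raw sunlight extremes or specular
reflection.

## Segmentation

`ExV` is rendered to 8-bit gray over its fixed theoretical range
`[−2.4, 3]` (not per-image min/max), so a given gray level means the same
index value in every image and thresholds are comparable across a batch.
Otsu's criterion — maximize between-class variance `w₀w₁(μ₀−μ₁)²` over the
256-bin histogram, classes `{≤ t}` / `{> t}` — picks the threshold. Ties
break toward the smallest maximizing `t` among thresholds whose lower class
is non-empty; this also makes the degenerate single-level histogram return
that level.

Two guards around plain Otsu:

* **Neutral floor** (`neutral_floor=True`): the applied threshold is
  clamped at the gray level of index value 0. Otsu always splits a
  histogram, so without the floor a plant-free image (bare soil) would come
  back roughly half foreground; with it, "plant" can only be declared on
  the green side of the achromatic point.
* **Symmetric cleanup** (`clean_mask`): plant components smaller than
  `min_object_px` (default 16 px, 8-connected) are removed, and enclosed
  background pockets up to `max_hole_px` (default 16 px) are filled.
  Filling *all* holes is deliberately avoided: overlapping leaves routinely
  enclose genuine soil, and annexing those pockets inflates coverage
  measurably (≈1.5 points at 18 % density in generator scenes).

Withered tissue has near-zero `ExV` and therefore segments as background —
by design, frozen tissue never counts toward coverage.

## Grading

Grades partition coverage totally and monotonically: grade 1 "no obvious"
(`VC ≥ 15`), 2 "slight" `[10, 15)`, 3 "severe" `[5, 10)`, 4 "most severe"
(`< 5`), in percent. Boundaries belong to the lighter-damage side so that
every value in `[0, 100]` maps to exactly one grade. Scoring sheets that
number the same intervals in listed order (lowest coverage = grade 1) are
supported via `grade(..., mapping="interval_order")`.

## Withered-leaf extraction

The image is converted with the classical geometric HSI transform
(`I = (R+G+B)/765`, `S = 1 − 3·min(r,g,b)`, arccos hue with reflection to
(180°, 360°) when `B > G`; `H = 0` for achromatic pixels). A pixel is
withered when

* `40° ≤ H ≤ 75°` and `I ≥ 0.35` (straw-yellow branch), or
* `S ≤ 0.15` and `I ≥ 0.70` (bleached-white branch).

All four thresholds are parameters (`WitheredThresholds`): the hue window
brackets straw tones while excluding both green tissue (H ≈ 130°) and
typical soil (H ≈ 30°); the intensity gate drops dark soil that drifts
hue-ward under noise; the white branch catches fully bleached tissue whose
saturation is too low for a meaningful hue. Real-world deviations — sunlit
specular patches reading as white, yellowing buds, pale crop residue —
shift these boundaries, which is exactly why they are exposed rather than
hard-coded.

## Synthetic scenes and what they do (not) show

The generator renders what the segmentation stage actually keys on: blades
as oriented hard-edged strips (2–5 px wide, 24–60 px long by default)
clustered into 6 horizontal bands emulating drill rows, over a
brightness-textured soil background; an optional tip fraction of each blade
is recolored from a straw/white palette and excluded from the plant truth
mask. One multiplicative illumination factor per scene (±4 %) mimics a
narrow controlled-light band, plus per-pixel Gaussian sensor noise
(sd 1.5 gray levels). Scenes are 256×256 by default — large enough for
stable Otsu histograms, small enough that a 50-scene validation sweep runs
in seconds. Blades are added until green coverage is within ±0.5 points of
target (final filler blades may be shorter than the nominal range);
unreachable targets raise after a bounded number of placements.

Ground truth is exact by construction (hard pixel membership, no
anti-aliasing on truth masks), so coverage-recovery results measure the
pipeline, not label noise. What passing these tests does **not** show:
robustness to specular highlights, mixed-pixel blade edges, cast shadows
with chroma, weeds, or crop residue — none of which the generator models.
Field deployment should expect coverage error well above the ~0.2-point
synthetic figure.

## Numerical choices

* Index math in float64; quantization only at the gray rendering, rounding
  half-up with a 1e-9 guard so exact half-integer targets (ulp-low in
  float64) round as real arithmetic would.
* Otsu tie-break: smallest maximizing threshold, matching common reference
  implementations; verified equivalent to exhaustive search.
* Zero-sum (black) pixels normalize to (0,0,0) → all indices 0 → classed
  background.
* 8-connectivity for plant components and contours; holes are treated as
  4-connected background.
* Plot-level coverage is the arithmetic mean over the plot's images, with
  the grade recomputed on the mean (not the mean of grades).
* Treatment ranking counts ties for every tied treatment and flags them, so
  fractions can exceed 1 per rank in degenerate tables.

## Batch conventions and limitations

Filenames map to plots as `{variety}_{treatment}_{replicate}_{k}`; variety
names may contain underscores (the last three fields are positional). An
image that fails to parse, decode or segment is logged and excluded — one
corrupt file does not kill a batch — and the treatment-ranking summary is
skipped (with a warning) when the variety × treatment table is incomplete.

Known limitations: no illumination/white-balance correction (acquisition is
assumed controlled); no per-plant instance separation or leaf counting; the
grade scale is calibrated to seedling-stage canopies where healthy coverage
is ~15–21 % — denser growth stages would saturate at grade 1; withered
extraction reports pixel fraction, not necrotic *area* on the plant.
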