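# Methods

## Color model

All image pixels are sRGB-encoded (gamma-companded) triples on [0, 1].
CIELAB conversion follows the standard pipeline — inverse sRGB companding,
the IEC 61966-2-1 linear-RGB→XYZ matrix, then CIELAB with the piecewise CIE
f(t) and threshold (6/29)³ — under the D65 2° observer illuminant, appropriate
for photographs taken in average daylight. The white point is taken as the row
sums of the rounded sRGB matrix rather than the textbook (0.95047, 1, 1.08883):
the two agree to 1e−7, and the matrix-consistent choice makes neutral inputs
(r = g = b) map to a\* = b\* = 0 and white to L\* = 100 *exactly*, which the
test suite relies on. Conversions are double precision throughout.

L\* values are reported on 0–100 and a\*/b\* on a nominal −100..100 scale, but
conversion output is **never clamped**: extreme chroma can exceed ±100, and
clamping would corrupt distances near the gamut edge. The inverse conversion
clips out-of-gamut colors channel-wise to [0, 1] and flags them; the flag is
informational (swatches for display), never an error.

## Reference tables

A reference table is an ordered list of named colors with CIELAB and sRGB
coordinates, a hue group, and zero or more pigment classes. Invariants
enforced at load time: non-empty unique names, L ∈ [0,100], a,b ∈ [−100,100],
RGB ∈ [0,1]. RGB columns supplied on 0–255 are auto-detected (any channel > 1)
and rescaled; pigment cells are split on ";" (configurable). Row order is
preserved because nearest-neighbour ties break to the lowest row index.
Delimited text is the canonical dialect (bit-exact fixtures: serialization
uses 17 significant digits and parsing uses correctly-rounded float
conversion); .xlsx input is a thin adapter. Munsell notation is not parsed —
the LAB/RGB columns are taken as authoritative, since chart conversion is a
one-time offline step. Pigment classes are stored per color name even though
in practice they are assigned per hue group; user tables may deviate and the
model does not enforce the many-to-one structure.

## Masking and binning

A pixel is background iff its alpha (when present) is below the cutoff
(default 0.5) or it lies channel-wise inside the chroma-key interval,
inclusive. The default interval, lower (0, 0.55, 0) to upper (0.24, 1, 0.24),
brackets the bright-green key color (0, 1, 0); an exact-match-only mask would
be useless for photographs, so an explicit, configurable interval is used.
Masking away every pixel is an error instructing the user to adjust bounds.

Histograms use fixed axis-aligned boxes, default 2 bins per channel (8 boxes):
CIELAB ranges L ∈ [0,100], a,b ∈ [−100,100] (centers 25/75 and ±50); RGB
[0,1] per channel (centers 0.25/0.75). Intervals are half-open [lo, hi) with
the final bin closed on top, so values exactly at a channel midpoint go to the
upper bin — a deterministic tie rule matching common histogram semantics.
Coordinates outside the nominal range (extreme chroma) are clamped into the
edge bins. The flat bin index is 1-based with the first channel varying
fastest: index = 1 + i₁ + n·i₂ + n²·i₃. Empty bins are retained and report
their geometric center with proportion 0; non-empty bins report the mean of
their member pixels computed in the histogram's own space (LAB means for LAB
histograms, not back-converted RGB means). Proportions are kept at full
precision internally; display rounding (Pct to 3 decimals, coordinates to 5)
happens only at serialization.

## Matching

Each bin representative is matched to the table entry minimising the chosen
metric; ties break to the earlier row. Euclidean is the default. Chi-square
uses the symmetric histogram form Σ(x−y)²/(x+y) applied to the coordinate
triple, with zero-denominator terms contributing 0. On CIELAB the signed
a\*/b\* axes can make denominators negative, so Chi-square "distances" can be
negative and the ranking erratic; this is computed as-is, with the argmin
still taken, because the mismatch between a distribution-comparison metric and
a signed perceptual space is itself the documented failure mode of that
pairing. The result table always contains all n³ rows in bin-index order —
the occupied bins are not promoted above empty ones — and Σ Pct = 1. The
three entry points (color names, hue groups, pigment classes) share one
pipeline and differ only in which column of the matched entry they report.

## Validation machinery

Predicted hue per image is the hue of the dominant (highest-Pct) bin,
collapsed to its first hue component ("purple-blue" → purple, "blue-green" →
blue, "yellow-red" → yellow); a Pct-weighted vote is available as an
alternative. The collapse-to-first-component rule is the package's own choice
where the deduction from compound chart hues to the five analysis categories
was genuinely open. Agreement between expected and predicted hues uses a
multiclass confusion matrix over yellow/green/red/blue/purple (configurable),
per-category one-vs-rest accuracy (TP+TN)/(TP+TN+FP+FN), and Cohen's
κ = (p₀ − pₑ)/(1 − pₑ). Degenerate cases: an empty matrix raises an
undefined-statistic error; pₑ = 1 with perfect observed agreement returns
κ = 1. Replicate summaries use the sample (n−1) standard deviation. Verbal κ
bands follow Landis–Koch (≤0.20 none/slight, ≤0.40 fair, ≤0.60 moderate,
≤0.80 substantial, ≤1 almost perfect); note that some published practice
labels κ ≈ 0.65 "moderate" — a banding divergence users should be aware of
when comparing reports. The pipeline itself is deterministic, so replicate sd
over repeated runs of identical inputs is 0 by construction.

## Synthetic data

The bundled 16-entry table is synthetic: eight entries sit exactly at the
default CIELAB bin centers (sRGB derived by gamut-clipped conversion) and
eight at the default RGB bin centers (CIELAB derived by conversion), with hue
groups spanning the five analysis categories plus compound forms, and pigment
classes spanning the classic colony-pigment families. Swatch images place a
foreground color (plus optional i.i.d. Gaussian noise per sRGB channel,
clipped to [0, 1]) on a chroma-key green field; labeled datasets sample table
entries uniformly. Everything is deterministic given a seed, down to PNG
bytes.

What these fixtures emulate is the color arithmetic of the pipeline — bin
boundaries, metric behaviour, hue recovery under channel noise. What they do
not emulate: photographic structure (texture, shadows, glare, mixed lighting),
camera color management, or the taxonomic composition of a real image corpus.
Passing recovery tests therefore bounds the algorithmic error, not field
performance on real colony photographs.

## Problem sizes and numerical choices

The test suite and acceptance script use 10×10–40×40 swatches, labeled
datasets of 30–50 images, noise levels {0, 0.02, 0.08, 0.2} sd per channel,
and 1000-query oracle comparisons — sizes chosen so each property is exercised
well away from sampling noise while the whole suite runs in seconds. At zero
noise, hue recovery on the bundled table is exact (κ = 1) in both color
spaces; κ is flat up to sd ≈ 0.08 (entries are ≥ 0.5 apart per RGB channel,
so small perturbations rarely flip a match) and degrades visibly by sd = 0.2.
Round-trip color conversion is accurate to < 1e−6 per channel in gamut; the
scikit-image conversion serves as an independent cross-check in the tests at
a 0.01 tolerance (white-point rounding differences, well under 0.5 ΔE).

## Known limitations

- The chroma-key interval is a fixed default; colonies with green hues close
  to the key color require user-adjusted bounds (or pre-masked images with
  alpha).
- 8 fixed bins coarsely quantise multi-colored colonies; the dominant-bin hue
  call can hide minority colors (inspect the full table or the histogram plot).
- Chi-square on CIELAB is intentionally unstable (see Matching) and should
  not be used for hue calls.
- The bundled table is a 16-color synthetic stand-in; real taxonomic work
  needs a full Rayner-style table supplied by the user.
- Very dark colonies photographed on backlit displays rarely reach true
  black; matching tends toward dark blue-gray names, a property of the input
  data rather than the matcher.
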