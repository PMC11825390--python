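# mycocolor

Colony color is a primary diagnostic character in fungal taxonomy, and it is
traditionally called by eye against a mycological color chart — R. W. Rayner's
1970 chart with its ~1252 named colors being the standard reference. Visual
matching depends on the observer's color perception and lighting, so two
mycologists can legitimately disagree about the same plate. `mycocolor` makes
the call computational: it reduces a background-masked photograph of a colony
to an 8-bin color histogram, matches each bin to the nearest entry of a
Rayner-style reference table, and reports color names, coarse hue groups, and
the fungal pigment classes (azaphilones, naphthoquinones, xylindein, melanins,
carotenoids, ...) associated with those hues. It is written for mycologists
describing cultures and for anyone validating automated color calls against
expert descriptions.

## Method

1. **Mask.** Load a PNG/JPEG; discard pixels inside a bright-green chroma-key
   interval (default `[0, 0.55, 0] ≤ RGB ≤ [0.24, 1, 0.24]`) or below an
   alpha cutoff.
2. **Bin.** Convert the remaining pixels to CIELAB (D65 reference white) or
   keep them in sRGB, and bin them 2 per channel into 8 fixed boxes
   (CIELAB ranges L\* ∈ [0,100], a\*, b\* ∈ [−100,100]; RGB [0,1]³). Each
   non-empty bin reports the mean of its member pixels and its pixel
   proportion; empty bins report their geometric center with proportion 0.
3. **Match.** Each bin representative x is matched to the reference entry y
   minimising either the Euclidean distance √Σᵢ(xᵢ−yᵢ)² (default) or the
   Chi-square histogram distance Σᵢ(xᵢ−yᵢ)²/(xᵢ+yᵢ). Chi-square is
   well-defined on RGB but unstable on the signed a\*/b\* axes of CIELAB —
   the instability is preserved, not patched, because it is diagnostic of
   why that pairing performs poorly.
4. **Validate.** Hue calls are compared with expert labels as two raters over
   a multiclass confusion matrix (yellow/green/red/blue/purple), reporting
   one-vs-rest accuracy (TP+TN)/(TP+TN+FP+FN) per hue and Cohen's
   κ = (p₀−pₑ)/(1−pₑ), with replicate runs summarised as mean ± sd.

The package bundles a 16-entry **synthetic** reference table (one entry at
every default CIELAB and RGB bin center) plus generators for labeled swatch
images, so everything runs with no downloads; a full Rayner-style table in the
nine-column format `Color,L,A,B,HueGroup,ClassOfCompounds,R,G,B` can be
supplied via `--lookup` / `load_lookup`.

## Worked example

```python
import numpy as np
from mycocolor import (SwatchSpec, make_swatch_image, make_fixture_table,
                       rayner_color)

table = make_fixture_table()                       # bundled synthetic chart
img = make_swatch_image(
    SwatchSpec(fg_color=(0.8, 0.78, 0.45), fg_fraction=0.6), "swatch.png")
print(rayner_color(img, table, space="lab").to_text(sep="\t"), end="")
```

prints

```
bin	L	a	b	Pct	ColorName
1	25.00000	-50.00000	-50.00000	0.000	Dark Delft Blue
2	75.00000	-50.00000	-50.00000	0.000	Bremen Blue
3	25.00000	50.00000	-50.00000	0.000	Amethyst Violet
4	75.00000	50.00000	-50.00000	0.000	Light Phlox Purple
5	25.00000	-50.00000	50.00000	0.000	Calliste Green
6	78.99704	-10.13780	42.52879	1.000	Sulphur Yellow
7	25.00000	50.00000	50.00000	0.000	Mars Yellow
8	75.00000	50.00000	50.00000	0.000	Olive-Ocher
```

Rows are in bin-index order (never sorted by Pct). The swatch's single
foreground color has L\* ≈ 79 (bright), a\* ≈ −10 (slightly green),
b\* ≈ 43 (strongly yellow), so every pixel lands in bin 6 (Pct 1.000) and its
mean is matched to the nearest reference color, "Sulphur Yellow". The seven
empty bins print their exact geometric centers with Pct 0.000, matched to the
reference colors nearest those centers.

The same analysis from a shell:

```
mycocolor color --space lab swatch.png
mycocolor hue --space rgb --metric chisq swatch.png
mycocolor validate manifest.csv --all-pairings
```

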