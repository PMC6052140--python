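# onoffscan

Tools for asking a simple question about any visual scene: **does it drive
the retina's ON pathway or its OFF pathway harder?**

ON ganglion cells respond to luminance increments (a bright center on a
darker surround), OFF cells to decrements. Ordinary text flips this balance
hard: dark letters on a light page overstimulate OFF pathways, light letters
on a dark page overstimulate ON pathways — and sustained reading of one
polarity measurably changes subfoveal choroidal thickness (SFChT), a
short-term biomarker of the eye-growth signaling implicated in myopia. This
package provides the three pieces needed to study that chain on a desk:

1. **`onoffscan.core`** — a multi-scale center-surround analyzer for images
   and video frames,
2. **`onoffscan.stimgen`** — reproducible synthetic stimuli
   (polarity-controlled text, matched-luminance pairs, checkerboards,
   1/f-noise scene surrogates),
3. **`onoffscan.choroid`** — the statistical pipeline for choroidal
   thickness reading experiments, plus a synthetic cohort generator for
   parameter-recovery testing.

## The core statistic

At every interior pixel of a grayscale frame, a simplified receptive field
computes a signed contrast

```
r_k(x, y) = I(x, y) − (1/8) Σ I(x + k·dx, y + k·dy),
            (dx, dy) ∈ {(±1,0), (0,±1), (±1,±1)}
```

— the center gray level minus the mean of 8 peripheral pixels at distance
`k`. Positions with `r > 0` are ON-stimulating, `r < 0` OFF-stimulating.
A 640×480 frame scanned at margin 10 yields 285,200 receptive fields per
scale. Scales `k = 1…10` probe spatial frequencies `sf(k) = sf₁ / k`
(default `sf₁ = 22.4` cyc/deg, so 22.4 down to 2.24 cyc/deg).

Per scale, responses are aggregated into ON and OFF strengths. The default
aggregator is **response energy** (`Σ r²` over each sign class); plain sums,
position counts, and thresholded variants are selectable. The normalized
summary is the polarity index

```
PI(k) = (ON_k − OFF_k) / (ON_k + OFF_k)   ∈ [−1, +1],
```

negative when OFF dominates. Two exact invariants anchor the analysis:
inverting a frame (`255 − I`) swaps ON and OFF exactly, and adding a
constant to every pixel changes nothing.

## Worked example

```python
from onoffscan import TextStimulusSpec, render_text, analyze_frame

frame = render_text(TextStimulusSpec(text="DARK TEXT ON A\nLIGHT PAGE",
                                     frame_width=320, frame_height=140))
print(analyze_frame(frame).to_dataframe().to_string(index=False))
```

```
 scale_k  spatial_frequency_cpd  on_strength  off_strength  on_count  off_count  polarity_index
       1                   22.4    1.194e+07     2.316e+07      1416        669         -0.3198
       2                   11.2    1.155e+07     2.497e+07      1686        669         -0.3675
       ...
      10                   2.24    8.894e+06     2.524e+07      2237        669         -0.4789
```

Although *more* positions are ON-stimulating (the bright halo around every
stroke), the few stroke-center responses are so much larger that OFF energy
dominates at every scale: the polarity index is negative throughout
(−0.32 to −0.56). Analyzing the photometrically inverted frame gives
exactly the mirrored profile (+0.3198 at k = 1): light text on a dark page
is ON-dominated. Checkerboards and 1/f noise come out balanced (|PI| <
0.02 and < 0.1), and the asymmetry survives any global brightness shift
unchanged.

The same workflow from a shell:

```bash
onoffscan generate text --text "READING" -o text.png
onoffscan analyze text.png -o results/ --plot
onoffscan simulate-cohort --seed 1 -o cohort.csv
onoffscan stats cohort.csv -o report.json
```

`stats` reports, per condition, the mean 30/60-minute change from baseline
with paired t-tests (eyes pooled as independent observations), a one-way
repeated-measures ANOVA over timepoint, and — for dark text — the OLS
regression of 60-minute thinning on spherical-equivalent refraction. The
default synthetic cohort (7 subjects × 2 eyes, 5 reads per cell, 7 µm read
SD) thins by −16.13 µm under dark text, thickens by +9.96 µm under light
text, stays flat for a blank screen, and thins 1.44 µm more per diopter of
myopia.

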