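# Methods

## The center-surround analyzer

The analyzer models a retinal ganglion cell as crudely as possible on
purpose: the response at pixel `(x, y)` and scale `k` is the center gray
level minus the unweighted mean of the 8 peripheral pixels at offsets
`{(±k, 0), (0, ±k), (±k, ±k)}` (a Moore neighborhood scaled by `k`). There
is no difference-of-Gaussians weighting, no contrast normalization, and no
gamma model — pixel values are treated directly as luminance proxies. The
virtue of this simplicity is a pair of exact algebraic properties that make
the statistic interpretable:

- **Inversion antisymmetry.** Replacing `I` with `255 − I` negates every
  response, so ON and OFF strengths and counts swap exactly, at every scale
  and under every aggregator. Polarity asymmetries measured on a stimulus
  pair rendered as exact photometric inverses are therefore genuine, not
  artifacts of the filter.
- **Offset invariance.** Adding a constant to every pixel cancels in
  center minus surround-mean, bit-exactly in IEEE arithmetic for
  integer-valued frames (all intermediate quantities are multiples of 1/8
  well below 2^53). Global brightness is a nuisance parameter the analyzer
  cannot see, which justifies matching stimulus pairs by mean pixel value
  (below).

One shared sampling grid is used for all scales, with margin equal to the
largest scale so that every surround sample is in-frame; for the default
scales 1–10 on a 640×480 frame this is every interior pixel,
(640−20)·(480−20) = 285,200 positions. Responses are computed in floating
point with no intermediate rounding; a response of exactly 0 counts as
neither ON nor OFF.

### Aggregation: why response energy

Positions are classified by response sign, but how the two classes are
*scored* is a genuine design choice, and the obvious candidates fail an
exact balance constraint: for any frame whose non-background content lies
at least `margin + k` from the edge, every content pixel enters the grid
once as a center (weight +1) and eight times as a surround (weight −1/8),
so the signed responses sum to exactly zero. A plain signed/magnitude sum
(`Σ r` per class) is therefore *always* balanced for interior content —
ON and OFF magnitude sums are equal no matter what the image looks like —
and a pure position count leans the other way (thin dark strokes produce
many weak bright-halo positions and few strong dark ones, so counting gives
ON dominance for dark text).

The default aggregator is therefore **energy**: `ON_k = Σ_{r>0} r²`,
`OFF_k = Σ_{r<0} r²` (power mode, exponent γ = 2). Squaring weights the few
large stroke responses over the many weak halo responses, which is what
makes thin dark text OFF-dominated and its inverse ON-dominated, and it
reproduces the observation that very thick dark letters are *less*
OFF-stimulating than thin ones (stroke interiors at widths ≫ 2k respond
zero, leaving only edge responses, which are symmetric). `sum`, `count`
and `threshold` modes remain selectable for sensitivity analyses; the
`threshold` mode restricts both counts and sums to `|r| > T`.

### Calibration

Scale maps to spatial frequency as `sf(k) = sf₁ / k`; a field at scale `k`
samples a period of 2k pixels, hence the 1/k law. The default
`sf₁ = 22.4 cyc/deg` reproduces the frequency axis of the original video
geometry (monochrome camera, 16 mm lens), giving 22.4, 11.2, …, 2.24
cyc/deg at k = 1, 2, …, 10. `Calibration.from_optics(focal_length_mm,
pixel_pitch_um)` derives `sf₁` as the Nyquist frequency
`1 / (2 · deg-per-pixel)` for other sensors. The constant only labels the
frequency axis; it never affects the strengths.

## Synthetic stimuli

**Text** is rendered with an embedded axis-aligned segment font (3×3 anchor
grid per glyph, strokes drawn as rectangles of exactly the requested
width), not with system fonts, so frames are bit-reproducible across
platforms and stroke width is controllable independently of glyph height.
Glyph shapes are blocky approximations — the object of study is the
contrast structure of print (thin uniform-polarity strokes on a uniform
field), not typography, and Latin-only coverage is a stated limit.
Anti-aliasing is off: strokes are binary, which keeps the
inversion-antisymmetry test exact.

**Luminance matching** of a stimulus pair shifts each frame by
`target − mean` (a pure offset). Physical-display matching in cd/m² is not
modeled; by the offset-invariance property the analyzer cannot distinguish
the two, which is the justification for the substitution. A shift that
would push any pixel outside [0, 255] raises an error reporting the
feasible target range — silent clipping would break the invariance being
relied on. A binary 0/255 frame is consequently unmatchable to any other
mean, by design.

**Checkerboards** (inversion-plus-translation symmetric, so balanced up to
border effects) and **constant fields** (zero profile) serve as negative
controls. **1/f noise** stands in for natural scenes: white Gaussian noise
is shaped to a 1/f amplitude spectrum in the Fourier domain, then affinely
rescaled to mean 128 with all values inside [20, 235]. It reproduces the
second-order statistics and the symmetric luminance distribution of natural
scenes — hence the near-balanced ON/OFF profile (|PI| < 0.1 at 128×128) —
but none of their higher-order structure (edges, occlusions, shadows), so
balance on these surrogates supports, but does not prove, balance on real
footage.

### Stroke-width harness

The thick-vs-thin comparison holds glyph geometry self-similar: stroke
widths w ∈ {1, 2, 4, 8, 16} px at glyph height 12 w. At scale k = 4 the
OFF share `OFF/(ON+OFF)` falls monotonically from ≈ 0.73 (w = 1) toward
0.5 (w = 16) for every test string. If width is varied at *fixed* glyph
height instead, the share still falls but can wiggle by a few 10⁻⁴ near
its 0.5 asymptote, where discretization noise dominates the vanishing edge
signal.

## Choroidal-thickness statistics

The pipeline mirrors a two-condition reading experiment: SFChT measured by
OCT at 0/30/60 minutes, ≥5 manual reads per B-scan. `change_from_baseline`
averages repeated reads per (subject, eye, condition, timepoint) cell
first, then subtracts the t = 0 cell mean. Eyes are treated as independent
observations when pooling ("eyes" mode, the convention of the underlying
analyses); a conservative "subjects" mode that averages the two eyes first
is provided and flagged in the report. Tests are the classical ones:
one-sample t on differences (n − 1 df, two-sided), one-way
repeated-measures ANOVA over timepoint with subject-eye as the repeated
unit (sphericity assumed, via `statsmodels` `AnovaRM`; an independent
sums-of-squares oracle checks it in the tests), and OLS with Pearson R for
the refraction regression. No multiple-comparison correction is applied
anywhere, matching the design being replicated. Zero-variance samples
raise a `DegenerateSampleError` rather than reporting p = 0.

## The synthetic cohort generator

The generator emulates the raw measurement spreadsheet of such an
experiment. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 7 | subjects, each contributing both eyes |
| `effect_60min_dark` | −16.13 µm | pooled-eyes true 60-min change, dark text |
| `effect_60min_light` | +9.96 µm | same, light text |
| `effect_60min_blank` | 0 µm | blank-screen control |
| `between_subject_sd_dark/light` | 4.54 / 6.51 µm | SD of the true effect across subjects |
| `effect_30min_fraction` | 0.5 | fraction of the 60-min effect expressed at 30 min |
| `measurement_sd` | 7 µm | SD of repeated manual reads (plausible mid-range of 5–10 µm) |
| `repeats` | 5 | reads per cell |
| `baseline_mean/sd` | 255 / 40 µm | subject baseline SFChT |
| `refraction_slope` | 1.44 µm/D | extra dark-text thinning per diopter |
| `refraction_range` | [−6.25, +0.25] D | uniform spherical-equivalent draw |

Per subject, one spherical equivalent and one baseline are drawn and shared
by both eyes. The dark-text refraction term is centered on the mid-range
refraction (−3 D), so the pooled mean change stays at `effect_60min_dark`
regardless of the cohort's refraction draw; with these defaults the
centered parameterization coincides (to 0.01 µm) with the uncentered line
`change = 1.44·SE − 11.8`. The 30-minute change is a fixed fraction of the
*realized* 60-minute change — the fraction 0.5 is a generator convention,
not an empirical claim, since only significance (not effect size) is
typically reported at 30 min. Reported between-subject SDs could also be
read as between-eye SDs; the generator treats them as between-subject and
shares the draw across a subject's eyes. A sinusoidal diurnal drift term
(`diurnal_amplitude`, default 0, period 24 h) is available but off by
default, reflecting time-locked morning measurement sessions.

What passing recovery tests shows: the *pipeline* is an unbiased estimator
of the generator's effects at the study's n. What it cannot show: anything
about real eyes — the generator has Gaussian noise, no segmentation error
structure, no inter-observer component, and no diurnal confound by default.

## Numerical and design notes

- Responses and strengths are float64 throughout; for integer-valued
  frames the zero-signed-sum and offset-invariance identities are exact,
  not approximate, and the vectorized analyzer is tested for exact
  equality against a scalar double-loop reference on small frames.
- Polarity index with ON = OFF = 0 (e.g. a constant frame) is reported as
  NaN (`null` in JSON, `nan` in CSV), never as 0.
- CSV output uses `.` decimals, a fixed column order, and 6 significant
  digits, so identical runs are byte-identical and diffable.
- Profile counts use one shared grid across scales, so `on_count +
  off_count ≤ grid size` with equality only when no response is exactly 0.
- Offline frame processing only: no claim of real-time throughput is made
  or needed for the analyses here.
- Problem sizes in the test-suite simulations (200-cohort recovery runs,
  20-seed noise sweeps, 128–256 px control stimuli) were chosen as the
  smallest sizes at which Monte-Carlo error is comfortably inside the
  asserted tolerances.

## Known limitations

- The aggregation rule of the original real-time analyzer that motivated
  this package is not recoverable from its published description (see the
  balance argument above); energy aggregation is this package's own
  documented choice, with the alternatives selectable.
- The embedded font covers A–Z, digits and basic punctuation; no CJK, no
  proportional spacing, no anti-aliasing by default.
- Eyes-as-independent pooling overstates effective n when eyes are
  correlated; the subject-level mode exists precisely because of this.
- The cohort generator's refraction is drawn per subject, so a 7-subject
  cohort has 7 distinct refractions duplicated across 14 eyes.
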