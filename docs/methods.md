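# Methods

## Disparity geometry

The display is modelled by its physical diagonal, aspect ratio, pixel
grid and viewing distance $D$; all conversions run through the
horizontal pixel pitch (square pixels assumed, as on the panels the
profiles describe). A binocular disparity $\eta$ corresponds to a total
on-screen shift $s = 2D\tan(\eta/2)$. The exact tangent form is used
rather than the small-angle approximation $s \approx D\eta$; at the
scales involved (≤ 2,400 arcsec at metres of distance) the two agree to
well under 0.01%, so this is a matter of exactness, not accuracy.

Content moves by whole pixels, so a requested disparity is quantized:
the exact pixel shift is rounded to the **nearest even integer**, ties
rounding up. Even, because the shift is split $\pm s/2$ per eye to keep
the cyclopean position of the figure fixed; rounding the total rather
than each half keeps the per-eye shifts integral. The achieved disparity
is recomputed from the applied shift and always lies within one pixel's
angular subtense of the request (about 5.5 arcsec on the default
profile). A warning flag is raised when the relative quantization error
exceeds 10% — on the default 23-in 4K profile at 5 m requests much below
40 arcsec start to carry such errors, which is why 40 arcsec is a
sensible finest level there (it is realised as 43.8 arcsec, a 9.4%
error; both numbers are reported rather than silently merged). Crossed disparity (figure in front of the screen)
is the default sign, since the protocol teaches subjects to look for
protruding figures; it is configurable per stimulus.

Two display profiles ship as plain-text configs: the default 23-in
16:9 3840×2160 panel at 5 m, and a 17.3-in 1920×1080 notebook panel.
A geometry may equivalently be given as width/height in mm.

## Stereogram synthesis

The construction is the classic single-field one. A base random dot
field is drawn once per pair: cells of `dot_size` × `dot_size` pixels
are independently bright with probability ρ. Defaults are ρ = 0.5 with
2-px black/white dots — maximal per-pixel entropy, the standard choice
for dense RDS; the source study does not state its dot statistics, so
these are declared package defaults, fully configurable. Each eye's
image is the base field with the figure region translated by its
half-shift; the disoccluded strip (figure-region pixels not covered by
the translated copy) is refilled from a fresh, independent dot field of
the same statistics rather than wrapped around, so no correlated seam
marks the figure border. By construction the dot density inside and
outside the figure is identical in distribution in either half-image —
the monocular-cue null that the test suite verifies statistically. Note
the independence unit for that check is the **dot cell**, not the pixel
(a 2-px dot covers four pixels), so binomial noise bounds use cell
counts.

Figure masks come from a closed catalogue: circle, square, triangle,
rectangle, cross, pentagon, capital letters and digits. Geometric shapes
are rasterized analytically (pixel-centre tests; squares by integer
slicing so an n-px square covers exactly n² pixels); letters and digits
use an embedded 5×7 bitmap atlas scaled by whole-pixel replication, so
stimuli are identical on every platform and glyph strokes (size/7 px,
i.e. ~140 px for a 1.5° figure on the default profile) comfortably
survive dot quantization. Shapes default to 1.5° of visual angle at the
figure centre of the canvas, except where physical sizes are fixed (the
two 15-cm teaching circles).

Multi-region stimuli (the screening item) apply shifts outermost-first,
each region sampling from the *base* field at its own absolute shift, so
an inner figure overwrites an outer one with its own disparity instead
of compounding. Default screening sizes are 2.8°/1.9°/1.0° for the
circle/square/pentagon: large enough to nest strictly after
rasterization with room for the ±half-shifts at 2,400 arcsec, small
enough to fit the default screen, which subtends only about 5.8° × 3.3°
at 5 m. Every generated pair records a ground-truth disparity map
(total pixel offset per left-eye pixel, occlusion-refill pixels flagged
invalid) and is bit-exactly reproducible from its seed and metadata.

Verification is by an independent brute-force block matcher: exhaustive
horizontal SSD over all lags, ties to the smallest |lag|. Ground truth
is used only to choose sampling locations where disparity is
well-defined (constant over the block, away from refill); the matcher
itself sees nothing but the two rasters.

## Examination protocol

The quantitative test descends 800 → 400 → 200 → 100 → 60 → 40 arcsec.
At each level up to five figures are drawn without replacement from the
ten-figure bank in seeded random order; the level is **passed on the
first correct naming** (the remaining figures are skipped — "up to five"
is read as a budget, not a quota), and **failed** after five consecutive
misses, which ends the descent. The recorded stereoacuity is the lowest
passed level. Failing the coarsest level yields no value, sets a
referral flag, and routes to the screening item, where failing to
recognise *any* of the three coarse concentric figures flags suspected
stereoblindness. Whether screening precedes the quantitative test or is
triggered by failure is left to the operator; both orders are supported.
Presenter hints are modelled on the responder side only (they shrink the
answer set, raising the guess rate), not as protocol state.

Consequences worth knowing: a deterministic observer with threshold θ is
always recorded at the smallest schedule level ≥ θ, and the pass rule
admits lucky passes — with guess rate γ the probability of passing a
five-trial level blind is $1-(1-\gamma)^5$ (≈ 0.41 at γ = 0.1), which is
the price of the fast "any of five" rule and is quantified, not hidden,
by the simulations.

## Simulated observers

Deterministic mode (correct iff disparity ≥ θ; the boundary counts as
visible, a declared convention) exercises the protocol logic exactly.
Stochastic mode uses a four-parameter psychometric function on
log-disparity with a cumulative-normal link,
$p(d) = \gamma + (1-\gamma-\lambda)\,\Phi(\beta(\ln d - \ln\theta))$,
with defaults γ = 1/10 (ten-figure forced choice), λ = 0, β = 8 per log
unit. The slope default is conventional psychophysics, not fitted to any
apparatus — no human psychometric data for this display exist in the
package. Wrong answers are uniform over the remaining figures. What the
simulations show is therefore the protocol's behaviour under a standard
observer model (bias, spread, lucky-pass rates); they do not model
crosstalk, eye movements, fatigue, accommodation, or any human factor
beyond the psychometric function.

## Agreement statistics

Instrument comparisons run on the three-band ordinal scale — fine
(20–60 arcsec for the near tests, whose finest level is 20; 40–60 for
the distance tests, whose finest is 40), moderate (100–200), coarse
(≥400), coded 1 < 2 < 3. A value below a scheme's fine floor raises an
error instead of clamping. The bands as stated leave gaps (61–99,
201–399); membership is implemented by thresholds at 60 and 200 so the
mapping is total, which is immaterial for the catalogued levels.

The Wilcoxon matched-pairs signed-rank test is implemented in the form
SPSS-family packages print: zero differences dropped before ranking
("wilcox" zero handling, not Pratt), average ranks over ties, variance
$n(n+1)(2n+1)/24 - \sum_t(t^3-t)/48$ with **no continuity correction**,
$|Z|$ from the smaller rank sum, and the sign of Z following the
dominant difference direction; all-tied input returns Z = 0, p = 1
exactly, and p is reported two-sided from the normal distribution. On
grade data ties are the rule, so the tie-corrected/uncorrected choice
changes results materially (on the bundled distance pairing: 1.414 vs
1.342). The test runs on grades, not raw arcsec, because the instruments
quantise differently and only the banded scale is commensurable.

On the accuracy of the normal approximation at small n: the signed-rank
statistic is a lattice variable, and for ≤ 10 non-zero differences the
uncorrected normal p tracks the exact sign-flip permutation mid-p
closely on average (mean deviation ≈ 0.02 on six-level ordinal data) but
can deviate by ~0.1–0.25 at balanced or extreme sign patterns — a
property of any normal approximation to a discrete distribution, not of
the implementation. The test suite pins this down with a full-enumeration
oracle; the mid-p convention is used there because an uncorrected
normal approximation estimates the mid-p (a continuity-corrected one
would target the inclusive p).

The bundled reference dataset has 13 records from 12 subjects (one
subject appears before and after refractive correction, with the
corrected record used for per-subject summaries).

## Numerical and testing choices

Test-suite stimulus work runs on a 960×540 rendering of the default
panel (pitch 4× coarser, shifts ≈ ¼ of full resolution); the end-to-end
stimulus checks additionally run at the full 3840×2160 profile, one pair
per level. Monocular-cue checks pool 100 seeded generations and compare
the standardized mask-vs-background density difference against its
binomial expectation at dot-cell granularity. Monte-Carlo guards in the
observer tests (recovery mode and spread) were frozen from one oracle
run of the generating model and serve as regression bounds, not claims
about human performance.

## Known limitations

- No model of the autostereoscopic channel separation itself: crosstalk,
  backlight optics, eye tracking, luminance and viewing-zone behaviour
  are hardware properties outside the package's scope; the render module
  substitutes software formats (side-by-side, anaglyph preview, per-eye
  frames).
- Disparity is purely the on-screen angular kind: no
  interocular-distance-dependent depth magnitude, no vergence or
  accommodation modelling.
- The glyph atlas is 5×7 and fixed; it trades typographic fidelity for
  bit-reproducibility.
- Simulated observers are stationary: no learning, fatigue or
  sequential effects across trials.
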