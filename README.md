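# rdstereo

A display-hardware-agnostic toolkit for **random-dot distance
stereoacuity testing**: the software side of a glasses-free clinical
stereotest, from disparity geometry and stereogram synthesis through the
examination protocol to the agreement statistics used to compare
stereotest instruments.

Stereoacuity — the smallest binocular disparity η (in arcseconds) a
person can detect — is measured at distance for strabismus follow-up and
for occupational screening. Random-dot stereograms (RDS) are the
instrument of choice because the hidden figure carries **no monocular
cue**: both half-images are statistically identical dot fields, and only
the horizontal displacement of the figure region between the eyes
encodes the shape. This package targets researchers and developers of
computerised stereotests who need reproducible stimuli, a simulatable
protocol, and the exact statistics clinical comparison studies report.

## What it computes

**Geometry.** On a flat display viewed from distance $D$, a disparity
$\eta$ is realised by a total horizontal shift
$s = 2D\tan(\eta/2)$ of the figure region, split as $\pm s/2$ between
the two eyes' images. Shifts are quantized to the nearest even pixel
count; both the requested and the achieved disparity are reported.

**Stimuli.** Classic Julesz-style construction: one random dot field,
figure region displaced per eye, disoccluded strips refilled at the same
dot density. Three items: a teaching graph (RDS circle beside an outline
circle, both 15 cm), a stereoblindness screening graph (concentric
circle/square/pentagon at 800/1,600/2,400 arcsec), and ten-figure banks
per quantitative level (800, 400, 200, 100, 60, 40 arcsec). Every pair
carries a ground-truth disparity map and can be verified by an
independent brute-force block matcher.

**Protocol.** Coarse-to-fine level descent: up to five figures per
level, a level is passed on the first correctly named figure, the
descent stops at the first fully-missed level, and the lowest passed
level is the recorded stereoacuity.

**Statistics.** Results are graded fine (≤60 arcsec) / moderate
(100–200) / coarse (≥400) and two instruments are compared by 3×3
cross-tab, concordance, and the tie-corrected Wilcoxon matched-pairs
signed-rank test

$$Z = \frac{\min(W^+, W^-) - n(n+1)/4}{\sqrt{n(n+1)(2n+1)/24 - \sum_t (t^3 - t)/48}},$$

with zero differences dropped, average ranks, no continuity correction,
and the sign of $Z$ following the dominant difference direction — the
convention clinical statistics packages print. A 13-record reference
dataset (12 subjects, four instruments) is bundled.

## Worked example

```sh
python examples/agreement_statistics.py
```

prints, for the two distance instruments:

```
--- Distance Randot (3 m) vs autostereoscopic test (5 m) ---
Distance Randot (3 m) \ autostereoscopic test (5 m)      fine  moderate    coarse
fine                 9         0         0
moderate             1         2         0
coarse               0         1         0
Wilcoxon (tie-corrected, zeros dropped): Z = -1.414, p = 0.157 (n non-zero = 2)
concordance: 84.6% (11 of 13)
```

Nine pairs grade fine on both tests; the two off-diagonal pairs differ
by exactly one grade in the same direction (the conventional card test
grading one band coarser). The signed-rank test finds no systematic
difference between instruments (p = 0.157), and 11 of 13 paired results
agree exactly. The other examples show the disparity-to-pixel budget of
the reference display (`disparity_geometry.py`), stimulus generation
with block-matching verification (`make_stimuli.py`), and threshold
recovery by simulated psychometric observers
(`simulated_examination.py`).

A thin CLI wraps the same calls: `rdstereo generate`, `rdstereo screen`,
`rdstereo session`, `rdstereo simulate`, `rdstereo analyze` (see
`rdstereo --help`).

## Layout

- `src/rdstereo/geometry.py` — display model, disparity/extent conversions, quantization, profiles
- `src/rdstereo/rds.py` — masks, glyph atlas, stereogram synthesis, the three stimulus items
- `src/rdstereo/blockmatch.py` — exhaustive SSD block matching for verification
- `src/rdstereo/render.py` — side-by-side / anaglyph / frame-pair PNG output
- `src/rdstereo/protocol.py` — screening and level-descent examination, transcripts
- `src/rdstereo/observer.py` — deterministic and psychometric simulated subjects
- `src/rdstereo/stats.py` — grading, cross-tabs, signed-rank test, concordance, reference data
- `docs/methods.md` — models, parameter choices and limitations
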