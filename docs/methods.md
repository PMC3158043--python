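# Methods

`stereocorr` simulates the detection of depth corrugations in dense
random-dot stereograms by a model observer whose disparity encoding stage
is a population of windowed, normalized cross-correlators with a
size/disparity correlation: detectors tuned to larger binocular
disparities integrate over larger spatial windows.  This note documents
the model, its parameters, the numerical choices, and what the synthetic
stimuli do and do not capture.

## Stimuli

A disparity grating modulates the binocular disparity of a random-dot
field as a function of vertical position,

    d(y) = A sin(2 pi f y + phi)            (sine grating)
    d(y) = A sgn[sin(2 pi f y + phi)]       (square grating)

with amplitude `A` in arcmin, corrugation frequency `f` in cycles/deg and
`sgn(0) = +1` as a deterministic tie-break.  The matched control stimulus
is *disparity noise*: each dot receives an i.i.d. draw from the grating's
marginal disparity distribution (`±A` with probability 1/2 for a square
parent; `A sin U`, `U ~ Uniform[0, 2 pi)`, i.e. an arcsine law, for a sine
parent), so grating and noise contain the same disparity range and differ
only in spatial arrangement.  Whether the original experiments scrambled
disparities or dot positions is not documented; marginal-distribution
sampling is the implemented interpretation.

Dot fields are Poisson in number (mean = density × area), uniform in
position, with 50/50 bright/dark dots on a mean-gray background
represented as luminance 0.  Defaults: density 120 dots/deg², dot
diameter 1.2 arcmin, field 2.0° × 2.0° (at least two corrugation periods
at the lowest core frequency; depth-limit runs size the field per
frequency, see below).  The dot parameters are not stated in the modelled
experiments' report and are chosen as typical "dense RDS" values; all are
configurable.

Each dot's disparity is split symmetrically, ±d/2 per eye, and dots are
rendered at 0.15 arcmin/px with analytic anti-aliasing: per-pixel disc
coverage approximated by a linear ramp of one pixel width across the disc
edge.  This keeps amplitudes as small as 0.3 arcmin (two render pixels of
interocular offset) faithfully representable.  Overlapping dots sum and
clip to [-1, 1]; dots extending past the field edge are clipped silently.

## Optics

The eye's optics are a single isotropic Gaussian point-spread function of
SD 2 arcmin, truncated at 4 SD (<1e-4 mass lost), followed by area-true
block-average downsampling to the working pitch of 0.6 arcmin/px.  The
default evaluation order downsamples first and then blurs at the working
pitch with the Gaussian SD reduced so the composite kernel variance is
exact (the block average contributes (k²-1)/12 render-pixel variances).
Because the PSF is much wider than a working pixel, this is
indistinguishable from the literal blur-then-downsample order (0.7% RMS
on rendered stimuli; a regression test bounds it at 1%) and an order of
magnitude faster.  The literal order remains available
(`order="blur_first"`).

## Disparity encoding

A correlator tuned to vertical position `y` and preferred disparity `dx`
compares a patch of the left image centred at a fixed column `x` with a
patch of the right image centred at `x + dx`.  Both patches are weighted
by a Gaussian window of SD `sigma`, truncated at two standard deviations,
and the response is the Pearson correlation coefficient of the two sets
of window-weighted pixel values: +1 for a perfect match, -1 for
anticorrelation, undefined (flagged NaN) where a patch has zero variance
or the window leaves the raster.  Edge windows are flagged rather than
shrunk — shrinking would covertly change the size/disparity relation.

The size/disparity correlation sets

    constant:   sigma = 3                      (the classic fixed window)
    linear:     sigma = 3 + 0.24 |dx|
    quadratic:  sigma = 3 + 0.032 dx²          (all in arcmin)

The linear coefficient 0.24 is this package's default, chosen so that the
linear and quadratic relations assign the same window (sigma = 4.85,
2 sigma ≈ 10 arcmin) to detectors preferring 7.6 arcmin; it is exposed as
a parameter rather than asserted as canonical.

The population grid steps by one working pixel (0.6 arcmin) in both `y`
and preferred disparity; the standard disparity range is ±13 arcmin
(realized as all multiples of 0.6 within that bound, ±12.6), extended to
as much as ±140 arcmin for the depth-limit runs.  The full surface
C(y, dx) is computed by a separable algorithm (row-weighted sums followed
by 1-D vertical convolutions), which is numerically identical to the
direct per-window Pearson computation (tested to 1e-10 against an
independent brute-force oracle) and fast enough for Monte-Carlo template
estimation (~30 ms per stimulus at core settings).

## Templates and decision

The observer's priors are per-condition mean and SD surfaces estimated
from `n` independently generated stereograms pushed through the identical
pipeline.  A bank at one frequency holds every phase × amplitude ×
waveform combination (default 36 phases in 10° steps × amplitudes
{0.3, 1.3, 2.5, 5.1, 7.6, 10.1} arcmin × {sine, square} = 432 grating
templates) plus one noise template per parent waveform and amplitude (12),
each from `n = 100` stereograms by default.  Template ensembles draw
their seed streams from (master seed, condition), so any template is
reproducible in isolation and banks are order-independent.

Matching uses the Pearson correlation between the observed surface and
each template's mean surface over jointly defined entries; undefined
(edge-flagged) entries are excluded from both template statistics and
matching.  The SD surfaces are stored (they are informative diagnostics)
but do not enter the score; a variance-weighted variant would slot into
`match_quality` directly.  In a two-interval trial the observer computes
`M_grating - M_noise` for each interval and picks the larger; exact ties
break uniformly at random (practically relevant only for bit-identical
surfaces).  The observer knows the blocked corrugation frequency but not
the trial's amplitude, waveform or phase; an unknown-frequency variant
maximizes the grating match across several banks.

## Simulated psychophysics

One trial synthesizes a grating stimulus (phase drawn from the bank's
phase set) and a matched noise stimulus with fresh dot fields, randomizes
the interval order, and scores the decision.  Percent correct per
(frequency, amplitude, waveform) carries a Wilson 95% interval (chosen
for small-n coverage; the comparison experiments' method is unstated).
All trial streams are seeded per condition, so a fixed master seed gives
bit-identical result tables.

The upper depth limit at a frequency is the largest amplitude whose
accuracy exceeds the 80% criterion, refined by interpolating the
criterion crossing in log-amplitude (the target relationship is a power
law); runs whose accuracy never crosses the criterion are flagged
censored instead of extrapolated.  The limit-versus-frequency slope is an
ordinary least-squares fit in log-log coordinates over uncensored
frequencies.

### Problem sizes

Two labelled profiles are used:

* **Core (default)**: 36 phases, 100 stereograms/template, 200
  trials/condition — the full study conditions.
* **Reduced (desk-scale)**: 12 phases, 50 stereograms/template, 150
  trials/waveform, used by the acceptance script and the heavier tests.
  Template-sampling noise at this scale costs a few percentage points of
  accuracy but preserves every qualitative contrast.

Depth-limit runs share one field height across all frequencies in the
run — two corrugation periods at the lowest frequency — mirroring the
procedure they emulate, where the same stimuli are re-analysed with a
wider detector range.  (Sizing the field per frequency instead gives low
frequencies several times more surface rows per period and visibly
steepens the measured limit-versus-frequency slope.)  The field width
accommodates the largest window at the largest preferred disparity; the
disparity grid extends to the largest tested amplitude plus margin
(capped at ±140 arcmin) with a 1.2-arcmin step; surface rows step by two
working pixels.  Tested amplitudes form a geometric ladder
`ratio × 29 arcmin·cpd / f` with ratios 0.3–1.8; the 29 arcmin·cpd scale
anchors the ladder to the ~80%-correct point of the high-frequency
detection runs (7.6 arcmin at 3.8 cpd) so the criterion crossing is
bracketed with margin on both sides at every frequency.

## Energy-model verification

A stereo energy unit is a quadrature pair of left/right Gabor subunits
with position disparity `dx` and zero phase disparity; its response
splits exactly as S = B + L + R into a binocular cross term and monocular
energies.  Summing B over units tuned to all spatial frequencies and
orientations (envelope size held fixed, truncated at 2 SD to match the
correlation window) collapses the carriers onto a delta function and
leaves the raw product sum of the window-weighted patches; normalizing by
the integrated monocular energies, C_int = B_int / (2 sqrt(L_int R_int)),
bounds the result to [-1, 1].

The raw bank sum retains a term in the mean windowed pixel values.  That
term is exactly the zero-frequency (envelope-only) unit's contribution,
and it does **not** vanish per window even for dense random-dot patterns:
optical blur limits a sigma = 3 window to roughly 25 independent samples,
so the window mean fluctuates at the ~20% level whatever the dot density.
By default the implementation subtracts the zero-frequency contribution
from the binocular and monocular sums, which turns them into the
covariance/variance sums of the correlator's Pearson coefficient; the
bank sum then reproduces the windowed correlation to better than 0.005
across random windows.  `subtract_dc=False` keeps the raw sum, the form
relevant for stimuli with genuine large-scale luminance structure.

Quadrature: 96 log-spaced radial frequencies from 0.25 cycles/deg to the
working-grid Nyquist (50 cycles/deg) × 48 orientations over the half
plane (the carriers are even in k), polar Jacobian weights with trapezoid
radial endpoints.  Doubling the density changes C_int by under 1e-4;
`integrated_correlation` re-evaluates at doubled density on demand and
raises if the discrepancy exceeds 1e-3.  The frequency integral is
truncated at the working Nyquist because the optics leave negligible
stimulus energy beyond it.

## What the synthetic stimuli do not capture

The generator emulates the modelled laboratory stimuli, not natural
viewing: luminance is mean-zero with statistically stationary dot
statistics, so conclusions about the retained mean-luminance term in
C_int for natural scenes do not follow from these tests.  No neuronal
noise is modelled, so absolute sensitivities (especially at the 0.3-arcmin
amplitude, below the 0.6-arcmin detector spacing) depend on the decision
stage's efficiency rather than on a noise floor; only one window size
exists per preferred disparity; vertical-disparity and oblique
corrugations, anisotropic windows, and chromatic/pupil-dependent optics
are out of scope.  The exact dot size, density and field extent of the
original psychophysics are not reproduced here (they are stated only in
the cited experimental report), so quantitative accuracies are expected
to match only approximately; the package's claims rest on the contrasts
(sine vs square, constant vs size-coupled windows, limit-vs-frequency
scaling) rather than absolute percent correct.

## Numerical conventions

* Float64 throughout the correlator and decision stages; surfaces clip
  to [-1, 1] only to absorb last-bit rounding.
* Zero-variance patches, all-NaN template cells and degenerate template
  pairings are flagged/skipped, never coerced to ±1 or 0.
* Window truncation uses the strict inequality |offset| < 2 sigma in
  arcmin, so sigma enters the window smoothly while the footprint is
  quantized to whole pixels.
* All seeds derive from `numpy.random.SeedSequence` with explicit
  entropy tuples (master seed, condition, salt); no global RNG state.
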