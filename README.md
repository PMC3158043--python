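# stereocorr

A computational model of human **spatial stereoresolution** — the
strikingly low spatial resolution of stereoscopic depth perception — built
on local cross-correlation of the two eyes' images with a
**size/disparity correlation**: disparity detectors tuned to larger
binocular disparities integrate over larger windows.

The classic fixed-window cross-correlation account of stereoresolution
predicts that square-wave depth corrugations (piecewise-frontoparallel)
should remain easy to detect at large disparity amplitudes, while human
observers lose both sine- and square-wave corrugations as amplitude
grows.  Coupling window size to preferred disparity reconciles the model
with that behaviour and, as a by-product, reproduces the disparity
gradient limit (upper depth limit ∝ 1/frequency) for both waveforms.
The package is aimed at visual psychophysicists and computational
neuroscientists who want to run, probe or extend this model class.

## The model

1. **Stimuli** — dense random-dot stereograms depicting horizontal
   disparity gratings, d(y) = A·sin(2πfy + φ) or the square-wave
   analogue, versus matched *disparity noise* (each dot's disparity drawn
   i.i.d. from the grating's marginal distribution).
2. **Optics** — Gaussian point-spread blur (SD 2 arcmin) and area-true
   rescaling to a 0.6 arcmin/px working grid.
3. **Encoding** — a population response C(y, Δx): the Pearson correlation
   of Gaussian-windowed left/right patches (window truncated at 2σ),
   where the left window sits at a fixed column, the right window is
   offset by the preferred disparity Δx, and the window size follows

       σ(Δx) = 3 + 0.032·Δx²   arcmin   (quadratic relation), or
       σ(Δx) = 3 + 0.24·|Δx|   arcmin   (linear relation).

4. **Read-out** — template matching: per-condition mean surfaces
   (36 phases × 6 amplitudes × 2 waveforms = 432 grating templates per
   frequency, plus 12 noise templates, each from 100 stereograms); the
   observer scores each interval by max-over-templates Pearson match and
   picks the interval with the larger M_grating − M_noise.
5. **Psychophysics** — simulated two-interval forced choice
   (grating vs noise), percent correct with Wilson 95% CIs, and the
   80%-correct upper depth limit as a function of corrugation frequency.
6. **Energy-model verification** — numerical proof that the windowed
   correlator equals a suitably normalized sum of binocular energy units
   (quadrature-pair Gabor subunits, S = B + L + R) over all spatial
   frequencies and orientations.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Detection of a 3.8 cycles/deg grating at 7.6 arcmin amplitude — the
regime where window enlargement hurts both waveforms — with the reduced
desk-scale profile (12 template phases, 50 stereograms per template,
150 trials per waveform):

```python
import stereocorr as sc
from stereocorr.templates import build_bank
from stereocorr.experiment import run_condition

cfg = sc.PipelineConfig()                      # quadratic relation
bank = build_bank(3.8, cfg, phases=12, n=50, seed=1)
for wf in ("sine", "square"):
    cond = sc.DisparityProfile(wf, 7.6, frequency=3.8)
    r = run_condition(cfg, cond, bank, n_trials=150, seed=1)
    print(f"{wf:6s} {r.percent_correct:5.1f}%  "
          f"CI [{r.ci_lo:.1f}, {r.ci_hi:.1f}]")
```

```
sine    86.0%  CI [79.5, 90.7]
square  87.3%  CI [81.1, 91.7]
```

Both waveforms sit in the low-to-mid 80s, and — the point of the model —
they sit **together**: the fixed-window model would put the square wave
near ceiling here while the sine wave falls away.  (Absolute accuracy
shifts by a few points with the dot-field parameters and the Monte-Carlo
seed; the sine/square parity is the stable signature.)

The analytic heart of the explanation is the range of stimulus
disparities falling inside a correlation window,

```python
from stereocorr.correlator import disparity_range_in_window
prof = sc.DisparityProfile("sine", 7.6, frequency=3.8, phase=90.0)
disparity_range_in_window(prof, y_center=0.0, halfwidth=5.0)  # -> 10.7
```

10.7 arcmin of disparity variation inside the enlarged window assigned to
7.6-arcmin detectors, versus 4.8 arcmin for the fixed σ = 3 arcmin
window —
enough to wash out the correlation peaks that made large square waves
trivially detectable.

## Command line

```bash
stereocorr gen-stim --waveform sine --frequency 1.3 --amplitude 5.1 \
    --seed 1 --out out/stim                # 16-bit PNG pair + JSON sidecar
stereocorr build-templates --freq 3.8 --relation quadratic --out bank.h5
stereocorr run-exp --config exp.yaml --out results/
stereocorr depth-limit --frequencies 0.5,1.0,2.0 --relation linear --out dl/
stereocorr verify-energy --windows 50 --out energy.json
```

Every command writes a JSON run manifest (full configuration, master
seed, package version) alongside its outputs; identical manifests give
bit-identical outputs.

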