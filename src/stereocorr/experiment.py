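"""Simulated two-interval forced-choice psychophysics.

One trial shows the model observer a stereogram of a disparity grating in
one interval and a matched disparity-noise stereogram (same amplitude and
parent waveform, fresh dots) in the other, in random order; the observer
picks the interval whose correlator output better matches the grating
templates.  Percent correct is tabulated per (frequency, amplitude,
waveform) with Wilson 95% confidence intervals, and the upper depth limit
(largest amplitude still detected above criterion) is extracted per
frequency together with its log-log slope against frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlator import CorrelatorGrid, SizeDisparityRelation
from .decision import decide_interval
from .pipeline import PipelineConfig, condition_rng
from .stimgen import DisparityProfile
from .templates import (
    DEFAULT_AMPLITUDES,
    DEFAULT_WAVEFORMS,
    TemplateBank,
    build_bank,
)

_TRIAL_SALT = 101


@dataclass(frozen=True)
class ExperimentConfig:
    """A grating-detection experiment over a condition grid.

    Frequency is blocked (one template bank per frequency, as in the
    psychophysics) while amplitude, waveform and phase vary from trial to
    trial; the observer never knows which amplitude, waveform or phase was
    shown.
    """

    frequencies: tuple
    amplitudes: tuple = DEFAULT_AMPLITUDES
    waveforms: tuple = DEFAULT_WAVEFORMS
    trials_per_condition: int = 200
    template_phases: int = 36
    template_n: int = 100
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0


@dataclass(frozen=True)
class PsychometricResult:
    """Percent correct for one condition, with a Wilson 95% CI."""

    frequency: float
    amplitude: float
    waveform: str
    n_trials: int
    n_correct: int
    percent_correct: float
    ci_lo: float
    ci_hi: float


@dataclass
class DepthLimitResult:
    """Upper depth limit (arcmin) per frequency at a criterion accuracy."""

    limits: dict                 # frequency -> limit (arcmin; NaN if censored)
    censored: dict               # frequency -> None | 'above' | 'below'
    criterion: float             # percent correct
    loglog_slope: float          # slope of log(limit) vs log(frequency)


def wilson_ci(n_correct: int, n_trials: int, alpha: float = 0.05) -> tuple:
    """Wilson score interval for a binomial proportion, in percent."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(n_correct, n_trials, alpha=alpha,
                                method="wilson")
    return 100.0 * lo, 100.0 * hi


def run_trial(cfg: PipelineConfig, condition: DisparityProfile,
              bank: TemplateBank, rng: np.random.Generator) -> bool:
    """One 2IFC trial; True when the observer picks the grating interval.

    The grating phase is drawn uniformly from the bank's phase set (the
    observer's templates cover exactly those phases); the noise interval
    uses the matched parent waveform and amplitude with fresh dots.
    """
    phases = bank.phases
    phase = float(phases[rng.integers(0, len(phases))]) if len(phases) else 0.0
    grating = DisparityProfile(waveform=condition.waveform,
                               amplitude=condition.amplitude,
                               frequency=condition.frequency,
                               phase=phase)
    noise = DisparityProfile(waveform="noise", amplitude=condition.amplitude,
                             noise_parent=condition.waveform)
    surf_g = cfg.simulate_surface(grating, rng)
    surf_n = cfg.simulate_surface(noise, rng)
    grating_pos = int(rng.integers(0, 2))
    pair = (surf_g, surf_n) if grating_pos == 0 else (surf_n, surf_g)
    choice = decide_interval(pair[0], pair[1], bank, rng)
    return choice == grating_pos


def run_condition(cfg: PipelineConfig, condition: DisparityProfile,
                  bank: TemplateBank, n_trials: int, seed: int
                  ) -> PsychometricResult:
    """Run ``n_trials`` seeded trials of one condition."""
    rng = condition_rng(seed, condition, salt=_TRIAL_SALT)
    correct = sum(run_trial(cfg, condition, bank, rng)
                  for _ in range(n_trials))
    pc = 100.0 * correct / n_trials
    lo, hi = wilson_ci(correct, n_trials)
    return PsychometricResult(
        frequency=condition.frequency, amplitude=condition.amplitude,
        waveform=condition.waveform, n_trials=n_trials, n_correct=correct,
        percent_correct=pc, ci_lo=lo, ci_hi=hi)


def run_experiment(config: ExperimentConfig, banks: dict | None = None,
                   progress: bool = False) -> list:
    """Percent correct per (frequency, amplitude, waveform).

    ``banks`` may supply prebuilt template banks keyed by frequency; a
    missing frequency raises.  When omitted, banks are built on the fly
    from the experiment configuration.  Results are deterministic for a
    fixed config seed.
    """
    results = []
    for f in config.frequencies:
        if banks is not None:
            if f not in banks:
                raise ValueError(f"no template bank for frequency {f:g} cpd")
            bank = banks[f]
        else:
            bank = build_bank(f, config.pipeline,
                              phases=config.template_phases,
                              amplitudes=config.amplitudes,
                              waveforms=config.waveforms,
                              n=config.template_n, seed=config.seed,
                              progress=progress)
        conditions = [
            DisparityProfile(waveform=w, amplitude=float(a),
                             frequency=float(f))
            for a in config.amplitudes for w in config.waveforms
        ]
        if progress:
            from tqdm import tqdm  # pragma: no cover - cosmetic
            conditions = tqdm(conditions, desc=f"trials {f:g} cpd")
        for cond in conditions:
            results.append(run_condition(config.pipeline, cond, bank,
                                         config.trials_per_condition,
                                         config.seed))
    return results


def results_to_frame(results):
    """Tidy DataFrame of psychometric results."""
    import pandas as pd

    return pd.DataFrame([{
        "frequency": r.frequency, "amplitude": r.amplitude,
        "waveform": r.waveform, "n": r.n_trials, "correct": r.n_correct,
        "pc": r.percent_correct, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
    } for r in results])


def upper_depth_limit(results, criterion: float = 80.0,
                      waveform: str | None = None) -> DepthLimitResult:
    """Largest amplitude with accuracy above criterion, per frequency.

    The limit is the log-amplitude interpolation of the criterion crossing
    between the largest supra-criterion amplitude and the next tested
    amplitude.  Frequencies whose accuracy never exceeds criterion are
    censored ``'below'``; frequencies that stay above criterion at the
    largest tested amplitude (no crossing, e.g. the constant-window model
    on square waves) are censored ``'above'``.  The log-log slope is fit
    by least squares over the uncensored frequencies.
    """
    rows = [r for r in results
            if waveform is None or r.waveform == waveform]
    freqs = sorted({r.frequency for r in rows})
    limits, censored = {}, {}
    for f in freqs:
        sub = sorted((r for r in rows if r.frequency == f),
                     key=lambda r: r.amplitude)
        amps = np.array([r.amplitude for r in sub])
        pcs = np.array([r.percent_correct for r in sub])
        above = np.nonzero(pcs > criterion)[0]
        if len(above) == 0:
            limits[f], censored[f] = float("nan"), "below"
            continue
        i = above[-1]
        if i == len(amps) - 1:
            limits[f], censored[f] = float("nan"), "above"
            continue
        # log-amplitude interpolation of the criterion crossing
        la, lb = np.log(amps[i]), np.log(amps[i + 1])
        t = (pcs[i] - criterion) / (pcs[i] - pcs[i + 1])
        limits[f], censored[f] = float(np.exp(la + t * (lb - la))), None
    ok = [f for f in freqs if censored[f] is None]
    if len(ok) >= 2:
        slope = float(np.polyfit(np.log([f for f in ok]),
                                 np.log([limits[f] for f in ok]), 1)[0])
    else:
        slope = float("nan")
    return DepthLimitResult(limits=limits, censored=censored,
                            criterion=criterion, loglog_slope=slope)


# ---------------------------------------------------------------------------
# upper-depth-limit experiment assembly

def _round_up(value: float, quantum: float) -> float:
    return float(np.ceil(value / quantum - 1e-9) * quantum)


def depth_limit_pipeline(frequency: float, max_amplitude: float,
                         relation: SizeDisparityRelation,
                         base: PipelineConfig | None = None,
                         grid_step: float = 1.2, y_step: int = 2,
                         height: float | None = None) -> PipelineConfig:
    """Pipeline sized for an upper-depth-limit run at one frequency.

    The disparity grid is widened to cover the stimulus disparities (up to
    the extended +-140 arcmin range) and the field width accommodates the
    largest window at the largest preferred disparity.  The field height
    defaults to two corrugation periods (>= 1.2 deg); a depth-limit run
    across several frequencies passes a common ``height`` so that every
    frequency is probed with the same stimulus extent, as in the
    psychophysics it emulates.
    """
    base = base or PipelineConfig()
    optics = base.optics
    quantum = optics.working_pitch * optics.factor / 60.0   # deg
    grid_max = min(140.0, _round_up(max_amplitude + 3.0, grid_step))
    grid = CorrelatorGrid.standard(max_disparity=grid_max, step=grid_step)
    sig_max = relation.sigma(grid_max)
    half_w = (grid_max + 2.0 * sig_max + 3.0) / 60.0        # deg
    width = _round_up(2.0 * half_w, quantum)
    if height is None:
        height = max(2.0 / frequency, 1.2)
    height = _round_up(height, quantum)
    return base.replace(extent=(width, height), relation=relation,
                        grid=grid, y_step=y_step)


def depth_limit_experiment(frequencies=(0.5, 1.0, 2.0),
                           relation: SizeDisparityRelation | None = None,
                           amplitude_scale: float = 29.0,
                           ratios=(0.3, 0.5, 0.8, 1.25, 1.8),
                           waveforms=("sine",),
                           trials: int = 40, phases: int = 6,
                           template_n: int = 12, seed: int = 0,
                           criterion: float = 80.0,
                           base: PipelineConfig | None = None,
                           progress: bool = False) -> tuple:
    """Scaled-down upper-depth-limit experiment across frequencies.

    Tested amplitudes at each frequency are ``ratios * amplitude_scale /
    frequency`` (arcmin), a geometric ladder centred on the expected
    criterion crossing; ``amplitude_scale`` defaults to 29 arcmin*cpd,
    anchored to the ~80%-correct point of the high-frequency detection
    runs (7.6 arcmin at 3.8 cpd).  Returns ``(results, DepthLimitResult)``.
    """
    relation = relation or SizeDisparityRelation.linear()
    results = []
    # one stimulus extent for the whole run: two periods at the lowest
    # frequency, so every frequency sees the same field
    common_height = max(2.0 / min(frequencies), 1.2)
    for f in frequencies:
        amps = [min(round(r * amplitude_scale / f, 1), 135.0)
                for r in ratios]
        cfg = depth_limit_pipeline(f, max(amps), relation, base=base,
                                   height=common_height)
        bank = build_bank(f, cfg, phases=phases, amplitudes=amps,
                          waveforms=waveforms, n=template_n, seed=seed,
                          progress=progress)
        for a in amps:
            for w in waveforms:
                cond = DisparityProfile(waveform=w, amplitude=a,
                                        frequency=float(f))
                results.append(run_condition(cfg, cond, bank, trials, seed))
    limit = upper_depth_limit(results, criterion=criterion)
    return results, limit
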