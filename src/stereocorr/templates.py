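"""The model observer's priors: Monte-Carlo template banks.

A template is the mean and standard deviation, over an ensemble of
independently generated stereograms, of the correlator population response
to one stimulus condition.  A bank collects the grating templates for one
corrugation frequency (every combination of phase, amplitude and waveform)
together with the frequency-independent disparity-noise templates.  With
the default configuration (36 phases x 6 amplitudes x 2 waveforms) a bank
holds 432 grating templates and 12 noise templates, each estimated from
100 stereograms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pipeline import PipelineConfig, condition_rng
from .stimgen import DisparityProfile

DEFAULT_AMPLITUDES = (0.3, 1.3, 2.5, 5.1, 7.6, 10.1)   # arcmin
DEFAULT_WAVEFORMS = ("sine", "square")


@dataclass
class Template:
    """Per-condition mean and SD correlation surfaces."""

    mean_surface: np.ndarray
    sd_surface: np.ndarray
    condition: DisparityProfile
    n_samples: int
    disparities: np.ndarray
    y_positions: np.ndarray

    def __post_init__(self) -> None:
        if self.mean_surface.shape != self.sd_surface.shape:
            raise ValueError("mean and SD surfaces must share a shape")


@dataclass
class TemplateBank:
    """All templates the observer may match against at one frequency."""

    frequency: float
    grating_templates: list
    noise_templates: list
    build_config: dict = field(default_factory=dict)

    @property
    def phases(self) -> np.ndarray:
        return np.asarray(sorted({t.condition.phase
                                  for t in self.grating_templates}))

    def counts(self) -> tuple:
        return len(self.grating_templates), len(self.noise_templates)


def bank_conditions(frequency: float, phases: int = 36,
                    amplitudes=DEFAULT_AMPLITUDES,
                    waveforms=DEFAULT_WAVEFORMS) -> tuple:
    """Enumerate the (grating, noise) conditions of a bank.

    Grating conditions are the full product phases x amplitudes x
    waveforms; noise conditions are independent of frequency and phase, so
    there is one per (parent waveform, amplitude).
    """
    if phases <= 0 or 360 % phases != 0:
        raise ValueError("the phase count must divide 360 evenly")
    if len(tuple(amplitudes)) == 0:
        raise ValueError("amplitude list must not be empty")
    if len(tuple(waveforms)) == 0:
        raise ValueError("waveform list must not be empty")
    phase_vals = np.arange(phases) * (360.0 / phases)
    gratings = [
        DisparityProfile(waveform=w, amplitude=float(a),
                         frequency=float(frequency), phase=float(ph))
        for w in waveforms for a in amplitudes for ph in phase_vals
    ]
    noises = [
        DisparityProfile(waveform="noise", amplitude=float(a), noise_parent=w)
        for w in waveforms for a in amplitudes
    ]
    return gratings, noises


def aggregate_surfaces(surfaces) -> tuple:
    """Elementwise mean and sample SD of a stack of surfaces.

    Undefined (NaN-flagged) entries are excluded; cells defined in fewer
    than two surfaces stay undefined in both outputs.
    """
    stack = np.stack([s.C for s in surfaces])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    n_def = np.isfinite(stack).sum(axis=0)
    mean[n_def < 2] = np.nan
    sd[n_def < 2] = np.nan
    return mean, sd


def build_template(condition: DisparityProfile, cfg: PipelineConfig,
                   n: int = 100, seed: int = 0) -> Template:
    """Estimate one template from ``n`` independent stereograms.

    The ensemble seed stream is derived from ``(seed, condition)`` so any
    template can be rebuilt in isolation.
    """
    if n < 2:
        raise ValueError("template SD needs at least n=2 samples")
    rng = condition_rng(seed, condition)
    surfaces = [cfg.simulate_surface(condition, rng) for _ in range(n)]
    mean, sd = aggregate_surfaces(surfaces)
    return Template(mean_surface=mean, sd_surface=sd, condition=condition,
                    n_samples=n, disparities=surfaces[0].disparities,
                    y_positions=surfaces[0].y_positions)


def build_bank(frequency: float, cfg: PipelineConfig, phases: int = 36,
               amplitudes=DEFAULT_AMPLITUDES, waveforms=DEFAULT_WAVEFORMS,
               n: int = 100, seed: int = 0, progress: bool = False
               ) -> TemplateBank:
    """Build the full template bank for one corrugation frequency."""
    gratings, noises = bank_conditions(frequency, phases=phases,
                                       amplitudes=amplitudes,
                                       waveforms=waveforms)
    conditions = gratings + noises
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic
        conditions = tqdm(conditions, desc=f"bank {frequency:g} cpd")
    templates = [build_template(c, cfg, n=n, seed=seed) for c in conditions]
    bank = TemplateBank(
        frequency=float(frequency),
        grating_templates=templates[: len(gratings)],
        noise_templates=templates[len(gratings):],
        build_config={
            "phases": phases,
            "amplitudes": list(map(float, amplitudes)),
            "waveforms": list(waveforms),
            "n_samples": n,
            "seed": int(seed),
        },
    )
    return bank


# ---------------------------------------------------------------------------
# persistence (one HDF5 file per frequency)

def _profile_to_json(p: DisparityProfile) -> str:
    return json.dumps({
        "waveform": p.waveform, "amplitude": p.amplitude,
        "frequency": p.frequency, "phase": p.phase,
        "noise_parent": p.noise_parent,
    })


def _profile_from_json(s: str) -> DisparityProfile:
    d = json.loads(s)
    return DisparityProfile(**d)


def save_bank(bank: TemplateBank, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["frequency"] = bank.frequency
        f.attrs["build_config"] = json.dumps(bank.build_config)
        for group_name, templates in (("gratings", bank.grating_templates),
                                      ("noise", bank.noise_templates)):
            grp = f.create_group(group_name)
            for i, t in enumerate(templates):
                g = grp.create_group(str(i))
                g.create_dataset("mean", data=t.mean_surface)
                g.create_dataset("sd", data=t.sd_surface)
                g.create_dataset("disparities", data=t.disparities)
                g.create_dataset("y_positions", data=t.y_positions)
                g.attrs["condition"] = _profile_to_json(t.condition)
                g.attrs["n_samples"] = t.n_samples


def load_bank(path) -> TemplateBank:
    import h5py

    with h5py.File(path, "r") as f:
        out = {}
        for group_name in ("gratings", "noise"):
            grp = f[group_name]
            templates = []
            for i in sorted(grp, key=int):
                g = grp[i]
                templates.append(Template(
                    mean_surface=g["mean"][()],
                    sd_surface=g["sd"][()],
                    condition=_profile_from_json(g.attrs["condition"]),
                    n_samples=int(g.attrs["n_samples"]),
                    disparities=g["disparities"][()],
                    y_positions=g["y_positions"][()],
                ))
            out[group_name] = templates
        return TemplateBank(
            frequency=float(f.attrs["frequency"]),
            grating_templates=out["gratings"],
            noise_templates=out["noise"],
            build_config=json.loads(f.attrs["build_config"]),
        )
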