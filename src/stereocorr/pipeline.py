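"""Shared stimulus-to-correlator pipeline configuration.

Templates and simulated experiments both push freshly generated stereograms
through the identical chain

    dot field -> stereogram render -> eye optics -> correlator population

so the stimulus, optics and encoding parameters are bundled here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .correlator import (
    CorrelationSurface,
    CorrelatorGrid,
    SizeDisparityRelation,
    correlation_surface,
)
from .optics import OpticsConfig, blur_and_scale
from .stimgen import (
    DisparityProfile,
    StereoPair,
    generate_dot_field,
    render_stereogram,
)

MAX_SEED = 2 ** 31 - 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to turn a disparity profile into a surface.

    Defaults give the core study conditions: a 2 deg x 2 deg field of
    120 dots/deg^2 (dot diameter 1.2 arcmin, 50/50 bright/dark), rendered
    at 0.15 arcmin/px, blurred by a 2-arcmin PSF, scaled to 0.6 arcmin/px,
    and correlated over preferred disparities within +-13 arcmin with the
    quadratic size/disparity relation.
    """

    extent: tuple = (2.0, 2.0)          # (width, height) deg
    density: float = 120.0              # dots / deg^2
    dot_diameter: float = 1.2           # arcmin
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    relation: SizeDisparityRelation = field(
        default_factory=SizeDisparityRelation.quadratic)
    grid: CorrelatorGrid = field(default_factory=CorrelatorGrid.standard)
    y_step: int = 1                     # working pixels between surface rows
    clip_range: tuple = (-1.0, 1.0)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def simulate_pair(self, profile: DisparityProfile,
                      rng: np.random.Generator) -> StereoPair:
        """Fresh dot field, rendered and passed through the optics."""
        seed = int(rng.integers(0, MAX_SEED))
        dots = generate_dot_field(self.extent, density=self.density,
                                  dot_diameter=self.dot_diameter, seed=seed)
        raw = render_stereogram(dots, profile,
                                render_pitch=self.optics.render_pitch,
                                rng=rng, clip_range=self.clip_range)
        return blur_and_scale(raw, self.optics)

    def simulate_surface(self, profile: DisparityProfile,
                         rng: np.random.Generator) -> CorrelationSurface:
        pair = self.simulate_pair(profile, rng)
        return correlation_surface(pair, self.grid, self.relation,
                                   y_step=self.y_step)


def condition_entropy(profile: DisparityProfile) -> tuple:
    """Stable integer key identifying a stimulus condition.

    Used to derive per-condition seed streams from a master seed, so that
    template banks are reproducible independently of build order.
    """
    kinds = {"sine": 0, "square": 1, "noise": 2}
    parent = {"sine": 0, "square": 1, None: 2}
    return (
        kinds[profile.waveform],
        int(round((profile.frequency or 0.0) * 1e6)),
        int(round(profile.amplitude * 1e6)),
        int(round((profile.phase or 0.0) * 1e6)),
        parent[profile.noise_parent],
    )


def condition_rng(master_seed: int, profile: DisparityProfile,
                  salt: int = 0) -> np.random.Generator:
    """Generator seeded deterministically by (master seed, condition, salt)."""
    ss = np.random.SeedSequence(
        entropy=(int(master_seed), int(salt)) + condition_entropy(profile))
    return np.random.default_rng(ss)
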