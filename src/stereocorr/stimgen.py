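"""Random-dot stereogram synthesis.

Stimuli are dense random-dot stereograms depicting horizontal disparity
gratings: the binocular disparity of the dots is a sine- or square-wave
function of vertical position in the image.  The matched control stimulus
is "disparity noise", in which each dot receives an independent disparity
drawn from the grating's marginal disparity distribution, so that grating
and noise stimuli contain the same range of disparities and differ only in
their spatial arrangement.

Conventions
-----------
* Spatial positions are in degrees of visual angle, with the origin at the
  image centre; disparities, dot diameters and pixel pitches are in arcmin.
* Luminance is expressed relative to the mean (gray) background, so an
  empty image is exactly zero and rendered images average to ~0.
* The disparity ``d`` of a dot is split symmetrically between the eyes:
  the dot is drawn at ``x - d/2`` in the left image and ``x + d/2`` in the
  right image.
* Dots are anti-aliased analytically: each pixel receives the approximate
  coverage of the dot disc, via a linear ramp of one pixel width across the
  disc edge.  Dots falling partly outside the raster are clipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

ARCMIN_PER_DEG = 60.0

_WAVEFORMS = ("sine", "square", "noise")
_PARENTS = ("sine", "square")


@dataclass(frozen=True)
class DisparityProfile:
    """Description of a depth corrugation (or its scrambled noise control).

    Parameters
    ----------
    waveform:
        ``"sine"`` or ``"square"`` for gratings; ``"noise"`` for the
        matched disparity-noise stimulus.
    amplitude:
        Disparity amplitude ``A`` in arcmin (>= 0).  Sine gratings span
        disparities ``[-A, A]`` continuously; square gratings alternate
        between ``+A`` and ``-A``.
    frequency:
        Corrugation frequency in cycles/deg (> 0); ignored for noise.
    phase:
        Phase of the grating in degrees, in ``[0, 360)``.
    noise_parent:
        For ``waveform="noise"``, the parent grating waveform whose
        marginal disparity distribution is sampled (``"sine"`` draws
        ``A*sin(U)`` with ``U ~ Uniform[0, 2pi)``; ``"square"`` draws
        ``+A`` or ``-A`` with probability 1/2 each).
    """

    waveform: str
    amplitude: float
    frequency: float | None = None
    phase: float = 0.0
    noise_parent: str | None = None

    def __post_init__(self) -> None:
        if self.waveform not in _WAVEFORMS:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.waveform == "noise":
            if self.noise_parent not in _PARENTS:
                raise ValueError(
                    "noise profiles require noise_parent in {'sine', 'square'}"
                )
        else:
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("gratings require frequency > 0 (cycles/deg)")
            if self.noise_parent is not None:
                raise ValueError("noise_parent only applies to waveform='noise'")
        if not 0.0 <= self.phase < 360.0:
            object.__setattr__(self, "phase", float(self.phase) % 360.0)

    @property
    def is_noise(self) -> bool:
        return self.waveform == "noise"

    def disparity_at(self, y):
        return disparity_at(self, y)


def disparity_at(profile: DisparityProfile, y):
    """Disparity (arcmin) of a grating at vertical position ``y`` (deg).

    ``d(y) = A sin(2 pi f y + phase)`` for sine gratings and
    ``A sgn(sin(2 pi f y + phase))`` for square gratings, with the
    tie-break ``sgn(0) = +1`` at exact zero crossings.  Noise profiles have
    no deterministic disparity as a function of position and raise.
    """
    if profile.is_noise:
        raise ValueError("disparity noise has no deterministic disparity profile")
    y = np.asarray(y, dtype=float)
    arg = 2.0 * np.pi * profile.frequency * y + np.deg2rad(profile.phase)
    s = np.sin(arg)
    if profile.waveform == "sine":
        d = profile.amplitude * s
    else:
        d = np.where(s >= 0.0, profile.amplitude, -profile.amplitude)
    return d if d.ndim else float(d)


def sample_noise_disparity(parent: str, amplitude: float,
                           rng: np.random.Generator, size=None):
    """Draw disparities from the marginal distribution of a parent grating.

    For a square-wave parent the marginal is Bernoulli on ``{+A, -A}``;
    for a sine-wave parent it is ``A sin(U)`` with uniform phase ``U``
    (an arcsine law on ``[-A, A]``).  Either way the disparity range of
    the noise matches the parent grating's.
    """
    if parent not in _PARENTS:
        raise ValueError(f"unknown parent waveform {parent!r}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if parent == "square":
        draws = amplitude * (2.0 * rng.integers(0, 2, size=size) - 1.0)
    else:
        draws = amplitude * np.sin(rng.uniform(0.0, 2.0 * np.pi, size=size))
    return draws


@dataclass(frozen=True)
class DotField:
    """A seeded random placement of bright/dark dots on a gray field."""

    dot_centers: np.ndarray      # (n, 2) array of (x, y) in deg
    polarities: np.ndarray       # (n,) array of +-1
    dot_diameter: float          # arcmin
    field_extent: tuple          # (width, height) deg
    density: float               # dots / deg^2
    seed: int | None

    @property
    def n_dots(self) -> int:
        return len(self.dot_centers)


def generate_dot_field(field_extent, density: float = 120.0,
                       dot_diameter: float = 1.2, seed=None) -> DotField:
    """Place dots uniformly at random over the field.

    The dot count is Poisson with mean ``density * area``; positions are
    uniform over the field and polarities (bright/dark relative to the
    mean-gray background) are +-1 with probability 1/2 each.  The same seed
    always reproduces the same field.
    """
    if np.isscalar(field_extent):
        field_extent = (float(field_extent), float(field_extent))
    w, h = (float(v) for v in field_extent)
    if w <= 0 or h <= 0:
        raise ValueError("field_extent must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    if dot_diameter <= 0:
        raise ValueError("dot_diameter must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density * w * h))
    xy = np.column_stack([
        rng.uniform(-w / 2.0, w / 2.0, size=n),
        rng.uniform(-h / 2.0, h / 2.0, size=n),
    ])
    pol = 2.0 * rng.integers(0, 2, size=n) - 1.0
    return DotField(dot_centers=xy, polarities=pol, dot_diameter=dot_diameter,
                    field_extent=(w, h), density=density,
                    seed=seed if (seed is None or np.isscalar(seed)) else None)


@dataclass
class StereoPair:
    """Left/right luminance rasters with a common angular pixel pitch.

    Luminance is relative to the mean background, so values are ~zero-mean.
    """

    left: np.ndarray
    right: np.ndarray
    pixel_pitch: float   # arcmin / pixel
    extent: tuple        # (width, height) deg

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right rasters must share dimensions")

    @property
    def shape(self):
        return self.left.shape

    def x_coords(self) -> np.ndarray:
        """Horizontal pixel-centre positions in deg (origin at centre)."""
        return _pixel_coords(self.left.shape[1], self.pixel_pitch)

    def y_coords(self) -> np.ndarray:
        """Vertical pixel-centre positions in deg (origin at centre)."""
        return _pixel_coords(self.left.shape[0], self.pixel_pitch)


def _pixel_coords(n: int, pitch_arcmin: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * (pitch_arcmin / ARCMIN_PER_DEG)


def _stamp_dots(image: np.ndarray, x_deg: np.ndarray, y_deg: np.ndarray,
                polarity: np.ndarray, radius_px: float, pitch_deg: float) -> None:
    """Accumulate anti-aliased dot discs into ``image`` (in place)."""
    n_rows, n_cols = image.shape
    if len(x_deg) == 0:
        return
    # continuous pixel coordinates of the dot centres
    cx = x_deg / pitch_deg + (n_cols - 1) / 2.0
    cy = y_deg / pitch_deg + (n_rows - 1) / 2.0
    half = int(np.ceil(radius_px + 1.0))
    off = np.arange(-half, half + 1)
    base_x = np.round(cx).astype(int)
    base_y = np.round(cy).astype(int)
    # dots whose disc cannot touch the raster are dropped; the rest are
    # clipped at the borders by the padded scatter below
    keep = ((base_x >= -half - 1) & (base_x <= n_cols + half) &
            (base_y >= -half - 1) & (base_y <= n_rows + half))
    if not np.all(keep):
        cx, cy = cx[keep], cy[keep]
        base_x, base_y = base_x[keep], base_y[keep]
        polarity = polarity[keep]
        if len(cx) == 0:
            return
    # patch pixel coordinates for every dot: (n, p, p)
    shape = (len(cx), len(off), len(off))
    px = np.broadcast_to(base_x[:, None, None] + off[None, None, :], shape)
    py = np.broadcast_to(base_y[:, None, None] + off[None, :, None], shape)
    dist = np.sqrt((px - cx[:, None, None]) ** 2
                   + (py - cy[:, None, None]) ** 2)
    cover = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    cover *= polarity[:, None, None]
    # pad, scatter-add, crop: dots partly outside are clipped silently
    pad = 2 * half + 2
    bh, bw = n_rows + 2 * pad, n_cols + 2 * pad
    flat_idx = (py.ravel() + pad) * bw + (px.ravel() + pad)
    buf = np.bincount(flat_idx, weights=cover.ravel(),
                      minlength=bh * bw).reshape(bh, bw)
    image += buf[pad:-pad, pad:-pad]


def render_stereogram(dots: DotField, profile: DisparityProfile,
                      render_pitch: float = 0.15,
                      rng: np.random.Generator | None = None,
                      clip_range: tuple = (-1.0, 1.0)) -> StereoPair:
    """Render a dot field as a left/right stereo pair at a fine pitch.

    Each dot's disparity ``d`` is taken from the deterministic grating
    profile at the dot's vertical position, or (for noise profiles) drawn
    independently per dot from the parent marginal.  The dot is drawn at
    ``x - d/2`` in the left raster and ``x + d/2`` in the right raster
    with analytic sub-pixel anti-aliasing.  Overlapping dots sum and the
    result is clipped to ``clip_range``.
    """
    if render_pitch <= 0:
        raise ValueError("render_pitch must be positive")
    w, h = dots.field_extent
    pitch_deg = render_pitch / ARCMIN_PER_DEG
    n_cols = int(round(w / pitch_deg))
    n_rows = int(round(h / pitch_deg))
    x = dots.dot_centers[:, 0]
    y = dots.dot_centers[:, 1]
    if profile.is_noise:
        if rng is None:
            raise ValueError("noise stimuli require an rng for per-dot draws")
        d = sample_noise_disparity(profile.noise_parent, profile.amplitude,
                                   rng, size=len(x))
    else:
        d = np.asarray(disparity_at(profile, y))
    half_shift = d / 2.0 / ARCMIN_PER_DEG   # deg
    radius_px = (dots.dot_diameter / 2.0) / render_pitch
    left = np.zeros((n_rows, n_cols))
    right = np.zeros((n_rows, n_cols))
    _stamp_dots(left, x - half_shift, y, dots.polarities, radius_px, pitch_deg)
    _stamp_dots(right, x + half_shift, y, dots.polarities, radius_px, pitch_deg)
    lo, hi = clip_range
    np.clip(left, lo, hi, out=left)
    np.clip(right, lo, hi, out=right)
    return StereoPair(left=left, right=right, pixel_pitch=render_pitch,
                      extent=(w, h))


# ---------------------------------------------------------------------------
# stimulus I/O: 16-bit grayscale PNG pair + JSON sidecar

def write_stimulus(pair: StereoPair, prefix, profile: DisparityProfile | None = None,
                   seed=None, clip_range: tuple = (-1.0, 1.0)) -> dict:
    """Write ``<prefix>_L.png``/``<prefix>_R.png`` (16-bit) plus a JSON sidecar.

    Luminance in ``clip_range`` is mapped linearly onto the 16-bit range;
    the sidecar records the mapping, pixel pitch and stimulus metadata so
    the pair can be reconstructed (up to 16-bit quantization).
    """
    import json
    from pathlib import Path

    from PIL import Image

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    lo, hi = clip_range
    paths = {}
    for tag, img in (("L", pair.left), ("R", pair.right)):
        scaled = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
        u16 = np.round(scaled * 65535.0).astype(np.uint16)
        p = prefix.parent / f"{prefix.name}_{tag}.png"
        Image.fromarray(u16).save(p)   # uint16 -> 16-bit grayscale PNG
        paths[tag] = str(p)
    sidecar = {
        "pixel_pitch_arcmin": pair.pixel_pitch,
        "extent_deg": list(pair.extent),
        "clip_range": [lo, hi],
        "seed": seed,
        "profile": None if profile is None else {
            "waveform": profile.waveform,
            "amplitude": profile.amplitude,
            "frequency": profile.frequency,
            "phase": profile.phase,
            "noise_parent": profile.noise_parent,
        },
        "files": paths,
    }
    sidecar_path = prefix.parent / f"{prefix.name}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    sidecar["sidecar"] = str(sidecar_path)
    return sidecar


def read_stimulus(prefix):
    """Read a stereo pair written by :func:`write_stimulus`.

    Returns ``(pair, sidecar_dict)``.
    """
    import json
    from pathlib import Path

    from PIL import Image

    prefix = Path(prefix)
    sidecar = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
    lo, hi = sidecar["clip_range"]
    imgs = {}
    for tag in ("L", "R"):
        u16 = np.asarray(Image.open(sidecar["files"][tag]), dtype=float)
        imgs[tag] = u16 / 65535.0 * (hi - lo) + lo
    pair = StereoPair(left=imgs["L"], right=imgs["R"],
                      pixel_pitch=sidecar["pixel_pitch_arcmin"],
                      extent=tuple(sidecar["extent_deg"]))
    return pair, sidecar
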