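"""Windowed normalized cross-correlation with a size/disparity correlation.

The disparity encoding stage is a population of local cross-correlators.
A correlator tuned to vertical position ``y`` and preferred disparity
``dx`` compares a Gaussian-windowed patch of the left image centred at
``(x, y)`` with a same-size patch of the right image centred at
``(x + dx, y)``.  Both patches are multiplied by a Gaussian window of
standard deviation ``sigma`` truncated at two standard deviations, and the
reported response is the Pearson correlation coefficient of the two sets
of weighted pixel values: +1 for a perfectly matched patch, -1 for an
anticorrelated one.

The model's key ingredient is that ``sigma`` grows with the preferred
disparity (detectors for larger disparities integrate over larger
regions): constant, linear and quadratic size/disparity relations are
supported, all with ``sigma = 3`` arcmin at zero disparity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .stimgen import ARCMIN_PER_DEG, DisparityProfile, StereoPair, disparity_at

_KINDS = ("constant", "linear", "quadratic")


@dataclass(frozen=True)
class SizeDisparityRelation:
    """Window size sigma (arcmin) as a function of preferred disparity.

    ``constant``:  sigma = sigma0
    ``linear``:    sigma = sigma0 + lin_slope * |dx|
    ``quadratic``: sigma = sigma0 + quad_coef * dx**2

    Defaults: ``sigma0 = 3`` arcmin (the classic fixed 2*sigma = 6 arcmin
    window), ``quad_coef = 0.032`` arcmin^-1, ``lin_slope = 0.24`` (chosen
    so the linear and quadratic relations coincide at dx = 7.6 arcmin).
    """

    kind: str = "quadratic"
    sigma0: float = 3.0
    lin_slope: float = 0.24
    quad_coef: float = 0.032

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown relation kind {self.kind!r}")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    def sigma(self, dx):
        """Window SD in arcmin for preferred disparity ``dx`` (arcmin)."""
        dx = np.asarray(dx, dtype=float)
        if self.kind == "constant":
            out = np.full_like(dx, self.sigma0)
        elif self.kind == "linear":
            out = self.sigma0 + self.lin_slope * np.abs(dx)
        else:
            out = self.sigma0 + self.quad_coef * dx ** 2
        return out if out.ndim else float(out)

    @classmethod
    def constant(cls, sigma0: float = 3.0) -> "SizeDisparityRelation":
        return cls(kind="constant", sigma0=sigma0)

    @classmethod
    def linear(cls, sigma0: float = 3.0, lin_slope: float = 0.24
               ) -> "SizeDisparityRelation":
        return cls(kind="linear", sigma0=sigma0, lin_slope=lin_slope)

    @classmethod
    def quadratic(cls, sigma0: float = 3.0, quad_coef: float = 0.032
                  ) -> "SizeDisparityRelation":
        return cls(kind="quadratic", sigma0=sigma0, quad_coef=quad_coef)


def window_sigma(rel: SizeDisparityRelation, dx):
    """Functional form of :meth:`SizeDisparityRelation.sigma`."""
    return rel.sigma(dx)


@dataclass(frozen=True)
class CorrelatorGrid:
    """Uniform grid of preferred disparities (arcmin).

    The step equals one working pixel (0.6 arcmin by default) so that
    preferred disparities are realizable as integer window offsets.  The
    standard range covers +-13 arcmin; extended grids (up to +-140 arcmin)
    are used for the upper-depth-limit experiments.
    """

    disparities: np.ndarray
    step: float = 0.6

    def __post_init__(self) -> None:
        d = np.asarray(self.disparities, dtype=float)
        if d.size == 0:
            raise ValueError("disparity grid must not be empty")
        mult = d / self.step
        if np.max(np.abs(mult - np.round(mult))) > 1e-6:
            raise ValueError("disparities must be multiples of the grid step")
        object.__setattr__(self, "disparities", d)

    @classmethod
    def standard(cls, max_disparity: float = 13.0, step: float = 0.6
                 ) -> "CorrelatorGrid":
        """Symmetric grid of all multiples of ``step`` within the range."""
        m = int(np.floor(max_disparity / step + 1e-9))
        return cls(disparities=np.arange(-m, m + 1) * step, step=step)

    @classmethod
    def extended(cls, max_disparity: float = 140.0, step: float = 0.6
                 ) -> "CorrelatorGrid":
        return cls.standard(max_disparity=max_disparity, step=step)

    def __len__(self) -> int:
        return len(self.disparities)


@dataclass
class CorrelationSurface:
    """Correlator population response C(y, dx).

    ``C`` is indexed ``[y, dx]``; entries where the correlation window does
    not fit inside the rasters, or where a windowed patch has zero
    variance, are flagged undefined (NaN).  Defined entries lie in
    ``[-1, 1]``.
    """

    C: np.ndarray
    disparities: np.ndarray    # arcmin
    y_positions: np.ndarray    # deg, image-centred
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.C)

    def to_hdf5(self, target) -> None:
        """Write to an HDF5 file path or open ``h5py.Group``."""
        import json

        import h5py

        if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
            with h5py.File(target, "w") as f:
                self.to_hdf5(f)
            return
        target.create_dataset("C", data=self.C)
        target.create_dataset("disparities", data=self.disparities)
        target.create_dataset("y_positions", data=self.y_positions)
        target.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, source) -> "CorrelationSurface":
        import json

        import h5py

        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            with h5py.File(source, "r") as f:
                return cls.from_hdf5(f)
        return cls(C=source["C"][()],
                   disparities=source["disparities"][()],
                   y_positions=source["y_positions"][()],
                   meta=json.loads(source.attrs.get("meta", "{}")))

    def save_heatmap(self, path, title: str | None = None) -> None:
        """Export the surface as a PNG heat map (for visual debugging)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.0, 4.8))
        im = ax.imshow(
            self.C, aspect="auto", origin="lower", cmap="viridis",
            extent=[self.disparities[0], self.disparities[-1],
                    self.y_positions[0] * ARCMIN_PER_DEG,
                    self.y_positions[-1] * ARCMIN_PER_DEG],
        )
        ax.set_xlabel("preferred disparity (arcmin)")
        ax.set_ylabel("vertical position (arcmin)")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="correlation")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _halfwidth_px(sigma_arcmin: float, pitch: float) -> int:
    """Largest pixel offset with |offset * pitch| strictly below 2*sigma."""
    t = 2.0 * sigma_arcmin / pitch
    k = int(np.ceil(t)) - 1
    return max(k, 0)


def _gauss_profile(k: int, sigma_arcmin: float, pitch: float) -> np.ndarray:
    off = np.arange(-k, k + 1) * pitch
    return np.exp(-(off ** 2) / (2.0 * sigma_arcmin ** 2))


def windowed_correlation(pair: StereoPair, x: int, y: int,
                         dx: float, sigma: float) -> float:
    """Correlation of Gaussian-windowed patches at one grid point.

    ``x`` and ``y`` are pixel indices of the left-eye window centre;
    ``dx`` is the preferred disparity in arcmin (must be a whole number of
    pixels) and ``sigma`` the window SD in arcmin.  Returns the Pearson
    correlation coefficient of the window-weighted left and right pixel
    sets, or NaN when either windowed patch has zero variance.  Raises if
    the truncated window does not fit inside both rasters.
    """
    p = pair.pixel_pitch
    ddx = dx / p
    if abs(ddx - round(ddx)) > 1e-6:
        raise ValueError("dx must be a whole number of pixels")
    ddx = int(round(ddx))
    k = _halfwidth_px(sigma, p)
    n_rows, n_cols = pair.shape
    if y - k < 0 or y + k >= n_rows:
        raise ValueError("window does not fit vertically")
    if x - k < 0 or x + k >= n_cols or x + ddx - k < 0 or x + ddx + k >= n_cols:
        raise ValueError("window does not fit horizontally")
    g = _gauss_profile(k, sigma, p)
    w = np.outer(g, g)
    a = (w * pair.left[y - k: y + k + 1, x - k: x + k + 1]).ravel()
    b = (w * pair.right[y - k: y + k + 1, x + ddx - k: x + ddx + k + 1]).ravel()
    n = a.size
    sa, sb = a.sum(), b.sum()
    cov = a @ b - sa * sb / n
    va = a @ a - sa * sa / n
    vb = b @ b - sb * sb / n
    if va <= 0.0 or vb <= 0.0:
        return float("nan")
    return float(np.clip(cov / np.sqrt(va * vb), -1.0, 1.0))


def correlation_surface(pair: StereoPair, grid: CorrelatorGrid,
                        rel: SizeDisparityRelation,
                        x: int | None = None, y_step: int = 1,
                        meta: dict | None = None) -> CorrelationSurface:
    """Population response over all grid disparities and vertical positions.

    The left-eye window sits in a single image column (``x``, default the
    image centre, matching the single-column population simulated here);
    the right-eye window is offset by each preferred disparity in turn and
    its size follows the size/disparity relation.  The vertical position
    grid steps by ``y_step`` working pixels (1 = every row).  Grid points
    whose window leaves the raster are flagged undefined.

    The computation exploits the separability of the truncated Gaussian
    window: per disparity, windowed sums over the patch factor into a
    row-weighted sum followed by a 1-D vertical convolution, which makes
    the full surface cheap enough for Monte-Carlo template building.
    """
    p = pair.pixel_pitch
    L, R = pair.left, pair.right
    n_rows, n_cols = L.shape
    if x is None:
        x = n_cols // 2
    if grid.step / p - round(grid.step / p) > 1e-6:
        raise ValueError("grid step must be a whole number of pixels")
    rows = np.arange(0, n_rows, y_step)
    disp = grid.disparities
    C = np.full((len(rows), len(disp)), np.nan)
    for j, dx in enumerate(disp):
        sigma = rel.sigma(dx)
        k = _halfwidth_px(sigma, p)
        ddx = int(round(dx / p))
        lo_l, hi_l = x - k, x + k
        lo_r, hi_r = x + ddx - k, x + ddx + k
        if lo_l < 0 or hi_l >= n_cols or lo_r < 0 or hi_r >= n_cols:
            continue
        g = _gauss_profile(k, sigma, p)
        g2 = g * g
        sl = L[:, lo_l: hi_l + 1]
        sr = R[:, lo_r: hi_r + 1]
        # horizontal window-weighted sums per row
        a1 = sl @ g
        b1 = sr @ g
        a2 = (sl * sl) @ g2
        b2 = (sr * sr) @ g2
        ab = (sl * sr) @ g2
        # vertical accumulation (kernels are symmetric)
        sa = np.convolve(a1, g, mode="same")
        sb = np.convolve(b1, g, mode="same")
        saa = np.convolve(a2, g2, mode="same")
        sbb = np.convolve(b2, g2, mode="same")
        sab = np.convolve(ab, g2, mode="same")
        n = float((2 * k + 1) ** 2)
        cov = sab - sa * sb / n
        va = saa - sa * sa / n
        vb = sbb - sb * sb / n
        valid = np.zeros(n_rows, dtype=bool)
        valid[k: n_rows - k] = True
        good = valid & (va > 0.0) & (vb > 0.0)
        col = np.full(n_rows, np.nan)
        col[good] = np.clip(cov[good] / np.sqrt(va[good] * vb[good]),
                            -1.0, 1.0)
        C[:, j] = col[rows]
    y_pos = (rows - (n_rows - 1) / 2.0) * (p / ARCMIN_PER_DEG)
    info = {"x": int(x), "y_step": int(y_step), "relation": rel.kind}
    if meta:
        info.update(meta)
    return CorrelationSurface(C=C, disparities=disp.copy(), y_positions=y_pos,
                              meta=info)


def disparity_range_in_window(profile: DisparityProfile, y_center: float,
                              halfwidth: float) -> float:
    """Range (max - min, arcmin) of grating disparity inside a window.

    The window covers vertical positions ``[y_center - h, y_center + h]``
    with ``y_center`` in deg and the half-width ``h`` given in arcmin
    (conventionally the 1-SD extent of the Gaussian window).  Exact for
    both waveforms: for sines the extrema lie at the interval endpoints or
    at interior peaks/troughs of the sinusoid; a square wave has range
    ``2A`` iff the window straddles an edge, else 0.
    """
    if profile.is_noise:
        raise ValueError("disparity noise has no deterministic profile")
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if halfwidth == 0 or profile.amplitude == 0:
        return 0.0
    h = halfwidth / ARCMIN_PER_DEG
    lo, hi = y_center - h, y_center + h
    f = profile.frequency
    ph = np.deg2rad(profile.phase)
    if profile.waveform == "sine":
        cand = [lo, hi]
        # interior extrema: 2*pi*f*y + ph = pi/2 + k*pi
        k_lo = int(np.ceil((2 * np.pi * f * lo + ph - np.pi / 2) / np.pi))
        k_hi = int(np.floor((2 * np.pi * f * hi + ph - np.pi / 2) / np.pi))
        for k in range(k_lo, k_hi + 1):
            cand.append((np.pi / 2 + k * np.pi - ph) / (2 * np.pi * f))
        d = profile.amplitude * np.sin(2 * np.pi * f * np.asarray(cand) + ph)
        return float(d.max() - d.min())
    # square wave: disparity flips sign where sin(2*pi*f*y + ph) crosses
    # zero; probe just inside the interval on both sides of each crossing
    k_lo = int(np.floor((2 * np.pi * f * lo + ph) / np.pi)) - 1
    k_hi = int(np.ceil((2 * np.pi * f * hi + ph) / np.pi)) + 1
    eps = 1e-9 / f
    cand = [lo, hi]
    for k in range(k_lo, k_hi + 1):
        yk = (k * np.pi - ph) / (2 * np.pi * f)
        for y in (yk - eps, yk + eps):
            if lo <= y <= hi:
                cand.append(y)
    d = np.asarray(disparity_at(profile, np.asarray(cand)))
    return float(d.max() - d.min())
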