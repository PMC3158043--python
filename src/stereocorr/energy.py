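"""Binocular energy-model verification of the cross-correlator.

A stereo energy unit with position disparity ``dx`` and zero phase
disparity is a quadrature pair of left/right Gabor subunits:

    S = (S_L1 + S_R1)^2 + (S_L2 + S_R2)^2

where ``S_L1`` is the inner product of the left image with a Gabor of
phase ``phi`` and ``S_L2`` with phase ``phi + pi/2`` (right analogously,
with the receptive field shifted by ``dx``).  The response splits exactly
into a binocular cross term and two monocular energies,

    S = B + L + R,   B = 2 (S_L1 S_R1 + S_L2 S_R2),
    L = S_L1^2 + S_L2^2,  R = S_R1^2 + S_R2^2,

and summing ``B`` over receptive fields tuned to all spatial frequencies
and orientations (with the envelope size held fixed) collapses the Gabor
carriers onto a delta function, leaving the covariance-like sum of the
window-weighted image patches plus a term in the mean windowed pixel
value.  Normalizing by the integrated monocular energies,

    C_int = B_int / sqrt(L_int * R_int),

gives a quantity in [-1, 1] that, for dense mean-zero random-dot
stimuli, equals the windowed correlation coefficient computed directly by
the correlator stage.  :func:`integrated_correlation` evaluates the bank
sum by numerical quadrature and verifies its own convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlator import _gauss_profile, _halfwidth_px
from .stimgen import ARCMIN_PER_DEG, StereoPair


@dataclass(frozen=True)
class GaborParams:
    """A Gabor receptive field.

    ``kx``/``ky`` are wavenumbers in cycles/deg (together: spatial
    frequency and orientation), ``phase`` in radians, envelope ``sigma``
    in arcmin, ``center`` in deg relative to the image centre.
    """

    kx: float
    ky: float
    phase: float
    sigma: float
    center: tuple = (0.0, 0.0)
    eye: str = "left"


@dataclass(frozen=True)
class EnergyResponse:
    """Energy-unit response and its exact decomposition S = B + L + R."""

    S: float
    B: float
    L: float
    R: float


def _patch_coords(pair: StereoPair, center_deg, k: int):
    """Pixel-offset coordinate grids (deg) and slice indices for a patch."""
    p_deg = pair.pixel_pitch / ARCMIN_PER_DEG
    n_rows, n_cols = pair.shape
    cx = center_deg[0] / p_deg + (n_cols - 1) / 2.0
    cy = center_deg[1] / p_deg + (n_rows - 1) / 2.0
    ix, iy = int(round(cx)), int(round(cy))
    if iy - k < 0 or iy + k >= n_rows or ix - k < 0 or ix + k >= n_cols:
        raise ValueError("receptive field does not fit inside the raster")
    off = np.arange(-k, k + 1)
    X = (off[None, :] + (ix - cx)) * p_deg
    Y = (off[:, None] + (iy - cy)) * p_deg
    return X, Y, (slice(iy - k, iy + k + 1), slice(ix - k, ix + k + 1))


def gabor_inner_product(image: np.ndarray, pixel_pitch: float,
                        params: GaborParams,
                        truncate_sigma: float = 2.0) -> float:
    """Inner product of an image with a truncated Gabor; linear in the image.

    The Gaussian envelope is cut off at ``truncate_sigma`` standard
    deviations (default two, matching the correlation windows).
    """
    pair = StereoPair(left=image, right=image, pixel_pitch=pixel_pitch,
                      extent=(image.shape[1] * pixel_pitch / 60.0,
                              image.shape[0] * pixel_pitch / 60.0))
    k = _halfwidth_px(params.sigma * truncate_sigma / 2.0, pixel_pitch)
    X, Y, sl = _patch_coords(pair, params.center, k)
    sigma_deg = params.sigma / ARCMIN_PER_DEG
    env = np.exp(-(X ** 2 + Y ** 2) / (2.0 * sigma_deg ** 2))
    carrier = np.cos(2.0 * np.pi * (params.kx * X + params.ky * Y)
                     + params.phase)
    return float(np.sum(image[sl] * env * carrier))


def energy_unit_response(pair: StereoPair, left_params: GaborParams,
                         dx: float, phase_disparity: float = 0.0
                         ) -> EnergyResponse:
    """Quadrature-pair energy response for position disparity ``dx`` (arcmin).

    The right receptive field is the left one shifted horizontally by
    ``dx``; its carrier phase differs by ``phase_disparity`` (zero for the
    pure position-disparity units used in the verification).
    """
    rx = (left_params.center[0] + dx / ARCMIN_PER_DEG, left_params.center[1])
    s = {}
    for tag, img, center, ph0 in (
            ("L", pair.left, left_params.center, left_params.phase),
            ("R", pair.right, rx, left_params.phase + phase_disparity)):
        for q, dph in (("1", 0.0), ("2", np.pi / 2.0)):
            prm = GaborParams(kx=left_params.kx, ky=left_params.ky,
                              phase=ph0 + dph, sigma=left_params.sigma,
                              center=center, eye=tag.lower())
            s[tag + q] = gabor_inner_product(img, pair.pixel_pitch, prm)
    B = 2.0 * (s["L1"] * s["R1"] + s["L2"] * s["R2"])
    L = s["L1"] ** 2 + s["L2"] ** 2
    R = s["R1"] ** 2 + s["R2"] ** 2
    S = (s["L1"] + s["R1"]) ** 2 + (s["L2"] + s["R2"]) ** 2
    return EnergyResponse(S=S, B=B, L=L, R=R)


def _bank_terms(pair: StereoPair, x: int, y: int, ddx: int, k: int,
                g2d: np.ndarray, freqs: np.ndarray, thetas: np.ndarray,
                weights: np.ndarray) -> tuple:
    """Quadrature sums of B, L, R over the frequency x orientation bank."""
    p_deg = pair.pixel_pitch / ARCMIN_PER_DEG
    off = np.arange(-k, k + 1) * p_deg
    X = np.broadcast_to(off[None, :], (2 * k + 1, 2 * k + 1)).ravel()
    Y = np.broadcast_to(off[:, None], (2 * k + 1, 2 * k + 1)).ravel()
    wl = (g2d * pair.left[y - k: y + k + 1, x - k: x + k + 1]).ravel()
    wr = (g2d * pair.right[y - k: y + k + 1,
                           x + ddx - k: x + ddx + k + 1]).ravel()
    FF, TT = np.meshgrid(freqs, thetas, indexing="ij")
    kx = (FF * np.cos(TT)).ravel()
    ky = (FF * np.sin(TT)).ravel()
    phase = 2.0 * np.pi * (kx[:, None] * X[None, :]
                           + ky[:, None] * Y[None, :])
    cosm = np.cos(phase)
    sinm = np.sin(phase)
    lc = cosm @ wl
    ls = sinm @ wl
    rc = cosm @ wr
    rs = sinm @ wr
    w = weights.ravel()
    B = 2.0 * float(w @ (lc * rc + ls * rs))
    L = float(w @ (lc * lc + ls * ls))
    R = float(w @ (rc * rc + rs * rs))
    return B, L, R


def _dc_terms(pair: StereoPair, x: int, y: int, ddx: int, k: int,
              g2d: np.ndarray) -> tuple:
    """Responses of the zero-frequency (envelope-only) unit.

    The bank sum of ``B`` equals the raw product sum of the windowed
    patches; the covariance the correlator computes differs from it by a
    term in the mean windowed pixel values, and that term is exactly the
    contribution of a unit with zero spatial frequency.  Subtracting it
    (and its monocular analogues) turns the bank sums into covariances.
    """
    wl = (g2d * pair.left[y - k: y + k + 1, x - k: x + k + 1]).sum()
    wr = (g2d * pair.right[y - k: y + k + 1,
                           x + ddx - k: x + ddx + k + 1]).sum()
    n = float(g2d.size)
    return wl * wr / n, wl * wl / n, wr * wr / n


def _cint_once(pair, x, y, ddx, k, g2d, n_freq, n_orient, f_min, f_max,
               radial, subtract_dc) -> float:
    if radial == "log":
        freqs = np.geomspace(f_min, f_max, n_freq)
        dlog = np.log(freqs[1] / freqs[0])
        wf = freqs ** 2 * dlog                     # f df = f^2 dlog f
    elif radial == "linear":
        freqs = np.linspace(f_min, f_max, n_freq)
        wf = freqs * (freqs[1] - freqs[0])
    else:
        raise ValueError(f"unknown radial spacing {radial!r}")
    # trapezoid endpoints in the radial direction
    wf = wf.astype(float).copy()
    wf[0] *= 0.5
    wf[-1] *= 0.5
    thetas = np.arange(n_orient) * (np.pi / n_orient)   # half plane suffices
    weights = np.outer(wf, np.full(n_orient, np.pi / n_orient))
    B, L, R = _bank_terms(pair, x, y, ddx, k, g2d, freqs, thetas, weights)
    # The full-plane bank sum approximates a delta function with weight
    # 1/(pixel area); the orientation quadrature covers the half plane
    # (the carriers are even in k), and B carries the quadrature-pair
    # factor 2 relative to the monocular energies.  Rescaling puts B, L,
    # R in raw patch-sum units (sum ab, sum a^2, sum b^2).
    px_area = (pair.pixel_pitch / ARCMIN_PER_DEG) ** 2
    B, L, R = B * px_area, 2.0 * L * px_area, 2.0 * R * px_area
    if subtract_dc:
        db, dl, dr = _dc_terms(pair, x, y, ddx, k, g2d)
        B, L, R = B - db, L - dl, R - dr
    if L <= 0.0 or R <= 0.0:
        return float("nan")
    return B / np.sqrt(L * R)


def integrated_correlation(pair: StereoPair, x: int, y: int, dx: float,
                           sigma: float, n_freq: int = 96,
                           n_orient: int = 48, f_min: float = 0.25,
                           f_max: float | None = None,
                           radial: str = "log", tol: float = 1e-3,
                           check_convergence: bool = True,
                           subtract_dc: bool = True) -> float:
    """Normalized, bank-summed binocular energy C_int at one grid point.

    The bank covers ``n_freq`` radial frequencies (log-spaced by default,
    from ``f_min`` up to the working-grid Nyquist) times ``n_orient``
    orientations over the half plane, each contributing a quadrature pair
    of position-disparity energy units whose shared Gaussian envelope has
    SD ``sigma`` (arcmin), truncated at two SD to match the correlator
    window.  When ``check_convergence`` is set, the bank density is
    doubled and a discrepancy above ``tol`` raises ``RuntimeError``.

    By default (``subtract_dc=True``) the zero-frequency unit's
    contribution — the term in the mean windowed pixel values — is
    removed from the binocular and monocular sums, which turns them into
    the covariance/variance sums of the correlator's Pearson coefficient;
    this is the quantity the bank sum is shown to reproduce.  With
    ``subtract_dc=False`` the raw normalized bank sum is returned; it
    retains the mean-luminance term, which matters for stimuli with
    large-scale luminance structure but fluctuates noticeably even for
    dense random-dot patterns because the optical blur limits the number
    of independent samples per window.
    """
    p = pair.pixel_pitch
    ddx = dx / p
    if abs(ddx - round(ddx)) > 1e-6:
        raise ValueError("dx must be a whole number of pixels")
    ddx = int(round(ddx))
    if f_max is None:
        f_max = ARCMIN_PER_DEG / (2.0 * p)   # working Nyquist, cycles/deg
    k = _halfwidth_px(sigma, p)
    n_rows, n_cols = pair.shape
    if (y - k < 0 or y + k >= n_rows or x - k < 0 or x + k >= n_cols
            or x + ddx - k < 0 or x + ddx + k >= n_cols):
        raise ValueError("window does not fit inside the rasters")
    g = _gauss_profile(k, sigma, p)
    g2d = np.outer(g, g)
    coarse = _cint_once(pair, x, y, ddx, k, g2d, n_freq, n_orient,
                        f_min, f_max, radial, subtract_dc)
    if not check_convergence:
        return float(coarse)
    fine = _cint_once(pair, x, y, ddx, k, g2d, 2 * n_freq, 2 * n_orient,
                      f_min, f_max, radial, subtract_dc)
    if not np.isfinite(fine) or abs(fine - coarse) > tol:
        raise RuntimeError(
            f"bank quadrature did not converge: |{fine:.6f} - {coarse:.6f}| "
            f"> {tol:g}")
    return float(fine)
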