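"""Template-matching perceptual read-out.

Each interval's correlator surface is compared against every template in
the bank via the Pearson correlation coefficient computed over all defined
(y, dx) entries; the match quality ``M`` is the best score over templates.
The observer judges the grating to be in the interval with the larger
``M_grating - M_noise``.  Only the template means enter the score (the SD
surfaces are stored with the bank but unused here); a variance-weighted
variant would slot in at :func:`match_quality`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlator import CorrelationSurface
from .templates import TemplateBank


@dataclass(frozen=True)
class MatchScore:
    """Best match qualities of one surface against a bank."""

    M_grating: float
    M_noise: float
    best_grating_id: int
    best_noise_id: int

    @property
    def evidence(self) -> float:
        """The decision variable ``M_grating - M_noise``."""
        return self.M_grating - self.M_noise


def _masked_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r over jointly defined entries; None when degenerate."""
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 2:
        return None
    x = a[m]
    y = b[m]
    x = x - x.mean()
    y = y - y.mean()
    vx = x @ x
    vy = y @ y
    if vx <= 0.0 or vy <= 0.0:
        return None
    return float(np.clip((x @ y) / np.sqrt(vx * vy), -1.0, 1.0))


def match_quality(surface: CorrelationSurface, templates) -> tuple:
    """Best Pearson match of a surface over a list of templates.

    Returns ``(M, index)`` of the best-matching template.  Zero-variance
    pairings are skipped; if every pairing is degenerate a ``ValueError``
    is raised.
    """
    if len(templates) == 0:
        raise ValueError("at least one template is required")
    best = None
    best_idx = -1
    for i, t in enumerate(templates):
        if t.mean_surface.shape != surface.C.shape:
            raise ValueError("surface and template grids differ in shape")
        r = _masked_pearson(surface.C, t.mean_surface)
        if r is None:
            continue
        if best is None or r > best:
            best, best_idx = r, i
    if best is None:
        raise ValueError("all surface/template pairings were degenerate")
    return best, best_idx


def score_surface(surface: CorrelationSurface, bank: TemplateBank) -> MatchScore:
    mg, ig = match_quality(surface, bank.grating_templates)
    mn, inn = match_quality(surface, bank.noise_templates)
    return MatchScore(M_grating=mg, M_noise=mn,
                      best_grating_id=ig, best_noise_id=inn)


def decide_interval(surface_1: CorrelationSurface,
                    surface_2: CorrelationSurface,
                    bank: TemplateBank,
                    rng: np.random.Generator) -> int:
    """Pick the interval (0 or 1) judged to contain the grating.

    The decision variable is ``M_grating - M_noise`` per interval; exact
    ties are broken uniformly at random (relevant only for bit-identical
    surfaces, but it keeps repeated runs well defined).
    """
    e1 = score_surface(surface_1, bank).evidence
    e2 = score_surface(surface_2, bank).evidence
    if e1 > e2:
        return 0
    if e2 > e1:
        return 1
    return int(rng.integers(0, 2))


def decide_interval_unknown_frequency(surface_1: CorrelationSurface,
                                      surface_2: CorrelationSurface,
                                      banks,
                                      rng: np.random.Generator) -> int:
    """Variant for an observer that does not know the grating frequency.

    ``M_grating`` is maximized across the grating templates of every bank
    in ``banks``; with a single bank this reduces exactly to
    :func:`decide_interval`.
    """
    banks = list(banks)
    if not banks:
        raise ValueError("at least one template bank is required")
    evidence = []
    for s in (surface_1, surface_2):
        mg = max(match_quality(s, b.grating_templates)[0] for b in banks)
        mn = max(match_quality(s, b.noise_templates)[0] for b in banks)
        evidence.append(mg - mn)
    if evidence[0] > evidence[1]:
        return 0
    if evidence[1] > evidence[0]:
        return 1
    return int(rng.integers(0, 2))
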