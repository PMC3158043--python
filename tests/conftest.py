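"""Shared fixtures.

The heavy session fixtures build the scaled-down template bank and trial
blocks once; several acceptance-level tests consume the same objects.
"""

from __future__ import annotations

import numpy as np
import pytest

import stereocorr as sc
from stereocorr.experiment import run_condition
from stereocorr.templates import build_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast pipeline for property checks (1 deg field, +-6' grid)."""
    return sc.PipelineConfig(
        extent=(1.0, 1.0),
        grid=sc.CorrelatorGrid.standard(max_disparity=6.0),
    )


@pytest.fixture(scope="session")
def reduced_bank38():
    """Reduced-profile template bank at 3.8 cpd (12 phases, 50 samples).

    This is the labelled fast profile of the headline simulation: the full
    36-phase / 100-sample bank is not desk-scale, but the reduced bank
    preserves the observer's priors (all six amplitudes, both waveforms).
    """
    return build_bank(3.8, sc.PipelineConfig(), phases=12, n=50, seed=7)


@pytest.fixture(scope="session")
def headline_results(reduced_bank38):
    """2IFC accuracy at 3.8 cpd with the quadratic size/disparity relation.

    150 trials per waveform at the 7.6-arcmin amplitude of the worked
    example, plus 100 trials per waveform at 2.5 arcmin for the sine
    versus square comparison.
    """
    cfg = sc.PipelineConfig()
    results = []
    for amplitude, trials in ((7.6, 150), (2.5, 100)):
        for wf in ("sine", "square"):
            cond = sc.DisparityProfile(waveform=wf, amplitude=amplitude,
                                       frequency=3.8)
            results.append(run_condition(cfg, cond, reduced_bank38,
                                         trials, seed=7))
    return results
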