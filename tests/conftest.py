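"""Shared fixtures: the scaled-down study spectra used by the trend checks.

The study band is compressed by 4 (5.5-10.25 MHz instead of 22-41 MHz) with
the geometry unchanged; this keeps the full six-pathology sweep inside a
workstation test run.  The non-calcified phantoms admit an exact layered
Bessel-series solution against which this fixture's FEM spectra agree to
three digits, so the trend tests built on it probe the model, not the
discretisation; docs/methods.md discusses which pathology contrasts the
wall-averaged spectra can and cannot resolve.
"""

import numpy as np
import pytest

from marginqus.geometry import Pathology, build_margin_model
from marginqus.qus_metrics import spectral_features
from marginqus.sweep import SweepConfig, run_sweep

DESK_SWEEP = SweepConfig(
    f_start=5.5e6, f_stop=10.25e6, step=0.1e6, center=7.875e6
)
DESK_DIVISOR = 6
BAND_SCALE = 4.0


@pytest.fixture(scope="session")
def desk_study_spectra():
    """One centered-duct spectrum per pathology at the desk scale."""
    return {
        p: run_sweep(
            build_margin_model(p), sweep=DESK_SWEEP,
            wavelength_divisor=DESK_DIVISOR,
        )
        for p in Pathology
    }


@pytest.fixture(scope="session")
def desk_study_metrics(desk_study_spectra):
    return {
        p: {
            mode: spectral_features(spec, mode)
            for mode in ("pulse_echo", "pitch_catch")
        }
        for p, spec in desk_study_spectra.items()
    }
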