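import numpy as np
import pandas as pd
import pytest

from ramanmf import synthetic
from ramanmf.spectra import BasisLibrary, RamanSpectrum, WavenumberAxis, default_axis


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def small_axis():
    return WavenumberAxis(np.linspace(450.0, 1800.0, 200))


@pytest.fixture(scope="session")
def library(axis):
    return synthetic.generate_basis_library(30, axis=axis, seed=42)


@pytest.fixture(scope="session")
def small_library(small_axis):
    return synthetic.generate_basis_library(5, axis=small_axis, seed=7)


@pytest.fixture(scope="session")
def tiny_design():
    return synthetic.generate_design(cells_per_sample=2)


@pytest.fixture(scope="session")
def analog_bundle(tiny_design, library):
    """Small study-analog bundle: raw dataset + truth + library."""
    truth = synthetic.simulate_score_trends(
        tiny_design, library, synthetic.study_analog_trends(),
        noise_cv=0.05, seed=42)
    dataset = synthetic.synthesize_spectra(truth, raw=True)
    return dataset, truth, library


def gaussian_spectrum(axis, centers, amps, fwhm=20.0, stage="raw"):
    """Smooth multi-peak test spectrum."""
    y = np.zeros_like(axis.values)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((axis.values - c) / (fwhm / 2.3548)) ** 2)
    return RamanSpectrum(axis, y, stage=stage)
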