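"""Shared fixtures: simulated dose panels are expensive, so one population
per noise condition is simulated once per session and shared between the
calibration-property tests and the acceptance-level checks."""

import numpy as np
import pytest

from nfkbinfo import infotheory as it
from nfkbinfo import nfkb_ssa as ns

N_CELLS = 500  # cells per dose for panel-level fixtures


@pytest.fixture(scope="session")
def rates():
    return ns.load_rates()


@pytest.fixture(scope="session")
def intrinsic_cell(rates):
    return ns.draw_cell(
        ns.ExtrinsicNoiseSpec(intrinsic_only=True), np.random.default_rng(0), rates=rates
    )


@pytest.fixture(scope="session")
def panels_intrinsic(rates):
    return ns.run_dose_panel(
        n_cells=N_CELLS, noise=ns.ExtrinsicNoiseSpec(intrinsic_only=True), seed=101, rates=rates
    )


@pytest.fixture(scope="session")
def panels_sigma0(rates):
    return ns.run_dose_panel(
        n_cells=N_CELLS, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0), seed=102, rates=rates
    )


@pytest.fixture(scope="session")
def panels_sigma03(rates):
    return ns.run_dose_panel(
        n_cells=N_CELLS, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.3), seed=103, rates=rates
    )


@pytest.fixture(scope="session")
def panels_sigma1(rates):
    return ns.run_dose_panel(
        n_cells=N_CELLS, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=1.0), seed=104, rates=rates
    )


@pytest.fixture(scope="session")
def panels_sigma3(rates):
    return ns.run_dose_panel(
        n_cells=N_CELLS, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=3.0), seed=105, rates=rates
    )


@pytest.fixture(scope="session")
def gaussian_ladder_panel():
    """Well-graded Gaussian panel for estimator cross-checks."""
    rng = np.random.default_rng(7)
    means = np.linspace(0.25, 0.75, 8)
    sds = np.linspace(0.05, 0.12, 8)
    samples = [rng.normal(m, s, 800) for m, s in zip(means, sds)]
    return it.DosePanel(np.arange(1, 9), samples)
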