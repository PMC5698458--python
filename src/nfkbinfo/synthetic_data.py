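"""Synthetic inputs with known ground truth for the analysis pipeline.

Three generators, all reproducible by seed:

* Gaussian dose-response panels ("eight overlapping Gaussians with
  increasing means and increasing variances") for validating the kNN mutual
  information estimator against quadrature truth;

* per-cell / per-frame intensity tables emulating segmented confocal output,
  with known ground-truth nuclear fractions and optional cytoplasmic
  interference contamination — the oracle for the imaging quantification;

* a discretized stand-in for the empirical distribution of the relative
  translocatable / inert NF-kB pool size (mean 1), from which per-cell pool
  sizes are drawn in the stochastic model.  This fixture is a synthetic
  surrogate constructed from a discretized log-normal shape, not digitized
  from published data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from nfkbinfo.imaging_quant import ci_apply
from nfkbinfo.infotheory import DosePanel, GaussianSpec, Sample

__all__ = [
    "TNF_DOSES",
    "GaussianPanelSpec",
    "PoolDistributionFixture",
    "gen_gaussian_panel",
    "gen_intensity_table",
    "pool_distribution_fixture",
]

# Canonical 8-dose TNF stimulation panel (ng/ml).
TNF_DOSES = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)

# Relative pool sizes probed in single-trajectory illustrations; the fixture
# support must contain them.
POOL_PROBES = (0.5, 0.7, 0.9, 1.3, 1.6)


@dataclass(frozen=True)
class GaussianPanelSpec:
    """Spec for an 8-dose panel of Gaussian readouts.

    Defaults mimic 30-min nuclear NF-kB translocation histograms: means
    rising from 0.25 (unstimulated, with cytoplasmic interference) to 0.75
    (saturated response) on the normalized-translocation axis, standard
    deviations rising from 0.05 to 0.12, several hundred to ~1500 cells per
    dose.  These are repository defaults, not measured data.
    """

    means: tuple = tuple(np.linspace(0.25, 0.75, 8))
    sds: tuple = tuple(np.linspace(0.05, 0.12, 8))
    n_per_dose: tuple = (500, 600, 700, 800, 900, 1000, 1200, 1500)
    seed: int = 0

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.size != sds.size or means.size != len(self.n_per_dose):
            raise ValueError("means, sds and n_per_dose must have equal length")
        if np.any(np.diff(means) <= 0):
            raise ValueError("means must be strictly increasing")
        if np.any(np.diff(sds) <= 0) or np.any(sds <= 0):
            raise ValueError("sds must be positive and strictly increasing")
        if any(n < 1 for n in self.n_per_dose):
            raise ValueError("n_per_dose must be positive")

    @property
    def gaussian_spec(self) -> GaussianSpec:
        return GaussianSpec(self.means, self.sds)


def gen_gaussian_panel(spec: GaussianPanelSpec | None = None) -> DosePanel:
    """Draw a reproducible 8-dose panel of Gaussian readouts."""
    spec = spec or GaussianPanelSpec()
    rng = np.random.default_rng(spec.seed)
    doses = TNF_DOSES if len(spec.means) == 8 else tuple(range(1, len(spec.means) + 1))
    samples = [
        Sample(rng.normal(m, s, size=n), label=d)
        for d, m, s, n in zip(doses, spec.means, spec.sds, spec.n_per_dose)
    ]
    return DosePanel(doses, samples)


# ---------------------------------------------------------------------------
# synthetic segmented-image tables
# ---------------------------------------------------------------------------

_CELLS_PER_FRAME = 25
_FRAME_AREA = 512 * 512


def gen_intensity_table(
    n_cells: int,
    true_fraction_distribution=0.24,
    ci: float = 0.0,
    bg_levels: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render synthetic per-cell and per-frame intensity tables.

    Each frame holds a group of cells sharing one background level per
    channel.  Every cell carries the same true whole-cell NF-kB content,
    attenuated by a per-cell focus factor that acts equally on the NF-kB and
    DAPI channels — the regime in which the DAPI-normalized quantification
    is exact.  With ``ci > 0`` a fraction ``ci`` of each cell's cytoplasmic
    signal is added to its nuclear sum, emulating cytoplasmic interference,
    so the quantified fraction becomes ``x + ci*(1 - x)``.

    Parameters
    ----------
    true_fraction_distribution : float, array-like, or callable(rng, n)
        Ground-truth nuclear fractions in [0, 1].
    bg_levels : (float, float)
        Per-pixel background added to the NF-kB and DAPI channels.

    Returns
    -------
    cells, frames, truth : DataFrame
        Tables in the documented CSV schema plus a ground-truth sidecar with
        ``true_fraction`` and the expected ``observed_fraction``.
    """
    rng = np.random.default_rng(seed)
    if callable(true_fraction_distribution):
        fractions = np.asarray(true_fraction_distribution(rng, n_cells), dtype=float)
    else:
        fractions = np.broadcast_to(
            np.asarray(true_fraction_distribution, dtype=float), (n_cells,)
        ).copy()
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("true fractions must lie in [0, 1]")
    bg_nfkb, bg_dapi = bg_levels

    frame_ids = np.arange(n_cells) // _CELLS_PER_FRAME
    focus = rng.lognormal(mean=0.0, sigma=0.15, size=n_cells)  # focus attenuation
    whole_cell = 1e6 * focus  # a.u., equal true content per cell
    dapi_nuc = 4e5 * focus
    area_nuc = rng.integers(400, 900, size=n_cells).astype(float)

    nuc_nfkb_signal = whole_cell * (fractions + ci * (1.0 - fractions))
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "frame_id": frame_ids,
            "nuc_intensity_nfkb": nuc_nfkb_signal + area_nuc * bg_nfkb,
            "nuc_intensity_dapi": dapi_nuc + area_nuc * bg_dapi,
            "nuc_area_nfkb": area_nuc,
            "nuc_area_dapi": area_nuc,
        }
    )

    grouped = pd.DataFrame({"frame_id": frame_ids, "w": whole_cell, "d": dapi_nuc})
    sums = grouped.groupby("frame_id").sum()
    frames = pd.DataFrame(
        {
            "frame_id": sums.index,
            "total_intensity_nfkb": sums["w"].to_numpy() + _FRAME_AREA * bg_nfkb,
            "total_intensity_dapi": sums["d"].to_numpy() + _FRAME_AREA * bg_dapi,
            "area_nfkb": float(_FRAME_AREA),
            "area_dapi": float(_FRAME_AREA),
            "bg_mean_nfkb": bg_nfkb,
            "bg_mean_dapi": bg_dapi,
        }
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "true_fraction": fractions,
            "observed_fraction": ci_apply(fractions, ci) if ci > 0 else fractions,
        }
    )
    return cells, frames, truth


# ---------------------------------------------------------------------------
# NF-kB pool-size distribution fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolDistributionFixture:
    """Discretized relative NF-kB pool-size distribution (mean exactly 1)."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if s.size != p.size:
            raise ValueError("support and probabilities must have equal length")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if abs(float(np.dot(s, p)) - 1.0) > 1e-6:
            raise ValueError("fixture mean must equal 1 within 1e-6")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "probabilities", p)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    @property
    def cv(self) -> float:
        var = float(np.dot(self.probabilities, (self.support - self.mean) ** 2))
        return float(np.sqrt(var) / self.mean)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.support, size=size, p=self.probabilities)


# Support grid: probes plus intermediate points covering ~[0.3, 2.2].
_POOL_SUPPORT = np.array(
    [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.45, 1.6, 1.8, 2.2]
)


def pool_distribution_fixture(cv: float = 0.35) -> PoolDistributionFixture:
    """Discretized log-normal-shaped pool distribution with mean exactly 1.

    A synthetic surrogate for the empirical distribution of relative
    translocatable NF-kB content observed after translation shutdown: the
    support grid includes the probe values {0.5, 0.7, 0.9, 1.3, 1.6} and the
    probabilities follow a log-normal density whose location parameter is
    solved so the *discrete* mean equals 1 within 1e-9; the coefficient of
    variation is config-exposed (default 0.35).
    """
    if not 0.0 < cv <= 0.5:
        raise ValueError("cv must lie in (0, 0.5] for this support grid")
    s = _POOL_SUPPORT

    def probs(mu: float, sigma: float) -> np.ndarray:
        logpdf = -((np.log(s) - mu) ** 2) / (2 * sigma**2) - np.log(s)
        pdf = np.exp(logpdf - logpdf.max())  # stable for small sigma
        return pdf / pdf.sum()

    def mu_for_mean_one(sigma: float) -> float:
        return brentq(
            lambda mu: float(np.dot(s, probs(mu, sigma))) - 1.0, -2.0, 2.0, xtol=1e-14
        )

    def cv_gap(sigma: float) -> float:
        p = probs(mu_for_mean_one(sigma), sigma)
        var = float(np.dot(p, (s - 1.0) ** 2))
        return float(np.sqrt(var)) - cv

    # discretization shrinks the spread, so solve for the shape parameter
    # that realizes the requested *discrete* coefficient of variation
    sigma = brentq(cv_gap, 1e-3, 1.5, xtol=1e-12)
    p = probs(mu_for_mean_one(sigma), sigma)
    return PoolDistributionFixture(support=s, probabilities=p)
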