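"""Stochastic simulation of the TNF -> NF-kB signaling network.

Single cells are simulated as continuous-time Markov jump processes over a
two-feedback network: TNF activates receptors (TNFR), active receptors
activate the IKKK kinase layer, IKKK drives IKK through an
active/inactive/neutral cycle, active IKK degrades IkBa (free and in complex
with NF-kB), liberated NF-kB translocates to the nucleus, and nuclear NF-kB
transcribes its own inhibitors IkBa (which re-sequesters and exports NF-kB)
and A20 (which attenuates IKKK activation and promotes IKK inactivation).
Cycloheximide (CHX) is modeled by zeroing both translation channels while
transcription proceeds.

Cell-to-cell (extrinsic) variability enters through the total receptor count
(log-normal with fixed median) and the translocatable / inert NF-kB pool
sizes (drawn from an empirical-shaped relative distribution of mean 1);
reaction stochasticity provides the intrinsic noise.  Two engines are
available: an exact Gillespie stochastic simulation algorithm, and a
fixed-step tau-leaping approximation used by default at panel scale, where
the ~1e5-copy IkBa/NF-kB pools make exact simulation expensive.

Rate constants are a repository calibration (``data/default_rates.yaml``)
fitted to behavioral constraints of the measured dose response (resting
nuclear fraction, peak timing, dose saturation; see ``scripts/calibrate.py``)
rather than a published kinetic dataset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from numba import njit

from nfkbinfo.infotheory import DosePanel, Sample
from nfkbinfo.synthetic_data import (
    PoolDistributionFixture,
    TNF_DOSES,
    pool_distribution_fixture,
)

__all__ = [
    "SPECIES",
    "ExtrinsicNoiseSpec",
    "CellParameters",
    "Trajectory",
    "ReadoutVector",
    "NormalizationSpec",
    "load_rates",
    "draw_cell",
    "simulate_cell",
    "peak_readouts",
    "normalize_nfkb",
    "run_dose_panel",
    "READOUT_NODES",
]

# state-vector layout
SPECIES = (
    "tnfr_off",
    "tnfr_a",
    "ikkk_off",
    "ikkk_a",
    "ikk_n",
    "ikk_a",
    "ikk_i",
    "ikba_cyt",
    "ikba_nuc",
    "ikba_mrna",
    "a20_mrna",
    "a20",
    "nfkb_cyt_complexed",
    "nfkb_cyt_free",
    "nfkb_nuc",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

RATE_NAMES = (
    "k_r_act",          # receptor activation, per (ng/ml) per receptor per min
    "k_r_deact",        # active-receptor deactivation, 1/min
    "k_kkk_act",        # IKKK activation, per active receptor per IKKK per min
    "k_kkk_deact",      # IKKK deactivation, 1/min
    "theta_a20_kkk",    # A20 scale for multiplicative IKKK-activation inhibition
    "k_ikk_act",        # IKK neutral->active, per active IKKK per IKK per min
    "k_ikk_inact",      # IKK active->inactive, 1/min (A20-enhanced)
    "theta_a20_ikk",    # A20 scale enhancing IKK inactivation
    "k_ikk_recover",    # IKK inactive->neutral, 1/min
    "k_ikba_deg",       # IKK_a-driven IkBa degradation, per IKK_a per IkBa per min
    "k_ikba_deg_complex",  # same, for IkBa complexed with NF-kB
    "k_ikba_basal",     # constitutive free/nuclear IkBa turnover, 1/min
    "k_complex_basal",  # constitutive turnover of complexed IkBa, 1/min
    "k_nfkb_import",    # free cytoplasmic NF-kB nuclear import, 1/min
    "k_bind_export",    # nuclear NF-kB:IkBa association + export, per pair per min
    "k_tx_ikba_basal",  # basal IkBa transcription, mRNA/min
    "k_tx_ikba",        # NF-kB_nuc-proportional IkBa transcription, per molecule per min
    "k_mrna_deg_ikba",  # IkBa mRNA decay, 1/min
    "k_tl_ikba",        # IkBa translation, proteins per mRNA per min (0 under CHX)
    "k_ikba_import",    # free IkBa nuclear import, 1/min
    "k_tx_a20_basal",
    "k_tx_a20",
    "k_mrna_deg_a20",
    "k_tl_a20",
    "k_a20_deg",
    "ikkk_total",
    "ikk_total",
)

N_REACTIONS = 20

READOUT_NODES = (
    "tnfr_a",
    "ikkk_a",
    "ikk_a",
    "ikba_deg",
    "nfkb_nuc_norm",
    "nfkb_nuc_norm_ci",
    "a20",
)


def load_rates(overrides: dict | None = None) -> dict:
    """Default calibrated rate constants, optionally updated with overrides."""
    ref = importlib.resources.files("nfkbinfo").joinpath("data/default_rates.yaml")
    rates = yaml.safe_load(ref.read_text())
    if overrides:
        unknown = set(overrides) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate constants: {sorted(unknown)}")
        rates.update(overrides)
    missing = set(RATE_NAMES) - set(rates)
    if missing:
        raise ValueError(f"rate table missing entries: {sorted(missing)}")
    return rates


def _rates_vector(rates: dict) -> np.ndarray:
    vec = np.array([float(rates[name]) for name in RATE_NAMES])
    if np.any(vec < 0):
        bad = [n for n, v in zip(RATE_NAMES, vec) if v < 0]
        raise ValueError(f"negative rate constants (would yield negative propensities): {bad}")
    return vec


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """Cell-to-cell variability of receptor and NF-kB abundance.

    ``sigma_tnfr`` is the log-normal shape parameter of the total TNFR count
    (median fixed at ``tnfr_median`` independently of sigma); the
    translocatable and inert NF-kB pools are drawn independently as
    ``mean * xi`` with ``xi`` from ``pool_distribution`` (mean 1).  With
    ``intrinsic_only`` both sources are switched off: every cell has exactly
    the median receptor count and the mean pools, leaving reaction
    stochasticity as the only noise.
    """

    sigma_tnfr: float = 0.3
    tnfr_median: float = 2e3
    nfkb_mean_translocatable: float = 1e5
    nfkb_mean_inert: float = 0.5e5
    pool_distribution: PoolDistributionFixture = field(
        default_factory=pool_distribution_fixture
    )
    intrinsic_only: bool = False

    def __post_init__(self):
        if self.sigma_tnfr < 0:
            raise ValueError("sigma_tnfr must be >= 0")
        if min(self.tnfr_median, self.nfkb_mean_translocatable, self.nfkb_mean_inert) <= 0:
            raise ValueError("medians/means must be positive")


@dataclass(frozen=True)
class CellParameters:
    """Extrinsic parameter draw for one simulated cell."""

    tnfr_total: int
    nfkb_translocatable: int
    nfkb_inert: int
    rates: dict

    def __post_init__(self):
        if min(self.tnfr_total, self.nfkb_translocatable, self.nfkb_inert) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Species counts of one cell on a fixed recording grid (minutes)."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_times, n_species), integer copy numbers
    cell: CellParameters
    dose: float
    chx: bool

    def species(self, name: str) -> np.ndarray:
        return self.counts[:, _IDX[name]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(SPECIES))
        df.insert(0, "time_min", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def nfkb_cytoplasmic(self) -> np.ndarray:
        return self.species("nfkb_cyt_complexed") + self.species("nfkb_cyt_free")

    @property
    def ikba_total(self) -> np.ndarray:
        """Total IkBa protein: free cytoplasmic + nuclear + complexed."""
        return (
            self.species("ikba_cyt")
            + self.species("ikba_nuc")
            + self.species("nfkb_cyt_complexed")
        )


@dataclass(frozen=True)
class NormalizationSpec:
    """Normalization of nuclear NF-kB counts to the population-average total.

    ``denominator`` is the mean total NF-kB per cell (translocatable + inert);
    ``ci`` is the cytoplasmic-interference fraction registering as nuclear.
    """

    ci: float = 0.24
    denominator: float = 1.5e5

    def __post_init__(self):
        if not 0.0 <= self.ci < 1.0:
            raise ValueError("ci must lie in [0, 1)")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")


@dataclass(frozen=True)
class ReadoutVector:
    """Per-node peak readouts of one cell over the first 30 min."""

    tnfr_a_max: float
    ikkk_a_max: float
    ikk_a_max: float
    ikba_deg_max: float
    nfkb_nuc_max: float
    a20_max: float
    nfkb_nuc_norm: float
    nfkb_nuc_norm_ci: float


# ---------------------------------------------------------------------------
# propensities and engines (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _propensities(x, par, dose, chx, a):
    # par follows RATE_NAMES order
    a20_inhib = 1.0 / (1.0 + x[11] / par[4])
    a[0] = par[0] * dose * x[0]                      # R_off -> R_on
    a[1] = par[1] * x[1]                             # R_on -> R_off
    a[2] = par[2] * x[1] * x[2] * a20_inhib          # KKK_off -> KKK_a
    a[3] = par[3] * x[3]                             # KKK_a -> KKK_off
    a[4] = par[5] * x[3] * x[4]                      # IKK_n -> IKK_a
    a[5] = par[6] * (1.0 + x[11] / par[7]) * x[5]    # IKK_a -> IKK_i
    a[6] = par[8] * x[6]                             # IKK_i -> IKK_n
    a[7] = (par[9] * x[5] + par[11]) * x[7]          # IkBa_cyt degradation
    a[8] = (par[10] * x[5] + par[12]) * x[12]        # complex -> NFkB_cyt_free
    a[9] = par[13] * x[13]                           # NFkB import
    a[10] = par[14] * x[14] * x[8]                   # nuc binding + export
    a[11] = par[15] + par[16] * x[14]                # IkBa transcription
    a[12] = par[17] * x[9]                           # IkBa mRNA decay
    a[13] = 0.0 if chx else par[18] * x[9]           # IkBa translation
    a[14] = par[19] * x[7]                           # IkBa nuclear import
    a[15] = par[11] * x[8]                           # nuclear IkBa turnover
    a[16] = par[20] + par[21] * x[14]                # A20 transcription
    a[17] = par[22] * x[10]                          # A20 mRNA decay
    a[18] = 0.0 if chx else par[23] * x[10]          # A20 translation
    a[19] = par[24] * x[11]                          # A20 decay


@njit(cache=True)
def _apply(x, r, n):
    # apply reaction r fired n times (n clamped to available substrate)
    if r == 0:
        n = min(n, x[0]); x[0] -= n; x[1] += n
    elif r == 1:
        n = min(n, x[1]); x[1] -= n; x[0] += n
    elif r == 2:
        n = min(n, x[2]); x[2] -= n; x[3] += n
    elif r == 3:
        n = min(n, x[3]); x[3] -= n; x[2] += n
    elif r == 4:
        n = min(n, x[4]); x[4] -= n; x[5] += n
    elif r == 5:
        n = min(n, x[5]); x[5] -= n; x[6] += n
    elif r == 6:
        n = min(n, x[6]); x[6] -= n; x[4] += n
    elif r == 7:
        n = min(n, x[7]); x[7] -= n
    elif r == 8:
        n = min(n, x[12]); x[12] -= n; x[13] += n
    elif r == 9:
        n = min(n, x[13]); x[13] -= n; x[14] += n
    elif r == 10:
        n = min(n, min(x[14], x[8])); x[14] -= n; x[8] -= n; x[12] += n
    elif r == 11:
        x[9] += n
    elif r == 12:
        n = min(n, x[9]); x[9] -= n
    elif r == 13:
        x[7] += n
    elif r == 14:
        n = min(n, x[7]); x[7] -= n; x[8] += n
    elif r == 15:
        n = min(n, x[8]); x[8] -= n
    elif r == 16:
        x[10] += n
    elif r == 17:
        n = min(n, x[10]); x[10] -= n
    elif r == 18:
        x[11] += n
    else:
        n = min(n, x[11]); x[11] -= n


@njit(cache=True)
def _simulate_exact(x0, par, dose, chx, t_end, dt_rec, seed):
    np.random.seed(seed)
    n_rec = int(round(t_end / dt_rec)) + 1
    rec = np.empty((n_rec, x0.size), dtype=np.int64)
    x = x0.copy()
    a = np.empty(N_REACTIONS)
    t = 0.0
    i_rec = 0
    rec[0] = x
    i_rec = 1
    while i_rec < n_rec:
        _propensities(x, par, dose, chx, a)
        a_tot = a.sum()
        if a_tot <= 0.0:
            break
        t += np.random.exponential(1.0 / a_tot)
        while i_rec < n_rec and i_rec * dt_rec <= t:
            rec[i_rec] = x
            i_rec += 1
        if i_rec >= n_rec:
            break
        u = np.random.random() * a_tot
        acc = 0.0
        r = 0
        for j in range(N_REACTIONS):
            acc += a[j]
            if u < acc:
                r = j
                break
        _apply(x, r, 1)
    while i_rec < n_rec:  # absorbing state: no further events
        rec[i_rec] = x
        i_rec += 1
    return rec


@njit(cache=True)
def _simulate_tau(x0, par, dose, chx, t_end, dt_rec, tau, seed):
    np.random.seed(seed)
    n_rec = int(round(t_end / dt_rec)) + 1
    sub = max(int(round(dt_rec / tau)), 1)
    rec = np.empty((n_rec, x0.size), dtype=np.int64)
    x = x0.copy()
    a = np.empty(N_REACTIONS)
    rec[0] = x
    for i_rec in range(1, n_rec):
        for _ in range(sub):
            _propensities(x, par, dose, chx, a)
            for r in range(N_REACTIONS):
                lam = a[r] * tau
                if lam > 0.0:
                    n = np.random.poisson(lam)
                    if n > 0:
                        _apply(x, r, n)
        rec[i_rec] = x
    return rec


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def draw_cell(
    noise: ExtrinsicNoiseSpec, rng: np.random.Generator, rates: dict | None = None
) -> CellParameters:
    """Draw one cell's extrinsic parameters.

    Total TNFR is log-normal with median ``tnfr_median`` and shape
    ``sigma_tnfr`` (the median is invariant under sigma changes); the
    translocatable and inert NF-kB pools are independent draws of
    ``mean * xi`` with xi from the pool distribution.  With
    ``intrinsic_only`` every cell gets the median receptor count and the
    exact mean pools.
    """
    rates = rates if rates is not None else load_rates()
    if noise.intrinsic_only or noise.sigma_tnfr == 0:
        tnfr = int(round(noise.tnfr_median))
    else:
        tnfr = int(round(noise.tnfr_median * np.exp(noise.sigma_tnfr * rng.standard_normal())))
        tnfr = min(tnfr, 10**8)
    if noise.intrinsic_only:
        pool_t = int(round(noise.nfkb_mean_translocatable))
        pool_i = int(round(noise.nfkb_mean_inert))
    else:
        xi_t, xi_i = noise.pool_distribution.sample(rng, 2)
        pool_t = int(round(noise.nfkb_mean_translocatable * xi_t))
        pool_i = int(round(noise.nfkb_mean_inert * xi_i))
    return CellParameters(
        tnfr_total=tnfr,
        nfkb_translocatable=pool_t,
        nfkb_inert=pool_i,
        rates=rates,
    )


def _initial_state(cell: CellParameters) -> np.ndarray:
    """Deterministic unstimulated steady state (approximate, rounded)."""
    r = cell.rates
    x = np.zeros(len(SPECIES), dtype=np.int64)
    x[_IDX["tnfr_off"]] = cell.tnfr_total
    x[_IDX["ikkk_off"]] = int(r["ikkk_total"])
    x[_IDX["ikk_n"]] = int(r["ikk_total"])
    m_ikba = r["k_tx_ikba_basal"] / r["k_mrna_deg_ikba"]
    x[_IDX["ikba_mrna"]] = int(round(m_ikba))
    ikba_cyt = r["k_tl_ikba"] * m_ikba / (r["k_ikba_basal"] + r["k_ikba_import"])
    x[_IDX["ikba_cyt"]] = int(round(ikba_cyt))
    x[_IDX["ikba_nuc"]] = int(round(r["k_ikba_import"] * ikba_cyt / r["k_ikba_basal"]))
    m_a20 = r["k_tx_a20_basal"] / r["k_mrna_deg_a20"]
    x[_IDX["a20_mrna"]] = int(round(m_a20))
    x[_IDX["a20"]] = int(round(r["k_tl_a20"] * m_a20 / r["k_a20_deg"]))
    x[_IDX["nfkb_cyt_complexed"]] = cell.nfkb_translocatable
    return x


def simulate_cell(
    cell: CellParameters,
    tnf_dose: float,
    t_end: float = 30.0,
    chx: bool = False,
    rng: np.random.Generator | int | None = None,
    engine: str = "tau",
    dt_record: float = 0.5,
    tau: float = 0.01,
) -> Trajectory:
    """Simulate one cell's stochastic response to a constant TNF dose.

    ``engine='exact'`` runs the exact Gillespie algorithm; ``engine='tau'``
    (default) a fixed-step tau-leaping approximation with step ``tau``
    minutes, recorded on a ``dt_record`` grid.  With ``chx`` both translation
    channels are silenced.  The translocatable NF-kB pool is conserved
    exactly along the trajectory.
    """
    if tnf_dose < 0:
        raise ValueError("dose must be >= 0")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    par = _rates_vector(cell.rates)
    x0 = _initial_state(cell)
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:
        rng = rng if rng is not None else np.random.default_rng()
        seed = int(rng.integers(0, 2**31 - 1))
    if engine == "exact":
        rec = _simulate_exact(x0, par, float(tnf_dose), chx, float(t_end), dt_record, seed)
    elif engine == "tau":
        rec = _simulate_tau(
            x0, par, float(tnf_dose), chx, float(t_end), dt_record, tau, seed
        )
    else:
        raise ValueError("engine must be 'exact' or 'tau'")
    times = np.arange(rec.shape[0]) * dt_record
    return Trajectory(times=times, counts=rec, cell=cell, dose=float(tnf_dose), chx=chx)


def normalize_nfkb(
    n_nuc: float,
    n_cyt: float,
    n_inert: float,
    spec: NormalizationSpec | None = None,
    with_ci: bool = True,
) -> float:
    """Normalized nuclear NF-kB, optionally with cytoplasmic interference.

    With interference: ``(n_nuc + ci*(n_cyt + n_inert)) / denominator``;
    without: ``n_nuc / denominator``.
    """
    spec = spec or NormalizationSpec()
    if min(n_nuc, n_cyt, n_inert) < 0:
        raise ValueError("counts must be non-negative")
    if with_ci:
        return (n_nuc + spec.ci * (n_cyt + n_inert)) / spec.denominator
    return n_nuc / spec.denominator


def peak_readouts(
    traj: Trajectory, norm: NormalizationSpec | None = None, window: float = 30.0
) -> ReadoutVector:
    """Per-node maxima over the first ``window`` minutes of a trajectory.

    ``ikba_deg_max`` is the maximal depletion of total IkBa relative to its
    initial level, clipped at zero.  The normalized nuclear NF-kB readouts
    take the per-time-point maximum of the normalized quantity (so the
    cytoplasmic-interference variant uses simultaneous nuclear and
    cytoplasmic counts).
    """
    norm = norm or NormalizationSpec()
    if traj.times[-1] + 1e-9 < window:
        raise ValueError(f"trajectory must cover at least {window} min")
    sel = traj.times <= window + 1e-9
    nuc = traj.species("nfkb_nuc")[sel].astype(float)
    cyt = traj.nfkb_cytoplasmic[sel].astype(float)
    ikba = traj.ikba_total[sel].astype(float)
    norm_plain = nuc / norm.denominator
    norm_ci = (nuc + norm.ci * (cyt + traj.cell.nfkb_inert)) / norm.denominator
    return ReadoutVector(
        tnfr_a_max=float(traj.species("tnfr_a")[sel].max()),
        ikkk_a_max=float(traj.species("ikkk_a")[sel].max()),
        ikk_a_max=float(traj.species("ikk_a")[sel].max()),
        ikba_deg_max=float(max(ikba[0] - ikba.min(), 0.0)),
        nfkb_nuc_max=float(nuc.max()),
        a20_max=float(traj.species("a20")[sel].max()),
        nfkb_nuc_norm=float(norm_plain.max()),
        nfkb_nuc_norm_ci=float(norm_ci.max()),
    )


def run_dose_panel(
    doses=TNF_DOSES,
    n_cells: int = 1000,
    noise: ExtrinsicNoiseSpec | None = None,
    chx: bool = False,
    seed: int = 0,
    rates: dict | None = None,
    engine: str = "tau",
    norm: NormalizationSpec | None = None,
    t_end: float = 30.0,
) -> dict[str, DosePanel]:
    """Simulate a cell population per dose and collect per-node peak panels.

    Each cell gets an independent extrinsic draw and an independent
    counter-based RNG substream derived from ``seed`` and its (dose, cell)
    index, so results are reproducible and independent of execution order.
    Returns one :class:`~nfkbinfo.infotheory.DosePanel` per readout node
    (see ``READOUT_NODES``); the per-cell table is available via
    :func:`panel_frame`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    noise = noise or ExtrinsicNoiseSpec()
    norm = norm or NormalizationSpec()
    rates = rates if rates is not None else load_rates()
    doses = tuple(float(d) for d in doses)
    readouts = {node: [] for node in READOUT_NODES}
    for i_dose, dose in enumerate(doses):
        vals = {node: np.empty(n_cells) for node in READOUT_NODES}
        for i_cell in range(n_cells):
            ss = np.random.SeedSequence([int(seed), i_dose, i_cell])
            rng = np.random.default_rng(ss)
            cell = draw_cell(noise, rng, rates=rates)
            kernel_seed = int(ss.generate_state(2)[1] % 2**31)
            traj = simulate_cell(
                cell, dose, t_end=t_end, chx=chx, rng=kernel_seed, engine=engine
            )
            rv = peak_readouts(traj, norm=norm)
            vals["tnfr_a"][i_cell] = rv.tnfr_a_max
            vals["ikkk_a"][i_cell] = rv.ikkk_a_max
            vals["ikk_a"][i_cell] = rv.ikk_a_max
            vals["ikba_deg"][i_cell] = rv.ikba_deg_max
            vals["a20"][i_cell] = rv.a20_max
            vals["nfkb_nuc_norm"][i_cell] = rv.nfkb_nuc_norm
            vals["nfkb_nuc_norm_ci"][i_cell] = rv.nfkb_nuc_norm_ci
        for node in READOUT_NODES:
            readouts[node].append(Sample(vals[node], label=dose))
    return {node: DosePanel(doses, readouts[node]) for node in READOUT_NODES}


def panel_frame(panels: dict[str, DosePanel]) -> pd.DataFrame:
    """Wide per-cell readout table (dose, cell_id, one column per node)."""
    frames = []
    for node, panel in panels.items():
        df = panel.to_frame().rename(columns={"readout": node})
        frames.append(df.set_index(["dose", "cell_id"]))
    return pd.concat(frames, axis=1).reset_index()
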