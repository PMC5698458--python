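"""Stochastic pathway model: exactness properties and calibration contract."""

import numpy as np
import pytest
from scipy import stats

from nfkbinfo import infotheory as it
from nfkbinfo import nfkb_ssa as ns


class TestDrawCell:
    def test_sigma_zero_gives_constant_receptor_count(self, rates):
        noise = ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0)
        rng = np.random.default_rng(0)
        cells = [ns.draw_cell(noise, rng, rates=rates) for _ in range(20)]
        assert all(c.tnfr_total == 2000 for c in cells)

    def test_intrinsic_only_fixes_pools_at_means(self, rates):
        noise = ns.ExtrinsicNoiseSpec(intrinsic_only=True, sigma_tnfr=3.0)
        rng = np.random.default_rng(1)
        cell = ns.draw_cell(noise, rng, rates=rates)
        assert (cell.tnfr_total, cell.nfkb_translocatable, cell.nfkb_inert) == (
            2000,
            10**5,
            5 * 10**4,
        )

    def test_lognormal_receptor_moments(self, rates):
        # median invariant under sigma; variance = (e^{s^2}-1)e^{s^2}e^{2mu}
        sigma = 1.0
        noise = ns.ExtrinsicNoiseSpec(sigma_tnfr=sigma)
        rng = np.random.default_rng(46)
        draws = np.array(
            [ns.draw_cell(noise, rng, rates=rates).tnfr_total for _ in range(10**5)]
        )
        assert np.median(draws) == pytest.approx(2000, rel=0.02)
        expected_var = (np.e - 1) * np.e * 2000.0**2
        assert draws.var() == pytest.approx(expected_var, rel=0.05)

    def test_pool_draws_follow_fixture(self, rates):
        noise = ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0)
        rng = np.random.default_rng(3)
        pools = np.array(
            [ns.draw_cell(noise, rng, rates=rates).nfkb_translocatable for _ in range(4000)]
        )
        assert pools.mean() == pytest.approx(1e5, rel=0.02)
        support = noise.pool_distribution.support * 1e5
        assert set(np.unique(pools)) <= {int(round(s)) for s in support}


class TestSimulateCell:
    @pytest.mark.parametrize("engine", ["exact", "tau"])
    def test_conservation_integrality_nonnegativity(self, intrinsic_cell, engine):
        traj = ns.simulate_cell(intrinsic_cell, 3.0, t_end=30, rng=5, engine=engine)
        assert traj.counts.dtype == np.int64
        assert (traj.counts >= 0).all()
        translocatable = (
            traj.species("nfkb_cyt_complexed")
            + traj.species("nfkb_cyt_free")
            + traj.species("nfkb_nuc")
        )
        assert (translocatable == intrinsic_cell.nfkb_translocatable).all()

    def test_unstimulated_nuclear_fraction_stays_low(self, intrinsic_cell):
        for seed in range(5):
            traj = ns.simulate_cell(intrinsic_cell, 0.0, t_end=30, rng=seed)
            frac = traj.species("nfkb_nuc") / intrinsic_cell.nfkb_translocatable
            assert frac.max() < 0.03

    def test_top_dose_peak_within_15_to_30_min(self, intrinsic_cell):
        nuc = np.mean(
            [
                ns.simulate_cell(intrinsic_cell, 10.0, t_end=60, rng=900 + s).species(
                    "nfkb_nuc"
                )
                for s in range(30)
            ],
            axis=0,
        )
        t_peak = 0.5 * nuc.argmax()
        assert 15.0 <= t_peak <= 30.0
        # no more than 2/3 of total NF-kB translocates
        assert nuc.max() / 1.5e5 <= 2.0 / 3.0

    def test_low_dose_response_weaker_at_15_than_30_min(self, intrinsic_cell):
        for dose in (0.1, 0.3):
            nuc = np.mean(
                [
                    ns.simulate_cell(intrinsic_cell, dose, t_end=30, rng=700 + s).species(
                        "nfkb_nuc"
                    )
                    for s in range(25)
                ],
                axis=0,
            )
            assert nuc[30] < nuc[60]  # 15 min < 30 min on the 0.5-min grid

    def test_chx_prolongs_nuclear_nfkb_and_accumulates_mrna(self, intrinsic_cell):
        nuc_chx, nuc_no, m_chx, m_no = [], [], [], []
        for s in range(20):
            chx = ns.simulate_cell(intrinsic_cell, 10.0, t_end=180, chx=True, rng=100 + s)
            plain = ns.simulate_cell(intrinsic_cell, 10.0, t_end=180, chx=False, rng=300 + s)
            nuc_chx.append(chx.species("nfkb_nuc"))
            nuc_no.append(plain.species("nfkb_nuc"))
            m_chx.append(chx.species("ikba_mrna")[-1])
            m_no.append(plain.species("ikba_mrna")[-1])
        nuc_chx, nuc_no = np.mean(nuc_chx, axis=0), np.mean(nuc_no, axis=0)
        i120, i180 = 240, 360
        # translation shutdown keeps NF-kB nuclear for hours
        assert nuc_chx[i120] > 0.5 * nuc_chx.max()
        assert nuc_chx[i180] > 0.5 * nuc_chx.max()
        assert nuc_no[i180] < 0.5 * nuc_no.max()
        # while inhibitor transcripts keep accumulating
        assert np.mean(m_chx) > np.mean(m_no)

    def test_deterministic_given_kernel_seed(self, intrinsic_cell):
        a = ns.simulate_cell(intrinsic_cell, 1.0, t_end=20, rng=77)
        b = ns.simulate_cell(intrinsic_cell, 1.0, t_end=20, rng=77)
        assert (a.counts == b.counts).all()

    def test_negative_rate_rejected_before_simulation(self, rates):
        bad = dict(rates, k_r_act=-1.0)
        cell = ns.CellParameters(2000, 10**5, 5 * 10**4, bad)
        with pytest.raises(ValueError):
            ns.simulate_cell(cell, 1.0, rng=0)

    def test_invalid_inputs_rejected(self, intrinsic_cell):
        with pytest.raises(ValueError):
            ns.simulate_cell(intrinsic_cell, -1.0, rng=0)
        with pytest.raises(ValueError):
            ns.simulate_cell(intrinsic_cell, 1.0, t_end=0.0, rng=0)


def test_receptor_activation_is_poisson_with_mean_proportional_to_dose(rates):
    """With downstream signaling and expression disabled, active-receptor
    counts at a fixed time follow a Poisson law with mean proportional to
    dose (immigration-death process started empty)."""
    stripped = dict(
        rates, k_kkk_act=0.0, k_tx_ikba_basal=0.0, k_tx_a20_basal=0.0
    )
    cell = ns.CellParameters(2000, 10**5, 5 * 10**4, stripped)
    means = {}
    for dose in (0.1, 0.3):
        counts = np.array(
            [
                ns.simulate_cell(
                    cell, dose, t_end=10, rng=3000 + s, engine="exact", dt_record=10.0
                ).species("tnfr_a")[-1]
                for s in range(3000)
            ]
        )
        lam = counts.mean()
        means[dose] = lam
        kmax = int(counts.max())
        obs = np.bincount(counts, minlength=kmax + 1).astype(float)
        exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
        while exp[-1] < 5 and exp.size > 3:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = 1.0 - stats.chi2.cdf(chi2, df=exp.size - 2)
        assert p > 0.01, f"Poisson fit rejected at dose {dose} (p={p:.4f})"
    assert means[0.3] / means[0.1] == pytest.approx(3.0, rel=0.15)


def test_tau_leaping_matches_exact_engine_distribution(intrinsic_cell):
    """Peak nuclear NF-kB distributions from the tau-leaping and exact
    engines agree (two-sample KS below the alpha=0.01 critical value)."""
    n = 250
    exact, tau = [], []
    for s in range(n):
        exact.append(
            ns.peak_readouts(
                ns.simulate_cell(intrinsic_cell, 0.3, t_end=30, rng=5000 + s, engine="exact")
            ).nfkb_nuc_norm
        )
        tau.append(
            ns.peak_readouts(
                ns.simulate_cell(intrinsic_cell, 0.3, t_end=30, rng=9000 + s, engine="tau")
            ).nfkb_nuc_norm
        )
    crit = 1.628 * np.sqrt(2.0 / n)  # alpha = 0.01
    assert it.ks_distance(exact, tau).ks < crit


class TestPeakReadouts:
    def _traj(self, intrinsic_cell, **series):
        n_t = 61
        counts = np.zeros((n_t, len(ns.SPECIES)), dtype=np.int64)
        for name, values in series.items():
            counts[:, ns.SPECIES.index(name)] = values
        return ns.Trajectory(
            times=np.arange(n_t) * 0.5, counts=counts, cell=intrinsic_cell, dose=1.0, chx=False
        )

    def test_constant_ikba_gives_zero_degradation(self, intrinsic_cell):
        traj = self._traj(intrinsic_cell, ikba_cyt=np.full(61, 100))
        assert ns.peak_readouts(traj).ikba_deg_max == 0.0

    def test_ikba_degradation_is_max_drop_from_initial(self, intrinsic_cell):
        vals = np.full(61, 100)
        vals[1], vals[2:] = 40, 70
        traj = self._traj(intrinsic_cell, ikba_cyt=vals)
        assert ns.peak_readouts(traj).ikba_deg_max == 60.0

    def test_monotone_trace_peaks_at_window_end(self, intrinsic_cell):
        traj = self._traj(intrinsic_cell, tnfr_a=np.arange(61))
        assert ns.peak_readouts(traj).tnfr_a_max == 60.0

    def test_short_trajectory_rejected(self, intrinsic_cell):
        counts = np.zeros((10, len(ns.SPECIES)), dtype=np.int64)
        traj = ns.Trajectory(
            times=np.arange(10) * 0.5, counts=counts, cell=intrinsic_cell, dose=0.0, chx=False
        )
        with pytest.raises(ValueError):
            ns.peak_readouts(traj)


class TestNormalizeNFkB:
    def test_resting_cell_with_interference_reads_024(self):
        assert ns.normalize_nfkb(0, 10**5, 5 * 10**4, with_ci=True) == pytest.approx(0.24)

    def test_full_translocation_without_interference_reads_two_thirds(self):
        assert ns.normalize_nfkb(10**5, 0, 5 * 10**4, with_ci=False) == pytest.approx(2 / 3)

    def test_full_translocation_with_interference(self):
        expected = (1e5 + 0.24 * 5e4) / 1.5e5
        assert ns.normalize_nfkb(10**5, 0, 5 * 10**4, with_ci=True) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ns.normalize_nfkb(-1, 0, 0)


class TestRunDosePanel:
    def test_single_cell_panel_shapes(self, rates):
        panels = ns.run_dose_panel(
            doses=(0.0, 1.0), n_cells=1, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0),
            seed=0, rates=rates,
        )
        assert set(panels) == set(ns.READOUT_NODES)
        assert panels["nfkb_nuc_norm"].n_per_dose == (1, 1)

    def test_identical_seeds_give_identical_panels(self, rates):
        kwargs = dict(
            doses=(0.0, 0.3), n_cells=5, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.3),
            seed=11, rates=rates,
        )
        a = ns.run_dose_panel(**kwargs)
        b = ns.run_dose_panel(**kwargs)
        for node in ns.READOUT_NODES:
            for sa, sb in zip(a[node].samples, b[node].samples):
                assert (sa.values == sb.values).all()

    def test_response_saturates_above_one_ng(self, panels_sigma0):
        # KS between saturating doses is far below the KS across the
        # transition region
        p = panels_sigma0["nfkb_nuc_norm"]
        ks_1_10 = it.ks_distance(p.samples[5], p.samples[7]).ks
        ks_01_1 = it.ks_distance(p.samples[3], p.samples[5]).ks
        assert ks_1_10 < 0.5 * ks_01_1

    def test_saturating_dose_means_within_ten_percent(self, panels_sigma0):
        means = [s.values.mean() for s in panels_sigma0["nfkb_nuc_norm"].samples[5:]]
        assert (max(means) - min(means)) / np.mean(means) < 0.10

    def test_panel_frame_round_trip(self, rates):
        panels = ns.run_dose_panel(
            doses=(0.0, 1.0), n_cells=3, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0),
            seed=2, rates=rates,
        )
        df = ns.panel_frame(panels)
        assert len(df) == 6
        back = it.DosePanel.from_frame(
            df.rename(columns={"nfkb_nuc_norm": "readout"})[["dose", "readout"]]
        )
        assert back.n_per_dose == (3, 3)


def test_receptor_capacity_decreases_with_extrinsic_noise(
    panels_sigma0, panels_sigma03, panels_sigma1, panels_sigma3
):
    mis = [
        it.maximize_mi(p["tnfr_a"], seed=1).mi_bits
        for p in (panels_sigma0, panels_sigma03, panels_sigma1, panels_sigma3)
    ]
    assert all(a > b for a, b in zip(mis, mis[1:]))
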