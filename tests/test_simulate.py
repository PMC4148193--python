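"""Synthetic-data generators: isotherms, Brownian traces, correlator, contact maps."""

import numpy as np
import pytest

import insulator_bridge as ib
from insulator_bridge.errors import ConfigError, InputError

from conftest import direct_correlation


class TestGenIsotherm:
    def test_zero_noise_returns_exact_model_values(self):
        iso = ib.gen_isotherm(68.0, 3.0, 100.0, 32.0, sigma=0.0, seed=0)
        expected = ib.anisotropy_model(iso.protein_conc, 100.0, 32.0, 68.0, 3.0)
        np.testing.assert_allclose(iso.anisotropy, expected, rtol=1e-12)
        assert iso.sigma is None

    def test_same_seed_reproduces(self):
        a = ib.gen_isotherm(68.0, 3.0, 100.0, 32.0, sigma=1.5, seed=11)
        b = ib.gen_isotherm(68.0, 3.0, 100.0, 32.0, sigma=1.5, seed=11)
        np.testing.assert_array_equal(a.anisotropy, b.anisotropy)

    def test_replicate_mean_converges_to_model(self):
        n_rep = 1000
        reps = np.array([
            ib.gen_isotherm(68.0, 3.0, 100.0, 32.0, sigma=1.5, seed=s).anisotropy
            for s in range(n_rep)
        ])
        expected = ib.anisotropy_model(
            np.asarray(ib.simulate.DEFAULT_CONC_GRID), 100.0, 32.0, 68.0, 3.0)
        assert np.all(np.abs(reps.mean(axis=0) - expected) < 3 * 1.5 / np.sqrt(n_rep))

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            ib.gen_isotherm(68.0, 3.0, 100.0, 32.0, conc_grid=[], seed=0)


class TestBrownianTraces:
    def test_all_dark_molecules_give_zero_traces(self):
        cfg = ib.FccsSimConfig(seed=1, n_molecules=10, mix_fraction_green=1.0,
                               label_eff_green=0.0, duration=0.01)
        tr = ib.simulate_intensity_traces(cfg)
        assert tr.green.sum() == 0 and tr.red.sum() == 0
        assert tr.green.size == int(round(cfg.duration / cfg.dt))

    def test_immobile_particle_at_focus_is_poisson_at_brightness(self):
        cfg = ib.FccsSimConfig(
            seed=2, n_molecules=1, diffusion_coeff=0.0, mix_fraction_green=1.0,
            label_eff_green=1.0, duration=2.0, brightness=1.0e5,
            initial_positions=np.zeros((1, 3)),
        )
        tr = ib.simulate_intensity_traces(cfg)
        mean_rate = cfg.brightness * cfg.dt  # counts per frame at the focus
        n = tr.green.size
        assert abs(tr.green.mean() - mean_rate) < 4 * np.sqrt(mean_rate / n)
        # Poisson: variance equals the mean
        assert tr.green.var() / tr.green.mean() == pytest.approx(1.0, abs=0.05)

    def test_same_seed_reproduces(self):
        cfg = dict(seed=3, n_molecules=5, duration=0.05)
        a = ib.simulate_intensity_traces(ib.FccsSimConfig(**cfg))
        b = ib.simulate_intensity_traces(ib.FccsSimConfig(**cfg))
        np.testing.assert_array_equal(a.green, b.green)
        np.testing.assert_array_equal(a.red, b.red)

    def test_large_step_warns(self):
        cfg = ib.FccsSimConfig(seed=4, n_molecules=2, diffusion_coeff=300.0,
                               dt=1e-4, duration=0.01, mix_fraction_green=1.0,
                               label_eff_green=1.0)
        with pytest.warns(UserWarning, match="step exceeds"):
            ib.simulate_intensity_traces(cfg)

    @pytest.mark.parametrize("kwargs", [
        dict(n_molecules=0),
        dict(bridged_fraction=1.5),
        dict(structure_s=0.9),
        dict(dt=0.0),
    ])
    def test_config_validation(self, kwargs):
        with pytest.raises(ConfigError):
            ib.FccsSimConfig(seed=0, **kwargs)

    def test_crosstalk_creates_spurious_cross_correlation_removed_by_pie(self):
        """Spectral crosstalk fakes co-diffusion; ideal PIE separation removes it."""
        amps = {}
        for label, xt in (("pie", 0.0), ("crosstalk", 0.3)):
            cfg = ib.FccsSimConfig(seed=9, n_molecules=40, bridged_fraction=0.0,
                                   duration=8.0, crosstalk=xt)
            tr = ib.simulate_intensity_traces(cfg)
            cross = ib.correlate_traces(tr.green, tr.red, dt=cfg.dt, channel_pair="cross")
            auto = ib.correlate_traces(tr.green, tr.green, dt=cfg.dt,
                                       channel_pair="green_auto")
            amps[label] = ib.relative_cc_amplitude(cross, auto)
        assert amps["crosstalk"] > 5 * max(amps["pie"], 0.01)


class TestMultiTauCorrelator:
    def test_zero_lag_of_autocorrelation_is_variance_over_mean_squared(self):
        rng = np.random.default_rng(0)
        tr = rng.poisson(5.0, 4096).astype(float)
        curve = ib.correlate_traces(tr, tr, dt=1e-5, channel_pair="green_auto")
        assert curve.lag[0] == 0.0
        assert curve.g[0] == pytest.approx(tr.var() / tr.mean() ** 2, rel=1e-12)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(10.0, 100_000).astype(float)
        b = rng.poisson(10.0, 100_000).astype(float)
        curve = ib.correlate_traces(a, b, dt=1e-5)
        assert np.max(np.abs(curve.g)) < 0.01

    def test_matches_direct_correlation_at_level_zero_exactly(self):
        rng = np.random.default_rng(2)
        tr = 50.0 + rng.normal(0, 5, 5000)
        curve = ib.correlate_traces(tr, tr, dt=1.0, channel_pair="green_auto")
        for lag, g in zip(curve.lag[:16], curve.g[:16]):
            assert g == pytest.approx(direct_correlation(tr, tr, int(lag)), rel=1e-12)

    def test_zero_mean_trace_rejected(self):
        with pytest.raises(InputError):
            ib.correlate_traces(np.zeros(1000), np.zeros(1000), dt=1e-5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ib.correlate_traces(np.ones(100), np.ones(99), dt=1e-5)


class TestContactMapGenerator:
    def test_same_seed_gives_identical_tables_and_peaks(self):
        cfg = ib.HicSimConfig(seed=5, chrom_sizes={"chrS": 300_000}, n_beaf32=40,
                              n_cp190=60, n_chromator=60)
        t1, p1 = ib.gen_contact_map(cfg)
        t2, p2 = ib.gen_contact_map(cfg)
        assert t1.df.equals(t2.df)
        assert all(p1[k].intervals == p2[k].intervals for k in p1)

    def test_distance_decay_of_mean_counts(self):
        cfg = ib.HicSimConfig(seed=6, chrom_sizes={"chrS": 1_000_000},
                              enrichment=1.0, alpha=1.0, background=10.0)
        table, _ = ib.gen_contact_map(cfg)
        df = table.df
        d = (df["bin_j"] - df["bin_i"]) // table.bin_size
        # mean Poisson rate at distance k bins is background / k; compare two
        # distance slices (sparse table: zero rows dropped, so sum/n_bins)
        nb = 1_000_000 // 500
        for k in (20, 80):
            total = df.loc[d == k, "count"].sum()
            assert total / (nb - k) == pytest.approx(10.0 / k, rel=0.15)

    def test_enrichment_raises_cobound_pair_counts(self):
        cfg = ib.HicSimConfig(seed=7, enrichment=30.0)
        table, peaks = ib.gen_contact_map(cfg)
        targets = ib.factor_bound_sites(table, [peaks["CP190"], peaks["Chromator"]])
        pairs = ib.select_anchor_target_pairs(peaks["BEAF32"], targets)
        prof = ib.aggregate_profile(pairs, table)
        i0 = int(np.where(prof.offsets == 0)[0][0])
        off = prof.signal[np.arange(prof.offsets.size) != i0].mean()
        assert prof.signal[i0] > 10 * off

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            ib.HicSimConfig(seed=0, alpha=0.0)
        with pytest.raises(ConfigError):
            ib.HicSimConfig(seed=0, enrichment=0.5)
        with pytest.raises(ConfigError):
            ib.HicSimConfig(seed=0, max_dist=10_000)


class TestSimulatedAmplitude:
    def test_acf_amplitude_matches_effective_volume_occupancy(self, fcs_run):
        """G(0) ~ 1/<N> with N = C * V_eff, V_eff = pi^(3/2) w^3 s."""
        cfg, _, _, fit = fcs_run
        v_eff = np.pi ** 1.5 * cfg.waist_xy ** 3 * cfg.structure_s
        n_eff = cfg.n_molecules / cfg.box_size ** 3 * v_eff
        assert fit.g0_total == pytest.approx(1.0 / n_eff, rel=0.15)
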