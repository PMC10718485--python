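import math

import numpy as np
import pytest

from cartoptics.montecarlo import (
    LookupTable,
    SphereMeasurement,
    TransportConfig,
    build_lookup_table,
    invert_sphere,
    sample_hg_cosine,
    simulate_rt,
    specular_reflectance,
)
from cartoptics.spectra import SampleGeometry, Spectrum


def chandrasekhar_plane_albedo(albedo: float, n_gauss: int = 64) -> float:
    """Independent radiative-transfer oracle.

    Normal-incidence plane albedo of a semi-infinite isotropically
    scattering half-space with matched boundaries,
    R = 1 - sqrt(1 - w) * H(1), with the Chandrasekhar H-function solved
    by fixed-point iteration of
    H(mu) = 1 / (sqrt(1-w) + (w/2) Int_0^1 mu' H(mu') / (mu + mu') dmu').
    """
    x, wt = np.polynomial.legendre.leggauss(n_gauss)
    mu = 0.5 * (x + 1.0)
    wt = 0.5 * wt
    root = math.sqrt(1.0 - albedo)
    H = np.ones_like(mu)
    H1 = 1.0
    for _ in range(5000):
        integ = np.array([np.sum(wt * mu * H / (m + mu)) for m in mu])
        Hn = 1.0 / (root + 0.5 * albedo * integ)
        H1 = 1.0 / (root + 0.5 * albedo * np.sum(wt * mu * Hn / (1.0 + mu)))
        if np.max(np.abs(Hn - H)) < 1e-13:
            H = Hn
            break
        H = Hn
    return 1.0 - root * H1


class TestHGSampler:
    def test_isotropic_closed_form(self):
        assert sample_hg_cosine(0.0, 0.75) == pytest.approx(0.5)

    def test_anisotropic_closed_form(self):
        assert sample_hg_cosine(0.9, 0.5) == pytest.approx(0.98550, abs=1e-5)

    def test_mean_cosine_equals_g(self):
        rng = np.random.default_rng(7)
        u = rng.random(1_000_000)
        draws = sample_hg_cosine(0.9, u)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.9) < 3.0 * se

    def test_support_and_input_validation(self):
        u = np.linspace(0.0, 1.0, 1001)
        draws = sample_hg_cosine(0.7, u)
        assert np.all((draws >= -1.0) & (draws <= 1.0))
        with pytest.raises(ValueError):
            sample_hg_cosine(0.7, 1.5)


class TestTransportPhysics:
    def test_energy_conservation_no_absorption(self):
        cfg = TransportConfig(
            SampleGeometry(thickness=1.0, radius=50.0),
            n_sample=1.0, n_surround=1.0, g=0.9, photons=100_000, seed=1,
        )
        res = simulate_rt(0.0, 10.0, cfg)
        se = math.sqrt(2.0) * res.se(res.rd)
        assert res.rd + res.td + res.side_loss == pytest.approx(1.0, abs=1e-9)
        assert res.rd + res.td == pytest.approx(1.0, abs=max(3 * se, 1e-3))
        assert res.balance_deficit < 1e-6

    def test_ballistic_beer_lambert_limit(self):
        cfg = TransportConfig(
            SampleGeometry(thickness=1.0, radius=7.5),
            n_sample=1.0, n_surround=1.0, photons=100_000, seed=2,
        )
        res = simulate_rt(1.0, 0.0, cfg)
        expected = math.exp(-1.0)
        assert abs(res.td - expected) < 3.0 * res.se(expected)
        assert res.absorbed == pytest.approx(1.0 - expected, abs=3.0 * res.se(expected))

    def test_specular_fresnel_exact(self):
        cfg = TransportConfig(SampleGeometry(thickness=1.0), photons=1_000, seed=3)
        res = simulate_rt(0.5, 5.0, cfg)
        assert res.specular == pytest.approx((0.358 / 2.358) ** 2, abs=1e-12)
        assert specular_reflectance(1.0, 1.358) == pytest.approx(0.02305, abs=5e-6)

    def test_semi_infinite_albedo_matches_h_function(self):
        oracle = chandrasekhar_plane_albedo(0.9)
        cfg = TransportConfig(
            SampleGeometry(thickness=200.0, radius=1e4),
            n_sample=1.0, n_surround=1.0, g=0.0, photons=200_000, seed=5,
        )
        res = simulate_rt(1.0, 9.0, cfg)
        assert abs(res.rd - oracle) / oracle < 0.01

    def test_seeded_determinism_bit_for_bit(self):
        cfg = TransportConfig(SampleGeometry(thickness=1.0), photons=5_000, seed=9)
        r1 = simulate_rt(0.1, 20.0, cfg)
        r2 = simulate_rt(0.1, 20.0, cfg)
        assert (r1.rd, r1.td, r1.absorbed) == (r2.rd, r2.td, r2.absorbed)

    def test_energy_bookkeeping_with_mismatched_index(self):
        cfg = TransportConfig(SampleGeometry(thickness=2.0), photons=20_000, seed=4)
        res = simulate_rt(0.05, 25.0, cfg)
        assert res.balance_deficit < 1e-6
        assert 0 < res.rd < 1 and 0 < res.td < 1

    def test_config_validation(self):
        geom = SampleGeometry(thickness=1.0)
        with pytest.raises(ValueError):
            TransportConfig(geom, photons=100)
        with pytest.raises(ValueError):
            TransportConfig(geom, g=1.0)
        with pytest.raises(ValueError):
            simulate_rt(-0.1, 1.0, TransportConfig(geom))


class TestLookupTable:
    def test_small_build_shapes_and_range(self, bulk_transport_config):
        cfg = TransportConfig(
            bulk_transport_config.geometry, photons=2_000, seed=20
        )
        lut = build_lookup_table(cfg, nodes=(3, 4))
        assert lut.Rd_table.shape == (3, 4)
        assert np.all((lut.Rd_table >= 0) & (lut.Rd_table <= 1))
        assert np.all((lut.Td_table >= 0) & (lut.Td_table <= 1))
        # Rd grows with scattering, Td falls with absorption
        assert lut.Rd_table[0, -1] > lut.Rd_table[0, 0]
        assert lut.Td_table[-1, 0] < lut.Td_table[0, 0]

    def test_save_load_round_trip(self, tmp_path, bulk_transport_config):
        cfg = TransportConfig(bulk_transport_config.geometry, photons=2_000, seed=21)
        lut = build_lookup_table(cfg, nodes=(3, 3))
        p = tmp_path / "lut.json"
        lut.save(p)
        lut2 = LookupTable.load(p)
        assert np.array_equal(lut.Rd_table, lut2.Rd_table)
        assert lut.config_fingerprint == lut2.config_fingerprint

    def test_fingerprint_mismatch_rejected(self, bulk_transport_config):
        cfg = TransportConfig(bulk_transport_config.geometry, photons=2_000, seed=22)
        lut = build_lookup_table(cfg, nodes=(3, 3))
        other = TransportConfig(SampleGeometry(thickness=1.0), photons=2_000)
        wl = np.array([700.0])
        meas = SphereMeasurement(
            Rd=Spectrum(wl, [0.3]), Td=Spectrum(wl, [0.3]),
            geometry=other.geometry,
        )
        with pytest.raises(ValueError, match="fingerprint"):
            invert_sphere(meas, lut, other)

    def test_measurement_energy_invariant_guard(self, bulk_geometry):
        wl = np.array([700.0])
        with pytest.raises(ValueError, match="exceed 1"):
            SphereMeasurement(
                Rd=Spectrum(wl, [0.6]), Td=Spectrum(wl, [0.6]),
                geometry=bulk_geometry,
            )


class TestInversionClosure:
    def test_exact_node_returns_node_properties(self, bulk_lut, bulk_transport_config):
        i, j = 12, 14
        wl = np.array([700.0])
        meas = SphereMeasurement(
            Rd=Spectrum(wl, [bulk_lut.Rd_table[i, j]]),
            Td=Spectrum(wl, [bulk_lut.Td_table[i, j]]),
            geometry=bulk_transport_config.geometry,
        )
        est = invert_sphere(meas, bulk_lut, bulk_transport_config)
        assert est.musp.values[0] == pytest.approx(bulk_lut.musp_grid[j], rel=0.02)
        assert est.mua.values[0] == pytest.approx(bulk_lut.mua_grid[i], rel=0.05)

    def test_forward_inverse_round_trip_bulk_regime(
        self, bulk_lut, bulk_transport_config
    ):
        """Recover literature-scale bulk properties from simulated (Rd, Td)."""
        targets = [(0.05, 2.5), (0.02, 3.45)]
        wl = np.array([600.0, 900.0])
        rd, td = [], []
        g = bulk_transport_config.g
        for k, (mua, musp) in enumerate(targets):
            cfg = TransportConfig(
                bulk_transport_config.geometry, photons=100_000, seed=100 + k
            )
            res = simulate_rt(mua, musp / (1.0 - g), cfg)
            rd.append(res.rd)
            td.append(res.td)
        meas = SphereMeasurement(
            Rd=Spectrum(wl, rd), Td=Spectrum(wl, td),
            geometry=bulk_transport_config.geometry,
        )
        est = invert_sphere(meas, bulk_lut, bulk_transport_config)
        for k, (mua, musp) in enumerate(targets):
            assert abs(est.musp.values[k] - musp) / musp < 0.05
            assert abs(est.mua.values[k] - mua) / mua < 0.10
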