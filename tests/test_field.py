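"""Wave-vector sampling and field construction."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from leveledwaves.field import (
    ComplexWaveField, DynamicsSpec, PartialWaveSet, WaveModelParams,
    WaveVectorDistribution, build_plane_wave_field,
    build_spherical_wave_field, evolve_field, layer_normal_order,
    sample_polar_cosines, sample_wavevectors, waves_for)

from conftest import make_params


def fisher_mean_by_quadrature(gamma: float) -> float:
    """Independent oracle: <cos theta> by numerical quadrature of the
    Fisher density on [-1, 1]."""
    if gamma == 0.0:
        return 0.0
    num = integrate.quad(lambda u: u * np.exp(gamma * (u - 1.0)), -1, 1)[0]
    den = integrate.quad(lambda u: np.exp(gamma * (u - 1.0)), -1, 1)[0]
    return num / den


class TestFisherSampling:
    def test_norm_constant_integrates_to_one(self):
        for gamma in (0.0, 0.5, 4.0, 32.0, 128.0):
            dist = WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=gamma)
            # c * exp(gamma cos th), evaluated as (c e^gamma) e^{gamma(cos-1)}
            # so large gamma stays finite
            scaled_norm = dist.fisher_norm * math.exp(gamma) if gamma < 500 \
                else gamma / (1.0 - math.exp(-2.0 * gamma))
            val = integrate.quad(
                lambda th: scaled_norm
                * math.exp(gamma * (math.cos(th) - 1.0)) * math.sin(th),
                0.0, math.pi, limit=200)[0]
            assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("gamma", [0.5, 4.0, 32.0, 128.0])
    def test_mean_cosine_matches_langevin(self, gamma, rng):
        """Sample mean of cos(theta) equals coth(G) - 1/G within 3 MC
        standard errors (and the quadrature oracle agrees)."""
        n = 100_000
        u = sample_polar_cosines(
            WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=gamma), n, rng)
        langevin = 1.0 / math.tanh(gamma) - 1.0 / gamma
        assert fisher_mean_by_quadrature(gamma) == pytest.approx(
            langevin, abs=1e-9)
        se = u.std(ddof=1) / math.sqrt(n)
        assert abs(u.mean() - langevin) < 3.0 * se

    def test_frozen_quadrature_values(self, rng):
        """Gamma=4 -> 0.7507, Gamma=128 -> 0.9922 (Langevin limits)."""
        n = 100_000
        u4 = sample_polar_cosines(
            WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=4.0), n, rng)
        assert u4.mean() == pytest.approx(0.7507, abs=0.005)
        u128 = sample_polar_cosines(
            WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=128.0), n, rng)
        assert u128.mean() == pytest.approx(1.0 - 1.0 / 128.0, abs=0.001)

    def test_isotropic_limit(self, rng):
        u = sample_polar_cosines(
            WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=0.0),
            100_000, rng)
        assert abs(u.mean()) < 0.01
        assert u.min() >= -1.0 and u.max() <= 1.0

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=-1.0)


class TestWaveVectorSampling:
    def test_magnitude_dispersion(self, rng):
        dist = WaveVectorDistribution(k0=2.0, sigma_k=0.05, gamma=0.0)
        ws = sample_wavevectors(dist, 100_000, rng)
        mags = np.linalg.norm(ws.wavevectors, axis=1)
        assert (mags / 2.0).std(ddof=1) == pytest.approx(0.05, abs=0.002)
        assert np.all(mags > 0)

    def test_truncation_keeps_magnitudes_positive(self, rng):
        dist = WaveVectorDistribution(k0=1.0, sigma_k=0.5, gamma=0.0)
        ws = sample_wavevectors(dist, 50_000, rng)
        assert np.all(np.linalg.norm(ws.wavevectors, axis=1) > 0)
        assert 0.9 < ws.acceptance_rate <= 1.0   # ~2.3% of N(1, 0.5) < 0

    def test_aligned_deterministic_limit(self, rng):
        dist = WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=1e6)
        ws = sample_wavevectors(dist, 1000, rng)
        units = ws.wavevectors / np.linalg.norm(ws.wavevectors, axis=1,
                                               keepdims=True)
        dev = np.linalg.norm(units - np.array([0.0, 0.0, 1.0]), axis=1)
        assert dev.max() < 1e-2

    def test_azimuth_uniform(self, rng):
        dist = WaveVectorDistribution(k0=1.0, sigma_k=0.0, gamma=0.0)
        ws = sample_wavevectors(dist, 100_000, rng)
        az = np.mod(np.arctan2(ws.wavevectors[:, 1], ws.wavevectors[:, 0]),
                    2 * np.pi)
        res = stats.kstest(az / (2 * np.pi), "uniform")
        # 1% critical value of the KS statistic ~ 1.63 / sqrt(n)
        assert res.statistic < 1.63 / math.sqrt(az.size)

    def test_phases_in_range(self, rng):
        ws = sample_wavevectors(
            WaveVectorDistribution(k0=1.0, sigma_k=0.1, gamma=2.0), 500, rng)
        assert np.all((ws.phases >= 0) & (ws.phases < 2 * np.pi))


class TestPlaneWaveField:
    def test_single_wave_is_cosine(self):
        p = make_params(sigma_k=0.0, gamma=1.0, n_waves=1, grid_n=32)
        k0 = p.dist.k0
        waves = PartialWaveSet(
            wavevectors=np.array([[0.0, 0.0, k0]]), phases=np.array([0.0]))
        fld = build_plane_wave_field(p, waves)
        z = (np.arange(32) + 0.5) * p.spacing
        expected = math.sqrt(2.0) * np.cos(k0 * z)
        assert np.allclose(fld.values.real[0, 0, :], expected, atol=1e-12)

    def test_unit_variance_is_ensemble_property(self):
        """Mean sample variance of Re S over realizations is 1 +- 0.05
        (a single high-Gamma box fluctuates because the correlation
        volume is comparable to the box)."""
        vs = []
        for seed in range(60):
            p = make_params(sigma_k=0.05, gamma=128.0, n_waves=500,
                            seed=seed)
            f = build_plane_wave_field(p, waves_for(p), dtype=np.complex64)
            vs.append(np.var(f.values.real))
        assert np.mean(vs) == pytest.approx(1.0, abs=0.05)

    def test_variance_tight_for_short_correlations(self):
        vs = []
        for seed in range(8):
            p = make_params(sigma_k=0.05, gamma=4.0, n_waves=500, seed=seed)
            f = build_plane_wave_field(p, waves_for(p), dtype=np.complex64)
            vs.append(np.var(f.values.real))
        assert np.mean(vs) == pytest.approx(1.0, abs=0.05)

    def test_seed_determinism(self):
        p = make_params(seed=11, grid_n=32, n_waves=200)
        f1 = build_plane_wave_field(p, waves_for(p))
        f2 = build_plane_wave_field(p, waves_for(p))
        assert np.array_equal(f1.values, f2.values)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError, match="too coarse"):
            p = make_params(grid_n=32, box_factor=32, n_waves=10)
            build_plane_wave_field(p, waves_for(p))

    def test_layer_normal_order_increases_with_gamma(self):
        p_hi = make_params(gamma=128.0, seed=1)
        p_lo = make_params(gamma=1.0, seed=1)
        s_hi = layer_normal_order(
            build_plane_wave_field(p_hi, waves_for(p_hi),
                                   dtype=np.complex64))
        s_lo = layer_normal_order(
            build_plane_wave_field(p_lo, waves_for(p_lo),
                                   dtype=np.complex64))
        assert s_hi > 0.8
        assert s_lo < 0.3


class TestSphericalWaveField:
    def test_single_wave_phase_is_radial(self):
        p = make_params(sigma_k=0.0, gamma=1.0, n_waves=1, grid_n=32)
        k0 = p.dist.k0
        center = 0.5 * p.box_edge
        waves = PartialWaveSet(
            wavevectors=np.array([[0.0, 0.0, k0]]), phases=np.array([0.0]),
            origins=np.array([[center, center, center]]))
        fld = build_spherical_wave_field(p, waves, origin_spread=0.0)
        x = (np.arange(32) + 0.5) * p.spacing
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        radius = np.sqrt((X - center) ** 2 + (Y - center) ** 2
                         + (Z - center) ** 2)
        phase = np.angle(fld.values)
        expected = np.angle(np.exp(1j * k0 * radius))
        assert np.allclose(np.angle(np.exp(1j * (phase - expected))), 0.0,
                           atol=1e-8)

    def test_zero_spread_is_spherically_symmetric(self):
        p = make_params(sigma_k=0.0, gamma=0.0, n_waves=50, grid_n=48,
                        seed=5)
        fld = build_spherical_wave_field(p, waves_for(p), origin_spread=0.0)
        center = 0.5 * p.box_edge
        x = (np.arange(48) + 0.5) * p.spacing
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt((X - center) ** 2 + (Y - center) ** 2 + (Z - center) ** 2)
        mag = np.abs(fld.values)
        # |S| must depend on radius only: tiny scatter within radial bins
        bins = np.clip((r / p.spacing).astype(int), 0, 23)
        spread = 0.0
        for b in range(4, 20):
            sel = bins == b
            if sel.sum() > 10:
                spread = max(spread, mag[sel].std() / max(mag[sel].mean(),
                                                          1e-12))
        assert spread < 0.05

    def test_onion_shells_alternate(self):
        """Clipped spherical-wave field shows concentric shells: the
        angular average of rho alternates >= 3 times along the radius."""
        from leveledwaves.scattering import clip_to_sld
        p = make_params(sigma_k=0.02, gamma=0.0, n_waves=100, grid_n=64,
                        seed=6)
        fld = build_spherical_wave_field(p, waves_for(p),
                                         origin_spread=p.d)
        sld = clip_to_sld(fld, 0.3)
        center = 0.5 * p.box_edge
        x = (np.arange(64) + 0.5) * p.spacing
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt((X - center) ** 2 + (Y - center) ** 2 + (Z - center) ** 2)
        bins = (r / (p.spacing * 2)).astype(int)
        prof = np.array([sld.values[bins == b].mean()
                         for b in range(16) if (bins == b).sum() > 0])
        centered = prof - prof.mean()
        alternations = int(np.sum(np.abs(np.diff(np.sign(centered))) > 0))
        assert alternations >= 3

    def test_negative_spread_rejected(self):
        p = make_params(n_waves=10, grid_n=32)
        with pytest.raises(ValueError):
            build_spherical_wave_field(p, waves_for(p), origin_spread=-1.0)


class TestEvolveField:
    def test_zero_time_identity(self):
        p = make_params(grid_n=32, n_waves=100, seed=2)
        waves = waves_for(p)
        static = build_plane_wave_field(p, waves)
        frames = evolve_field(p, waves,
                              DynamicsSpec(omega0=1.0, sigma_omega=0.2,
                                           times=(0.0, 1.0)))
        assert np.array_equal(frames[0].values, static.values)

    def test_common_rate_is_global_phase(self):
        p = make_params(grid_n=32, n_waves=100, seed=2)
        frames = evolve_field(p, waves_for(p),
                              DynamicsSpec(omega0=0.7, sigma_omega=0.0,
                                           times=(0.0, 0.5, 1.5)))
        mag0 = np.abs(frames[0].values)
        for f in frames[1:]:
            assert np.max(np.abs(np.abs(f.values) - mag0)) < 1e-10

    def test_variance_time_invariant(self):
        p = make_params(gamma=4.0, grid_n=48, n_waves=500, seed=9)
        frames = evolve_field(p, waves_for(p),
                              DynamicsSpec(omega0=1.0, sigma_omega=0.5,
                                           times=(0.0, 2.0, 7.0)))
        for f in frames:
            assert np.var(f.values.real) == pytest.approx(1.0, abs=0.05)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            DynamicsSpec(omega0=1.0, sigma_omega=0.1, times=())


class TestContainers:
    def test_partial_wave_set_length_mismatch(self):
        with pytest.raises(ValueError):
            PartialWaveSet(wavevectors=np.zeros((3, 3)),
                           phases=np.zeros(2))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            make_params(alpha=1.2)
        with pytest.raises(ValueError):
            make_params(grid_n=16)
        with pytest.raises(ValueError):
            make_params(box_factor=2)
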