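"""MSD estimation, GSER inversion and per-bead viscosity distributions."""

import numpy as np
import pytest
from scipy.constants import Boltzmann as K_B

from mucorheo.errors import InvalidInputError
from mucorheo.microrheology import (
    GserConfig,
    MSDCurve,
    ViscoelasticSpectrum,
    eta_star_at,
    gser_spectrum,
    local_loglog_slope,
    msd_ensemble,
    msd_track,
    per_bead_eta_distribution,
    static_error_correction,
    subsample_loglog,
)
from mucorheo.synthetic_data import (
    FluidModel,
    TrajectoryParams,
    simulate_fbm_tracks,
    simulate_population_mixture,
)


def _brute_force_msd(xy, dt, max_lag_fraction=1 / 3):
    """Independent double-loop oracle for the overlapping-pair estimator."""
    n = len(xy)
    out = []
    for k in range(1, max(int((n - 1) * max_lag_fraction), 1) + 1):
        acc, cnt = 0.0, 0
        for i in range(n - k):
            d = xy[i + k] - xy[i]
            acc += d @ d
            cnt += 1
        out.append((k * dt, acc / cnt, cnt))
    return out


class TestMsdTrack:
    def test_single_pair(self):
        frames = np.array([0, 1])
        xy = np.array([[0.0, 0.0], [3.0, 4.0]])
        c = msd_track(frames, xy, 0.5, max_lag_fraction=1.0)
        assert c.lags[0] == 0.5
        assert c.msd[0] == 25.0
        assert c.n_pairs[0] == 1

    def test_ballistic_track_quadratic(self):
        frames = np.arange(100)
        t = frames / 60
        xy = np.column_stack([2.0 * t, np.zeros_like(t)])
        c = msd_track(frames, xy, 1 / 60)
        assert np.allclose(c.msd, (2.0 * c.lags) ** 2, rtol=1e-12)
        assert np.allclose(local_loglog_slope(c), 1.0)  # clipped from 2

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized estimator equals the double loop exactly at n <= 100."""
        for n in (10, 37, 100):
            xy = np.cumsum(rng.normal(0, 0.1, (n, 2)), axis=0)
            frames = np.arange(n)
            c = msd_track(frames, xy, 1 / 60)
            oracle = _brute_force_msd(xy, 1 / 60)
            assert len(c.lags) == len(oracle)
            for (lag, msd, cnt), got_l, got_m, got_n in zip(
                oracle, c.lags, c.msd, c.n_pairs
            ):
                assert got_l == pytest.approx(lag)
                assert got_m == pytest.approx(msd, rel=1e-12)
                assert got_n == cnt

    def test_gap_frames_excluded_from_pairs(self):
        frames = np.array([0, 1, 3, 4])
        xy = np.array([[0.0, 0], [1.0, 0], [3.0, 0], [4.0, 0]])
        c = msd_track(frames, xy, 1.0, max_lag_fraction=0.5)
        # lag 1: pairs (0,1), (3,4) only; lag 2: (1,3) only
        assert c.n_pairs[0] == 2 and c.msd[0] == 1.0
        assert c.n_pairs[1] == 1 and c.msd[1] == 4.0

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            msd_track(np.array([0]), np.zeros((1, 2)), 1.0)


class TestMsdEnsemble:
    def test_single_curve_identity(self):
        c = MSDCurve([0.1, 0.2], [1.0, 2.0], [5, 3])
        e = msd_ensemble([c])
        assert np.allclose(e.msd, c.msd)

    def test_two_identical_curves_double_pairs(self):
        c = MSDCurve([0.1, 0.2], [1.0, 2.0], [5, 3])
        e = msd_ensemble([c, c])
        assert np.allclose(e.msd, c.msd)
        assert np.array_equal(e.n_pairs, [10, 6])

    def test_pair_weighted_mean(self):
        a = MSDCurve([0.1], [1.0], [4])
        b = MSDCurve([0.1], [3.0], [4])
        assert msd_ensemble([a, b]).msd[0] == pytest.approx(2.0)

    def test_incompatible_grids_rejected(self):
        a = MSDCurve([0.1], [1.0], [1])
        b = MSDCurve([0.15], [1.0], [1])
        with pytest.raises(InvalidInputError):
            msd_ensemble([a, b])


class TestStaticErrorCorrection:
    def test_zero_sigma_identity(self):
        c = MSDCurve([0.1, 0.2], [1.0, 2.0], [1, 1])
        out = static_error_correction(c, 0.0)
        assert np.allclose(out.msd, c.msd)

    def test_pure_noise_floored_with_warning(self):
        sigma = 0.02
        c = MSDCurve([0.1, 0.2], [4 * sigma**2] * 2, [1, 1])
        with pytest.warns(UserWarning, match="noise-dominated"):
            out = static_error_correction(c, sigma)
        assert np.all(out.msd > 0)
        assert np.all(out.msd <= 1e-12)

    def test_removes_known_offset(self, critical_gel):
        p = TrajectoryParams(n_beads=150, n_frames=300, localization_sigma_um=0.03)
        ts = simulate_fbm_tracks(critical_gel, p, seed=13)
        curves = [
            msd_track(f, xy, ts.frame_interval_s, max_lag_fraction=0.1)
            for _, f, xy in ts.iter_tracks()
        ]
        ens = static_error_correction(msd_ensemble(curves), 0.03)
        truth = critical_gel.msd2d_um2(ens.lags)
        assert np.abs(ens.msd / truth - 1).max() < 0.05


class TestLocalSlope:
    def test_linear_msd_slope_one(self):
        lags = np.geomspace(0.01, 1, 20)
        c = MSDCurve(lags, 4 * 0.4 * lags, np.ones(20))
        assert np.allclose(local_loglog_slope(c), 1.0, atol=1e-10)

    def test_half_power(self):
        lags = np.geomspace(0.01, 1, 20)
        c = MSDCurve(lags, 2.5 * lags**0.5, np.ones(20))
        assert np.allclose(local_loglog_slope(c), 0.5, atol=1e-10)

    def test_constant_msd_slope_zero(self):
        lags = np.geomspace(0.01, 1, 10)
        c = MSDCurve(lags, np.full(10, 0.3), np.ones(10))
        assert np.allclose(local_loglog_slope(c), 0.0, atol=1e-12)


class TestGser:
    def test_viscous_limit_recovers_eta(self):
        """Analytic Brownian MSD inverts to a flat |eta*| = 1 mPa s."""
        eta, a, T = 1e-3, 0.5e-6, 298.15
        d_um2 = K_B * T / (6 * np.pi * eta * a) * 1e12
        lags = np.geomspace(0.02, 2.0, 25)
        curve = MSDCurve(lags, 4 * d_um2 * lags, np.ones(25))
        spec = gser_spectrum(curve, GserConfig())
        assert np.allclose(spec.eta_star_mag, eta, rtol=1e-6)

    def test_elastic_plateau(self):
        m0 = 1e-3  # um^2
        lags = np.geomspace(0.01, 1, 15)
        curve = MSDCurve(lags, np.full(15, m0), np.ones(15))
        spec = gser_spectrum(curve, GserConfig())
        g_expected = 2 * K_B * 298.15 / (3 * np.pi * 0.5e-6 * m0 * 1e-12)
        assert np.allclose(spec.g_prime, g_expected, rtol=1e-9)
        assert np.allclose(spec.g_dprime, 0.0, atol=1e-9 * g_expected)
        assert np.allclose(spec.tan_delta, 0.0, atol=1e-12)

    def test_critical_gel_tan_delta_flat(self, critical_gel):
        lags = np.geomspace(0.02, 2.0, 25)
        curve = MSDCurve(lags, critical_gel.msd2d_um2(lags), np.ones(25))
        spec = gser_spectrum(curve, GserConfig())
        assert np.allclose(spec.tan_delta, 0.300, atol=0.001)
        assert eta_star_at(spec, 1.0) == pytest.approx(critical_gel.eta_1hz, rel=1e-6)

    def test_spectrum_consistency_identities(self, critical_gel):
        lags = np.geomspace(0.02, 2.0, 25)
        curve = MSDCurve(lags, critical_gel.msd2d_um2(lags), np.ones(25))
        spec = gser_spectrum(curve, GserConfig())
        assert np.allclose(
            spec.g_star_mag**2, spec.g_prime**2 + spec.g_dprime**2, rtol=1e-9
        )
        assert np.allclose(spec.eta_star_mag * spec.omega, spec.g_star_mag, rtol=1e-12)

    def test_msd_scaling_inverts_eta(self, critical_gel):
        lags = np.geomspace(0.02, 2.0, 25)
        base = MSDCurve(lags, critical_gel.msd2d_um2(lags), np.ones(25))
        scaled = MSDCurve(lags, 3.0 * base.msd, np.ones(25))
        s_base = gser_spectrum(base, GserConfig())
        s_scaled = gser_spectrum(scaled, GserConfig())
        assert np.allclose(s_scaled.eta_star_mag, s_base.eta_star_mag / 3.0, rtol=1e-12)

    def test_zero_msd_rejected(self):
        c = MSDCurve([0.1, 0.2, 0.3], [0.0, 1.0, 2.0], [1, 1, 1])
        with pytest.raises(InvalidInputError, match="static_error_correction"):
            gser_spectrum(c, GserConfig())

    def test_parameter_recovery_across_alphas(self):
        """Simulated gels at alpha in {0.2, 0.5, 0.8}: alpha within 0.05,
        |eta*|(1 Hz) within 15%."""
        for alpha in (0.2, 0.5, 0.8):
            fluid = FluidModel(alpha=alpha, eta_1hz=0.05)
            p = TrajectoryParams(n_beads=100, n_frames=400, localization_sigma_um=0.01)
            ts = simulate_fbm_tracks(fluid, p, seed=int(alpha * 100))
            curves = [
                msd_track(f, xy, ts.frame_interval_s) for _, f, xy in ts.iter_tracks()
            ]
            ens = subsample_loglog(msd_ensemble(curves))
            ens = static_error_correction(ens, 0.01)
            spec = gser_spectrum(ens, GserConfig())
            assert eta_star_at(spec, 1.0) == pytest.approx(0.05, rel=0.15)
            mid_alpha = np.median(ens.alpha_local[1:-1])
            assert mid_alpha == pytest.approx(alpha, abs=0.05)


class TestEtaStarAt:
    def test_no_extrapolation(self, critical_gel):
        lags = np.geomspace(0.1, 1.0, 10)
        spec = gser_spectrum(
            MSDCurve(lags, critical_gel.msd2d_um2(lags), np.ones(10)), GserConfig()
        )
        with pytest.raises(InvalidInputError, match="extrapolate"):
            eta_star_at(spec, 100.0)

    def test_rad_convention(self):
        spec = ViscoelasticSpectrum(
            np.array([0.5, 1.0, 2.0]), np.array([0.0, 0.0, 0.0]), np.array([0.5, 1.0, 2.0])
        )
        # Newtonian: G'' = eta * omega with eta = 1
        assert eta_star_at(spec, 1.0, convention="rad") == pytest.approx(1.0)


class TestPerBeadDistribution:
    def test_single_fluid_unimodal(self, gel_tracks, critical_gel):
        cfg = GserConfig(static_error_sigma_um=0.02)
        d = per_bead_eta_distribution(gel_tracks, cfg, 1.0)
        assert d.bimodal is False
        assert d.median == pytest.approx(critical_gel.eta_1hz, rel=0.2)
        assert d.q25 <= d.median <= d.q75

    def test_bimodal_mixture_detected(self, critical_gel):
        lo = FluidModel(alpha=critical_gel.alpha, eta_1hz=critical_gel.eta_1hz / 10**0.5)
        hi = FluidModel(alpha=critical_gel.alpha, eta_1hz=critical_gel.eta_1hz * 10**0.5)
        p = TrajectoryParams(
            n_beads=150,
            n_frames=600,
            localization_sigma_um=0.02,
            mixture=((0.5, lo), (0.5, hi)),
        )
        ts = simulate_population_mixture(p, seed=11)
        cfg = GserConfig(static_error_sigma_um=0.02)
        d = per_bead_eta_distribution(ts, cfg, 1.0)
        assert d.bimodal is True
        assert d.separation_decades == pytest.approx(1.0, abs=0.2)
        lo_mean, hi_mean = d.mixture_means_log10
        assert lo_mean <= np.log10(d.median) <= hi_mean

    def test_few_beads_mixture_fit_refused(self, critical_gel):
        p = TrajectoryParams(n_beads=5, n_frames=200, localization_sigma_um=0.0)
        ts = simulate_fbm_tracks(critical_gel, p, seed=2)
        d = per_bead_eta_distribution(ts, GserConfig(), 1.0)
        assert d.bimodal is None
        assert d.mixture_weights is None
        assert len(d.values) == 5
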