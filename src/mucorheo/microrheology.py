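"""Passive microrheology: MSD estimation and the generalized Stokes-Einstein relation.

Thermal motion of embedded tracer beads is summarized as a time-averaged
mean squared displacement (MSD) per bead, ensemble-averaged across beads,
and converted to the complex shear modulus via Mason's local power-law
form of the generalized Stokes-Einstein relation (GSER):

    |G*(omega)| = 2 k_B T / (3 pi a MSD_2D(1/omega) Gamma[1 + alpha(1/omega)])

with G' = |G*| cos(pi alpha / 2), G'' = |G*| sin(pi alpha / 2) and
|eta*| = |G*| / omega.  MSD here follows the 2-D convention (sum of the
two tracked coordinates); the 2/(3 pi) prefactor already contains the 3/2
dimensional conversion from 2-D MSD to the 3-D form of the relation.
alpha(tau) is the local log-log slope d ln MSD / d ln tau.

Frequencies: the lag-to-frequency map is omega = 1/tau (Mason
convention).  Queries in Hz use omega = 2 pi f by default; the
``convention`` argument of :func:`eta_star_at` exposes the alternative
omega = f reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.special import gamma as gamma_fn

from mucorheo.errors import InvalidInputError
from mucorheo.trajectories import TrajectorySet

__all__ = [
    "GserConfig",
    "MSDCurve",
    "ViscoelasticSpectrum",
    "EtaDistribution",
    "msd_track",
    "msd_ensemble",
    "subsample_loglog",
    "static_error_correction",
    "local_loglog_slope",
    "gser_spectrum",
    "eta_star_at",
    "per_bead_eta_distribution",
]


@dataclass(frozen=True)
class GserConfig:
    """Physical constants of the GSER conversion.

    temperature in K, bead radius in um.  ``static_error_sigma_um``, when
    set, is the per-axis localization noise removed from MSDs before
    inversion (the standard +4 sigma^2 offset).
    """

    temperature_k: float = 298.15
    bead_radius_um: float = 0.5
    static_error_sigma_um: float | None = None

    def __post_init__(self):
        if self.temperature_k <= 0 or self.bead_radius_um <= 0:
            raise InvalidInputError("temperature and bead radius must be > 0")


@dataclass
class MSDCurve:
    """Time-averaged MSD vs lag, with pair counts.

    lags in seconds (strictly increasing), msd in um^2 (2-D convention),
    n_pairs the number of displacement pairs entering each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        self.n_pairs = np.asarray(self.n_pairs)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise InvalidInputError("lags, msd, n_pairs must be equal length")
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise InvalidInputError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise InvalidInputError("msd must be >= 0")

    @property
    def alpha_local(self) -> np.ndarray:
        return local_loglog_slope(self)


@dataclass
class ViscoelasticSpectrum:
    """G', G'', |G*|, tan delta and |eta*| on an omega grid (rad/s)."""

    omega: np.ndarray
    g_prime: np.ndarray
    g_dprime: np.ndarray

    @property
    def g_star_mag(self) -> np.ndarray:
        return np.hypot(self.g_prime, self.g_dprime)

    @property
    def tan_delta(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.g_prime > 0, self.g_dprime / self.g_prime, np.inf)

    @property
    def eta_star_mag(self) -> np.ndarray:
        return self.g_star_mag / self.omega


@dataclass
class EtaDistribution:
    """Per-bead |eta*| at one frequency, with summary and bimodality call.

    The mixture fit is a 2-component Gaussian EM on log10 eta with
    deterministic quartile initialization; ``bimodal`` requires minor
    weight >= 0.2 and mode separation >= 0.5 decades.
    """

    f_hz: float
    values: np.ndarray  # per-bead |eta*|, Pa s
    track_ids: list
    median: float
    q25: float
    q75: float
    mixture_weights: tuple | None = None
    mixture_means_log10: tuple | None = None
    mixture_sigmas_log10: tuple | None = None
    separation_decades: float | None = None
    bimodal: bool | None = None


def msd_track(
    frames: np.ndarray,
    xy_um: np.ndarray,
    frame_interval_s: float,
    max_lag_fraction: float = 1 / 3,
) -> MSDCurve:
    """Time-averaged overlapping-pair MSD of one track.

    MSD(k dt) = mean over i of |r(i+k) - r(i)|^2, for integer frame lags k
    up to ``max_lag_fraction`` of the track duration.  Gap frames (from
    linking memory) are handled by placing positions on the full frame
    grid and ignoring pairs touching a gap.
    """
    frames = np.asarray(frames, int)
    xy = np.asarray(xy_um, float)
    if len(frames) < 2:
        raise InvalidInputError("track must have at least 2 frames")
    f0, f1 = frames.min(), frames.max()
    n = f1 - f0 + 1
    grid = np.full((n, 2), np.nan)
    grid[frames - f0] = xy
    max_k = max(int((n - 1) * max_lag_fraction), 1)
    lags, msds, counts = [], [], []
    for k in range(1, max_k + 1):
        d = grid[k:] - grid[:-k]
        sq = np.einsum("ij,ij->i", d, d)
        good = ~np.isnan(sq)
        cnt = int(good.sum())
        if cnt == 0:
            continue
        lags.append(k * frame_interval_s)
        msds.append(float(sq[good].mean()))
        counts.append(cnt)
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts))


def msd_ensemble(curves: list[MSDCurve]) -> MSDCurve:
    """Pair-count-weighted ensemble MSD over a shared lag grid.

    All curves must be built on a common frame interval; per lag, the
    weighted mean over every curve containing that lag is taken and pair
    counts are summed.  No interpolation is performed.
    """
    if not curves:
        raise InvalidInputError("need at least one MSD curve")
    all_lags = np.concatenate([c.lags for c in curves])
    base = all_lags.min()
    ratios = all_lags / base
    if np.any(np.abs(ratios - np.round(ratios)) > 1e-9):
        raise InvalidInputError("curves do not share a common lag grid")
    acc: dict[int, tuple[float, float]] = {}
    for c in curves:
        for lag, m, np_ in zip(c.lags, c.msd, c.n_pairs):
            key = int(round(lag / base))
            s, w = acc.get(key, (0.0, 0.0))
            acc[key] = (s + m * np_, w + np_)
    keys = sorted(acc)
    lags = np.array([k * base for k in keys])
    msd = np.array([acc[k][0] / acc[k][1] for k in keys])
    n_pairs = np.array([acc[k][1] for k in keys])
    return MSDCurve(lags, msd, n_pairs)


def subsample_loglog(curve: MSDCurve, points_per_decade: int = 8) -> MSDCurve:
    """Restrict an MSD curve to approximately log-spaced lags.

    Integer-frame lag grids are nearly uniform in linear time, so at long
    lags adjacent points are separated by ~1% in log tau and finite-
    difference slopes amplify estimator noise enormously.  Selecting the
    nearest available lag to each node of a log-uniform grid (duplicates
    dropped) is the standard preparation for the local power-law GSER.
    """
    if points_per_decade < 2:
        raise InvalidInputError("points_per_decade must be >= 2")
    if len(curve.lags) < 3:
        return curve
    lo, hi = np.log10(curve.lags[0]), np.log10(curve.lags[-1])
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 3)
    targets = np.logspace(lo, hi, n)
    idx = np.unique(
        [int(np.argmin(np.abs(curve.lags - t))) for t in targets]
    )
    return MSDCurve(curve.lags[idx], curve.msd[idx], curve.n_pairs[idx])


def static_error_correction(
    curve: MSDCurve, sigma_um: float, floor: float = 1e-12
) -> MSDCurve:
    """Remove the i.i.d. localization-noise offset 4 sigma^2 from an MSD.

    Values driven at or below zero are floored at ``floor`` with a
    warning — such lags are noise-dominated and should not be inverted.
    """
    if sigma_um < 0:
        raise InvalidInputError("sigma_um must be >= 0")
    corrected = curve.msd - 4.0 * sigma_um**2
    if np.any(corrected <= 0):
        warnings.warn(
            "static-error correction drove some MSD values to <= 0; "
            "those lags are noise-dominated",
            stacklevel=2,
        )
        corrected = np.maximum(corrected, floor)
    return MSDCurve(curve.lags.copy(), corrected, curve.n_pairs.copy())


def local_loglog_slope(curve: MSDCurve) -> np.ndarray:
    """alpha(tau) = d ln MSD / d ln tau by centered log-log differences.

    One-sided differences at the ends; values are clipped to [0, 1] (the
    physical range for passive thermal motion) with a warning.
    """
    if len(curve.lags) < 2:
        raise InvalidInputError("need >= 2 lags for a slope")
    lt = np.log(curve.lags)
    lm = np.log(np.maximum(curve.msd, 1e-300))
    alpha = np.gradient(lm, lt)
    if np.any(alpha < -1e-9) or np.any(alpha > 1 + 1e-9):
        warnings.warn("local MSD slope outside [0, 1]; clipping", stacklevel=2)
    return np.clip(alpha, 0.0, 1.0)


def gser_spectrum(curve: MSDCurve, cfg: GserConfig) -> ViscoelasticSpectrum:
    """Mason local power-law GSER inversion of an MSD curve.

    Each lag tau maps to omega = 1/tau; the returned spectrum is sorted by
    increasing omega.  MSDs must be strictly positive (run
    :func:`static_error_correction` first if noise-dominated).
    """
    if len(curve.lags) < 3:
        raise InvalidInputError("need >= 3 lags for a spectrum")
    if np.any(curve.msd <= 0):
        raise InvalidInputError(
            "MSD contains non-positive values; apply static_error_correction "
            "or drop noise-dominated lags before GSER inversion"
        )
    msd = curve.msd
    if cfg.static_error_sigma_um:
        curve = static_error_correction(curve, cfg.static_error_sigma_um)
        msd = curve.msd
    alpha = local_loglog_slope(curve)
    a_m = cfg.bead_radius_um * 1e-6
    msd_m2 = msd * 1e-12
    g_mag = (
        2.0
        * K_B
        * cfg.temperature_k
        / (3.0 * np.pi * a_m * msd_m2 * gamma_fn(1.0 + alpha))
    )
    g_p = g_mag * np.cos(np.pi * alpha / 2.0)
    g_pp = g_mag * np.sin(np.pi * alpha / 2.0)
    omega = 1.0 / curve.lags
    order = np.argsort(omega)
    return ViscoelasticSpectrum(omega[order], g_p[order], g_pp[order])


def eta_star_at(
    spectrum: ViscoelasticSpectrum,
    f_hz: float,
    convention: str = "2pi",
) -> float:
    """|eta*| at frequency ``f_hz`` by log-log interpolation.

    ``convention='2pi'`` (default) queries omega = 2 pi f; ``'rad'``
    treats f as already in rad/s.  Queries outside the spectrum's omega
    range raise rather than extrapolate.
    """
    omega_q = 2.0 * np.pi * f_hz if convention == "2pi" else f_hz
    om, eta = spectrum.omega, spectrum.eta_star_mag
    if not om[0] <= omega_q <= om[-1]:
        raise InvalidInputError(
            f"omega={omega_q:.4g} rad/s outside spectrum range "
            f"[{om[0]:.4g}, {om[-1]:.4g}]; refusing to extrapolate"
        )
    return float(np.exp(np.interp(np.log(omega_q), np.log(om), np.log(eta))))


def _em_two_gaussians(x: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """2-component 1-D Gaussian EM with deterministic quartile init."""
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    sd = np.full(2, max(x.std() / 2.0, 1e-3))
    w = np.array([0.5, 0.5])
    ll_prev = -np.inf
    for _ in range(max_iter):
        log_pdf = (
            -0.5 * ((x[:, None] - mu) / sd) ** 2
            - np.log(sd)
            - 0.5 * np.log(2 * np.pi)
            + np.log(w)
        )
        m = log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((m.ravel() + np.log(tot.ravel())).sum())
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-4)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    order = np.argsort(mu)
    return w[order], mu[order], sd[order]


def per_bead_eta_distribution(
    ts: TrajectorySet,
    cfg: GserConfig,
    f_hz: float = 1.0,
    convention: str = "2pi",
    max_lag_fraction: float = 1 / 3,
    min_beads_for_fit: int = 10,
    minor_weight_threshold: float = 0.2,
    separation_threshold_decades: float = 0.5,
    points_per_decade: int = 8,
) -> EtaDistribution:
    """Per-bead |eta*|(f) distribution with a bimodality verdict.

    Each sufficiently long track is inverted individually (MSD -> GSER ->
    |eta*| at f).  With >= ``min_beads_for_fit`` beads, a 2-component
    Gaussian mixture is fit on log10 eta; the sample is called bimodal
    when the minor weight and mode separation clear their thresholds.
    """
    values, ids = [], []
    for tid, frames, xy in ts.iter_tracks():
        if len(frames) < 3:
            continue
        curve = msd_track(frames, xy, ts.frame_interval_s, max_lag_fraction)
        if cfg.static_error_sigma_um:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = static_error_correction(curve, cfg.static_error_sigma_um)
        curve = subsample_loglog(curve, points_per_decade)
        if len(curve.lags) < 3:
            continue
        with warnings.catch_warnings():
            # per-bead slope estimates routinely graze the [0, 1] clip
            warnings.simplefilter("ignore")
            spec = gser_spectrum(
                curve, GserConfig(cfg.temperature_k, cfg.bead_radius_um)
            )
        try:
            values.append(eta_star_at(spec, f_hz, convention))
        except InvalidInputError:
            continue  # track too short for the queried lag
        ids.append(tid)
    if not values:
        raise InvalidInputError("no track long enough for the queried frequency")
    vals = np.array(values)
    dist = EtaDistribution(
        f_hz=f_hz,
        values=vals,
        track_ids=ids,
        median=float(np.median(vals)),
        q25=float(np.quantile(vals, 0.25)),
        q75=float(np.quantile(vals, 0.75)),
    )
    if len(vals) >= min_beads_for_fit:
        w, mu, sd = _em_two_gaussians(np.log10(vals))
        sep = float(mu[1] - mu[0])
        dist.mixture_weights = (float(w[0]), float(w[1]))
        dist.mixture_means_log10 = (float(mu[0]), float(mu[1]))
        dist.mixture_sigmas_log10 = (float(sd[0]), float(sd[1]))
        dist.separation_decades = sep
        dist.bimodal = bool(
            min(w) >= minor_weight_threshold and sep >= separation_threshold_decades
        )
    return dist
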