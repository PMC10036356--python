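"""Synthetic generators for every input the mucus-rheology pipeline consumes.

Generates, with known ground truth: tonicity cohorts (sample tables),
viscoelastic bead trajectories (exact fractional Brownian motion),
rendered microscopy stacks, and oscillatory sweep tables.

Fluid model
-----------
The material is a critical gel: G*(omega) = S (i omega)^alpha, so that

    |G*| = S omega^alpha,   tan delta = tan(pi alpha / 2)   (frequency-flat).

A bead of radius a embedded in such a gel performs fractional Brownian
motion with 2-D MSD

    MSD_2D(tau) = 4 D_alpha tau^alpha,
    4 D_alpha   = 2 k_B T / (3 pi a S Gamma(1 + alpha)),

which is exactly the relation the Mason GSER inversion assumes, so the
measurement chain can be validated against closed-form ground truth.
``eta_1hz`` parameterizes S through |eta*|(omega_0) = S omega_0^(alpha-1)
at omega_0 = 2 pi rad/s.  alpha = 1 recovers a Newtonian fluid with
D = k_B T / (6 pi eta a).

Per-axis increments are fractional Gaussian noise with Hurst index
alpha/2, synthesized by the exact Hosking (Durbin–Levinson innovation)
recursion — O(n^2), exact covariance at any n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann as K_B
from scipy.special import erf, gamma as gamma_fn

from mucorheo.errors import InvalidInputError
from mucorheo.sample_qc import SampleRecord
from mucorheo.tracking import ImageStack
from mucorheo.trajectories import TrajectorySet

__all__ = [
    "FluidModel",
    "ConcentrationLaw",
    "TrajectoryParams",
    "RenderParams",
    "viscosity_from_concentration",
    "fluid_for_concentration",
    "effective_fluid",
    "simulate_fbm_tracks",
    "simulate_population_mixture",
    "render_image_stack",
    "simulate_macro_sweep",
    "simulate_sample_table",
    "fgn_covariance",
]

OMEGA_1HZ = 2.0 * math.pi  # rad/s at the 1 Hz reference


@dataclass(frozen=True)
class FluidModel:
    """Critical-gel fluid: power-law exponent and |eta*| at 1 Hz.

    alpha in (0, 1]; eta_1hz in Pa s; temperature in K; bead radius in um.
    """

    alpha: float
    eta_1hz: float
    temperature_k: float = 298.15
    bead_radius_um: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidInputError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.eta_1hz <= 0:
            raise InvalidInputError("eta_1hz must be > 0")

    @property
    def gel_strength(self) -> float:
        """S in Pa s^alpha: |G*| = S omega^alpha."""
        return self.eta_1hz * OMEGA_1HZ ** (1.0 - self.alpha)

    @property
    def tan_delta(self) -> float:
        return math.tan(math.pi * self.alpha / 2.0)

    def g_star_mag(self, omega: np.ndarray) -> np.ndarray:
        return self.gel_strength * np.asarray(omega, float) ** self.alpha

    def msd2d_um2(self, tau_s: np.ndarray) -> np.ndarray:
        """Ground-truth 2-D MSD (um^2) at lag tau."""
        return self.msd_prefactor_um2 * np.asarray(tau_s, float) ** self.alpha

    @property
    def msd_prefactor_um2(self) -> float:
        """4 D_alpha in um^2 / s^alpha."""
        a_m = self.bead_radius_um * 1e-6
        pref_m2 = (
            2.0
            * K_B
            * self.temperature_k
            / (3.0 * math.pi * a_m * self.gel_strength * gamma_fn(1.0 + self.alpha))
        )
        return pref_m2 * 1e12


@dataclass(frozen=True)
class ConcentrationLaw:
    """Power-law concentration scaling |eta*| = eta_ref (c / c_ref)^gamma."""

    c_ref_pct: float = 2.0
    eta_ref: float = 0.05  # Pa s at 1 Hz, near the entanglement concentration
    gamma: float = 3.9

    def __post_init__(self):
        if self.c_ref_pct <= 0 or self.eta_ref <= 0:
            raise InvalidInputError("c_ref_pct and eta_ref must be > 0")


@dataclass(frozen=True)
class TrajectoryParams:
    """Bead-motion simulation parameters.

    n_frames/frame_rate default to the study's video format (1,200 frames
    at 60 fps); localization noise is i.i.d. Gaussian per frame per axis,
    giving the standard +4 sigma^2 MSD offset.  ``mixture`` is an
    optional list of (weight, FluidModel) for heterogeneous populations.
    ``start_box`` ((xmin, xmax), (ymin, ymax)) in um scatters starting
    positions uniformly; default starts every bead at the origin.
    """

    n_beads: int = 50
    n_frames: int = 1200
    frame_rate_hz: float = 60.0
    localization_sigma_um: float = 0.02
    drift_velocity_um_per_frame: tuple[float, float] = (0.0, 0.0)
    mixture: tuple | None = None
    start_box: tuple | None = None

    def __post_init__(self):
        if self.n_frames < 2:
            raise InvalidInputError("n_frames must be >= 2")
        if self.n_beads < 0:
            raise InvalidInputError("n_beads must be >= 0")
        if self.mixture is not None:
            w = sum(w for w, _ in self.mixture)
            if not self.mixture or abs(w - 1.0) > 1e-9:
                raise InvalidInputError("mixture weights must sum to 1")


def viscosity_from_concentration(c_pct: float, law: ConcentrationLaw) -> float:
    """|eta*|(1 Hz) in Pa s at ``c_pct`` % solids under the power law."""
    if c_pct <= 0:
        raise InvalidInputError("concentration must be > 0")
    return law.eta_ref * (c_pct / law.c_ref_pct) ** law.gamma


def fluid_for_concentration(
    c_pct: float, law: ConcentrationLaw, alpha: float = 0.1856, **kw
) -> FluidModel:
    """Critical-gel model at a given % solids (default tan delta ~ 0.3)."""
    return FluidModel(alpha=alpha, eta_1hz=viscosity_from_concentration(c_pct, law), **kw)


def effective_fluid(mixture) -> FluidModel:
    """Effective single-fluid model of a mixture.

    Weight-averaged alpha and log-mean (geometric) eta — the
    effective-medium compromise between the series and parallel coupling
    bounds of a well-mixed biphasic gel.
    """
    if not mixture:
        raise InvalidInputError("mixture must be non-empty")
    w = np.array([wi for wi, _ in mixture], float)
    alphas = np.array([f.alpha for _, f in mixture])
    etas = np.array([f.eta_1hz for _, f in mixture])
    f0 = mixture[0][1]
    return FluidModel(
        alpha=float(w @ alphas),
        eta_1hz=float(np.exp(w @ np.log(etas))),
        temperature_k=f0.temperature_k,
        bead_radius_um=f0.bead_radius_um,
    )


def fgn_covariance(alpha: float, n: int, dt_s: float, msd1d_prefactor: float) -> np.ndarray:
    """Autocovariance gamma[0..n-1] of per-axis fGn increments.

    The per-axis 1-D MSD is msd1d_prefactor * tau^alpha; increments over
    dt then have Var = msd1d_prefactor * dt^alpha and the standard fGn
    covariance with Hurst H = alpha / 2.
    """
    k = np.arange(n, dtype=float)
    var = msd1d_prefactor * dt_s**alpha
    return 0.5 * var * (
        np.abs(k + 1) ** alpha - 2.0 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )


def _fgn_hosking(gamma: np.ndarray, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample paths via the Durbin–Levinson innovation recursion.

    Returns an (n_series, n) array; O(n^2) in the series length but
    vectorized across series.
    """
    n = len(gamma)
    eps = rng.standard_normal((n_series, n))
    out = np.empty((n_series, n))
    v = gamma[0]
    out[:, 0] = math.sqrt(v) * eps[:, 0]
    phi = np.zeros(n)
    for i in range(1, n):
        if i == 1:
            kappa = gamma[1] / v
        else:
            kappa = (gamma[i] - phi[: i - 1] @ gamma[i - 1 : 0 : -1]) / v
        phi[: i - 1] -= kappa * phi[: i - 1][::-1].copy()
        phi[i - 1] = kappa
        v *= 1.0 - kappa**2
        mean = out[:, :i][:, ::-1] @ phi[:i]
        out[:, i] = mean + math.sqrt(v) * eps[:, i]
    return out


def _tracks_dataframe(pos: np.ndarray) -> pd.DataFrame:
    """Stack an (n_beads, n_frames, 2) position array into tidy form."""
    n_beads, n_frames, _ = pos.shape
    return pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_beads), n_frames),
            "frame": np.tile(np.arange(n_frames), n_beads),
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        }
    )


def simulate_fbm_tracks(
    fluid: FluidModel, params: TrajectoryParams, seed: int
) -> TrajectorySet:
    """Simulate bead trajectories in a single critical-gel fluid.

    Per-axis increments are exact fGn with Hurst alpha/2 scaled so the
    ensemble 2-D MSD is 4 D_alpha tau^alpha; localization noise and
    linear drift are added afterwards.  Pure function of (inputs, seed).
    """
    rng = np.random.default_rng(seed)
    return _simulate(fluid, params, rng, eta_scale=None)


def _simulate(
    fluid: FluidModel,
    params: TrajectoryParams,
    rng: np.random.Generator,
    eta_scale: np.ndarray | None,
) -> TrajectorySet:
    n, nb = params.n_frames, params.n_beads
    dt = 1.0 / params.frame_rate_hz
    if nb == 0:
        return TrajectorySet(
            pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"]),
            frame_interval_s=dt,
            meta={"fluid": fluid, "params": params},
        )
    gamma = fgn_covariance(fluid.alpha, n - 1, dt, fluid.msd_prefactor_um2 / 2.0)
    incr = _fgn_hosking(gamma, 2 * nb, rng)  # x rows then y rows
    if eta_scale is not None:
        # MSD prefactor ~ 1/eta: scale each bead's increments accordingly
        s = np.sqrt(1.0 / eta_scale)
        incr *= np.concatenate([s, s])[:, None]
    pos = np.zeros((nb, n, 2))
    pos[:, 1:, 0] = np.cumsum(incr[:nb], axis=1)
    pos[:, 1:, 1] = np.cumsum(incr[nb:], axis=1)
    if params.start_box is not None:
        (x0, x1), (y0, y1) = params.start_box
        starts = np.column_stack(
            [rng.uniform(x0, x1, nb), rng.uniform(y0, y1, nb)]
        )
        pos += starts[:, None, :]
    vx, vy = params.drift_velocity_um_per_frame
    if vx or vy:
        t = np.arange(n, dtype=float)
        pos[:, :, 0] += vx * t
        pos[:, :, 1] += vy * t
    if params.localization_sigma_um > 0:
        pos += rng.normal(0.0, params.localization_sigma_um, pos.shape)
    return TrajectorySet(
        _tracks_dataframe(pos),
        frame_interval_s=dt,
        meta={"fluid": fluid, "params": params},
    )


def simulate_population_mixture(
    params: TrajectoryParams,
    seed: int,
    eta_dispersion_decades: float = 0.25,
) -> TrajectorySet:
    """Simulate a heterogeneous bead population from ``params.mixture``.

    Each bead is assigned a component by weighted draw; within a
    component, each bead's eta is drawn log-normally around the component
    value with spread ``eta_dispersion_decades`` (log10 s.d.), emulating
    the within-phase heterogeneity of real per-bead distributions.
    Ground-truth labels and per-bead eta are recorded in ``meta``.
    """
    if params.mixture is None or not params.mixture:
        raise InvalidInputError("params.mixture must be a non-empty list")
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _ in params.mixture], float)
    fluids = [f for _, f in params.mixture]
    nb = params.n_beads
    labels = rng.choice(len(fluids), size=nb, p=weights)
    eta_mult = 10.0 ** rng.normal(0.0, eta_dispersion_decades, nb)
    dt = 1.0 / params.frame_rate_hz

    parts = []
    true_eta = np.empty(nb)
    for ci, fluid in enumerate(fluids):
        idx = np.nonzero(labels == ci)[0]
        if len(idx) == 0:
            continue
        sub = TrajectoryParams(
            n_beads=len(idx),
            n_frames=params.n_frames,
            frame_rate_hz=params.frame_rate_hz,
            localization_sigma_um=params.localization_sigma_um,
            drift_velocity_um_per_frame=params.drift_velocity_um_per_frame,
            start_box=params.start_box,
        )
        ts = _simulate(fluid, sub, rng, eta_scale=eta_mult[idx])
        df = ts.data.copy()
        df["track_id"] = idx[df["track_id"].to_numpy()]
        parts.append(df)
        true_eta[idx] = fluid.eta_1hz * eta_mult[idx]
    data = (
        pd.concat(parts, ignore_index=True).sort_values(
            ["track_id", "frame"], kind="stable"
        )
        if parts
        else pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    )
    return TrajectorySet(
        data.reset_index(drop=True),
        frame_interval_s=dt,
        meta={
            "params": params,
            "component": {int(i): int(labels[i]) for i in range(nb)},
            "true_eta_1hz": {int(i): float(true_eta[i]) for i in range(nb)},
            "eta_dispersion_decades": eta_dispersion_decades,
        },
    )


@dataclass(frozen=True)
class RenderParams:
    """Synthetic microscopy rendering parameters.

    Pixel size defaults to a x40 air objective; the point-spread function
    is an integrated 2-D Gaussian; ``peak_counts`` is the expected
    central-pixel count of a pixel-centered bead.
    """

    pixel_size_um: float = 0.1625
    psf_sigma_px: float = 1.3
    peak_counts: float = 4000.0
    background_counts: float = 100.0
    poisson_noise: bool = True
    shape_yx: tuple[int, int] | None = None

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.psf_sigma_px <= 0:
            raise InvalidInputError("pixel_size_um and psf_sigma_px must be > 0")


def render_image_stack(
    tracks: TrajectorySet, render: RenderParams, seed: int
) -> ImageStack:
    """Render trajectories as a 16-bit grayscale video.

    Each bead becomes an integrated 2-D Gaussian spot; counts are
    Poisson-sampled when enabled.  If no field shape is given, one is
    sized to the trajectories plus a margin and the pixel offset recorded
    in ``meta['origin_offset_px']``.  Beads leaving the field (after the
    PSF margin) raise an error naming the offenders.
    """
    rng = np.random.default_rng(seed)
    px = render.pixel_size_um
    sig = render.psf_sigma_px
    margin = int(math.ceil(4 * sig)) + 1
    df = tracks.data
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1

    xs = df["x_um"].to_numpy() / px
    ys = df["y_um"].to_numpy() / px
    if render.shape_yx is None:
        off_x = margin - (math.floor(xs.min()) if len(df) else 0)
        off_y = margin - (math.floor(ys.min()) if len(df) else 0)
        w = int(math.ceil(xs.max() + off_x)) + margin + 1 if len(df) else 2 * margin
        h = int(math.ceil(ys.max() + off_y)) + margin + 1 if len(df) else 2 * margin
        shape = (h, w)
    else:
        off_x = off_y = 0
        shape = render.shape_yx
    h, w = shape
    xs = xs + off_x
    ys = ys + off_y
    bad = (xs < margin - 1) | (xs > w - margin) | (ys < margin - 1) | (ys > h - margin)
    if bad.any():
        offenders = df.loc[bad, ["track_id", "frame"]].drop_duplicates("track_id")
        raise InvalidInputError(
            "beads outside the field after margin: "
            + ", ".join(f"track {r.track_id} (frame {r.frame})" for r in offenders.itertuples())
        )

    peak_frac = erf(0.5 / (sig * math.sqrt(2.0))) ** 2
    amplitude = render.peak_counts / peak_frac
    stack = np.full((n_frames, h, w), float(render.background_counts))
    half = margin
    frames_arr = df["frame"].to_numpy(int)
    for i in range(len(df)):
        t, xc, yc = frames_arr[i], xs[i], ys[i]
        x0, y0 = int(round(xc)), int(round(yc))
        xg = np.arange(x0 - half, x0 + half + 1)
        yg = np.arange(y0 - half, y0 + half + 1)
        fx = 0.5 * (
            erf((xg + 0.5 - xc) / (sig * math.sqrt(2)))
            - erf((xg - 0.5 - xc) / (sig * math.sqrt(2)))
        )
        fy = 0.5 * (
            erf((yg + 0.5 - yc) / (sig * math.sqrt(2)))
            - erf((yg - 0.5 - yc) / (sig * math.sqrt(2)))
        )
        ys_ok = (yg >= 0) & (yg < h)
        xs_ok = (xg >= 0) & (xg < w)
        stack[t, yg[ys_ok][:, None], xg[xs_ok][None, :]] += (
            amplitude * np.outer(fy[ys_ok], fx[xs_ok])
        )
    if render.poisson_noise:
        stack = rng.poisson(stack).astype(float)
    frames16 = np.clip(stack, 0, 65535).astype(np.uint16)
    return ImageStack(
        frames16,
        pixel_size_um=px,
        frame_rate_hz=1.0 / tracks.frame_interval_s,
        meta={"origin_offset_px": (off_x, off_y), "render": render},
    )


def simulate_macro_sweep(
    fluid: FluidModel,
    omega_rad_s: np.ndarray | None = None,
    strain_pct: np.ndarray | None = None,
    fixed_omega_rad_s: float = OMEGA_1HZ,
    critical_strain_pct: float = 2.0,
    thinning_exponents: tuple[float, float] = (0.6, 0.3),
) -> pd.DataFrame:
    """Cone-and-plate style sweep table for a critical-gel fluid.

    Frequency sweep (``omega_rad_s`` given): G' = |G*| cos(pi alpha / 2),
    G'' = |G*| sin(pi alpha / 2) with |G*| = S omega^alpha, so tan delta
    is frequency-flat and |eta*|(1 Hz) equals the fluid's eta_1hz.

    Strain sweep (``strain_pct`` given, at ``fixed_omega_rad_s``): both
    moduli plateau below ``critical_strain_pct`` and decay smoothly as
    (strain / critical)^-p above, with p per modulus (G' decays faster —
    strain thinning raises tan delta).
    """
    if (omega_rad_s is None) == (strain_pct is None):
        raise InvalidInputError("give exactly one of omega_rad_s or strain_pct")
    phase = math.pi * fluid.alpha / 2.0
    if omega_rad_s is not None:
        om = np.asarray(omega_rad_s, float)
        if np.any(om <= 0) or np.any(np.diff(om) <= 0):
            raise InvalidInputError("omega grid must be positive and increasing")
        g = fluid.g_star_mag(om)
        return pd.DataFrame(
            {
                "omega_rad_s": om,
                "Gp_Pa": g * math.cos(phase),
                "Gpp_Pa": g * math.sin(phase),
            }
        )
    gam = np.asarray(strain_pct, float)
    if np.any(gam <= 0) or np.any(np.diff(gam) <= 0):
        raise InvalidInputError("strain grid must be positive and increasing")
    g0 = fluid.g_star_mag(np.array([fixed_omega_rad_s]))[0]
    gp0, gpp0 = g0 * math.cos(phase), g0 * math.sin(phase)
    p_gp, p_gpp = thinning_exponents
    ratio = np.maximum(gam / critical_strain_pct, 1.0)
    return pd.DataFrame(
        {
            "strain_pct": gam,
            "Gp_Pa": gp0 * ratio**-p_gp,
            "Gpp_Pa": gpp0 * ratio**-p_gpp,
        }
    )


def simulate_sample_table(
    n: int,
    tonicity_mix: tuple[float, float, float],
    seed: int,
) -> list[SampleRecord]:
    """Synthetic ETT sample cohort with controlled tonicity composition.

    ``tonicity_mix`` gives (hypo, iso, hyper) proportions.  Na is drawn
    per class — hypo ~ N(66, 15), iso ~ N(113, 7), hyper ~ N(155, 10),
    truncated positive; K ~ N(13, 5) truncated at 0; volumes log-normal
    around 400 uL; % solids ~ N(5, 1.5) truncated to [1.5, 10].  Class
    means mirror the characterized hypotonic / isotonic / hypertonic
    cohorts.
    """
    if abs(sum(tonicity_mix) - 1.0) > 1e-9:
        raise InvalidInputError("tonicity_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    na_params = {0: (66.0, 15.0), 1: (113.0, 7.0), 2: (155.0, 10.0)}

    def _trunc_normal(mu, sd, lo, hi=np.inf):
        while True:
            v = rng.normal(mu, sd)
            if lo < v < hi:
                return v

    records = []
    classes = rng.choice(3, size=n, p=list(tonicity_mix))
    for i, cls in enumerate(classes):
        mu, sd = na_params[int(cls)]
        records.append(
            SampleRecord(
                sample_id=f"SYN-{i + 1}",
                volume_ul=float(np.exp(rng.normal(math.log(400.0), 0.5))),
                pct_solids=_trunc_normal(5.0, 1.5, 1.5, 10.0),
                na_mM=_trunc_normal(mu, sd, 0.0),
                k_mM=_trunc_normal(13.0, 5.0, 0.0),
            )
        )
    return records
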