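"""Bulk oscillatory-sweep analysis: LVR detection, tan delta, |eta*|, cross-scale comparison.

Consumes cone-and-plate style sweep tables — strain sweeps (at fixed
frequency, to locate the linear viscoelastic regime) and frequency
sweeps (at fixed strain, to characterize the gel) — and compares the
bulk complex viscosity against the particle-tracking median.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from mucorheo.errors import InvalidInputError
from mucorheo.microrheology import EtaDistribution, ViscoelasticSpectrum, eta_star_at

__all__ = [
    "StrainSweep",
    "FrequencySweep",
    "CrossScaleReport",
    "find_lvr",
    "tan_delta",
    "bulk_eta_star",
    "cross_scale_compare",
]


@dataclass
class StrainSweep:
    """Amplitude sweep at fixed frequency: strain (%) vs G', G'' (Pa)."""

    strain_pct: np.ndarray
    g_prime: np.ndarray
    g_dprime: np.ndarray

    def __post_init__(self):
        self.strain_pct = np.asarray(self.strain_pct, float)
        self.g_prime = np.asarray(self.g_prime, float)
        self.g_dprime = np.asarray(self.g_dprime, float)
        if np.any(np.diff(self.strain_pct) <= 0):
            raise InvalidInputError("strain grid must be strictly increasing")


@dataclass
class FrequencySweep:
    """Frequency sweep at fixed strain: omega (rad/s) vs G', G'' (Pa)."""

    omega_rad_s: np.ndarray
    g_prime: np.ndarray
    g_dprime: np.ndarray
    strain_at_pct: float = 1.0

    def __post_init__(self):
        self.omega_rad_s = np.asarray(self.omega_rad_s, float)
        self.g_prime = np.asarray(self.g_prime, float)
        self.g_dprime = np.asarray(self.g_dprime, float)
        if np.any(np.diff(self.omega_rad_s) <= 0):
            raise InvalidInputError("omega grid must be strictly increasing")

    def spectrum(self) -> ViscoelasticSpectrum:
        return ViscoelasticSpectrum(self.omega_rad_s, self.g_prime, self.g_dprime)


@dataclass
class CrossScaleReport:
    """Bulk vs PTMR |eta*| at one frequency."""

    f_hz: float
    micro_eta: float
    bulk_eta: float
    ratio: float
    bound: float
    within_bound: bool


def find_lvr(sweep: StrainSweep, tolerance: float = 0.10) -> tuple[float, float] | None:
    """Low-strain-anchored interval where both moduli are strain-flat.

    The reference level per modulus is the median over the three lowest
    strains; the interval extends from the lowest strain to the last
    point at which both moduli stay within ``tolerance`` (relative) of
    their references.  Returns None (with a warning) when even the first
    point is outside the band.
    """
    if len(sweep.strain_pct) < 4:
        raise InvalidInputError("need >= 4 strain points to identify an LVR")
    ref_p = float(np.median(sweep.g_prime[:3]))
    ref_pp = float(np.median(sweep.g_dprime[:3]))
    if ref_p <= 0 or ref_pp <= 0:
        raise InvalidInputError("moduli must be positive in the low-strain anchor")
    ok = (np.abs(sweep.g_prime / ref_p - 1.0) <= tolerance) & (
        np.abs(sweep.g_dprime / ref_pp - 1.0) <= tolerance
    )
    if not ok[0]:
        warnings.warn("no linear viscoelastic regime found", stacklevel=2)
        return None
    last = int(np.nonzero(~ok)[0][0]) - 1 if not ok.all() else len(ok) - 1
    return float(sweep.strain_pct[0]), float(sweep.strain_pct[last])


def tan_delta(
    g_prime: np.ndarray, g_dprime: np.ndarray
) -> tuple[np.ndarray, str]:
    """Loss tangent G''/G' per point and a gel/viscous verdict.

    tan delta < 1 throughout the sweep marks elastic-dominant (gel)
    behavior; G' = 0 yields a +inf sentinel and a viscous verdict.
    """
    gp = np.atleast_1d(np.asarray(g_prime, float))
    gpp = np.atleast_1d(np.asarray(g_dprime, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        td = np.where(gp > 0, gpp / np.where(gp > 0, gp, 1.0), math.inf)
    verdict = "gel" if np.max(td) < 1.0 else "viscous"
    return td, verdict


def bulk_eta_star(sweep: FrequencySweep) -> np.ndarray:
    """|eta*|(omega) = sqrt(G'^2 + G''^2) / omega, per grid point (Pa s)."""
    return np.hypot(sweep.g_prime, sweep.g_dprime) / sweep.omega_rad_s


def cross_scale_compare(
    bulk: FrequencySweep,
    micro: EtaDistribution | ViscoelasticSpectrum,
    f_hz: float = 1.0,
    bound: float = 2.0,
    convention: str = "2pi",
) -> CrossScaleReport:
    """Fold-agreement between bulk and PTMR complex viscosity at ``f_hz``.

    ratio = max(micro/bulk, bulk/micro); the report carries both values
    and a pass flag against ``bound`` (the factor-of-2 criterion used for
    heterogeneous low-concentration samples).
    """
    if isinstance(micro, EtaDistribution):
        if abs(micro.f_hz - f_hz) > 1e-9:
            raise InvalidInputError(
                f"distribution evaluated at {micro.f_hz} Hz, requested {f_hz} Hz"
            )
        m = micro.median
    else:
        m = eta_star_at(micro, f_hz, convention)
    b = float(eta_star_at(bulk.spectrum(), f_hz, convention))
    if m <= 0 or b <= 0:
        raise InvalidInputError("viscosities must be positive for comparison")
    ratio = max(m / b, b / m)
    return CrossScaleReport(
        f_hz=f_hz,
        micro_eta=float(m),
        bulk_eta=b,
        ratio=float(ratio),
        bound=bound,
        within_bound=bool(ratio <= bound),
    )
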