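"""Within-canopy light environment: extinction, reflectance, absorption.

Beam and diffuse PAR attenuate differently inside a canopy, so a canopy
of leaf area index ``L`` is described here by a small set of optical
coefficients (extinction with and without scattering, canopy
reflectances), the absorbed PAR of the whole canopy and of its sunlit
and shaded fractions (closed-form depth integrals of the layer
equations, after De Pury & Farquhar-style sun/shade theory), the
sunlit/shaded leaf area, and the available-energy split between canopy
and soil.

All absorbed fluxes are per unit ground area (W m-2) unless a function
says "per unit leaf area".  A spherical leaf-angle distribution is
assumed throughout (``G_L = 0.5``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from .solar import IncidentPAR

#: cap on the net-radiation extinction coefficient near sunrise/sunset
KAPPA_R_MAX = 1.0


@dataclass(frozen=True)
class OpticalParams:
    """Extinction and reflectance coefficients for one sun position.

    Attributes
    ----------
    leaf_absorptivity : float
        Leaf absorptivity for PAR (``alpha``), 0.8 for green leaves.
    g_l : float
        Leaf-angle distribution parameter; 0.5 for spherical.
    kappa_b : float
        Beam extinction coefficient for black (non-scattering) leaves,
        ``G_L / cos(zenith)``.
    kappa_b_prime : float
        Beam extinction including scattering, ``kappa_b * sqrt(alpha)``.
    kappa_d : float
        Diffuse extinction coefficient for black leaves (0.7).
    kappa_d_prime : float
        Diffuse extinction including scattering, ``kappa_d * sqrt(alpha)``.
    rho_h : float
        Beam reflectance of a canopy of horizontal leaves.
    rho_cb : float
        Canopy beam reflectance for the actual (spherical) leaf angles.
    rho_cd : float
        Canopy diffuse reflectance (hemispheric integral of ``rho_cb``).
    kappa_r : float
        Net-radiation extinction coefficient, ``G_L / cos(zenith)``
        capped at :data:`KAPPA_R_MAX`.
    """

    leaf_absorptivity: float
    g_l: float
    kappa_b: float
    kappa_b_prime: float
    kappa_d: float
    kappa_d_prime: float
    rho_h: float
    rho_cb: float
    rho_cd: float
    kappa_r: float


@dataclass(frozen=True)
class LayerIrradiance:
    """Absorbed PAR per unit leaf area at one canopy depth.

    ``xi`` is the cumulative leaf area index measured downward from the
    canopy top.  ``total_beam`` is unintercepted-plus-scattered beam;
    ``sunlit`` applies to the sunlit leaves only (direct + diffuse +
    scattered); ``sunlit_fraction`` is ``exp(-kappa_b * xi)``.
    """

    xi: float
    total_beam: float
    direct_beam: float
    diffuse: float
    scattered: float
    total: float
    sunlit: float
    sunlit_fraction: float


@dataclass(frozen=True)
class CanopyAbsorption:
    """Whole-canopy absorbed PAR and its sunlit/shaded split (W m-2 ground)."""

    q_canopy: float
    q_sunlit: float
    q_shaded: float
    lai: float
    lai_sunlit: float
    lai_shaded: float
    frac_sunlit: float
    frac_shaded: float


@dataclass(frozen=True)
class AvailableEnergy:
    """Available energy above the canopy and at the soil surface (W m-2)."""

    r_n: float
    r_ns: float
    g: float
    total: float
    soil: float


def _rho_h(alpha: float) -> float:
    sq = math.sqrt(alpha)
    return (1.0 - sq) / (1.0 + sq)


def _rho_cb(alpha: float, kappa_b: float) -> float:
    return 1.0 - math.exp(-2.0 * _rho_h(alpha) * kappa_b / (1.0 + kappa_b))


@lru_cache(maxsize=16)
def diffuse_canopy_reflectance(alpha: float, g_l: float = 0.5) -> float:
    """Canopy reflectance for diffuse PAR.

    Integrates the beam reflectance over a uniform-overcast sky,
    weighting each sky zenith by its irradiance contribution
    ``2 sin(z) cos(z)``.  For alpha = 0.8 this evaluates to ~0.036.
    """

    def integrand(zenith_rad: float) -> float:
        kb = g_l / math.cos(zenith_rad)
        return _rho_cb(alpha, kb) * 2.0 * math.sin(zenith_rad) * math.cos(zenith_rad)

    value, _ = quad(integrand, 0.0, math.pi / 2.0 - 1e-9, limit=200)
    return value


def derive_optics(
    alpha: float = 0.8,
    g_l: float = 0.5,
    kappa_d: float = 0.7,
    zenith_deg: float = 0.0,
) -> OpticalParams:
    """Optical coefficients for one sun position.

    Raises
    ------
    ValueError
        For a sun at or below the horizon (callers use the night path).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("leaf absorptivity must be in (0, 1]")
    if zenith_deg >= 90.0:
        raise ValueError("sun below horizon: optics undefined, use night path")
    cos_z = math.cos(math.radians(zenith_deg))
    kappa_b = g_l / cos_z
    sq = math.sqrt(alpha)
    return OpticalParams(
        leaf_absorptivity=alpha,
        g_l=g_l,
        kappa_b=kappa_b,
        kappa_b_prime=kappa_b * sq,
        kappa_d=kappa_d,
        kappa_d_prime=kappa_d * sq,
        rho_h=_rho_h(alpha),
        rho_cb=_rho_cb(alpha, kappa_b),
        rho_cd=diffuse_canopy_reflectance(alpha, g_l),
        kappa_r=min(kappa_b, KAPPA_R_MAX),
    )


def layer_irradiance(xi: float, optics: OpticalParams, inc: IncidentPAR) -> LayerIrradiance:
    """Absorbed PAR per unit leaf area at cumulative leaf area ``xi``.

    Three streams are tracked: total beam (unintercepted plus
    down-scattered), unintercepted direct beam, and diffuse.  The
    scattered-beam component is the difference between the total-beam
    and direct-beam absorption; sunlit leaves at this depth absorb
    direct + diffuse + scattered.
    """
    if xi < 0.0:
        raise ValueError("cumulative leaf area index must be nonnegative")
    if inc.beam < 0.0 or inc.diffuse < 0.0:
        raise ValueError("irradiance inputs must be nonnegative")
    o = optics
    q_bt = (1.0 - o.rho_cb) * o.kappa_b_prime * inc.beam * math.exp(-o.kappa_b_prime * xi)
    q_d = (1.0 - o.rho_cd) * o.kappa_d_prime * inc.diffuse * math.exp(-o.kappa_d_prime * xi)
    q_b = o.leaf_absorptivity * o.kappa_b * inc.beam * math.exp(-o.kappa_b * xi)
    q_s = q_bt - q_b
    f_sl = math.exp(-o.kappa_b * xi)
    return LayerIrradiance(
        xi=xi,
        total_beam=q_bt,
        direct_beam=q_b,
        diffuse=q_d,
        scattered=q_s,
        total=q_bt + q_d,
        sunlit=q_b + q_d + q_s,
        sunlit_fraction=f_sl,
    )


def sunlit_lai(lai: float, kappa_b: float) -> tuple[float, float, float, float]:
    """Sunlit and shaded leaf area index and their shares of total LAI.

    The sunlit fraction of leaf area declines as ``exp(-kappa_b xi)``
    with depth, so ``LAI_sl = (1 - exp(-kappa_b LAI)) / kappa_b``, which
    saturates at ``1/kappa_b`` for deep canopies.  Returns
    ``(lai_sl, lai_sh, frac_sl, frac_sh)``; the shares are defined by
    limit (1 and 0) for a zero-LAI canopy.
    """
    if kappa_b <= 0.0:
        raise ValueError("beam extinction coefficient must be positive")
    if lai < 0.0:
        raise ValueError("LAI must be nonnegative")
    lai_sl = (1.0 - math.exp(-kappa_b * lai)) / kappa_b
    lai_sh = lai - lai_sl
    if lai > 0.0:
        frac_sl = lai_sl / lai
    else:
        frac_sl = 1.0
    return lai_sl, lai_sh, frac_sl, 1.0 - frac_sl


def canopy_absorption(lai: float, optics: OpticalParams, inc: IncidentPAR) -> CanopyAbsorption:
    """Whole-canopy absorbed PAR with the sunlit/shaded split.

    Closed-form depth integrals of :func:`layer_irradiance` over
    ``xi in [0, LAI]``:

    * whole canopy: beam ``(1-rho_cb) Q_b (1 - e^{-kb' L})`` plus the
      analogous diffuse term;
    * sunlit fraction: direct beam (all of it lands on sunlit leaves)
      ``alpha Q_b (1 - e^{-kb L})``, diffuse weighted by the sunlit
      profile, and the down-scattered beam remainder;
    * shaded fraction: the difference, clamped at zero against
      floating-point cancellation at tiny LAI.
    """
    if lai < 0.0:
        raise ValueError("LAI must be nonnegative")
    o = optics
    q_b, q_d = inc.beam, inc.diffuse
    alpha = o.leaf_absorptivity
    kb, kbp, kdp = o.kappa_b, o.kappa_b_prime, o.kappa_d_prime

    q_canopy = (1.0 - o.rho_cb) * q_b * (1.0 - math.exp(-kbp * lai)) + (
        1.0 - o.rho_cd
    ) * q_d * (1.0 - math.exp(-kdp * lai))

    direct = alpha * q_b * (1.0 - math.exp(-kb * lai))
    diffuse = (
        (1.0 - o.rho_cd)
        * q_d
        * (1.0 - math.exp(-(kdp + kb) * lai))
        * kdp
        / (kdp + kb)
    )
    scattered = (1.0 - o.rho_cb) * q_b * (1.0 - math.exp(-(kbp + kb) * lai)) * kbp / (
        kbp + kb
    ) - alpha * q_b * (1.0 - math.exp(-2.0 * kb * lai)) / 2.0
    q_sl = direct + diffuse + scattered

    q_sh = q_canopy - q_sl
    if q_sh < 0.0:
        if q_sh < -1e-9 * max(q_canopy, 1.0):
            warnings.warn(
                f"shaded absorption {q_sh:.3e} W m-2 clamped to 0 (LAI={lai})",
                stacklevel=2,
            )
        q_sh = 0.0
        q_sl = q_canopy

    lai_sl, lai_sh, frac_sl, frac_sh = sunlit_lai(lai, kb) if lai > 0 else (0.0, 0.0, 1.0, 0.0)
    return CanopyAbsorption(
        q_canopy=q_canopy,
        q_sunlit=q_sl,
        q_shaded=q_sh,
        lai=lai,
        lai_sunlit=lai_sl,
        lai_shaded=lai_sh,
        frac_sunlit=frac_sl,
        frac_shaded=frac_sh,
    )


def night_absorption(lai: float) -> CanopyAbsorption:
    """Zero-absorption record for a sun-below-horizon timestep."""
    return CanopyAbsorption(
        q_canopy=0.0,
        q_sunlit=0.0,
        q_shaded=0.0,
        lai=lai,
        lai_sunlit=0.0,
        lai_shaded=lai,
        frac_sunlit=0.0 if lai > 0 else 1.0,
        frac_shaded=1.0 if lai > 0 else 0.0,
    )


def available_energy(r_n: float, g: float, kappa_r: float, lai: float) -> AvailableEnergy:
    """Partition available energy between canopy and soil surface.

    Net radiation decays through the canopy as ``R_ns = R_n
    exp(-kappa_r LAI)``; the total and soil available energies are
    ``A = R_n - G`` and ``A_s = R_ns - G``.
    """
    if lai < 0.0:
        raise ValueError("LAI must be nonnegative")
    r_ns = r_n * math.exp(-kappa_r * lai)
    return AvailableEnergy(r_n=r_n, r_ns=r_ns, g=g, total=r_n - g, soil=r_ns - g)


def cumulative_lai_at_height(z: float, h_c: float, lai: float) -> float:
    """Cumulative LAI from the top down to height ``z``, uniform leaf area density."""
    if h_c <= 0.0:
        raise ValueError("canopy height must be positive")
    z = min(max(z, 0.0), h_c)
    return lai * (1.0 - z / h_c)
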