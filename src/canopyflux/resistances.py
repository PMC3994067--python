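"""Aerodynamic, boundary-layer and surface resistances (s m-1).

The dual-source combination scheme needs five resistances:

* ``r_aa`` - aerodynamic resistance between the in-canopy source height
  and the reference height (log profile above the canopy plus an
  eddy-diffusivity integral through the upper canopy);
* ``r_ac`` - bulk boundary-layer resistance of the foliage,
  ``r_b / (2 LAI)`` with a leaf boundary-layer resistance from the
  characteristic leaf dimension and the wind speed at the canopy top;
* ``r_as`` - aerodynamic resistance between the soil surface and the
  canopy source height (eddy-diffusivity integral);
* ``r_sc`` - canopy stomatal resistance, the reciprocal of canopy
  conductance (computed elsewhere);
* ``r_ss`` - soil surface resistance, an empirical power function of
  relative surface soil moisture, divided by the exposed-ground
  fraction when the surface is partly sealed by plastic-film mulch.

The aerodynamic trio follows the classical sparse-crop scheme: full
canopy values (displacement 0.63 h, roughness 0.13 h) blended linearly
in LAI/4 toward the bare-substrate limit, with an exponential
eddy-diffusivity decay (coefficient ``n``) inside the canopy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: wind speeds below this (m s-1) are floored to keep resistances bounded
WIND_FLOOR = 0.1

#: leaf boundary-layer transfer coefficient, m s^-1/2
LEAF_TRANSFER_COEFF = 0.01


@dataclass(frozen=True)
class AeroParams:
    """Constants of the aerodynamic scheme.

    drag_coefficient : mean drag coefficient of canopy elements (0.1),
        used only by the optional "drag" roughness closure.
    leaf_dimension : characteristic leaf dimension, m (0.068).
    z0_soil : roughness length of the substrate, m (0.01).
    von_karman : von Karman constant (0.41).
    eddy_decay_n : in-canopy eddy-diffusivity attenuation coefficient (2.5).
    reference_height : measurement/reference height above ground, m; if
        None the working reference is canopy height + 1 m.
    roughness : "fixed" (full-cover 0.63/0.13 constants with LAI/4
        interpolation) or "drag" (drag-partition displacement height).
    """

    drag_coefficient: float = 0.1
    leaf_dimension: float = 0.068
    z0_soil: float = 0.01
    von_karman: float = 0.41
    eddy_decay_n: float = 2.5
    reference_height: float | None = None
    roughness: str = "fixed"

    def __post_init__(self) -> None:
        if min(self.drag_coefficient, self.leaf_dimension, self.z0_soil, self.von_karman, self.eddy_decay_n) <= 0:
            raise ValueError("aerodynamic constants must be positive")
        if self.roughness not in ("fixed", "drag"):
            raise ValueError("roughness must be 'fixed' or 'drag'")


@dataclass(frozen=True)
class SoilResistanceParams:
    """Empirical soil-surface-resistance coefficients and mulch fraction.

    ``r_ss_bare = b1 (theta_g / theta_s)^b2 + b3`` with b2 < 0 so the
    resistance rises as the surface dries; mulching divides by the
    exposed fraction ``1 - f_mulch``.
    """

    b1: float = 15.2
    b2: float = -5.8
    b3: float = 88.7
    f_mulch: float = 0.5

    def __post_init__(self) -> None:
        if self.b2 >= 0:
            raise ValueError("b2 must be negative (resistance rises as soil dries)")
        if not 0.0 <= self.f_mulch < 1.0:
            raise ValueError("mulch fraction must be in [0, 1); a fully sealed surface is unsupported")


@dataclass(frozen=True)
class ResistanceSet:
    """The five resistances of the dual-source network (s m-1)."""

    r_aa: float
    r_ac: float
    r_as: float
    r_sc: float
    r_ss: float


def soil_surface_resistance(theta_g: float, theta_s: float, params: SoilResistanceParams) -> float:
    """Soil surface resistance adjusted for plastic-film mulch.

    Monotone decreasing in surface moisture; at saturation it equals
    ``(b1 + b3) / (1 - f_mulch)``.
    """
    if theta_g <= 0.0 or theta_s <= 0.0:
        raise ValueError("soil water contents must be positive")
    if theta_g > theta_s:
        raise ValueError("surface moisture cannot exceed saturation")
    bare = params.b1 * (theta_g / theta_s) ** params.b2 + params.b3
    return bare / (1.0 - params.f_mulch)


def conductance_to_resistance(g_sc_mm_s: float) -> float:
    """Canopy conductance (mm s-1) to stomatal resistance (s m-1).

    A zero conductance maps to an infinite resistance (closed canopy
    path), which the combination equations handle analytically.
    """
    if g_sc_mm_s < 0.0:
        raise ValueError("conductance must be nonnegative")
    if g_sc_mm_s == 0.0:
        return math.inf
    return 1000.0 / g_sc_mm_s


def roughness_parameters(h_c: float, lai: float, params: AeroParams) -> tuple[float, float]:
    """Displacement height and roughness length of the canopy.

    "fixed" mode returns the full-cover values ``d = 0.63 h`` and
    ``z0 = 0.13 h`` (the LAI dependence enters through the resistance
    interpolation instead); "drag" mode uses the drag-partition
    closure ``d = 1.1 h ln(1 + (c_d LAI)^{1/4})`` with the matching
    piecewise roughness.
    """
    if params.roughness == "fixed":
        return 0.63 * h_c, 0.13 * h_c
    x = params.drag_coefficient * lai
    d = 1.1 * h_c * math.log(1.0 + x ** 0.25)
    if x < 0.2:
        z0 = params.z0_soil + 0.3 * h_c * math.sqrt(x)
    else:
        z0 = 0.3 * h_c * (1.0 - d / h_c)
    return d, z0


def wind_to_reference(u_measured: float, z_measured: float, h_c: float, params: AeroParams) -> tuple[float, float]:
    """Log-extrapolate measured wind to the working reference height.

    The working reference is ``max(z_measured, h_c + 1)`` so that the
    reference always clears the canopy even mid-season.  Returns
    ``(u_ref, z_ref)``.  If the measurement height is inside the
    canopy's roughness sublayer the measured value is used unchanged.
    """
    z_ref = max(z_measured, h_c + 1.0)
    if z_ref == z_measured:
        return max(u_measured, WIND_FLOOR), z_ref
    d, z0 = 0.63 * h_c, 0.13 * h_c
    if z_measured <= d + z0:
        return max(u_measured, WIND_FLOOR), z_ref
    factor = math.log((z_ref - d) / z0) / math.log((z_measured - d) / z0)
    return max(u_measured * factor, WIND_FLOOR), z_ref


def aerodynamic_resistances(
    u_ref: float,
    h_c: float,
    lai: float,
    params: AeroParams,
) -> tuple[float, float, float]:
    """The aerodynamic resistance trio ``(r_aa, r_ac, r_as)``.

    ``u_ref`` is the wind speed at the reference height
    (``params.reference_height`` or canopy height + 1 m).  Full-canopy
    values come from the log profile and the exponential
    eddy-diffusivity integral; they are blended linearly in ``LAI/4``
    toward the bare-substrate limit, in which the total log-law
    resistance from the soil roughness to the reference height is split
    at the notional canopy source height ``d + z0``.

    At ``LAI = 0`` the transpiration path is closed: ``r_ac = inf``.
    """
    if h_c <= 0.0:
        raise ValueError("canopy height must be positive")
    if lai < 0.0:
        raise ValueError("LAI must be nonnegative")
    u = max(u_ref, WIND_FLOOR)
    k = params.von_karman
    n = params.eddy_decay_n
    z_ref = params.reference_height if params.reference_height is not None else h_c + 1.0
    if z_ref <= h_c:
        raise ValueError("reference height must exceed canopy height")

    d, z0 = roughness_parameters(h_c, lai, params)
    z0s = params.z0_soil

    # full-cover values from the log profile + in-canopy eddy integral
    ustar = k * u / math.log((z_ref - d) / z0)
    k_h = k * ustar * (h_c - d)
    r_aa_full = math.log((z_ref - d) / (h_c - d)) / (k * ustar) + (
        h_c / (n * k_h)
    ) * (math.exp(n * (1.0 - (z0 + d) / h_c)) - 1.0)
    r_as_full = (h_c * math.exp(n) / (n * k_h)) * (
        math.exp(-n * z0s / h_c) - math.exp(-n * (z0 + d) / h_c)
    )

    # bare-substrate limit: total log-law resistance split at d + z0
    log_total = math.log(z_ref / z0s)
    r_as_bare = log_total * math.log((d + z0) / z0s) / (k * k * u)
    r_aa_bare = log_total * math.log(z_ref / (d + z0)) / (k * k * u)

    w = min(lai / 4.0, 1.0)
    r_aa = w * r_aa_full + (1.0 - w) * r_aa_bare
    r_as = w * r_as_full + (1.0 - w) * r_as_bare

    if lai == 0.0:
        return r_aa, math.inf, r_as

    # leaf boundary layer from wind at canopy top
    u_h = max((ustar / k) * math.log((h_c - d) / z0), WIND_FLOOR)
    r_b = (
        n
        * math.sqrt(params.leaf_dimension / u_h)
        / (LEAF_TRANSFER_COEFF * (1.0 - math.exp(-n / 2.0)))
    )
    r_ac = r_b / (2.0 * lai)
    return r_aa, r_ac, r_as
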