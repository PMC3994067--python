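"""Dual-source combination equations for latent heat flux.

The canopy and the soil surface are two sources in series-parallel with
the atmosphere.  Total latent heat flux is a weighted sum of two
Penman-Monteith-like terms,

    lambda_ET = C_c PM_c + C_s PM_s,

after Shuttleworth & Wallace.  The vapour pressure deficit at the
in-canopy source height (``D_o``) then partitions the total into canopy
transpiration and soil evaporation, and the same algebra can be
inverted to recover the canopy stomatal resistance from a measured
flux.

Sign conventions: fluxes in W m-2, positive upward; negative component
fluxes (dew, condensation) are preserved, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .resistances import ResistanceSet

#: specific heat of air at constant pressure, J kg-1 K-1
CP_AIR = 1013.0
#: ratio of molecular weights of water vapour and dry air
EPSILON = 0.622
#: specific gas constant of dry air, J kg-1 K-1
R_DRY = 287.05


@dataclass(frozen=True)
class ThermoState:
    """Psychrometric state of the air at reference height.

    lambda_v : latent heat of vaporisation, J kg-1
    rho_air  : moist air density, kg m-3
    delta    : slope of the saturation vapour-pressure curve, kPa K-1
    gamma    : psychrometric constant, kPa K-1
    vpd      : vapour pressure deficit, kPa
    """

    t_air: float
    pressure: float
    e_sat: float
    e_act: float
    vpd: float
    delta: float
    gamma: float
    lambda_v: float
    rho_air: float
    c_p: float = CP_AIR


def saturation_vapor_pressure(t_celsius: float) -> float:
    """Saturation vapour pressure (kPa), Tetens/FAO-56 form."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def thermo_state(t_air: float, rh: float, pressure: float) -> ThermoState:
    """Psychrometric quantities from air temperature, RH and pressure.

    Standard FAO-56 formulas: Tetens saturation curve and its slope,
    ``gamma = c_p P / (0.622 lambda)`` with a temperature-dependent
    latent heat, and moist-air density from the ideal gas law with
    virtual temperature.
    """
    if not -20.0 <= t_air <= 50.0:
        raise ValueError("air temperature outside [-20, 50] degC")
    if not 0.0 < rh <= 100.0:
        raise ValueError("relative humidity must be in (0, 100]")
    if pressure <= 0.0:
        raise ValueError("pressure must be positive")
    e_s = saturation_vapor_pressure(t_air)
    e_a = e_s * rh / 100.0
    delta = 4098.0 * e_s / (t_air + 237.3) ** 2
    lambda_v = (2.501 - 0.002361 * t_air) * 1e6
    gamma = CP_AIR * pressure / (EPSILON * lambda_v / 1000.0) / 1000.0
    t_k = t_air + 273.15
    t_virtual = t_k / (1.0 - 0.378 * e_a / pressure)
    rho = 1000.0 * pressure / (R_DRY * t_virtual)
    return ThermoState(
        t_air=t_air,
        pressure=pressure,
        e_sat=e_s,
        e_act=e_a,
        vpd=e_s - e_a,
        delta=delta,
        gamma=gamma,
        lambda_v=lambda_v,
        rho_air=rho,
    )


@dataclass(frozen=True)
class FluxResult:
    """Latent heat flux and its partition (W m-2)."""

    lambda_et: float
    lambda_tc: float
    lambda_es: float
    pm_c: float
    pm_s: float
    weight_c: float
    weight_s: float
    d_o: float


def _weights(delta: float, gamma: float, res: ResistanceSet) -> tuple[float, float]:
    """The source weights C_c, C_s of the combination equation.

    Written to stay finite when r_sc or r_ss is infinite (a closed
    canopy or sealed-soil path): the corresponding branch resistance
    becomes infinite and the weight ratios are taken in the limit.
    """
    dg = delta + gamma
    r_a = dg * res.r_aa
    r_c = dg * res.r_ac + gamma * res.r_sc
    r_s = dg * res.r_as + gamma * res.r_ss

    if math.isinf(r_c) and math.isinf(r_s):
        return 0.0, 0.0
    if math.isinf(r_c):
        c_c = 1.0 / (1.0 + r_a / r_s)
        c_s = 1.0
    elif math.isinf(r_s):
        c_c = 1.0
        c_s = 1.0 / (1.0 + r_a / r_c)
    else:
        c_c = 1.0 / (1.0 + r_c * r_a / (r_s * (r_c + r_a)))
        c_s = 1.0 / (1.0 + r_s * r_a / (r_c * (r_s + r_a)))
    return c_c, c_s


def sw_total_et(ae, thermo: ThermoState, res: ResistanceSet) -> FluxResult:
    """Total latent heat flux from the two-source combination equation.

    ``ae`` is an available-energy record with ``total`` (A) and
    ``soil`` (A_s) members.  Returns a partial :class:`FluxResult`
    (components and D_o are filled by :func:`partition_fluxes`).
    """
    d, g = thermo.delta, thermo.gamma
    rho_cp = thermo.rho_air * thermo.c_p
    a, a_s = ae.total, ae.soil

    raa_rac = res.r_aa + res.r_ac
    if math.isinf(res.r_sc) or math.isinf(raa_rac):
        pm_c = 0.0
    else:
        pm_c = (d * a + (rho_cp * thermo.vpd - d * res.r_ac * a_s) / raa_rac) / (
            d + g * (1.0 + res.r_sc / raa_rac)
        )
    raa_ras = res.r_aa + res.r_as
    if math.isinf(res.r_ss):
        pm_s = 0.0
    else:
        pm_s = (d * a + (rho_cp * thermo.vpd - d * res.r_as * (a - a_s)) / raa_ras) / (
            d + g * (1.0 + res.r_ss / raa_ras)
        )
    c_c, c_s = _weights(d, g, res)
    lam_et = c_c * pm_c + c_s * pm_s
    return FluxResult(
        lambda_et=lam_et,
        lambda_tc=math.nan,
        lambda_es=math.nan,
        pm_c=pm_c,
        pm_s=pm_s,
        weight_c=c_c,
        weight_s=c_s,
        d_o=math.nan,
    )


def canopy_source_vpd(lambda_et: float, ae, thermo: ThermoState, r_aa: float) -> float:
    """Vapour pressure deficit at the canopy source height (kPa).

    ``D_o = VPD + (Delta A - (Delta + gamma) lambda_ET) r_aa / (rho c_p)``;
    equals the reference-height VPD when r_aa vanishes or when the flux
    is at its equilibrium value.
    """
    rho_cp = thermo.rho_air * thermo.c_p
    return thermo.vpd + (thermo.delta * ae.total - (thermo.delta + thermo.gamma) * lambda_et) * r_aa / rho_cp


def partition_fluxes(
    d_o: float, ae, thermo: ThermoState, res: ResistanceSet, lambda_et: float | None = None
) -> tuple[float, float]:
    """Partition the total flux into canopy transpiration and soil evaporation.

    Penman-Monteith forms driven by the canopy-source VPD:

    ``lambda_Tc = [Delta (A - A_s) + rho c_p D_o / r_ac] /
    [Delta + gamma (1 + r_sc / r_ac)]`` and the analogous soil term
    with ``A_s``, ``r_as`` and ``r_ss``.  When ``lambda_et`` is given,
    the analytic identity ``lambda_Tc + lambda_Es == lambda_ET`` is
    checked to 1e-3 relative and violated states raise.
    """
    d, g = thermo.delta, thermo.gamma
    rho_cp = thermo.rho_air * thermo.c_p
    a, a_s = ae.total, ae.soil

    if math.isinf(res.r_sc) or math.isinf(res.r_ac):
        lam_tc = 0.0
    else:
        lam_tc = (d * (a - a_s) + rho_cp * d_o / res.r_ac) / (
            d + g * (1.0 + res.r_sc / res.r_ac)
        )
    if math.isinf(res.r_ss):
        lam_es = 0.0
    else:
        lam_es = (d * a_s + rho_cp * d_o / res.r_as) / (d + g * (1.0 + res.r_ss / res.r_as))

    if lambda_et is not None:
        scale = max(abs(lambda_et), 1.0)
        if abs(lam_tc + lam_es - lambda_et) > 1e-3 * scale:
            raise ArithmeticError(
                f"flux partition inconsistent: Tc+Es={lam_tc + lam_es:.6f} vs ET={lambda_et:.6f}"
            )
    return lam_tc, lam_es


def sw_fluxes(ae, thermo: ThermoState, res: ResistanceSet) -> FluxResult:
    """Full forward model: total flux, source VPD and the partition."""
    partial = sw_total_et(ae, thermo, res)
    d_o = canopy_source_vpd(partial.lambda_et, ae, thermo, res.r_aa)
    lam_tc, lam_es = partition_fluxes(d_o, ae, thermo, res, lambda_et=partial.lambda_et)
    return FluxResult(
        lambda_et=partial.lambda_et,
        lambda_tc=lam_tc,
        lambda_es=lam_es,
        pm_c=partial.pm_c,
        pm_s=partial.pm_s,
        weight_c=partial.weight_c,
        weight_s=partial.weight_s,
        d_o=d_o,
    )


def invert_gsc(
    lambda_et_measured: float,
    ae,
    thermo: ThermoState,
    r_aa: float,
    r_ac: float,
    r_as: float,
    r_ss: float,
    use_measured_vpd: bool = False,
) -> float | None:
    """Canopy conductance (mm s-1) inverted from a measured flux.

    The coupled system is triangular: the source VPD depends only on
    the measured total flux, the soil evaporation only on the source
    VPD, and the stomatal resistance follows from the transpiration
    equation, so the solve is direct.  ``use_measured_vpd=True``
    substitutes the reference-height VPD for the source VPD instead.

    Returns None (flagged missing) when the implied transpiration is
    not positive - e.g. at night - where the conductance is undefined.
    """
    d, g = thermo.delta, thermo.gamma
    rho_cp = thermo.rho_air * thermo.c_p
    if use_measured_vpd:
        d_o = thermo.vpd
    else:
        d_o = canopy_source_vpd(lambda_et_measured, ae, thermo, r_aa)
    lam_es = (d * ae.soil + rho_cp * d_o / r_as) / (d + g * (1.0 + r_ss / r_as))
    lam_tc = lambda_et_measured - lam_es
    if lam_tc <= 0.0:
        return None
    r_sc = (r_ac / g) * ((d * (ae.total - ae.soil) + rho_cp * d_o / r_ac) / lam_tc - d - g)
    if r_sc <= 0.0:
        return None
    return 1000.0 / r_sc
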