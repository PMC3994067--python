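"""Half-hourly simulation driver and the model sensitivity tables.

Chains the component modules for each forcing record: solar geometry ->
beam/diffuse split -> canopy absorption -> stomatal upscaling ->
resistances -> two-source combination -> flux partition.  Also provides
the two sensitivity analyses the model is usually examined with: the
big-leaf vs dual-leaf conductance comparison over an irradiance sweep,
and the clear-sky diurnal course of absorption, sunlit/shaded leaf area
and conductance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import RunConfig
from .forcing import generate_clearsky_forcing
from .radiation import (
    AvailableEnergy,
    available_energy,
    canopy_absorption,
    derive_optics,
    night_absorption,
)
from .resistances import (
    ResistanceSet,
    aerodynamic_resistances,
    conductance_to_resistance,
    soil_surface_resistance,
    wind_to_reference,
)
from .solar import diffuse_fraction, night_incident, partition_incident, solar_zenith
from .stomatal import SoilMoistureState, canopy_conductance, selected_gsc
from .sw import invert_gsc, sw_fluxes, thermo_state


def _step(row, config: RunConfig, day_of_year: int) -> dict:
    """One half-hour of the full model chain; returns a result row."""
    cfg = config
    state = solar_zenith(cfg.site, day_of_year, float(row["solar_time"]))
    thermo = thermo_state(float(row["t_air"]), float(row["rh"]), float(row["pressure"]))
    lai = float(row["lai"])
    h_c = float(row["h_c"])

    if state.sun_up:
        f_d = diffuse_fraction(cfg.optics.tau_a, cfg.optics.f_a, state.air_mass)
        inc = partition_incident(float(row["q_par"]), f_d)
        optics = derive_optics(
            cfg.optics.leaf_absorptivity, cfg.optics.g_l, cfg.optics.kappa_d, state.zenith_deg
        )
        absorption = canopy_absorption(lai, optics, inc)
        kappa_r = optics.kappa_r
    else:
        inc = night_incident()
        absorption = night_absorption(lai)
        kappa_r = cfg.optics.kappa_d  # beam geometry undefined at night

    moist = SoilMoistureState(
        theta=float(row["theta"]),
        theta_field=cfg.theta_field,
        theta_wilt=cfg.theta_wilt,
        theta_surface=float(row["theta_g"]),
        theta_sat=cfg.theta_sat,
    )
    cond = canopy_conductance(
        absorption, thermo.vpd, moist.extractable, cfg.stomatal, model=cfg.conductance_model
    )
    g_sc = selected_gsc(cond, cfg.conductance_model)

    u_ref, _ = wind_to_reference(float(row["wind"]), cfg.wind_height, h_c, cfg.aero)
    r_aa, r_ac, r_as = aerodynamic_resistances(u_ref, h_c, lai, cfg.aero)
    res = ResistanceSet(
        r_aa=r_aa,
        r_ac=r_ac,
        r_as=r_as,
        r_sc=conductance_to_resistance(g_sc),
        r_ss=soil_surface_resistance(moist.theta_surface, moist.theta_sat, cfg.soil_resistance),
    )
    ae = available_energy(float(row["r_n"]), float(row["g_soil"]), kappa_r, lai)
    flux = sw_fluxes(ae, thermo, res)
    return {
        "solar_time": row["solar_time"],
        "zenith_deg": state.zenith_deg,
        "sun_up": state.sun_up,
        "q_par": inc.total,
        "diffuse_fraction": inc.diffuse_fraction,
        "q_canopy": absorption.q_canopy,
        "q_sunlit": absorption.q_sunlit,
        "q_shaded": absorption.q_shaded,
        "lai_sunlit": absorption.lai_sunlit,
        "lai_shaded": absorption.lai_shaded,
        "gsc_bigleaf": cond.g_canopy_bigleaf,
        "gsc_dualleaf": cond.g_canopy_dualleaf,
        "gsc_sunlit": cond.g_canopy_sunlit,
        "gsc_shaded": cond.g_canopy_shaded,
        "vpd": thermo.vpd,
        "d_o": flux.d_o,
        "r_aa": res.r_aa,
        "r_ac": res.r_ac,
        "r_as": res.r_as,
        "r_sc": res.r_sc,
        "r_ss": res.r_ss,
        "available_energy": ae.total,
        "available_energy_soil": ae.soil,
        "lambda_et": flux.lambda_et,
        "lambda_tc": flux.lambda_tc,
        "lambda_es": flux.lambda_es,
        "weight_canopy": flux.weight_c,
        "weight_soil": flux.weight_s,
    }


def simulate(forcing: pd.DataFrame, config: RunConfig, day_of_year: int) -> pd.DataFrame:
    """Run the full model over a half-hourly forcing table."""
    rows = [_step(row, config, day_of_year) for _, row in forcing.iterrows()]
    return pd.DataFrame(rows)


def simulate_clearsky_day(
    config: RunConfig, day_of_year: int, lai: float, h_c: float, **forcing_kwargs
) -> pd.DataFrame:
    """Generate synthetic clear-sky forcing and run the model over it."""
    forcing = generate_clearsky_forcing(
        config.site,
        day_of_year,
        lai,
        h_c,
        tau_a=config.optics.tau_a,
        f_a=config.optics.f_a,
        **forcing_kwargs,
    )
    return simulate(forcing, config, day_of_year)


def invert_conductance(
    forcing: pd.DataFrame,
    lambda_et_measured,
    config: RunConfig,
    day_of_year: int,
) -> pd.DataFrame:
    """Recover canopy conductance from measured fluxes, row by row.

    Rows whose implied transpiration is not positive (night,
    condensation) get a missing conductance.
    """
    results = simulate(forcing, config, day_of_year)
    measured = np.asarray(lambda_et_measured, dtype=float)
    if measured.shape[0] != len(results):
        raise ValueError("measured flux series must match the forcing length")
    g_out = []
    for (_, row), (_, frc), lam in zip(results.iterrows(), forcing.iterrows(), measured):
        thermo = thermo_state(float(frc["t_air"]), float(frc["rh"]), float(frc["pressure"]))
        a = float(row["available_energy"])
        a_s = float(row["available_energy_soil"])
        ae = AvailableEnergy(
            r_n=float(frc["r_n"]), r_ns=a_s + float(frc["g_soil"]), g=float(frc["g_soil"]),
            total=a, soil=a_s,
        )
        g = invert_gsc(
            float(lam),
            ae,
            thermo,
            float(row["r_aa"]),
            float(row["r_ac"]),
            float(row["r_as"]),
            float(row["r_ss"]),
            use_measured_vpd=(config.inversion_mode == "measured_vpd"),
        )
        g_out.append(math.nan if g is None else g)
    results["gsc_inverted"] = g_out
    return results


def compare_gsc(
    config: RunConfig,
    lai_values,
    q_o_grid,
    zenith_deg: float,
) -> pd.DataFrame:
    """Big-leaf vs dual-leaf conductance over an irradiance sweep.

    No VPD or soil-water stress is applied so the comparison isolates
    the light-upscaling difference.  Returns one row per (LAI, Q_o)
    with both conductances and the relative big-leaf error in percent.
    """
    m_a = (config.site.pressure / 101.325) / math.cos(math.radians(zenith_deg))
    f_d = diffuse_fraction(config.optics.tau_a, config.optics.f_a, m_a)
    optics = derive_optics(
        config.optics.leaf_absorptivity, config.optics.g_l, config.optics.kappa_d, zenith_deg
    )
    rows = []
    for lai in lai_values:
        for q_o in q_o_grid:
            absorption = canopy_absorption(float(lai), optics, partition_incident(float(q_o), f_d))
            cond = canopy_conductance(absorption, 0.0, 1.0, config.stomatal)
            g1, g2 = cond.g_canopy_bigleaf, cond.g_canopy_dualleaf
            rows.append(
                {
                    "lai": float(lai),
                    "q_o": float(q_o),
                    "zenith_deg": zenith_deg,
                    "diffuse_fraction": f_d,
                    "gsc_bigleaf": g1,
                    "gsc_dualleaf": g2,
                    "rel_error_pct": 100.0 * (g1 - g2) / g2 if g2 > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def max_bigleaf_overestimation(
    config: RunConfig,
    lai: float,
    q_o_grid,
    zenith_scan,
) -> dict:
    """Peak big-leaf overestimation over an irradiance sweep and zenith scan.

    For each zenith in the scan, find the maximum of the relative
    big-leaf error over the irradiance grid; report the largest such
    peak, the irradiance where it occurs, and the per-zenith table.
    """
    per_zenith = []
    for zen in zenith_scan:
        table = compare_gsc(config, [lai], q_o_grid, float(zen))
        valid = table.dropna(subset=["rel_error_pct"])
        i = valid["rel_error_pct"].idxmax()
        per_zenith.append(
            {
                "zenith_deg": float(zen),
                "max_overestimation_pct": float(valid.loc[i, "rel_error_pct"]),
                "q_o_at_max": float(valid.loc[i, "q_o"]),
            }
        )
    per_zenith = pd.DataFrame(per_zenith)
    j = per_zenith["max_overestimation_pct"].idxmax()
    return {
        "max_overestimation_pct": float(per_zenith.loc[j, "max_overestimation_pct"]),
        "q_o_at_max": float(per_zenith.loc[j, "q_o_at_max"]),
        "zenith_at_max": float(per_zenith.loc[j, "zenith_deg"]),
        "per_zenith": per_zenith,
    }


def diurnal_table(config: RunConfig, day_of_year: int, lai: float, h_c: float = 2.0) -> pd.DataFrame:
    """Clear-sky diurnal course of absorption, leaf area and conductance.

    Columns include the whole-canopy and sunlit/shaded absorbed PAR,
    sunlit/shaded LAI, and both canopy conductances; the daytime
    sunlit share of absorbed PAR is attached as ``DataFrame.attrs``.
    """
    results = simulate_clearsky_day(config, day_of_year, lai, h_c)
    day = results[results["sun_up"]]
    q_c = day["q_canopy"].sum()
    results.attrs["daytime_sunlit_share_pct"] = (
        100.0 * day["q_sunlit"].sum() / q_c if q_c > 0 else math.nan
    )
    return results


def sunlit_share_clearsky(config: RunConfig, day_of_year: int, lai: float) -> float:
    """Daytime share (%) of canopy-absorbed PAR taken by sunlit leaves.

    The share is the ratio of the daytime sums (the energy share), on a
    synthetic clear-sky day generated for the configured site.
    """
    table = diurnal_table(config, day_of_year, lai)
    return float(table.attrs["daytime_sunlit_share_pct"])
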