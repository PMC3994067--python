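"""Jarvis-Stewart leaf stomatal conductance and its canopy upscaling.

Leaf stomatal conductance is the product of a maximum conductance and
three independent stress functions: a rectangular hyperbola in absorbed
PAR, an exponential decline in vapour pressure deficit, and a
saturating rise in extractable root-zone soil water.  Two upscaling
routes to canopy conductance are provided:

* big-leaf: one mean leaf driven by the canopy-mean absorbed
  irradiance, multiplied by an empirical effective LAI;
* dual-leaf: sunlit and shaded leaf populations, each driven by its own
  mean absorbed irradiance and weighted by its own leaf area.

Because the light response is concave, the big-leaf route errs whenever
the light distribution over leaves is uneven; the dual-leaf sum is the
better approximation to a full multilayer integration.

Conductances are in mm s-1 throughout (resistance s m-1 = 1000 / g).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .radiation import CanopyAbsorption

#: quantum-to-energy conversion for PAR: 1 W m-2 = 4.57 umol m-2 s-1
UMOL_PER_W = 4.57

#: leaf-area fractions below this are dropped to avoid 0/0 mean irradiance
TINY_LAI = 1e-9


@dataclass(frozen=True)
class StomatalParams:
    """Jarvis-Stewart parameters.

    g_smax : maximum leaf stomatal conductance, mm s-1
    k_q    : half-saturation of the light response, W m-2 (absorbed PAR)
    k_d    : VPD sensitivity, kPa-1
    k_w    : soil-water sensitivity, dimensionless
    vpd_form : "exponential" (default) or "inverse" for F_D
    """

    g_smax: float = 7.5
    k_q: float = 150.0
    k_d: float = 0.2
    k_w: float = 7.5
    vpd_form: str = "exponential"

    def __post_init__(self) -> None:
        if min(self.g_smax, self.k_q, self.k_d, self.k_w) <= 0.0:
            raise ValueError("all stomatal parameters must be strictly positive")
        if self.vpd_form not in ("exponential", "inverse"):
            raise ValueError("vpd_form must be 'exponential' or 'inverse'")


@dataclass(frozen=True)
class SoilMoistureState:
    """Root-zone and surface soil moisture (m3 m-3)."""

    theta: float
    theta_field: float = 0.30
    theta_wilt: float = 0.12
    theta_surface: float = 0.25
    theta_sat: float = 0.42

    def __post_init__(self) -> None:
        if self.theta_wilt >= self.theta_field:
            raise ValueError("wilting point must be below field capacity")

    @property
    def extractable(self) -> float:
        """Extractable soil water fraction, clipped to [0, 1]."""
        raw = (self.theta - self.theta_wilt) / (self.theta_field - self.theta_wilt)
        return min(max(raw, 0.0), 1.0)


@dataclass(frozen=True)
class ConductanceResult:
    """Leaf and canopy conductances from both upscaling routes (mm s-1)."""

    g_leaf_bigleaf: float = math.nan
    g_canopy_bigleaf: float = math.nan
    g_leaf_sunlit: float = math.nan
    g_leaf_shaded: float = math.nan
    g_canopy_sunlit: float = math.nan
    g_canopy_shaded: float = math.nan
    g_canopy_dualleaf: float = math.nan
    lai_effective: float = math.nan


def stress_light(q_absorbed, k_q: float):
    """Light stress function: rectangular hyperbola ``Q / (Q + k_q)``."""
    q = np.asarray(q_absorbed, dtype=float)
    if np.any(q < 0.0):
        raise ValueError("absorbed PAR must be nonnegative")
    out = q / (q + k_q)
    return float(out) if np.isscalar(q_absorbed) or q.ndim == 0 else out


def stress_vpd(vpd, k_d: float, form: str = "exponential"):
    """VPD stress function, ``exp(-k_d VPD)`` or ``1/(1 + k_d VPD)``."""
    d = np.asarray(vpd, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("VPD must be nonnegative")
    if form == "exponential":
        out = np.exp(-k_d * d)
    elif form == "inverse":
        out = 1.0 / (1.0 + k_d * d)
    else:
        raise ValueError("form must be 'exponential' or 'inverse'")
    return float(out) if np.isscalar(vpd) or d.ndim == 0 else out


def stress_soil(theta_e, k_w: float):
    """Soil-water stress: normalised saturating exponential.

    ``F_w = (1 - exp(-k_w theta_E)) / (1 - exp(-k_w))`` so that
    ``F_w(1) = 1`` exactly; with ``k_w = 7.5`` the function is within a
    few percent of saturation by 50% extractable water, reproducing the
    usual crop-stress threshold at half of total available water.
    """
    t = np.asarray(theta_e, dtype=float)
    if np.any((t < 0.0) | (t > 1.0)):
        warnings.warn("extractable soil water outside [0, 1] clipped", stacklevel=2)
        t = np.clip(t, 0.0, 1.0)
    out = (1.0 - np.exp(-k_w * t)) / (1.0 - math.exp(-k_w))
    return float(out) if np.isscalar(theta_e) or t.ndim == 0 else out


def leaf_gs(q_absorbed, vpd, theta_e, params: StomatalParams):
    """Leaf stomatal conductance (mm s-1): ``g_smax F_Q F_D F_w``."""
    return (
        params.g_smax
        * stress_light(q_absorbed, params.k_q)
        * stress_vpd(vpd, params.k_d, params.vpd_form)
        * stress_soil(theta_e, params.k_w)
    )


def effective_lai(lai: float) -> float:
    """Empirical effective LAI for the big-leaf model.

    Equal to LAI up to 2, half the LAI above 4, and 2.0 in between.
    """
    if lai < 0.0:
        raise ValueError("LAI must be nonnegative")
    if lai <= 2.0:
        return lai
    if lai >= 4.0:
        return lai / 2.0
    return 2.0


def bigleaf_gsc(
    absorption: CanopyAbsorption,
    vpd: float,
    theta_e: float,
    params: StomatalParams,
    mean_irradiance: str = "per_lai",
) -> ConductanceResult:
    """Big-leaf canopy conductance.

    The mean leaf is driven by the canopy-mean absorbed irradiance
    (whole-canopy absorbed PAR divided by total LAI, or by the
    effective LAI when ``mean_irradiance="per_lai_e"``), then scaled by
    the effective LAI.
    """
    lai = absorption.lai
    lai_e = effective_lai(lai)
    if lai <= TINY_LAI:
        return ConductanceResult(g_leaf_bigleaf=0.0, g_canopy_bigleaf=0.0, lai_effective=lai_e)
    if mean_irradiance == "per_lai":
        q_mean = absorption.q_canopy / lai
    elif mean_irradiance == "per_lai_e":
        q_mean = absorption.q_canopy / lai_e
    else:
        raise ValueError("mean_irradiance must be 'per_lai' or 'per_lai_e'")
    g_leaf = leaf_gs(q_mean, vpd, theta_e, params)
    return ConductanceResult(
        g_leaf_bigleaf=g_leaf,
        g_canopy_bigleaf=g_leaf * lai_e,
        lai_effective=lai_e,
    )


def dualleaf_gsc(
    absorption: CanopyAbsorption,
    vpd: float,
    theta_e: float,
    params: StomatalParams,
) -> ConductanceResult:
    """Dual-leaf canopy conductance: sunlit + shaded contributions.

    ``G_sc = g_sl LAI_sl + g_sh LAI_sh`` with each mean leaf driven by
    its fraction's mean absorbed irradiance.  Fractions with negligible
    leaf area contribute zero.
    """
    lai_sl, lai_sh = absorption.lai_sunlit, absorption.lai_shaded
    if lai_sl + lai_sh <= TINY_LAI:
        return ConductanceResult(
            g_leaf_sunlit=0.0,
            g_leaf_shaded=0.0,
            g_canopy_sunlit=0.0,
            g_canopy_shaded=0.0,
            g_canopy_dualleaf=0.0,
        )
    if lai_sl > TINY_LAI:
        g_sl = leaf_gs(absorption.q_sunlit / lai_sl, vpd, theta_e, params)
        contrib_sl = g_sl * lai_sl
    else:
        g_sl, contrib_sl = 0.0, 0.0
    if lai_sh > TINY_LAI:
        g_sh = leaf_gs(absorption.q_shaded / lai_sh, vpd, theta_e, params)
        contrib_sh = g_sh * lai_sh
    else:
        g_sh, contrib_sh = 0.0, 0.0
    return ConductanceResult(
        g_leaf_sunlit=g_sl,
        g_leaf_shaded=g_sh,
        g_canopy_sunlit=contrib_sl,
        g_canopy_shaded=contrib_sh,
        g_canopy_dualleaf=contrib_sl + contrib_sh,
    )


def canopy_conductance(
    absorption: CanopyAbsorption,
    vpd: float,
    theta_e: float,
    params: StomatalParams,
    model: str = "dualleaf",
) -> ConductanceResult:
    """Both upscaling routes in one result; ``model`` picks the headline one."""
    big = bigleaf_gsc(absorption, vpd, theta_e, params)
    dual = dualleaf_gsc(absorption, vpd, theta_e, params)
    if model not in ("bigleaf", "dualleaf"):
        raise ValueError("model must be 'bigleaf' or 'dualleaf'")
    return ConductanceResult(
        g_leaf_bigleaf=big.g_leaf_bigleaf,
        g_canopy_bigleaf=big.g_canopy_bigleaf,
        g_leaf_sunlit=dual.g_leaf_sunlit,
        g_leaf_shaded=dual.g_leaf_shaded,
        g_canopy_sunlit=dual.g_canopy_sunlit,
        g_canopy_shaded=dual.g_canopy_shaded,
        g_canopy_dualleaf=dual.g_canopy_dualleaf,
        lai_effective=big.lai_effective,
    )


def selected_gsc(result: ConductanceResult, model: str) -> float:
    """The canopy conductance of the selected upscaling route."""
    return result.g_canopy_bigleaf if model == "bigleaf" else result.g_canopy_dualleaf


def fit_jarvis_params(
    light_curve,
    diurnal_obs,
    vpd_form: str = "exponential",
) -> tuple[StomatalParams, dict]:
    """Two-stage nonlinear least-squares fit of the Jarvis-Stewart model.

    Stage 1 fits ``(g_smax, k_q)`` to a light-response curve of
    ``(Q_absorbed, g_s)`` pairs measured at low VPD and ample soil
    water.  Stage 2 fixes those and fits ``(k_d, k_w)`` to diurnal
    observations of ``(Q, VPD, theta_E, g_s)``.

    Parameters
    ----------
    light_curve : array-like, shape (n, 2)
        Columns Q (W m-2) and g_s (mm s-1); n >= 4.
    diurnal_obs : array-like, shape (m, 4)
        Columns Q, VPD (kPa), theta_E, g_s; m >= 6.

    Returns
    -------
    (StomatalParams, dict)
        Fitted parameters and a diagnostics dict with the residual sum
        of squares of each stage.
    """
    lc = np.asarray(light_curve, dtype=float)
    di = np.asarray(diurnal_obs, dtype=float)
    if lc.ndim != 2 or lc.shape[0] < 4 or lc.shape[1] != 2:
        raise ValueError("light curve needs >= 4 rows of (Q, g_s)")
    if di.ndim != 2 or di.shape[0] < 6 or di.shape[1] != 4:
        raise ValueError("diurnal data needs >= 6 rows of (Q, VPD, theta_E, g_s)")
    q1, gs1 = lc[:, 0], lc[:, 1]
    if np.ptp(q1) == 0.0 or np.ptp(gs1) == 0.0:
        raise ValueError("degenerate (constant) light-curve input")

    def hyperbola(q, g_smax, k_q):
        return g_smax * q / (q + k_q)

    p0 = [max(gs1.max(), 1e-3), max(np.median(q1), 1.0)]
    try:
        (g_smax, k_q), _ = curve_fit(
            hyperbola, q1, gs1, p0=p0, bounds=([1e-6, 1e-6], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"light-curve fit did not converge: {err}") from err
    rss1 = float(np.sum((hyperbola(q1, g_smax, k_q) - gs1) ** 2))

    q2, vpd2, th2, gs2 = di[:, 0], di[:, 1], di[:, 2], di[:, 3]
    if np.ptp(gs2) == 0.0:
        raise ValueError("degenerate (constant) diurnal input")

    def diurnal_model(x, k_d, k_w):
        q, vpd, th = x
        fq = q / (q + k_q)
        fd = np.exp(-k_d * vpd) if vpd_form == "exponential" else 1.0 / (1.0 + k_d * vpd)
        fw = (1.0 - np.exp(-k_w * th)) / (1.0 - np.exp(-k_w))
        return g_smax * fq * fd * fw

    try:
        (k_d, k_w), _ = curve_fit(
            diurnal_model,
            (q2, vpd2, th2),
            gs2,
            p0=[0.1, 5.0],
            bounds=([1e-6, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"diurnal fit did not converge: {err}") from err
    rss2 = float(np.sum((diurnal_model((q2, vpd2, th2), k_d, k_w) - gs2) ** 2))

    params = StomatalParams(
        g_smax=float(g_smax), k_q=float(k_q), k_d=float(k_d), k_w=float(k_w), vpd_form=vpd_form
    )
    return params, {"rss_light_curve": rss1, "rss_diurnal": rss2}
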