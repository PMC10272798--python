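"""Static arterial mechanics under a pressurized cuff.

The brachial artery segment under the cuff is treated as a collapsible tube
whose luminal cross-sectional area follows a nonlinear tube law in transmural
pressure ``Ptm`` (arterial pressure minus cuff pressure, mmHg):

    A(Ptm) = d * [ln(a*Ptm + 3.3)]^(1 + exp(-c*Ptm))        [cm^2]

with collapse parameters ``a`` (collapse slope, mmHg^-1), ``c`` (collapse
steepness, mmHg^-1) and ``d`` (area scale).  From the area follow the
Poiseuille flow resistance of the cuffed segment, the local area compliance
dA/dPtm, the Bramwell-Hill pulse wave velocity and segment transit times.

All functions broadcast over numpy arrays of transmural pressure and over
arrays of tube-law parameters (for vectorized batch simulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TubeLawParams",
    "BloodProperties",
    "ArmGeometry",
    "A_MIN_CM2",
    "R_MAX",
    "MMHG_TO_PA",
    "luminal_area",
    "area_compliance",
    "elastic_compliance",
    "poiseuille_resistance",
    "pulse_wave_velocity",
    "segment_transit_time",
    "is_transmitting",
]

#: Pascal per mmHg.
MMHG_TO_PA = 133.322

#: Area floor (cm^2) applied once the tube law collapses or becomes undefined.
A_MIN_CM2 = 1e-6

#: Resistance cap (mmHg*s/mL) representing a fully occluded segment.
R_MAX = 1e9

#: Central-difference step (mmHg) for the area compliance.
_COMPLIANCE_H = 0.01


def _positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class TubeLawParams:
    """Collapse parameters of the arterial pressure-area law."""

    a: float = 0.03  # mmHg^-1
    c: float = 0.1  # mmHg^-1
    d: float = 0.08  # area scale (reported in cm; area is treated as cm^2)

    def __post_init__(self) -> None:
        _positive("a", self.a)
        _positive("c", self.c)
        _positive("d", self.d)


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties used for resistance and wave speed."""

    viscosity_mmHg_s: float = 2.63e-5  # ~3.5 mPa*s
    density_kg_m3: float = 1060.0

    def __post_init__(self) -> None:
        _positive("viscosity", self.viscosity_mmHg_s)
        _positive("density", self.density_kg_m3)


@dataclass(frozen=True)
class ArmGeometry:
    """Arm and cuff lengths (m); the distal segment is their difference."""

    arm_length_m: float = 1.0
    cuff_length_m: float = 0.14

    def __post_init__(self) -> None:
        _positive("arm_length_m", self.arm_length_m)
        _positive("cuff_length_m", self.cuff_length_m)
        if not np.all(np.asarray(self.cuff_length_m) < np.asarray(self.arm_length_m)):
            raise ValueError("cuff_length_m must be smaller than arm_length_m")

    @property
    def distal_length_m(self) -> float:
        return self.arm_length_m - self.cuff_length_m


def luminal_area(ptm, params: TubeLawParams | None = None, *, a=None, c=None, d=None):
    """Luminal cross-sectional area (cm^2) at transmural pressure ``ptm`` (mmHg).

    Out-of-domain arguments (log argument <= 1, i.e. deep collapse) clamp to
    ``A_MIN_CM2`` rather than raising, so the ODE right-hand side stays finite.
    """
    if params is not None:
        a, c, d = params.a, params.c, params.d
    ptm = np.asarray(ptm, dtype=float)
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)

    u = a * ptm + 3.3
    safe_u = np.where(u > 1.0, u, np.e)  # placeholder where collapsed
    with np.errstate(over="ignore", under="ignore"):
        expo = 1.0 + np.exp(-c * ptm)
        area = d * np.log(safe_u) ** expo
    area = np.where(u > 1.0, area, A_MIN_CM2)
    area = np.maximum(area, A_MIN_CM2)
    if area.ndim == 0:
        return float(area)
    return area


def area_compliance(ptm, params: TubeLawParams | None = None, *, a=None, c=None, d=None):
    """dA/dPtm (cm^2/mmHg) by central finite difference (step 0.01 mmHg).

    The tube-law clamp applies inside the stencil, so the compliance is exactly
    zero on the flat collapsed floor.
    """
    h = _COMPLIANCE_H
    hi = luminal_area(np.asarray(ptm, dtype=float) + h, params, a=a, c=c, d=d)
    lo = luminal_area(np.asarray(ptm, dtype=float) - h, params, a=a, c=c, d=d)
    comp = (np.asarray(hi) - np.asarray(lo)) / (2.0 * h)
    comp = np.maximum(comp, 0.0)
    if comp.ndim == 0:
        return float(comp)
    return comp


def elastic_compliance(ptm, params: TubeLawParams | None = None, *, a=None, c=None, d=None):
    """Elastic (fast) area compliance dA/dPtm (cm^2/mmHg) at fixed collapse state.

    Differentiates the tube law holding the collapse exponent
    E = 1 + exp(-c*Ptm) fixed:

        dA/dP|_E = d * E * a * ln(u)^(E-1) / u,    u = a*Ptm + 3.3.

    The exponent's own pressure dependence describes the slow, quasi-static
    change of the collapse state; the elastic response the pressure pulse
    rides on is the wall stiffness at the current state.  Unlike the full
    derivative of the tube law (which is negative in a narrow band around
    zero transmural pressure), this quantity is strictly positive wherever
    the tube is open, which makes the wave speed well defined and monotone.
    Zero where the tube is collapsed (u <= 1).
    """
    if params is not None:
        a, c, d = params.a, params.c, params.d
    ptm = np.asarray(ptm, dtype=float)
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    u = a * ptm + 3.3
    safe_u = np.where(u > 1.0, u, np.e)
    with np.errstate(over="ignore", under="ignore"):
        expo = 1.0 + np.exp(-c * ptm)
        comp = d * expo * a * np.log(safe_u) ** (expo - 1.0) / safe_u
    comp = np.where(u > 1.0, comp, 0.0)
    if comp.ndim == 0:
        return float(comp)
    return comp


def resistance_from_area(area_cm2, cuff_length_m, viscosity_mmHg_s):
    """Poiseuille resistance (mmHg*s/mL) of the cuffed segment from its area.

    R = 8*eta*L / (pi * r^4) with r = sqrt(A/pi), i.e. R = 8*eta*L*pi / A^2,
    evaluated with L in cm and A in cm^2.  Capped at ``R_MAX``.
    """
    area = np.asarray(area_cm2, dtype=float)
    length_cm = np.asarray(cuff_length_m, dtype=float) * 100.0
    with np.errstate(over="ignore"):
        r = 8.0 * viscosity_mmHg_s * length_cm * np.pi / area**2
    r = np.minimum(r, R_MAX)
    if r.ndim == 0:
        return float(r)
    return r


def poiseuille_resistance(
    ptm,
    geometry: ArmGeometry,
    blood: BloodProperties,
    params: TubeLawParams,
):
    """Flow resistance (mmHg*s/mL) of the artery under the cuff at ``ptm``."""
    area = luminal_area(ptm, params)
    return resistance_from_area(area, geometry.cuff_length_m, blood.viscosity_mmHg_s)


def is_transmitting(ptm, params: TubeLawParams | None = None, *, a=None, c=None, d=None):
    """Whether a pressure pulse can propagate at ``ptm``.

    Propagation requires the area to be above the collapse floor and the local
    compliance to be strictly positive (Bramwell-Hill wave speed defined).
    """
    area = np.asarray(luminal_area(ptm, params, a=a, c=c, d=d))
    comp = np.asarray(elastic_compliance(ptm, params, a=a, c=c, d=d))
    ok = (area > 2.0 * A_MIN_CM2) & (comp > 0.0)
    if ok.ndim == 0:
        return bool(ok)
    return ok


def pulse_wave_velocity(
    ptm,
    params: TubeLawParams | None = None,
    blood: BloodProperties | None = None,
    *,
    a=None,
    c=None,
    d=None,
    density_kg_m3=None,
):
    """Bramwell-Hill pulse wave velocity (m/s) at transmural pressure ``ptm``.

    PWV = sqrt(A * (dP/dA) / rho), with dA/dP the elastic compliance at
    fixed collapse state (:func:`elastic_compliance`), so the speed is
    positive, finite and monotone increasing over the open range and falls
    toward zero as the tube approaches collapse.  Non-transmitting states
    (collapsed area or zero compliance) are signalled as NaN.
    """
    if blood is not None:
        density_kg_m3 = blood.density_kg_m3
    if density_kg_m3 is None:
        density_kg_m3 = BloodProperties().density_kg_m3
    area = np.asarray(luminal_area(ptm, params, a=a, c=c, d=d), dtype=float)
    comp = np.asarray(elastic_compliance(ptm, params, a=a, c=c, d=d), dtype=float)
    ok = (area > 2.0 * A_MIN_CM2) & (comp > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pwv = np.sqrt(area / comp * MMHG_TO_PA / density_kg_m3)
    pwv = np.where(ok, pwv, np.nan)
    if pwv.ndim == 0:
        return float(pwv)
    return pwv


def segment_transit_time(
    ptm,
    length_m,
    params: TubeLawParams | None = None,
    blood: BloodProperties | None = None,
    *,
    a=None,
    c=None,
    d=None,
    density_kg_m3=None,
):
    """Pulse transit time (ms) across a segment of ``length_m`` at ``ptm``.

    NaN where the pulse is non-transmitting; exactly linear in length.
    """
    pwv = pulse_wave_velocity(
        ptm, params, blood, a=a, c=c, d=d, density_kg_m3=density_kg_m3
    )
    t = np.asarray(length_m, dtype=float) / np.asarray(pwv, dtype=float) * 1000.0
    if t.ndim == 0:
        return float(t)
    return t
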