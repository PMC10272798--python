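"""Two-compartment RC circulation of the arm distal to an inflating cuff.

The distal arm is modelled as two lumped compartments — a distal arterial
node (compliance ``C_art``) and a distal venous node (compliance ``C_ven``) —
fed from a sinusoidal systemic arterial pressure through the cuff-compressed
brachial segment (Poiseuille resistance ``R_art(Ptm)`` from the tube law) and
drained through the microvascular resistance ``R_systemic`` into the brachial
vein (resistance ``R_ven(P_cuff)``, collapsing to effectively infinite once
cuff pressure exceeds ~30 mmHg):

    dP_art/dt = [P_sys/R_art - P_art(1/R_art + 1/R_sys) + P_ven/R_sys] / C_art
    dP_ven/dt = [P_art/R_sys - P_ven(1/R_sys + 1/R_ven) + P_ven_sys/R_ven] / C_ven

``R_art`` is re-evaluated every step at the instantaneous transmural
pressure of the cuffed segment, Ptm = P_sys(t) - P_cuff(t): the proximal
(systemic) arterial pressure minus cuff pressure.  Using the proximal
pressure makes the cuffed segment act as a pressure-gated valve during deep
inflation — systolic peaks keep refilling the distal node while diastolic
backflow is blocked — which produces the characteristic flattening of the
distal waveform toward systolic pressure before full occlusion.
Integration is fixed-step explicit Euler; the venous collapse is smoothed
(log-space sigmoid), which keeps the system non-stiff at the default step
of 0.5 ms.

The module provides a scalar :func:`simulate` returning full pressure traces
and a vectorized :func:`simulate_batch` that integrates thousands of
parameter sets simultaneously, reducing each heartbeat to per-beat summary
statistics on the fly (the memory-friendly path used by the sensitivity
analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import (
    A_MIN_CM2,
    R_MAX,
    ArmGeometry,
    BloodProperties,
    TubeLawParams,
)

__all__ = [
    "SystemicInput",
    "CuffProtocol",
    "CircuitParams",
    "SimulationResult",
    "BatchRun",
    "systemic_pressure",
    "cuff_pressure",
    "venous_resistance",
    "equilibrium_closed_form",
    "simulate",
    "simulate_batch",
    "occlusion_time",
]


@dataclass(frozen=True)
class SystemicInput:
    """Systemic drive: sinusoidal arterial pressure plus a fixed venous level."""

    sbp: float = 120.0  # systolic pressure, mmHg
    pp: float = 40.0  # pulse pressure, mmHg
    hr: float = 60.0  # heart rate, beats/min
    p_ven_sys: float = 10.0  # systemic venous pressure, mmHg

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.pp) > 0):
            raise ValueError("pulse pressure must be positive")
        if not np.all(np.asarray(self.sbp) > np.asarray(self.pp)):
            raise ValueError("SBP must exceed PP")
        if not np.all(np.asarray(self.p_ven_sys) >= 0):
            raise ValueError("venous pressure must be non-negative")
        if not np.all(np.asarray(self.dbp) > np.asarray(self.p_ven_sys)):
            raise ValueError("DBP must exceed systemic venous pressure")
        if not np.all(np.asarray(self.hr) > 0):
            raise ValueError("heart rate must be positive")

    @property
    def dbp(self):
        return self.sbp - self.pp

    @property
    def map(self):
        """Beat-averaged pressure of the ideal sinusoid: (SBP + DBP) / 2."""
        return (self.sbp + self.dbp) / 2.0

    @property
    def period_s(self):
        return 60.0 / self.hr


@dataclass(frozen=True)
class CuffProtocol:
    """Linear inflation ramp followed by a hold at maximum pressure."""

    rate_mmHg_s: float = 6.0
    start_s: float = 6.0
    max_pressure_mmHg: float | None = None  # None -> SBP + 50 at run time
    hold_s: float = 60.0

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.rate_mmHg_s) > 0):
            raise ValueError("inflation rate must be positive")
        if self.max_pressure_mmHg is not None and not np.all(
            np.asarray(self.max_pressure_mmHg) > 0
        ):
            raise ValueError("max cuff pressure must be positive")
        if self.hold_s < 0 or self.start_s < 0:
            raise ValueError("start and hold durations must be non-negative")

    def resolved_max(self, inp: SystemicInput):
        if self.max_pressure_mmHg is None:
            return np.asarray(inp.sbp) + 50.0
        return self.max_pressure_mmHg


@dataclass(frozen=True)
class CircuitParams:
    """Fixed RC constants of the distal-arm circuit."""

    r_systemic: float = 100.0  # mmHg*s/mL
    c_art: float = 0.03  # mL/mmHg
    c_ven: float = 0.9  # mL/mmHg (~30 x C_art)
    r_ven_open: float = 10.0  # mmHg*s/mL, open-vein resistance
    collapse_threshold_mmHg: float = 30.0  # cuff pressure of full venous collapse
    collapse_width_mmHg: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "r_systemic",
            "c_art",
            "c_ven",
            "r_ven_open",
            "collapse_threshold_mmHg",
            "collapse_width_mmHg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationResult:
    """Time-gridded pressures from one inflation run (output starts at t=0;
    the cuff ramp begins at ``CuffProtocol.start_s``, so the first beats are
    the pre-inflation baseline)."""

    time: np.ndarray  # s
    p_art_sys: np.ndarray  # mmHg
    p_cuff: np.ndarray  # mmHg
    p_art_distal: np.ndarray  # mmHg
    p_ven_distal: np.ndarray  # mmHg
    dt: float  # s

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("p_art_sys", "p_cuff", "p_art_distal", "p_ven_distal"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError("all series must share the time grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BatchRun:
    """Per-beat reduced output of a vectorized batch simulation.

    Beat-indexed arrays have shape ``(n_beats, n_rows)``.
    """

    t_beat_start: np.ndarray  # (n_beats,) s, aligned to systemic troughs
    sbp_distal: np.ndarray
    dbp_distal: np.ndarray
    map_distal: np.ndarray
    p_cuff_beat: np.ndarray  # cuff pressure at beat start
    p_art_end: np.ndarray  # (n_rows,) final distal arterial pressure
    p_ven_end: np.ndarray
    dpdt_end: np.ndarray  # (n_rows,) mmHg/s over the final 2 s
    dt: float = 0.0
    meta: dict = field(default_factory=dict)


def systemic_pressure(t, inp: SystemicInput):
    """Sinusoidal systemic arterial pressure: MAP + (PP/2) sin(2 pi f t)."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(inp.hr, dtype=float) / 60.0
    out = np.asarray(inp.map) + np.asarray(inp.pp) / 2.0 * np.sin(2.0 * np.pi * f * t)
    if out.ndim == 0:
        return float(out)
    return out


def cuff_pressure(t, protocol: CuffProtocol, inp: SystemicInput | None = None):
    """Cuff pressure: zero before start, linear ramp, constant hold at max."""
    t = np.asarray(t, dtype=float)
    pmax = protocol.max_pressure_mmHg
    if pmax is None:
        if inp is None:
            raise ValueError("max pressure unresolved: pass the systemic input")
        pmax = protocol.resolved_max(inp)
    out = np.clip((t - protocol.start_s) * protocol.rate_mmHg_s, 0.0, pmax)
    if out.ndim == 0:
        return float(out)
    return out


def venous_resistance(p_cuff, params: CircuitParams, r_max: float = R_MAX):
    """Brachial-vein resistance vs cuff pressure (mmHg*s/mL).

    Log-space sigmoid from the open value to ``r_max``, centered at the
    collapse threshold (~30 mmHg) with the configured transition width.
    """
    p = np.asarray(p_cuff, dtype=float)
    x = (p - params.collapse_threshold_mmHg) / params.collapse_width_mmHg
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(-x))
    lo = math.log(params.r_ven_open)
    hi = math.log(r_max)
    out = np.exp(lo + (hi - lo) * sig)
    if out.ndim == 0:
        return float(out)
    return out


def equilibrium_closed_form(p_a, p_v, circuit: CircuitParams):
    """Compliance-weighted common pressure after all flow paths close.

    With no external flow, charge C_art*P_art + C_ven*P_ven is conserved while
    the two nodes equilibrate through R_systemic, so both converge to
    (C_art*P_a + C_ven*P_v) / (C_art + C_ven).
    """
    out = (circuit.c_art * np.asarray(p_a) + circuit.c_ven * np.asarray(p_v)) / (
        circuit.c_art + circuit.c_ven
    )
    if np.ndim(out) == 0:
        return float(out)
    return out


def _as_row_arrays(n, *values):
    return [np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy() for v in values]


def _integrate_batch(
    *,
    sbp,
    pp,
    hr: float,
    p_ven_sys: float,
    rate,
    start_s: float,
    pmax,
    t_end: float,
    circuit: CircuitParams,
    a,
    c,
    d,
    cuff_length_m,
    blood: BloodProperties,
    dt: float,
    pre_roll_s: float,
    store: bool,
    a_min: float = A_MIN_CM2,
    r_max: float = R_MAX,
):
    """Shared Euler integrator.

    Returns ``(time, p_a_series, p_v_series)`` when ``store`` is true (series
    shaped ``(n_steps, n_rows)``), else per-beat reductions plus final state.
    Output (stored or reduced) covers t in [0, t_end]; the pre-roll settles
    the initial condition and is discarded.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    n = max(
        np.size(sbp), np.size(pp), np.size(rate), np.size(pmax),
        np.size(a), np.size(c), np.size(d), np.size(cuff_length_m),
    )
    sbp, pp, rate, pmax, a, c, d, cuff_len = _as_row_arrays(
        n, sbp, pp, rate, pmax, a, c, d, cuff_length_m
    )
    dbp = sbp - pp
    pmean = (sbp + dbp) / 2.0
    amp = pp / 2.0
    f = hr / 60.0
    w = 2.0 * math.pi * f
    eta = blood.viscosity_mmHg_s
    len_cm = cuff_len * 100.0
    r_coeff = 8.0 * eta * len_cm * math.pi  # R_art = r_coeff / A^2

    inv_rsys = 1.0 / circuit.r_systemic
    c_art = circuit.c_art
    c_ven = circuit.c_ven
    thr = circuit.collapse_threshold_mmHg
    width = circuit.collapse_width_mmHg
    lr_lo = math.log(circuit.r_ven_open)
    lr_hi = math.log(r_max)

    # state: start near steady state to shorten the pre-roll
    p_art = pmean.copy()
    p_ven = np.full(n, float(p_ven_sys))

    steps_per_beat = int(round(1.0 / (f * dt)))
    if abs(steps_per_beat * f * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide the beat period 60/HR")

    n_pre = int(round(pre_roll_s / dt))
    n_out = int(round(t_end / dt))
    # first systemic trough (sin = -1) at t = 3/(4f)
    i_trough0 = int(math.ceil(0.75 / f / dt - 1e-9))
    n_beats = (n_out - i_trough0) // steps_per_beat

    def step(i_abs, p_a, p_v):
        # i_abs counts from -pre_roll; t = (i_abs - n_pre) * dt
        t = (i_abs - n_pre) * dt
        p_sys = pmean + amp * np.sin(w * t)
        p_cuff = np.clip((t - start_s) * rate, 0.0, pmax)
        ptm = p_sys - p_cuff
        u = a * ptm + 3.3
        safe_u = np.where(u > 1.0, u, math.e)
        with np.errstate(over="ignore", under="ignore"):
            area = d * np.log(safe_u) ** (1.0 + np.exp(-c * ptm))
        area = np.where(u > 1.0, area, a_min)
        np.maximum(area, a_min, out=area)
        inv_rart = np.maximum(area * area / r_coeff, 1.0 / r_max)
        x = (p_cuff - thr) / width
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-x))
        inv_rven = np.exp(-(lr_lo + (lr_hi - lr_lo) * sig))
        dpa = (p_sys * inv_rart - p_a * (inv_rart + inv_rsys) + p_v * inv_rsys) / c_art
        dpv = (
            p_a * inv_rsys - p_v * (inv_rsys + inv_rven) + p_ven_sys * inv_rven
        ) / c_ven
        return p_a + dt * dpa, p_v + dt * dpv

    # ---- pre-roll (discarded) ----
    for i in range(n_pre):
        p_art, p_ven = step(i, p_art, p_ven)
        if i % 5000 == 4999 and not np.all(np.isfinite(p_art)):
            raise FloatingPointError("simulation diverged during pre-roll")

    if store:
        pa_series = np.empty((n_out + 1, n), dtype=float)
        pv_series = np.empty((n_out + 1, n), dtype=float)
        pa_series[0] = p_art
        pv_series[0] = p_ven
        for j in range(n_out):
            p_art, p_ven = step(n_pre + j, p_art, p_ven)
            pa_series[j + 1] = p_art
            pv_series[j + 1] = p_ven
        if not np.all(np.isfinite(pa_series)) or not np.all(np.isfinite(pv_series)):
            raise FloatingPointError("simulation diverged")
        time = np.arange(n_out + 1) * dt
        return time, pa_series, pv_series

    # ---- beat-reduced path ----
    sbp_b = np.empty((n_beats, n))
    dbp_b = np.empty((n_beats, n))
    map_b = np.empty((n_beats, n))
    pcuff_b = np.empty((n_beats, n))
    t_beat = i_trough0 * dt + np.arange(n_beats) / f

    buf = np.empty((steps_per_beat, n))
    n_tail = max(1, int(round(2.0 / dt)))  # dP/dt window: final 2 s
    i_tail = n_out - n_tail
    if i_tail <= 0:
        raise ValueError("run too short for the end-slope estimate (needs > 2 s)")
    tail_mark = None
    # integrate [0, first trough)
    j = 0
    while j < i_trough0:
        if j == i_tail:
            tail_mark = p_art.copy()
        p_art, p_ven = step(n_pre + j, p_art, p_ven)
        j += 1
    for b in range(n_beats):
        t0 = j * dt
        pcuff_b[b] = np.clip((t0 - start_s) * rate, 0.0, pmax)
        for s in range(steps_per_beat):
            if j == i_tail:
                tail_mark = p_art.copy()
            buf[s] = p_art  # state at sample j, matching windowed reductions
            p_art, p_ven = step(n_pre + j, p_art, p_ven)
            j += 1
        if not np.all(np.isfinite(p_art)):
            raise FloatingPointError(f"simulation diverged in beat {b}")
        sbp_b[b] = buf.max(axis=0)
        dbp_b[b] = buf.min(axis=0)
        map_b[b] = buf.mean(axis=0)
    # run out the remaining partial beat
    while j < n_out:
        if j == i_tail:
            tail_mark = p_art.copy()
        p_art, p_ven = step(n_pre + j, p_art, p_ven)
        j += 1
    dpdt_end = (p_art - tail_mark) / (n_tail * dt)
    return BatchRun(
        t_beat_start=t_beat,
        sbp_distal=sbp_b,
        dbp_distal=dbp_b,
        map_distal=map_b,
        p_cuff_beat=pcuff_b,
        p_art_end=p_art.copy(),
        p_ven_end=p_ven.copy(),
        dpdt_end=dpdt_end,
        dt=dt,
    )


def _protocol_t_end(protocol: CuffProtocol, pmax) -> float:
    return float(protocol.start_s + np.max(pmax) / np.min(
        np.asarray(protocol.rate_mmHg_s, dtype=float)
    ) + protocol.hold_s)


def simulate(
    inp: SystemicInput,
    protocol: CuffProtocol | None = None,
    circuit: CircuitParams | None = None,
    geometry: ArmGeometry | None = None,
    tube: TubeLawParams | None = None,
    blood: BloodProperties | None = None,
    dt: float = 5e-4,
    pre_roll_s: float = 10.0,
) -> SimulationResult:
    """Run one cuff-inflation simulation and return full pressure traces.

    The output grid starts at t = 0 with the cuff still deflated (baseline
    beats); the ramp starts at ``protocol.start_s`` and the run ends after the
    hold at maximum pressure.
    """
    protocol = protocol or CuffProtocol()
    circuit = circuit or CircuitParams()
    geometry = geometry or ArmGeometry()
    tube = tube or TubeLawParams()
    blood = blood or BloodProperties()
    pmax = float(protocol.resolved_max(inp))
    t_end = _protocol_t_end(protocol, pmax)
    time, pa, pv = _integrate_batch(
        sbp=inp.sbp,
        pp=inp.pp,
        hr=inp.hr,
        p_ven_sys=inp.p_ven_sys,
        rate=protocol.rate_mmHg_s,
        start_s=protocol.start_s,
        pmax=pmax,
        t_end=t_end,
        circuit=circuit,
        a=tube.a,
        c=tube.c,
        d=tube.d,
        cuff_length_m=geometry.cuff_length_m,
        blood=blood,
        dt=dt,
        pre_roll_s=pre_roll_s,
        store=True,
    )
    p_sys = systemic_pressure(time, inp)
    p_cuff = np.clip((time - protocol.start_s) * protocol.rate_mmHg_s, 0.0, pmax)
    return SimulationResult(
        time=time,
        p_art_sys=np.asarray(p_sys),
        p_cuff=p_cuff,
        p_art_distal=pa[:, 0],
        p_ven_distal=pv[:, 0],
        dt=dt,
    )


def simulate_batch(
    *,
    sbp,
    pp,
    rate,
    a,
    c,
    d,
    cuff_length_m,
    inp: SystemicInput | None = None,
    protocol: CuffProtocol | None = None,
    circuit: CircuitParams | None = None,
    blood: BloodProperties | None = None,
    dt: float = 5e-4,
    pre_roll_s: float = 10.0,
) -> BatchRun:
    """Vectorized simulation of many parameter sets on a common time grid.

    ``sbp, pp, rate, a, c, d, cuff_length_m`` broadcast to the batch size;
    heart rate, venous pressure and circuit constants are shared (as in the
    sensitivity analysis, where they are fixed at reference values).  The
    common grid extends to the slowest ramp's hold end; rows that occlude
    earlier simply hold longer at max pressure, which leaves their metrics
    unchanged.  Returns per-beat summaries instead of full traces.
    """
    inp = inp or SystemicInput()
    protocol = protocol or CuffProtocol()
    circuit = circuit or CircuitParams()
    blood = blood or BloodProperties()
    if protocol.max_pressure_mmHg is None:
        pmax = np.asarray(sbp, dtype=float) + 50.0
    else:
        pmax = np.asarray(protocol.max_pressure_mmHg, dtype=float)
    ramp_s = np.asarray(pmax, dtype=float) / np.asarray(rate, dtype=float)
    t_end = float(protocol.start_s + np.max(ramp_s) + protocol.hold_s)
    run = _integrate_batch(
        sbp=sbp,
        pp=pp,
        hr=inp.hr,
        p_ven_sys=inp.p_ven_sys,
        rate=rate,
        start_s=protocol.start_s,
        pmax=pmax,
        t_end=t_end,
        circuit=circuit,
        a=a,
        c=c,
        d=d,
        cuff_length_m=cuff_length_m,
        blood=blood,
        dt=dt,
        pre_roll_s=pre_roll_s,
        store=False,
    )
    run.meta = {"hr": inp.hr, "p_ven_sys": inp.p_ven_sys, "t_end": t_end}
    return run


def occlusion_time(
    result: SimulationResult,
    inp: SystemicInput,
    tube: TubeLawParams | None = None,
) -> float:
    """First time from which the cuffed segment stays collapsed a full beat.

    Collapse is read from the tube law at the instantaneous midpoint
    transmural pressure; from this time on the distal compartments are
    isolated and C_art*P_art + C_ven*P_ven is conserved.
    """
    from .mechanics import luminal_area

    tube = tube or TubeLawParams()
    ptm = result.p_art_sys - result.p_cuff
    closed = np.asarray(luminal_area(ptm, tube)) <= 2.0 * A_MIN_CM2
    w = int(round(inp.period_s / result.dt))
    cs = np.concatenate([[0], np.cumsum(closed.astype(np.int64))])
    window = cs[w:] - cs[:-w]
    idx = np.nonzero(window == w)[0]
    if len(idx) == 0:
        raise ValueError("run never reaches full occlusion")
    return float(result.time[idx[0]])
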