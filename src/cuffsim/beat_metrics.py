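"""Per-beat segmentation, transit-time series and scalar response metrics.

A cuff-inflation run is reduced to one row per heartbeat (distal SBP, DBP,
beat-mean MAP, cuff pressure), from which per-beat transit-time changes are
derived:

* ``dPTT_cuff`` — change of the transit time across the cuffed brachial
  segment, evaluated at the diastolic (foot-of-wave) transmural pressure
  ``(DBP_sys + DBP_distal)/2 - P_cuff``;
* ``dPTT_distal`` — change of the transit time across the arm distal to the
  cuff, evaluated at the distal diastolic pressure (no external pressure);
* ``dPAT_total = dPTT_cuff + dPTT_distal`` — the change a heart-referenced
  pulse arrival time would show, since the pre-ejection period is constant
  during an inflation.

All changes are referenced to the mean of the last five pre-inflation beats.
Six scalar response metrics summarize a run: the maximum drop in distal PTT,
the maximum total PAT change, the maximum rises of distal MAP and DBP, the
post-occlusion equilibrium pressure P_eq, and the onset margin dPTT_onset
(systemic MAP minus cuff pressure at the first sustained distal-PTT drop).

Beat-indexed arrays may be 1-D (one run) or 2-D ``(n_beats, n_rows)`` (a
vectorized batch); every function here is shape-agnostic over axis 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circulation import (
    BatchRun,
    SimulationResult,
    SystemicInput,
)
from .mechanics import ArmGeometry, BloodProperties, TubeLawParams, segment_transit_time

__all__ = [
    "BeatSeries",
    "PTTSeries",
    "ResponseMetrics",
    "ONSET_PTT_THRESHOLD_MS",
    "ONSET_SUSTAIN_BEATS",
    "ONSET_MAP_THRESHOLD_MMHG",
    "N_BASELINE_BEATS",
    "segment_beats",
    "beats_from_batch",
    "compute_ptt_series",
    "detect_onset",
    "extract_metrics",
    "metrics_matrix",
]

#: Onset detection: sustained per-beat distal-PTT drop below this (ms) ...
ONSET_PTT_THRESHOLD_MS = 0.05
#: ... for this many consecutive beats.
ONSET_SUSTAIN_BEATS = 3
#: Cross-check threshold for the distal-MAP onset criterion (mmHg).
ONSET_MAP_THRESHOLD_MMHG = 0.5
#: Baseline = mean over the last this-many pre-inflation beats.
N_BASELINE_BEATS = 5

#: Slope guard for reading P_eq at the hold end (mmHg/s).
P_EQ_SLOPE_GUARD = 0.01


@dataclass
class BeatSeries:
    """Per-beat summaries of the distal pressure trace.

    Arrays are indexed ``[beat]`` or ``[beat, row]``.
    """

    t_start: np.ndarray  # beat start time (systemic trough), s
    sbp: np.ndarray  # distal systolic, mmHg
    dbp: np.ndarray  # distal diastolic, mmHg
    map: np.ndarray  # distal beat mean, mmHg
    p_cuff: np.ndarray  # cuff pressure at beat start, mmHg
    sys_dbp: np.ndarray  # systemic diastolic (per row), mmHg
    sys_sbp: np.ndarray  # systemic systolic (per row), mmHg
    sys_map: np.ndarray  # systemic beat mean (per row), mmHg

    @property
    def n_beats(self) -> int:
        return self.sbp.shape[0]

    @property
    def baseline_mask(self) -> np.ndarray:
        """Pre-inflation beats: cuff still fully deflated at beat start."""
        p = self.p_cuff if self.p_cuff.ndim == 1 else self.p_cuff.max(axis=1)
        return p <= 1e-12

    def baseline_index(self, n: int = N_BASELINE_BEATS) -> np.ndarray:
        idx = np.nonzero(self.baseline_mask)[0]
        if len(idx) == 0:
            raise ValueError("no pre-inflation baseline beats in the run")
        return idx[-n:]


@dataclass
class PTTSeries:
    """Per-beat transit-time changes (ms) relative to the pre-inflation
    baseline, plus the absolute segment transit times they derive from."""

    dptt_cuff: np.ndarray
    dptt_distal: np.ndarray
    dpat_total: np.ndarray
    transmitting: np.ndarray  # bool: pulse still crosses the cuffed segment
    t_cuff: np.ndarray  # absolute cuff-segment transit time, ms
    t_distal: np.ndarray  # absolute distal-segment transit time, ms


@dataclass
class ResponseMetrics:
    """The six scalar outputs characterizing one inflation run."""

    max_dptt_distal_ms: float  # maximum drop of distal PTT (magnitude)
    max_dpat_total_ms: float  # maximum |total PAT change|
    max_dmap_mmhg: float  # maximum rise of distal MAP above baseline
    p_eq_mmhg: float  # equilibrium pressure after full occlusion
    max_ddbp_mmhg: float  # maximum rise of distal DBP above baseline
    dptt_onset_mmhg: float  # systemic MAP - cuff pressure at onset (NaN if none)

    def as_dict(self) -> dict:
        return {
            "max_dptt_distal_ms": self.max_dptt_distal_ms,
            "max_dpat_total_ms": self.max_dpat_total_ms,
            "max_dmap_mmhg": self.max_dmap_mmhg,
            "p_eq_mmhg": self.p_eq_mmhg,
            "max_ddbp_mmhg": self.max_ddbp_mmhg,
            "dptt_onset_mmhg": self.dptt_onset_mmhg,
        }


#: Canonical column order of :func:`metrics_matrix`.
METRIC_NAMES = (
    "max_dptt_distal_ms",
    "max_dpat_total_ms",
    "max_dmap_mmhg",
    "p_eq_mmhg",
    "max_ddbp_mmhg",
    "dptt_onset_mmhg",
)


def segment_beats(result: SimulationResult, inp: SystemicInput) -> BeatSeries:
    """Cut a stored run into consecutive one-period windows aligned to the
    systemic-sinusoid troughs and reduce each to SBP/DBP/MAP."""
    f = inp.hr / 60.0
    period = 1.0 / f
    steps_per_beat = int(round(period / result.dt))
    if abs(steps_per_beat * result.dt - period) > 1e-9:
        raise ValueError("dt must divide the beat period")
    t0 = result.time[0]
    # first trough at t = 3/(4f) + k/f >= t0
    k0 = math.ceil((t0 - 0.75 * period) / period - 1e-9)
    t_tr0 = 0.75 * period + k0 * period
    i0 = int(round((t_tr0 - t0) / result.dt))
    n_beats = (len(result.time) - i0 - 1) // steps_per_beat
    if n_beats < 2:
        raise ValueError("run must cover at least two full beats")
    pa = result.p_art_distal[i0 : i0 + n_beats * steps_per_beat]
    windows = pa.reshape(n_beats, steps_per_beat)
    t_start = result.time[i0] + np.arange(n_beats) * period
    p_cuff = result.p_cuff[i0 : i0 + n_beats * steps_per_beat : steps_per_beat]
    return BeatSeries(
        t_start=t_start,
        sbp=windows.max(axis=1),
        dbp=windows.min(axis=1),
        map=windows.mean(axis=1),
        p_cuff=p_cuff.copy(),
        sys_dbp=np.asarray(float(inp.dbp)),
        sys_sbp=np.asarray(float(inp.sbp)),
        sys_map=np.asarray(float(inp.map)),
    )


def beats_from_batch(run: BatchRun, sbp, pp, inp: SystemicInput) -> BeatSeries:
    """Assemble a (possibly 2-D) :class:`BeatSeries` from a batch run."""
    sbp = np.asarray(sbp, dtype=float)
    pp = np.asarray(pp, dtype=float)
    dbp = sbp - pp
    return BeatSeries(
        t_start=run.t_beat_start,
        sbp=run.sbp_distal,
        dbp=run.dbp_distal,
        map=run.map_distal,
        p_cuff=run.p_cuff_beat,
        sys_dbp=dbp,
        sys_sbp=sbp,
        sys_map=(sbp + dbp) / 2.0,
    )


def compute_ptt_series(
    beats: BeatSeries,
    geometry: ArmGeometry | None = None,
    tube: TubeLawParams | None = None,
    blood: BloodProperties | None = None,
    distal_tube: TubeLawParams | None = None,
) -> PTTSeries:
    """Per-beat transit-time changes from the beat series.

    Transit times follow the foot-of-wave convention: clinical fiducials are
    waveform feet, so both segments are evaluated at per-beat diastolic
    pressures.

    The cuffed segment's effective slowness averages its two bounding states
    (a two-point quadrature over the pressure swing the transmitted pulse
    samples): the reopening-foot state at Ptm = (DBP_sys + DBP_distal)/2 -
    P_cuff and the crest state at Ptm = (SBP_sys + SBP_distal)/2 - P_cuff,
    both floored at zero — once cuff pressure exceeds the respective phase
    pressure, the segment acts as a pinch valve that reopens when upstream
    pressure crosses cuff pressure, so the wave crosses at about zero
    transmural pressure.  Transmission stops altogether (flag cleared) once
    cuff pressure reaches systemic systolic pressure — the oscillometric
    endpoint where distal pulses vanish.

    The arm distal to the cuff is mechanically unloaded, so its wave speed
    uses ``distal_tube`` (reference parameters by default) at the distal
    diastolic pressure; this series needs no transmitted pulse and is defined
    for every beat.
    """
    geometry = geometry or ArmGeometry()
    tube = tube or TubeLawParams()
    blood = blood or BloodProperties()
    distal_tube = distal_tube or TubeLawParams()

    ptm_foot = np.maximum(0.5 * (beats.sys_dbp + beats.dbp) - beats.p_cuff, 0.0)
    ptm_crest = np.maximum(0.5 * (beats.sys_sbp + beats.sbp) - beats.p_cuff, 0.0)
    t_foot = np.asarray(
        segment_transit_time(ptm_foot, geometry.cuff_length_m, tube, blood)
    )
    t_crest = np.asarray(
        segment_transit_time(ptm_crest, geometry.cuff_length_m, tube, blood)
    )
    t_cuff = 0.5 * (t_foot + t_crest)
    t_dist = np.asarray(
        segment_transit_time(beats.dbp, geometry.distal_length_m, distal_tube, blood)
    )
    transmitting = (
        (beats.p_cuff < beats.sys_sbp) & np.isfinite(t_cuff) & np.isfinite(t_dist)
    )

    base = beats.baseline_index()
    t_cuff_base = np.nanmean(t_cuff[base], axis=0)
    t_dist_base = np.nanmean(t_dist[base], axis=0)
    dptt_cuff = t_cuff - t_cuff_base
    dptt_dist = t_dist - t_dist_base
    return PTTSeries(
        dptt_cuff=dptt_cuff,
        dptt_distal=dptt_dist,
        dpat_total=dptt_cuff + dptt_dist,
        transmitting=np.broadcast_to(transmitting, t_cuff.shape).copy(),
        t_cuff=t_cuff,
        t_distal=t_dist,
    )


def _first_sustained(cond: np.ndarray, n_sustain: int) -> np.ndarray:
    """First axis-0 index where ``cond`` holds for ``n_sustain`` consecutive
    entries; -1 where never.  ``cond`` is 1-D or 2-D (beats [, rows])."""
    cond = np.asarray(cond, dtype=bool)
    squeeze = cond.ndim == 1
    if squeeze:
        cond = cond[:, None]
    run = cond[: cond.shape[0] - n_sustain + 1].copy()
    for k in range(1, n_sustain):
        run &= cond[k : cond.shape[0] - n_sustain + 1 + k]
    any_hit = run.any(axis=0)
    idx = np.where(any_hit, run.argmax(axis=0), -1)
    return int(idx[0]) if squeeze else idx


def _onset_index(
    dptt_distal: np.ndarray,
    threshold_ms: float = ONSET_PTT_THRESHOLD_MS,
    n_sustain: int = ONSET_SUSTAIN_BEATS,
) -> np.ndarray:
    """First beat of a sustained distal-PTT drop; -1 where never.

    The drop below ``-threshold_ms`` must hold for ``n_sustain`` consecutive
    beats.  The distal series is defined for every beat, so no transmission
    gating applies here.
    """
    dptt = np.asarray(dptt_distal)
    squeeze = dptt.ndim == 1
    if squeeze:
        dptt = dptt[:, None]
    cond = np.isfinite(dptt) & (dptt < -threshold_ms)
    idx = np.atleast_1d(_first_sustained(cond, n_sustain))
    return idx[0] if squeeze else idx


def detect_onset(
    beats: BeatSeries,
    ptt: PTTSeries,
    threshold_ms: float = ONSET_PTT_THRESHOLD_MS,
    n_sustain: int = ONSET_SUSTAIN_BEATS,
):
    """Onset of the distal filling effect from the distal-PTT series.

    Returns ``(beat_index, cuff_pressure_mmHg)`` for the first beat at which
    ``dPTT_distal`` drops below ``-threshold_ms`` and the drop is sustained
    for ``n_sustain`` beats (occlusion terminating the series counts as
    sustained), or ``None`` if never triggered.  1-D input only.
    """
    idx = _onset_index(ptt.dptt_distal, threshold_ms, n_sustain)
    if idx < 0:
        return None
    p = beats.p_cuff[idx]
    return int(idx), float(p if np.ndim(p) == 0 else p.item())


def _metrics_arrays(
    beats: BeatSeries,
    ptt: PTTSeries,
    p_art_end: np.ndarray,
    dpdt_end: np.ndarray,
    *,
    strict_p_eq: bool,
) -> dict:
    """Shape-agnostic core of :func:`extract_metrics` (axis 0 = beats)."""
    base = beats.baseline_index()
    map_base = beats.map[base].mean(axis=0)
    dbp_base = beats.dbp[base].mean(axis=0)

    dpat = np.where(ptt.transmitting, ptt.dpat_total, np.nan)
    with np.errstate(invalid="ignore"):
        max_drop = np.nanmax(-ptt.dptt_distal, axis=0)
        max_dpat = np.nanmax(np.abs(dpat), axis=0)
    max_dmap = beats.map.max(axis=0) - map_base
    max_ddbp = beats.dbp.max(axis=0) - dbp_base

    converged = np.abs(dpdt_end) < P_EQ_SLOPE_GUARD
    if strict_p_eq and not np.all(converged):
        raise ValueError(
            "distal pressure still drifting at hold end "
            f"(|dP/dt| = {np.max(np.abs(dpdt_end)):.3g} mmHg/s); extend hold_s"
        )
    p_eq = np.where(converged, p_art_end, np.nan)

    idx = _onset_index(ptt.dptt_distal)
    idx_arr = np.atleast_1d(np.asarray(idx))
    pc = beats.p_cuff if beats.p_cuff.ndim == 2 else beats.p_cuff[:, None]
    cols = np.arange(idx_arr.shape[0])
    p_onset = pc[np.clip(idx_arr, 0, None), cols % pc.shape[1]]
    onset = np.where(idx_arr >= 0, np.asarray(beats.sys_map).reshape(-1) - p_onset, np.nan)
    if np.ndim(beats.sbp) == 1:
        onset = onset[0]
    return {
        "max_dptt_distal_ms": max_drop,
        "max_dpat_total_ms": max_dpat,
        "max_dmap_mmhg": max_dmap,
        "p_eq_mmhg": p_eq,
        "max_ddbp_mmhg": max_ddbp,
        "dptt_onset_mmhg": onset,
    }


def extract_metrics(
    result: SimulationResult,
    beats: BeatSeries,
    ptt: PTTSeries,
    inp: SystemicInput,
) -> ResponseMetrics:
    """The six scalar response metrics of one stored run.

    Raises if the hold is too short for the distal pressure to settle onto
    P_eq (end slope above 0.01 mmHg/s).
    """
    n_tail = max(1, int(round(2.0 / result.dt)))
    if n_tail >= len(result.time):
        raise ValueError("run too short to estimate the end slope")
    dpdt_end = (result.p_art_distal[-1] - result.p_art_distal[-1 - n_tail]) / (
        n_tail * result.dt
    )
    vals = _metrics_arrays(
        beats,
        ptt,
        np.asarray(result.p_art_distal[-1]),
        np.asarray(dpdt_end),
        strict_p_eq=True,
    )
    return ResponseMetrics(**{k: float(v) for k, v in vals.items()})


def metrics_matrix(
    run: BatchRun,
    beats: BeatSeries,
    ptt: PTTSeries,
) -> np.ndarray:
    """Response metrics of a batch run, shape ``(n_rows, 6)`` in
    :data:`METRIC_NAMES` order.  Rows whose hold did not converge get NaN
    P_eq instead of raising."""
    vals = _metrics_arrays(
        beats, ptt, run.p_art_end, run.dpdt_end, strict_p_eq=False
    )
    return np.column_stack([np.atleast_1d(vals[k]) for k in METRIC_NAMES])
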