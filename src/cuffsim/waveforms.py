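"""Synthetic ECG/ABP/PPG recordings and fiducial-based interval extraction.

This toolkit emulates the clinical measurement chain on model output: an ECG
channel sampled at 500 Hz and ABP/PPG channels at 125 Hz are synthesized
from a simulation run, with known (ground-truth) fiducial times, and the
per-beat PAT/PTT intervals are then re-extracted the way one would from real
recordings — R-peaks by thresholded peak search, pulse feet by the
intersecting-tangent method.  It exists to validate the interval-measurement
pipeline against ground truth, not to produce realistic signal morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .beat_metrics import BeatSeries, N_BASELINE_BEATS, PTTSeries
from .circulation import SimulationResult

__all__ = [
    "SyntheticRecording",
    "FS_ECG",
    "FS_PULSE",
    "synthesize_recording",
    "detect_fiducials",
    "measure_intervals",
]

FS_ECG = 500.0  # Hz
FS_PULSE = 125.0  # Hz, ABP and PPG
PEP_S = 0.08  # pre-ejection period, constant throughout an inflation


@dataclass
class SyntheticRecording:
    """Three synchronized channels plus the ground truth they were built from."""

    t_ecg: np.ndarray
    ecg: np.ndarray
    t_pulse: np.ndarray  # shared grid of the 125 Hz channels
    abp: np.ndarray  # mmHg
    ppg: np.ndarray  # arbitrary units
    truth: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.t_ecg[-1] - self.t_ecg[0]) if len(self.t_ecg) else 0.0


def _template_pulse(t_rel: np.ndarray, rise_s: float = 0.20) -> np.ndarray:
    """Unit pulse: raised-cosine upstroke then exponential relaxation."""
    up = 0.5 * (1.0 - np.cos(np.pi * t_rel / rise_s))
    down = np.exp(-(t_rel - rise_s) / 0.25)
    out = np.where(t_rel < rise_s, up, down)
    return np.where((t_rel >= 0) & (t_rel < 0.8), out, 0.0)


def synthesize_recording(
    result: SimulationResult,
    beats: BeatSeries,
    ptt: PTTSeries,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Build ECG/ABP/PPG channels from one simulation run.

    * ECG — narrow unit-amplitude R waves at each beat start (500 Hz);
    * ABP — the distal arterial pressure resampled to 125 Hz (the invasive
      radial line);
    * PPG — one template pulse per transmitting beat whose foot sits at
      R-peak + PEP + (cuff + distal transit time), amplitude following the
      distal pulse pressure; beats with no transmitted pulse produce no
      PPG pulse (a gap, as in suprasystolic cuff pressures).

    ``noise_sd`` is additive white noise expressed as a fraction of each
    channel's pulse amplitude; the ground-truth fiducials and inserted
    delays are recorded in ``truth``.
    """
    rng = np.random.default_rng(seed)
    t_end = float(result.time[-1])
    t0 = float(result.time[0])
    t_ecg = np.arange(t0, t_end, 1.0 / FS_ECG)
    t_pulse = np.arange(t0, t_end, 1.0 / FS_PULSE)

    r_times = np.asarray(beats.t_start, dtype=float)
    ecg = np.zeros_like(t_ecg)
    for r in r_times:
        ecg += np.exp(-0.5 * ((t_ecg - r) / 0.008) ** 2)

    abp = np.interp(t_pulse, result.time, result.p_art_distal)

    total_ms = np.asarray(ptt.t_cuff, dtype=float) + np.asarray(
        ptt.t_distal, dtype=float
    )
    ppg_feet = r_times + PEP_S + total_ms / 1000.0
    amp = np.asarray(beats.sbp, dtype=float) - np.asarray(beats.dbp, dtype=float)
    transmitting = np.asarray(ptt.transmitting, dtype=bool)
    ppg = np.zeros_like(t_pulse)
    for k, foot in enumerate(ppg_feet):
        if not transmitting[k] or not np.isfinite(foot):
            continue
        ppg += amp[k] * _template_pulse(t_pulse - foot)

    if noise_sd > 0:
        ecg += rng.normal(0.0, noise_sd, size=ecg.shape)
        abp += rng.normal(0.0, noise_sd * max(np.ptp(abp), 1.0), size=abp.shape)
        ppg_amp = np.nanmax(amp[transmitting]) if transmitting.any() else 1.0
        ppg += rng.normal(0.0, noise_sd * ppg_amp, size=ppg.shape)

    # ABP ground-truth feet: per-beat minimum of the distal pressure
    abp_feet = np.full(len(r_times), np.nan)
    period = float(r_times[1] - r_times[0]) if len(r_times) > 1 else 1.0
    for k, r in enumerate(r_times):
        sel = (result.time >= r) & (result.time < r + period)
        if sel.any():
            seg = result.p_art_distal[sel]
            abp_feet[k] = result.time[sel][np.argmin(seg)]

    truth = {
        "r_peaks_s": r_times,
        "ppg_feet_s": np.where(transmitting, ppg_feet, np.nan),
        "abp_feet_s": abp_feet,
        "pat_ms": np.where(transmitting, (ppg_feet - r_times) * 1000.0, np.nan),
        "pep_s": PEP_S,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SyntheticRecording(
        t_ecg=t_ecg, ecg=ecg, t_pulse=t_pulse, abp=abp, ppg=ppg, truth=truth
    )


def _tangent_foot(t: np.ndarray, y: np.ndarray) -> float:
    """Intersecting-tangent foot of one upstroke segment.

    The max-slope tangent of the upstroke is intersected with the horizontal
    level of the preceding minimum; NaN when the segment carries no pulse.
    """
    if len(t) < 5 or np.ptp(y) <= 0:
        return np.nan
    dy = np.gradient(y, t)
    i_up = int(np.argmax(dy))
    if dy[i_up] <= 0:
        return np.nan
    base = float(np.min(y[: i_up + 1])) if i_up > 0 else float(y[0])
    foot = t[i_up] - (y[i_up] - base) / dy[i_up]
    lo, hi = float(t[0]), float(t[i_up])
    return float(min(max(foot, lo), hi))


def detect_fiducials(recording: SyntheticRecording, smooth: bool = True) -> dict:
    """R-peaks and pulse feet from the raw channels.

    R-peaks by local-maximum search above half the global maximum; ABP and
    PPG feet by the intersecting-tangent rule applied beat by beat in windows
    anchored to the detected R-peaks.  Beats without a detectable pulse yield
    NaN; an empty recording yields empty arrays.
    """
    out = {"r_peaks_s": np.array([]), "abp_feet_s": np.array([]), "ppg_feet_s": np.array([])}
    if len(recording.ecg) == 0 or np.ptp(recording.ecg) == 0:
        return out
    peaks, _ = signal.find_peaks(
        recording.ecg,
        height=0.5 * float(np.max(recording.ecg)),
        distance=int(0.4 * FS_ECG),
    )
    r_times = recording.t_ecg[peaks]
    out["r_peaks_s"] = r_times
    if len(r_times) == 0:
        return out
    period = float(np.median(np.diff(r_times))) if len(r_times) > 1 else 1.0

    abp = recording.abp
    ppg = recording.ppg
    if smooth and len(ppg) > 33:
        abp = signal.savgol_filter(abp, 11, 3)
        ppg = signal.savgol_filter(ppg, 11, 3)

    def feet(channel: np.ndarray, lag: float) -> np.ndarray:
        res = np.full(len(r_times), np.nan)
        for k, r in enumerate(r_times):
            sel = (recording.t_pulse >= r + lag) & (
                recording.t_pulse < r + lag + period
            )
            if sel.sum() < 5:
                continue
            seg_t = recording.t_pulse[sel]
            seg_y = channel[sel]
            if np.ptp(seg_y) < 1e-6:
                continue
            res[k] = _tangent_foot(seg_t, seg_y)
        return res

    out["abp_feet_s"] = feet(abp, 0.0)
    out["ppg_feet_s"] = feet(ppg, 0.0)
    return out


def measure_intervals(
    fiducials: dict, n_baseline: int = N_BASELINE_BEATS
) -> dict:
    """Per-beat dPAT (ECG->PPG) and dPTT (ABP->PPG), baseline-referenced (ms).

    Intervals are computed per beat from matched fiducials; the change is
    referenced to the mean over the first ``n_baseline`` beats with valid
    intervals.  Missing fiducials propagate as NaN gaps.
    """
    r = np.asarray(fiducials["r_peaks_s"], dtype=float)
    abp = np.asarray(fiducials["abp_feet_s"], dtype=float)
    ppg = np.asarray(fiducials["ppg_feet_s"], dtype=float)
    if not (len(r) == len(abp) == len(ppg)):
        raise ValueError("fiducial channels have unmatched beat counts")
    pat_ms = (ppg - r) * 1000.0
    ptt_ms = (ppg - abp) * 1000.0

    def referenced(x: np.ndarray) -> np.ndarray:
        valid = np.nonzero(np.isfinite(x))[0][:n_baseline]
        if len(valid) == 0:
            return np.full_like(x, np.nan)
        return x - np.mean(x[valid])

    return {
        "pat_ms": pat_ms,
        "dpat_ms": referenced(pat_ms),
        "dptt_abp_ppg_ms": referenced(ptt_ms),
    }
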