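"""Result persistence: CSV for series and tables, JSON for scalar results.

Every artifact embeds the resolved configuration hash, the seed, and the
package version, so a results directory is self-describing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beat_metrics import BeatSeries, PTTSeries, ResponseMetrics
from .circulation import SimulationResult
from .config import RunConfig, config_hash

__all__ = [
    "write_simulation_csv",
    "read_simulation_csv",
    "write_beats_csv",
    "write_metrics_json",
    "write_json",
    "write_sidecar",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.9g"


def _ensure_dir(path: Path) -> None:
    if not path.parent.exists():
        path.parent.mkdir(parents=True, exist_ok=True)
        logger.info("created output directory %s", path.parent)


def write_simulation_csv(result: SimulationResult, path: str | Path) -> Path:
    """Time series as CSV: t_s,p_sys,p_cuff,p_art_distal,p_ven_distal."""
    path = Path(path)
    _ensure_dir(path)
    df = pd.DataFrame(
        {
            "t_s": result.time,
            "p_sys": result.p_art_sys,
            "p_cuff": result.p_cuff,
            "p_art_distal": result.p_art_distal,
            "p_ven_distal": result.p_ven_distal,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_simulation_csv(path: str | Path) -> SimulationResult:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    return SimulationResult(
        time=t,
        p_art_sys=df["p_sys"].to_numpy(),
        p_cuff=df["p_cuff"].to_numpy(),
        p_art_distal=df["p_art_distal"].to_numpy(),
        p_ven_distal=df["p_ven_distal"].to_numpy(),
        dt=dt,
    )


def write_beats_csv(beats: BeatSeries, ptt: PTTSeries | None, path: str | Path) -> Path:
    """Per-beat table (1-D series only)."""
    path = Path(path)
    _ensure_dir(path)
    data = {
        "beat": np.arange(beats.n_beats),
        "t_s": beats.t_start,
        "p_sbp": beats.sbp,
        "p_dbp": beats.dbp,
        "p_map": beats.map,
        "p_cuff": beats.p_cuff,
    }
    if ptt is not None:
        data.update(
            dptt_cuff_ms=ptt.dptt_cuff,
            dptt_distal_ms=ptt.dptt_distal,
            dpat_total_ms=ptt.dpat_total,
            transmitting=ptt.transmitting.astype(int),
        )
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _meta(config: RunConfig | None, seed: int | None) -> dict:
    meta = {"package_version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.seed if seed is None else seed
    elif seed is not None:
        meta["seed"] = seed
    return meta


def write_metrics_json(
    metrics: ResponseMetrics,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """The six response metrics, keyed by their study names."""
    payload = {
        "max|dPTT_distal| (ms)": metrics.max_dptt_distal_ms,
        "max|dPAT_total| (ms)": metrics.max_dpat_total_ms,
        "max|dMAP| (mmHg)": metrics.max_dmap_mmhg,
        "P_eq (mmHg)": metrics.p_eq_mmhg,
        "max|dDBP| (mmHg)": metrics.max_ddbp_mmhg,
        "dPTT_onset (mmHg)": metrics.dptt_onset_mmhg,
        "_meta": _meta(config, seed),
    }
    return write_json(payload, path)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    _ensure_dir(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
    return path


def write_sidecar(config: RunConfig, path: str | Path, **extra) -> Path:
    """Run-metadata sidecar with all resolved parameters."""
    payload = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "package_version": __version__,
        **extra,
    }
    return write_json(payload, path)
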