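"""Virtual experiments: regressions and sweeps over the sampled design.

The sensitivity-analysis sample doubles as a virtual study population; these
helpers reproduce the dependency analyses a practitioner would run on it:

* ordinary-least-squares fits of a response metric on one or two inputs,
* the cuff-length dependence of the maximum total PAT change,
* the joint PP/SBP dependence of the maximum distal PTT drop,
* a controlled sweep of the cuff inflation rate with everything else at the
  reference operating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import beat_metrics as bm
from . import circulation as circ
from .beat_metrics import METRIC_NAMES
from .sobol import SampleDesign

__all__ = [
    "LinearFitResult",
    "linear_fit",
    "experiment_cuff_length",
    "experiment_bp_correlation",
    "experiment_inflation_rate",
]

logger = logging.getLogger(__name__)

_COL = {name: j for j, name in enumerate(METRIC_NAMES)}


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit summary: response ~ intercept + X @ coefficients."""

    coefficients: tuple
    intercept: float
    r_squared: float
    n: int

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ np.asarray(self.coefficients)


def linear_fit(X, y) -> LinearFitResult:
    """Ordinary least squares with intercept; R^2 = 1 - SS_res/SS_tot.

    Raises on rank deficiency.  A constant response (SS_tot = 0) returns
    R^2 = 0 with a warning — there is nothing to explain.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in the fit inputs")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {n}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient predictor matrix")
    if np.ptp(y) == 0.0 or np.var(y) == 0.0:
        warnings.warn("constant response; R^2 reported as 0", stacklevel=2)
        return LinearFitResult(
            coefficients=tuple(0.0 for _ in range(p)),
            intercept=float(y[0]),
            r_squared=0.0,
            n=n,
        )
    fit = sm.OLS(y, design).fit()
    return LinearFitResult(
        coefficients=tuple(float(b) for b in fit.params[1:]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=n,
    )


def _valid_rows(outputs: np.ndarray) -> np.ndarray:
    ok = np.all(np.isfinite(np.asarray(outputs, dtype=float)), axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("excluding %d rows with missing metrics from fits", dropped)
    return ok


def experiment_cuff_length(design: SampleDesign, outputs: np.ndarray) -> LinearFitResult:
    """max|dPAT_total| regressed on cuff length over all valid sampled sets."""
    ok = _valid_rows(outputs)
    return linear_fit(
        design.column("cuff_length")[ok], outputs[ok, _COL["max_dpat_total_ms"]]
    )


def experiment_bp_correlation(
    design: SampleDesign, outputs: np.ndarray
) -> tuple[LinearFitResult, LinearFitResult]:
    """max|dPTT_distal| regressed (a) on PP alone, (b) on PP and SBP jointly."""
    ok = _valid_rows(outputs)
    y = outputs[ok, _COL["max_dptt_distal_ms"]]
    pp = design.column("pp")[ok]
    sbp = design.column("sbp")[ok]
    fit_pp = linear_fit(pp, y)
    fit_joint = linear_fit(np.column_stack([pp, sbp]), y)
    return fit_pp, fit_joint


def experiment_inflation_rate(
    rates=None,
    *,
    inp: circ.SystemicInput | None = None,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Controlled sweep of the cuff inflation rate at reference settings.

    Returns one row per rate with P_eq and max|dPTT_distal|; the attribute
    ``df.attrs["dptt_range_ms"]`` holds the spread (max - min) of
    max|dPTT_distal| across the sweep.
    """
    if rates is None:
        rates = np.linspace(4.0, 8.0, 9)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    inp = inp or circ.SystemicInput()
    run = circ.simulate_batch(
        sbp=inp.sbp,
        pp=inp.pp,
        rate=rates,
        a=0.03,
        c=0.1,
        d=0.08,
        cuff_length_m=0.14,
        inp=inp,
        dt=dt,
    )
    beats = bm.beats_from_batch(run, inp.sbp, inp.pp, inp)
    ptt = bm.compute_ptt_series(beats)
    metrics = bm.metrics_matrix(run, beats, ptt)
    df = pd.DataFrame(
        {
            "rate_mmHg_s": rates,
            "p_eq_mmhg": metrics[:, _COL["p_eq_mmhg"]],
            "max_dptt_distal_ms": metrics[:, _COL["max_dptt_distal_ms"]],
            "max_dpat_total_ms": metrics[:, _COL["max_dpat_total_ms"]],
        }
    )
    span = df["max_dptt_distal_ms"]
    df.attrs["dptt_range_ms"] = float(span.max() - span.min()) if len(span) else 0.0
    return df
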