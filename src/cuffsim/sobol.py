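"""Variance-based global sensitivity analysis of the inflation response.

First- and total-order Sobol indices of the six response metrics with
respect to the six varied inputs (tube-law ``a`` and ``c``, systolic
pressure, pulse pressure, cuff inflation rate, cuff length) are estimated
from a Saltelli radial design built on a scrambled Sobol low-discrepancy
sequence: two base matrices A and B of size N x k plus the k hybrid
matrices A_B^(i) (A with column i taken from B), N(k+2) model runs total.

Estimators (the standard defaults of the variance-based methodology):

* first order, Saltelli 2010:  S1_i = mean(f_B * (f_AB_i - f_A)) / V(Y)
* total order, Jansen:         ST_i = mean((f_A - f_AB_i)^2) / (2 V(Y))

Confidence half-widths come from bootstrap resampling of the base rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import beat_metrics as bm
from . import circulation as circ
from .mechanics import ArmGeometry, BloodProperties

__all__ = [
    "ParameterSpec",
    "SampleDesign",
    "SobolResult",
    "table2_specs",
    "generate_design",
    "run_model_batch",
    "compute_sobol_indices",
    "run_sobol_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterSpec:
    """Marginal distribution of one analyzed input parameter."""

    name: str
    kind: str  # "uniform" | "normal"
    args: tuple  # (lo, hi) or (mean, sd)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if len(self.args) != 2:
            raise ValueError("distribution needs exactly two parameters")
        if self.kind == "uniform" and not self.args[0] <= self.args[1]:
            raise ValueError(f"uniform bounds out of order for {self.name}")
        if self.kind == "normal" and not self.args[1] > 0:
            raise ValueError(f"normal sd must be positive for {self.name}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "uniform":
            lo, hi = self.args
            return lo + (hi - lo) * u
        mu, sd = self.args
        return stats.norm.ppf(u, loc=mu, scale=sd)


def table2_specs() -> list[ParameterSpec]:
    """The six analyzed parameters and their assumed population ranges."""
    return [
        ParameterSpec("a", "uniform", (0.017, 0.035)),
        ParameterSpec("c", "uniform", (0.08, 0.14)),
        ParameterSpec("sbp", "normal", (125.0, 15.0)),
        ParameterSpec("pp", "normal", (40.0, 5.0)),
        ParameterSpec("rate", "uniform", (4.0, 8.0)),
        ParameterSpec("cuff_length", "uniform", (0.1, 0.18)),
    ]


@dataclass
class SampleDesign:
    """Saltelli radial design: rows [A; B; A_B^1; ...; A_B^k], N(k+2) total."""

    specs: list[ParameterSpec]
    n_base: int
    unit: np.ndarray  # (N(k+2), k) in the unit hypercube
    physical: np.ndarray  # (N(k+2), k) in physical units
    seed: int
    scheme: str = "saltelli-radial/sobol-scrambled"

    @property
    def k(self) -> int:
        return len(self.specs)

    @property
    def n_rows(self) -> int:
        return self.n_base * (self.k + 2)

    def column(self, name: str) -> np.ndarray:
        names = [s.name for s in self.specs]
        return self.physical[:, names.index(name)]


def generate_design(specs: list[ParameterSpec], n_base: int, seed: int) -> SampleDesign:
    """Build the Saltelli design from a scrambled Sobol sequence.

    ``n_base`` must be a power of two (balance property of the sequence).
    A and B come from one 2k-dimensional draw; normal margins are mapped
    through the exact inverse CDF, uniform margins affinely.
    """
    k = len(specs)
    if k < 1:
        raise ValueError("need at least one parameter")
    m = int(n_base).bit_length() - 1
    if n_base <= 0 or 2**m != n_base:
        raise ValueError(f"n_base must be a power of two, got {n_base}")
    sampler = stats.qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random_base2(m)
    a_blk = base[:, :k]
    b_blk = base[:, k:]
    blocks = [a_blk, b_blk]
    for i in range(k):
        ab = a_blk.copy()
        ab[:, i] = b_blk[:, i]
        blocks.append(ab)
    unit = np.vstack(blocks)
    unit = np.clip(unit, 1e-12, 1.0 - 1e-12)
    physical = np.column_stack([spec.ppf(unit[:, j]) for j, spec in enumerate(specs)])
    return SampleDesign(
        specs=list(specs), n_base=n_base, unit=unit, physical=physical, seed=seed
    )


def run_model_batch(
    design: SampleDesign,
    *,
    inp: circ.SystemicInput | None = None,
    protocol: circ.CuffProtocol | None = None,
    circuit: circ.CircuitParams | None = None,
    blood: BloodProperties | None = None,
    arm_length_m: float = 1.0,
    d: float = 0.08,
    dt: float = 5e-4,
    max_failure_fraction: float = 0.01,
) -> np.ndarray:
    """Simulate every design row and return the (rows, 6) metrics matrix.

    Each row uses its sampled (a, c, SBP, PP, rate, cuff length); everything
    else stays at the reference values.  Physiologically impossible draws
    (DBP within 5 mmHg of the systemic venous pressure) are excluded and
    reported as NaN rows; the run aborts if more than
    ``max_failure_fraction`` of rows are invalid.
    """
    inp = inp or circ.SystemicInput()
    protocol = protocol or circ.CuffProtocol()
    circuit = circuit or circ.CircuitParams()
    blood = blood or BloodProperties()

    a = design.column("a")
    c = design.column("c")
    sbp = design.column("sbp")
    pp = design.column("pp")
    rate = design.column("rate")
    cuff_len = design.column("cuff_length")

    valid = (pp > 0) & (sbp - pp > inp.p_ven_sys + 5.0) & (cuff_len < arm_length_m)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "excluding %d/%d non-physiological design rows: %s",
            n_bad,
            len(valid),
            np.nonzero(~valid)[0][:20],
        )
    if n_bad > max_failure_fraction * len(valid):
        raise RuntimeError(
            f"{n_bad} design rows invalid (> {max_failure_fraction:.0%}); "
            "check the parameter specifications"
        )

    run = circ.simulate_batch(
        sbp=sbp[valid],
        pp=pp[valid],
        rate=rate[valid],
        a=a[valid],
        c=c[valid],
        d=d,
        cuff_length_m=cuff_len[valid],
        inp=inp,
        protocol=protocol,
        circuit=circuit,
        blood=blood,
        dt=dt,
    )
    beats = bm.beats_from_batch(run, sbp[valid], pp[valid], inp)
    geometry = ArmGeometry(arm_length_m=arm_length_m, cuff_length_m=cuff_len[valid])
    # Transit times are a measurement model and use the nominal (reference)
    # tube law; the sampled collapse parameters act on the simulated artery
    # through R_art inside the ODE.
    ptt = bm.compute_ptt_series(beats, geometry, blood=blood)
    sub = bm.metrics_matrix(run, beats, ptt)

    out = np.full((len(valid), sub.shape[1]), np.nan)
    out[valid] = sub
    return out


@dataclass
class SobolResult:
    """First/total-order indices per parameter x metric plus bootstrap CIs."""

    parameters: list[str]
    metrics: list[str]
    s1: np.ndarray  # (k, n_metrics), raw estimates (may be slightly < 0)
    st: np.ndarray
    s1_conf: np.ndarray  # 95% bootstrap half-widths
    st_conf: np.ndarray
    n_base: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def s1_clipped(self) -> np.ndarray:
        """Presentation values: sampling noise below zero clipped at 0."""
        return np.clip(self.s1, 0.0, None)

    @property
    def st_clipped(self) -> np.ndarray:
        return np.clip(self.st, 0.0, None)

    def s1_of(self, parameter: str, metric: str) -> float:
        return float(
            self.s1[self.parameters.index(parameter), self.metrics.index(metric)]
        )

    def st_of(self, parameter: str, metric: str) -> float:
        return float(
            self.st[self.parameters.index(parameter), self.metrics.index(metric)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Report table: rows = parameters, column pairs S1/ST per metric."""
        cols = pd.MultiIndex.from_product([self.metrics, ["S1", "ST"]])
        data = np.empty((len(self.parameters), 2 * len(self.metrics)))
        data[:, 0::2] = self.s1_clipped
        data[:, 1::2] = self.st_clipped
        return pd.DataFrame(data, index=self.parameters, columns=cols)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "metrics": self.metrics,
            "s1": self.s1.tolist(),
            "st": self.st.tolist(),
            "s1_conf": self.s1_conf.tolist(),
            "st_conf": self.st_conf.tolist(),
            "n_base": self.n_base,
            "seed": self.seed,
            "meta": self.meta,
        }


def _saltelli_estimators(f_a, f_b, f_ab, variance):
    """S1 (Saltelli 2010) and ST (Jansen) for one parameter and metric."""
    s1 = np.mean(f_b * (f_ab - f_a)) / variance
    st = 0.5 * np.mean((f_a - f_ab) ** 2) / variance
    return s1, st


def compute_sobol_indices(
    design: SampleDesign,
    outputs: np.ndarray,
    *,
    metric_names: list[str] | None = None,
    n_bootstrap: int = 100,
    bootstrap_seed: int | None = None,
) -> SobolResult:
    """Estimate S1/ST per parameter and output column.

    Base rows with a non-finite value in any block are dropped (listwise per
    metric).  Raises if an output column has (numerically) zero variance.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] == design.n_rows and outputs.ndim == 2:
        pass
    elif outputs.shape[1] == design.n_rows:
        outputs = outputs.T
    else:
        raise ValueError("outputs not aligned with the design")
    k = design.k
    n = design.n_base
    n_metrics = outputs.shape[1]
    metric_names = metric_names or [f"y{j}" for j in range(n_metrics)]

    rng = np.random.default_rng(
        design.seed + 1 if bootstrap_seed is None else bootstrap_seed
    )
    s1 = np.empty((k, n_metrics))
    st = np.empty((k, n_metrics))
    s1_conf = np.empty((k, n_metrics))
    st_conf = np.empty((k, n_metrics))

    for j in range(n_metrics):
        y = outputs[:, j]
        f_a = y[:n]
        f_b = y[n : 2 * n]
        f_ab = np.stack([y[(2 + i) * n : (3 + i) * n] for i in range(k)])
        ok = np.isfinite(f_a) & np.isfinite(f_b) & np.all(np.isfinite(f_ab), axis=0)
        if ok.sum() < 8:
            raise ValueError(f"too few valid rows for metric {metric_names[j]!r}")
        f_a, f_b, f_ab = f_a[ok], f_b[ok], f_ab[:, ok]
        variance = np.var(np.concatenate([f_a, f_b]))
        if variance <= 1e-12 * max(1.0, np.mean(np.abs(f_a))) ** 2:
            raise ValueError(f"metric {metric_names[j]!r} has ~zero variance")
        for i in range(k):
            s1[i, j], st[i, j] = _saltelli_estimators(f_a, f_b, f_ab[i], variance)

        m = ok.sum()
        boot_s1 = np.empty((n_bootstrap, k))
        boot_st = np.empty((n_bootstrap, k))
        for r in range(n_bootstrap):
            sel = rng.integers(0, m, size=m)
            fa, fb, fab = f_a[sel], f_b[sel], f_ab[:, sel]
            v = np.var(np.concatenate([fa, fb]))
            for i in range(k):
                boot_s1[r, i], boot_st[r, i] = _saltelli_estimators(
                    fa, fb, fab[i], v
                )
        s1_conf[:, j] = 1.96 * boot_s1.std(axis=0, ddof=1)
        st_conf[:, j] = 1.96 * boot_st.std(axis=0, ddof=1)

    return SobolResult(
        parameters=[s.name for s in design.specs],
        metrics=list(metric_names),
        s1=s1,
        st=st,
        s1_conf=s1_conf,
        st_conf=st_conf,
        n_base=n,
        seed=design.seed,
    )


def run_sobol_analysis(
    specs: list[ParameterSpec] | None = None,
    n_base: int = 1024,
    seed: int = 0,
    *,
    dt: float = 5e-4,
    **model_kwargs,
) -> tuple[SobolResult, np.ndarray, SampleDesign]:
    """Design -> batch simulation -> indices, end to end.

    Returns the :class:`SobolResult`, the raw (rows, 6) outputs matrix and
    the design (the latter two feed the regression experiments).
    """
    specs = specs or table2_specs()
    design = generate_design(specs, n_base, seed)
    outputs = run_model_batch(design, dt=dt, **model_kwargs)
    result = compute_sobol_indices(
        design, outputs, metric_names=list(bm.METRIC_NAMES)
    )
    result.meta["dt"] = dt
    return result, outputs, design
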