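"""Aggregated-Markov likelihood of idealized gating records and the two-stage fit.

A record is an alternating sequence of closed/open dwell durations
(t_c1, t_o1, ..., t_cn, t_on).  Its likelihood under a generator Q partitioned
into open/closed blocks is the matrix product

    L = pi_C @ e^(Qcc tc1) @ Qco @ e^(Qoo to1) @ Qoc @ ... @ e^(Qoo ton) @ 1_O,

where pi_C = W_O @ Q_OC / J is the equilibrium entry distribution into the
closed aggregate (records are assumed to begin at stationarity) and the final
open dwell contributes only its survival factor: the record ends because the
recording stopped, not because the channel closed.

The fitting procedure is two-stage, mirroring how the single-channel data were
analyzed: (1) a least-squares fit of the occupancy parameters to measured
(Po, pi_L, pi_I, pi_H) summaries; (2) a Nelder-Mead maximum-likelihood fit of
the flux parameters on the dwell sequences with occupancies held fixed.
Both stages optimize in log10 parameter space to enforce positivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm
from scipy.optimize import least_squares, minimize

from .model import (
    GeneratorMatrix,
    build_generator,
    modal_prevalences,
    open_probability,
)
from .params import (
    FLUX_NAMES,
    FluxParams,
    M146L_FREE_FLUX,
    M146L_FREE_OCCUPANCY,
    OccupancyParams,
)
from .states import STATE_NAMES, LigandCondition

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


__all__ = [
    "IdealizedTrace",
    "GatingSummary",
    "FitResult",
    "dwell_sequence_loglik",
    "trace_loglik",
    "dataset_loglik",
    "fit_occupancy",
    "fit_flux",
    "write_traces",
    "read_traces",
]


@dataclass(frozen=True)
class IdealizedTrace:
    """Alternating closed/open dwell sequence of one gating record.

    ``durations`` holds (t_c1, t_o1, ..., t_cn, t_on) in ms: the record starts
    with a closed dwell and ends with an open dwell, whose end is censored by
    the end of the recording.
    """

    durations: np.ndarray
    lig: LigandCondition
    variant: str = "unknown"
    record_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "durations", d)
        if d.ndim != 1 or len(d) == 0 or len(d) % 2 != 0:
            raise ValueError(
                "a trace must contain an even, positive number of dwells "
                "(closed-leading, open-trailing)"
            )
        if not (d > 0).all():
            raise ValueError("dwell durations must be > 0")

    @property
    def n_pairs(self) -> int:
        return len(self.durations) // 2

    @property
    def closed_dwells(self) -> np.ndarray:
        return self.durations[0::2]

    @property
    def open_dwells(self) -> np.ndarray:
        return self.durations[1::2]

    @property
    def total_ms(self) -> float:
        return float(self.durations.sum())


@dataclass(frozen=True)
class GatingSummary:
    """Measured equilibrium observables of a trace ensemble at one condition."""

    lig: LigandCondition
    po: float
    pi_l: float
    pi_i: float
    pi_h: float
    po_se: float = float("nan")
    pi_se: tuple[float, float, float] = (float("nan"),) * 3
    tau_o_ms: float = float("nan")
    tau_c_ms: float = float("nan")
    n_records: int = 0


@dataclass
class FitResult:
    """Outcome of one fitting stage."""

    params: OccupancyParams | FluxParams
    objective: float
    converged: bool
    n_iter: int
    free: tuple[str, ...]
    message: str = ""


# ---------------------------------------------------------------------------
# Likelihood propagation


@njit(cache=False)
def _propagate_eig(durations, Vc, Vci, lc, Vo, Voi, lo, Qco, Qoc, pi_c, u_o):
    """Log-likelihood of one dwell sequence via precomputed eigenbases.

    Renormalizes the state row-vector after every dwell factor, accumulating
    log norms, so arbitrarily long records cannot underflow.
    """
    n = durations.shape[0] // 2
    v = pi_c.copy()
    logl = 0.0
    for i in range(n):
        tc = durations[2 * i]
        to = durations[2 * i + 1]
        # closed dwell density factor, then transition into the open block
        c = (v.astype(np.complex128) @ Vc) * np.exp(lc * tc)
        v = (c @ Vci).real.copy()
        v = v @ Qco
        s = np.abs(v).sum()
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf
        v = v / s
        logl += np.log(s)
        # open dwell
        c = (v.astype(np.complex128) @ Vo) * np.exp(lo * to)
        v = (c @ Voi).real.copy()
        if i < n - 1:
            v = v @ Qoc
        s = np.abs(v).sum()
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf
        v = v / s
        logl += np.log(s)
    final = v @ u_o
    if final <= 0.0:
        return -np.inf
    return logl + np.log(final)


def _propagate_expm(durations, Qcc, Qoo, Qco, Qoc, pi_c, u_o):
    """Reference propagation using scipy.linalg.expm per dwell (slow, robust)."""
    n = len(durations) // 2
    v = pi_c.copy()
    logl = 0.0
    for i in range(n):
        v = v @ expm(Qcc * durations[2 * i]) @ Qco
        s = np.abs(v).sum()
        if s <= 0 or not np.isfinite(s):
            return -np.inf
        v /= s
        logl += np.log(s)
        v = v @ expm(Qoo * durations[2 * i + 1])
        if i < n - 1:
            v = v @ Qoc
        s = np.abs(v).sum()
        if s <= 0 or not np.isfinite(s):
            return -np.inf
        v /= s
        logl += np.log(s)
    final = float(v @ u_o)
    return logl + np.log(final) if final > 0 else -np.inf


class _Propagator:
    """Per-condition likelihood engine: eigendecomposes the Q blocks once."""

    def __init__(self, gen: GeneratorMatrix):
        self.gen = gen
        J = gen.exit_flux()
        if J <= 0:
            raise ValueError("open<->closed flux is zero: likelihood undefined")
        self.pi_c = (gen.w_open @ gen.Qoc) / J
        self.u_o = np.ones(gen.Qoo.shape[0])
        self._eig_ok = True
        try:
            lc, Vc = np.linalg.eig(gen.Qcc)
            lo, Vo = np.linalg.eig(gen.Qoo)
            Vci = np.linalg.inv(Vc)
            Voi = np.linalg.inv(Vo)
            if (
                np.linalg.cond(Vc) > 1e10
                or np.linalg.cond(Vo) > 1e10
            ):
                self._eig_ok = False
            else:
                as_c = lambda a: np.ascontiguousarray(a, dtype=np.complex128)
                self.Vc, self.Vci, self.lc = as_c(Vc), as_c(Vci), as_c(lc)
                self.Vo, self.Voi, self.lo = as_c(Vo), as_c(Voi), as_c(lo)
        except np.linalg.LinAlgError:
            self._eig_ok = False

    def loglik(self, durations: np.ndarray) -> float:
        if self._eig_ok and _HAVE_NUMBA:
            return float(
                _propagate_eig(
                    np.ascontiguousarray(durations, dtype=np.float64),
                    self.Vc, self.Vci, self.lc,
                    self.Vo, self.Voi, self.lo,
                    np.ascontiguousarray(self.gen.Qco),
                    np.ascontiguousarray(self.gen.Qoc),
                    np.ascontiguousarray(self.pi_c),
                    self.u_o,
                )
            )
        return float(
            _propagate_expm(
                durations, self.gen.Qcc, self.gen.Qoo,
                self.gen.Qco, self.gen.Qoc, self.pi_c, self.u_o,
            )
        )


def dwell_sequence_loglik(
    durations: np.ndarray,
    Qoo: np.ndarray,
    Qoc: np.ndarray,
    Qco: np.ndarray,
    Qcc: np.ndarray,
    w_open: np.ndarray,
) -> float:
    """Log-likelihood of one alternating dwell sequence for arbitrary block sizes.

    Generic core, independent of the twelve-state model: useful for small
    hand-checkable chains.  ``w_open`` are the unnormalized equilibrium
    occupancies of the open states, from which the closed-entry distribution
    pi_C = W_O @ Q_OC / J is formed.
    """
    J = float(w_open @ Qoc @ np.ones(Qcc.shape[0]))
    if J <= 0:
        raise ValueError("open<->closed flux is zero")
    pi_c = (w_open @ Qoc) / J
    return float(
        _propagate_expm(np.asarray(durations, float), Qcc, Qoo, Qco, Qoc,
                        pi_c, np.ones(Qoo.shape[0]))
    )


def trace_loglik(trace: IdealizedTrace, gen: GeneratorMatrix) -> float:
    """Log-likelihood of one record under a generator built at its condition."""
    return _Propagator(gen).loglik(trace.durations)


def dataset_loglik(
    traces: list[IdealizedTrace],
    occ: OccupancyParams,
    flux: FluxParams,
) -> float:
    """Total log-likelihood over an ensemble; Q is rebuilt per ligand condition."""
    if not traces:
        raise ValueError("empty dataset")
    props: dict[tuple[float, float], _Propagator] = {}
    total = 0.0
    for tr in traces:
        key = (tr.lig.ca, tr.lig.ip3)
        if key not in props:
            props[key] = _Propagator(build_generator(occ, flux, tr.lig))
        total += props[key].loglik(tr.durations)
    return total


# ---------------------------------------------------------------------------
# Stage 1: occupancy fit


def fit_occupancy(
    summaries: list[GatingSummary],
    start: OccupancyParams,
    free: tuple[str, ...] = M146L_FREE_OCCUPANCY,
    variant: str = "fit",
) -> FitResult:
    """Least-squares fit of occupancy parameters to (Po, pi_L, pi_I, pi_H).

    Unweighted SSE over all supplied conditions; only the parameters named in
    ``free`` move, the rest stay pinned to ``start``.  Optimization is over
    log10 of the free parameters.
    """
    n_data = 4 * len(summaries)
    if n_data < len(free):
        raise ValueError(
            f"{len(free)} free parameters but only {n_data} data values"
        )

    def build(theta: np.ndarray) -> OccupancyParams:
        return start.with_values(
            variant=variant,
            **{name: 10.0 ** float(t) for name, t in zip(free, theta)},
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        occ = build(theta)
        res = []
        for s in summaries:
            pl, pi, ph = modal_prevalences(occ, s.lig)
            res += [
                open_probability(occ, s.lig) - s.po,
                pl - s.pi_l, pi - s.pi_i, ph - s.pi_h,
            ]
        return np.array(res)

    # optimize in log10 space within +-8 decades of the start, so summaries
    # carrying no information about a parameter leave it finite rather than
    # running it to zero
    theta0 = np.log10([start[name] for name in free])
    sol = least_squares(
        residuals, theta0, method="trf",
        bounds=(theta0 - 8.0, theta0 + 8.0),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return FitResult(
        params=build(sol.x),
        objective=float(2 * sol.cost),  # SSE
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        free=tuple(free),
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# Stage 2: flux fit


@dataclass(frozen=True)
class OptimizerConfig:
    """Nelder-Mead settings for the flux fit."""

    fatol: float = 1e-6
    xatol: float = 1e-6
    maxiter: int = 5000
    restarts: int = 3
    perturbation: float = 0.15  # log10 units for restart simplices
    seed: int = 0


def fit_flux(
    traces: list[IdealizedTrace],
    occ: OccupancyParams,
    start: FluxParams,
    free: tuple[str, ...] = M146L_FREE_FLUX,
    config: OptimizerConfig | None = None,
    variant: str = "fit",
) -> FitResult:
    """Maximum-likelihood flux fit with occupancies held fixed.

    Nelder-Mead minimization of -log-likelihood over log10 of the free flux
    parameters, with optional restarts from randomly perturbed starting
    points (seeded).  Returns the best point found; ``converged`` is False if
    no restart reported success.
    """
    cfg = config or OptimizerConfig()
    rng = np.random.default_rng(cfg.seed)

    def build(theta: np.ndarray) -> FluxParams:
        return start.with_values(
            variant=variant, **{name: 10.0 ** t for name, t in zip(free, theta)}
        )

    def objective(theta: np.ndarray) -> float:
        ll = dataset_loglik(traces, occ, build(theta))
        return -ll if np.isfinite(ll) else 1e300

    theta0 = np.log10([start[name] for name in free])
    best = None
    best_success = False
    n_iter = 0
    for k in range(1 + cfg.restarts):
        x0 = theta0 if k == 0 else theta0 + rng.normal(0, cfg.perturbation, len(free))
        sol = minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(fatol=cfg.fatol, xatol=cfg.xatol, maxiter=cfg.maxiter),
        )
        n_iter += int(sol.nit)
        if best is None or sol.fun < best.fun:
            best = sol
            best_success = bool(sol.success)
    return FitResult(
        params=build(best.x),
        objective=float(best.fun),
        converged=best_success,
        n_iter=n_iter,
        free=tuple(free),
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Trace file I/O: CSV of (record_id, conductance, duration_ms) plus a YAML
# sidecar carrying ligand condition and variant per record.


def write_traces(path, traces: list[IdealizedTrace]) -> None:
    rows = []
    meta = {}
    for k, tr in enumerate(traces):
        rid = tr.record_id or f"rec{k:03d}"
        conds = np.zeros(len(tr.durations), dtype=int)
        conds[1::2] = 1
        for c, d in zip(conds, tr.durations):
            rows.append((rid, int(c), float(d)))
        meta[rid] = dict(ca_uM=tr.lig.ca, ip3_uM=tr.lig.ip3, variant=tr.variant)
    pd.DataFrame(rows, columns=["record_id", "conductance", "duration_ms"]).to_csv(
        path, index=False
    )
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_traces(path) -> list[IdealizedTrace]:
    df = pd.read_csv(path)
    with open(str(path) + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    traces = []
    for rid, grp in df.groupby("record_id", sort=False):
        cond = grp["conductance"].to_numpy()
        if not (cond[0::2] == 0).all() or not (cond[1::2] == 1).all():
            raise ValueError(f"record {rid}: dwells must alternate closed/open")
        m = meta[rid]
        traces.append(
            IdealizedTrace(
                durations=grp["duration_ms"].to_numpy(float),
                lig=LigandCondition(m["ca_uM"], m["ip3_uM"]),
                variant=m.get("variant", "unknown"),
                record_id=str(rid),
            )
        )
    return traces
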