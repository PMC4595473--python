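"""Stochastic simulation of single-channel gating and empirical trace analysis.

This module is the synthetic stand-in for nuclear-patch-clamp gating records:
it generates stationary trajectories of the twelve-state chain at fixed ligand
concentrations by exact stochastic simulation, collapses them to idealized
alternating closed/open dwell sequences, and analyzes records the way the
experimental traces were analyzed — burst filtering of short closings followed
by modal segmentation with critical burst duration T_b = 100 ms and critical
gap duration T_g = 200 ms.

Ensemble defaults mirror the study conditions: 30 records (WT) or 15 records
(M146L), 30 s each, per ligand condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import GatingSummary, IdealizedTrace
from .model import GeneratorMatrix, build_generator
from .params import FluxParams, OccupancyParams
from .states import N_OPEN, STATE_NAMES, LigandCondition

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco


__all__ = [
    "StateTrajectory",
    "SegmentationParams",
    "ModalSegmentation",
    "simulate_trajectory",
    "merge_conductance",
    "to_idealized",
    "segment_modes",
    "segment_dwell_sequence",
    "empirical_summary",
    "trajectory_summary",
    "simulate_ensemble",
    "simulate_trajectory_ensemble",
    "default_ensemble_size",
]


def default_ensemble_size(variant: str) -> int:
    """Number of records per condition used in the study: 30 WT, 15 mutant."""
    return 15 if variant == "M146L" else 30


@dataclass(frozen=True)
class StateTrajectory:
    """A Markov-jump realization: visited states and their sojourn times (ms)."""

    states: np.ndarray     # int indices in canonical order
    sojourns_ms: np.ndarray
    lig: LigandCondition
    variant: str
    seed: int

    @property
    def duration_ms(self) -> float:
        return float(self.sojourns_ms.sum())


@njit(cache=False)
def _jump_chain(cum_rows, exit_rates, start, t_max, seed, cap):
    """Exact CTMC simulation; returns filled length or -1 if cap was hit."""
    np.random.seed(seed)
    states = np.empty(cap, dtype=np.int64)
    sojourns = np.empty(cap, dtype=np.float64)
    s = start
    t = 0.0
    n = 0
    while t < t_max:
        if n >= cap:
            return states, sojourns, -1
        rate = exit_rates[s]
        if rate <= 0.0:  # absorbing (cannot happen for this model at I>0)
            states[n] = s
            sojourns[n] = t_max - t
            return states, sojourns, n + 1
        dt = np.random.exponential(1.0 / rate)
        if t + dt > t_max:
            dt = t_max - t
            states[n] = s
            sojourns[n] = dt
            return states, sojourns, n + 1
        states[n] = s
        sojourns[n] = dt
        n += 1
        t += dt
        u = np.random.random()
        row = cum_rows[s]
        nxt = 0
        for k in range(row.shape[0]):
            if u <= row[k]:
                nxt = k
                break
        s = nxt
    return states, sojourns, n


def simulate_trajectory(
    gen: GeneratorMatrix,
    duration_ms: float,
    seed: int,
    variant: str = "unknown",
    start_state: int | None = None,
) -> StateTrajectory:
    """Exact stochastic simulation of the chain for ``duration_ms``.

    The initial state is drawn from the equilibrium occupancy distribution
    unless ``start_state`` is given.  Sojourns are exponential with rate
    -Q_ii; the final sojourn is truncated at the horizon.  Fully reproducible
    under a fixed seed.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    Q = gen.Q
    exit_rates = -np.diag(Q)
    P = Q.copy()
    np.fill_diagonal(P, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = P / exit_rates[:, None]
    P[~np.isfinite(P)] = 0.0
    cum = np.cumsum(P, axis=1)
    # guard against roundoff leaving the last cumulative slightly below 1
    cum[:, -1] = 1.0

    rng = np.random.default_rng(seed)
    if start_state is None:
        w = gen.weights / gen.weights.sum()
        start_state = int(rng.choice(len(w), p=w))
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    mean_rate = float(np.sum(gen.weights / gen.weights.sum() * exit_rates))
    cap = max(1000, int(3 * mean_rate * duration_ms) + 1000)
    while True:
        states, sojourns, n = _jump_chain(
            cum, exit_rates, start_state, float(duration_ms), kernel_seed, cap
        )
        if n >= 0:
            break
        cap *= 4
    return StateTrajectory(
        states=states[:n].copy(),
        sojourns_ms=sojourns[:n].copy(),
        lig=gen.lig,
        variant=variant,
        seed=seed,
    )


_OPEN_STATE = np.array([i < N_OPEN for i in range(len(STATE_NAMES))])


def merge_conductance(traj: StateTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a trajectory to conductance dwells without any trimming.

    Returns (conductances, durations) with conductance 0 = closed, 1 = open.
    Unlike :func:`to_idealized` this keeps censored leading/trailing dwells,
    so time-weighted statistics over the full record remain unbiased — which
    matters here because the model's low-activity mode contains quiescent
    sojourns that can exceed the record length.
    """
    if len(traj.states) == 0:
        raise ValueError("empty trajectory")
    is_open = _OPEN_STATE[traj.states]
    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [len(is_open)]))
    durations = np.add.reduceat(traj.sojourns_ms, bounds[:-1])
    conds = is_open[bounds[:-1]].astype(int)
    return conds, durations


def to_idealized(traj: StateTrajectory) -> IdealizedTrace:
    """Collapse a state trajectory to an alternating closed/open dwell record.

    Consecutive sojourns in the same conductance class merge into one dwell.
    The record is then trimmed to the likelihood convention: it starts at the
    first closed dwell that follows a closing transition (so the first closed
    dwell is entry-distributed, matching the equilibrium entry vector used in
    the likelihood) and ends with the last open dwell (censored).
    """
    if len(traj.states) == 0:
        raise ValueError("empty trajectory")
    is_open = _OPEN_STATE[traj.states]
    # merge runs of equal conductance
    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [len(is_open)]))
    durations = np.add.reduceat(traj.sojourns_ms, bounds[:-1])
    conds = is_open[bounds[:-1]]
    if not conds.any():
        raise ValueError("trajectory contains no opening: no idealized trace")
    # start: first closed dwell preceded by an open dwell
    first_open = int(np.argmax(conds))
    start = first_open + 1
    # end: last open dwell
    last_open = len(conds) - 1 - int(np.argmax(conds[::-1]))
    if start >= last_open:
        raise ValueError("trajectory too short to form a closed-leading record")
    d = durations[start : last_open + 1]
    return IdealizedTrace(
        durations=d, lig=traj.lig, variant=traj.variant,
        record_id=f"sim-{traj.seed}",
    )


# ---------------------------------------------------------------------------
# Burst filtering and modal segmentation


@dataclass(frozen=True)
class SegmentationParams:
    """Critical durations of the burst/gap analysis (ms).

    Closings shorter than ``t_short`` are treated as intraburst flicker and
    removed before burst parsing; closed gaps of at least ``t_g_crit`` are
    L-mode quiescent periods; bursts lasting at least ``t_b_crit`` are H mode,
    shorter bursts I mode.  Ties at exactly a critical value go to the
    longer-duration class.
    """

    t_b_crit: float = 100.0
    t_g_crit: float = 200.0
    t_short: float = 10.0

    def __post_init__(self) -> None:
        if min(self.t_b_crit, self.t_g_crit, self.t_short) <= 0:
            raise ValueError("segmentation thresholds must be > 0")


@dataclass(frozen=True)
class ModalSegmentation:
    """Modal segments tiling one record, with derived summary statistics."""

    segments: tuple[tuple[str, float, float], ...]  # (mode, start_ms, end_ms)
    total_ms: float

    @property
    def prevalences(self) -> dict[str, float]:
        t = {"L": 0.0, "I": 0.0, "H": 0.0}
        for mode, a, b in self.segments:
            t[mode] += b - a
        return {m: v / self.total_ms for m, v in t.items()}

    @property
    def mean_sojourn_ms(self) -> dict[str, float]:
        tot = {"L": 0.0, "I": 0.0, "H": 0.0}
        cnt = {"L": 0, "I": 0, "H": 0}
        for mode, a, b in self.segments:
            tot[mode] += b - a
            cnt[mode] += 1
        return {m: (tot[m] / cnt[m] if cnt[m] else float("nan")) for m in tot}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["mode", "start_ms", "end_ms"])


def _filter_short_closings(
    conds: np.ndarray, durs: np.ndarray, t_short: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge closed dwells shorter than t_short into the surrounding burst.

    Interior short closings become open (burst) time; merging never decreases
    any burst duration.  Leading/trailing short closings merge into the first/
    last burst as well.
    """
    keep_closed = (conds == 0) & (durs >= t_short)
    new_conds = np.where(keep_closed, 0, 1)
    change = np.flatnonzero(np.diff(new_conds)) + 1
    bounds = np.concatenate(([0], change, [len(new_conds)]))
    out_d = np.add.reduceat(durs, bounds[:-1])
    out_c = new_conds[bounds[:-1]]
    return out_c, out_d


def segment_modes(
    trace: IdealizedTrace, seg: SegmentationParams | None = None
) -> ModalSegmentation:
    """Assign L/I/H gating modes along a record from burst/gap durations."""
    conds = np.zeros(len(trace.durations), dtype=int)
    conds[1::2] = 1
    return segment_dwell_sequence(conds, trace.durations, seg)


def segment_dwell_sequence(
    conds: np.ndarray, durations: np.ndarray, seg: SegmentationParams | None = None
) -> ModalSegmentation:
    """Burst/gap modal segmentation of an arbitrary conductance dwell sequence."""
    seg = seg or SegmentationParams()
    fc, fd = _filter_short_closings(np.asarray(conds), np.asarray(durations, float),
                                    seg.t_short)

    segments: list[tuple[str, float, float]] = []
    t = 0.0
    burst_start: float | None = None
    for c, d in zip(fc, fd):
        is_gap = c == 0 and d >= seg.t_g_crit
        if is_gap:
            if burst_start is not None:
                dur = t - burst_start
                segments.append(("H" if dur >= seg.t_b_crit else "I", burst_start, t))
                burst_start = None
            segments.append(("L", t, t + d))
        else:
            if burst_start is None:
                burst_start = t
        t += d
    if burst_start is not None:
        dur = t - burst_start
        segments.append(("H" if dur >= seg.t_b_crit else "I", burst_start, t))
    return ModalSegmentation(segments=tuple(segments), total_ms=t)


# ---------------------------------------------------------------------------
# Empirical ensemble summaries


def empirical_summary(
    traces: list[IdealizedTrace],
    seg: SegmentationParams | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> GatingSummary:
    """Measured Po, mean dwell times and modal prevalences of an ensemble.

    Po and prevalences are time-weighted over the pooled records; standard
    errors come from a per-record bootstrap.
    """
    if not traces:
        raise ValueError("need at least one trace")
    seg = seg or SegmentationParams()

    def stats(sub: list[IdealizedTrace]) -> tuple[float, float, float, float]:
        open_t = sum(float(tr.open_dwells.sum()) for tr in sub)
        total_t = sum(tr.total_ms for tr in sub)
        mode_t = {"L": 0.0, "I": 0.0, "H": 0.0}
        for tr in sub:
            ms = segment_modes(tr, seg)
            for m, a, b in ms.segments:
                mode_t[m] += b - a
        tot_mode = sum(mode_t.values())
        return (
            open_t / total_t,
            mode_t["L"] / tot_mode, mode_t["I"] / tot_mode, mode_t["H"] / tot_mode,
        )

    po, pl, pi, ph = stats(traces)
    tau_o = float(np.mean(np.concatenate([tr.open_dwells for tr in traces])))
    tau_c = float(np.mean(np.concatenate([tr.closed_dwells for tr in traces])))

    rng = np.random.default_rng(seed)
    boots = []
    if n_boot > 0 and len(traces) > 1:
        for _ in range(n_boot):
            idx = rng.integers(0, len(traces), len(traces))
            boots.append(stats([traces[i] for i in idx]))
        se = np.std(np.array(boots), axis=0, ddof=1)
    else:
        se = np.full(4, np.nan)

    lig = traces[0].lig
    return GatingSummary(
        lig=lig, po=po, pi_l=pl, pi_i=pi, pi_h=ph,
        po_se=float(se[0]), pi_se=(float(se[1]), float(se[2]), float(se[3])),
        tau_o_ms=tau_o, tau_c_ms=tau_c, n_records=len(traces),
    )


def trajectory_summary(
    trajs: list[StateTrajectory],
    seg: SegmentationParams | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> GatingSummary:
    """Ensemble summary measured on untrimmed trajectories.

    Includes records with no openings at all (pure quiescence), which the
    closed-leading/open-trailing trace convention necessarily discards; with
    L-mode sojourns comparable to the record length those silent records carry
    a substantial share of the stationary closed time, so this estimator is
    the one to use when feeding measured summaries back into parameter fits.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    seg = seg or SegmentationParams()
    merged = [merge_conductance(tr) for tr in trajs]

    def stats(items) -> tuple[float, float, float, float]:
        open_t = total_t = 0.0
        mode_t = {"L": 0.0, "I": 0.0, "H": 0.0}
        for conds, durs in items:
            open_t += float(durs[conds == 1].sum())
            total_t += float(durs.sum())
            ms = segment_dwell_sequence(conds, durs, seg)
            for m, a, b in ms.segments:
                mode_t[m] += b - a
        tot = sum(mode_t.values())
        return (open_t / total_t,
                mode_t["L"] / tot, mode_t["I"] / tot, mode_t["H"] / tot)

    po, pl, pi, ph = stats(merged)
    # mean dwell times from interior (uncensored) dwells only
    opens, closes = [], []
    for conds, durs in merged:
        if len(durs) > 2:
            interior_c, interior_d = conds[1:-1], durs[1:-1]
            opens.append(interior_d[interior_c == 1])
            closes.append(interior_d[interior_c == 0])
    tau_o = float(np.concatenate(opens).mean()) if opens else float("nan")
    tau_c = float(np.concatenate(closes).mean()) if closes else float("nan")

    rng = np.random.default_rng(seed)
    if n_boot > 0 and len(merged) > 1:
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(merged), len(merged))
            boots.append(stats([merged[i] for i in idx]))
        se = np.std(np.array(boots), axis=0, ddof=1)
    else:
        se = np.full(4, np.nan)

    return GatingSummary(
        lig=trajs[0].lig, po=po, pi_l=pl, pi_i=pi, pi_h=ph,
        po_se=float(se[0]), pi_se=(float(se[1]), float(se[2]), float(se[3])),
        tau_o_ms=tau_o, tau_c_ms=tau_c, n_records=len(trajs),
    )


def simulate_trajectory_ensemble(
    occ: OccupancyParams,
    flux: FluxParams,
    lig: LigandCondition,
    n_records: int,
    record_s: float,
    seed: int = 0,
) -> list[StateTrajectory]:
    """Independent stationary trajectories with deterministically derived seeds."""
    gen = build_generator(occ, flux, lig)
    children = np.random.SeedSequence(seed).spawn(n_records)
    return [
        simulate_trajectory(
            gen, record_s * 1e3,
            int(child.generate_state(1)[0] % (2**31 - 1)),
            variant=occ.variant,
        )
        for child in children
    ]


def simulate_ensemble(
    occ: OccupancyParams,
    flux: FluxParams,
    lig: LigandCondition,
    n_records: int | None = None,
    record_s: float = 30.0,
    seed: int = 0,
) -> list[IdealizedTrace]:
    """Generate an ensemble of idealized records at one ligand condition.

    Record count defaults to the study's ensemble size for the parameter
    variant.  Each record gets an independent, deterministically derived seed.
    """
    if n_records is None:
        n_records = default_ensemble_size(occ.variant)
    gen = build_generator(occ, flux, lig)
    children = np.random.SeedSequence(seed).spawn(n_records)
    traces = []
    for k, child in enumerate(children):
        rec_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        traj = simulate_trajectory(gen, record_s * 1e3, rec_seed, variant=occ.variant)
        try:
            tr = to_idealized(traj)
        except ValueError:
            # a record spent entirely in quiescence carries no dwell
            # alternations and cannot form a closed-leading/open-trailing
            # trace; the ensemble simply contains fewer usable records, as
            # patch-clamp ensembles do
            continue
        traces.append(
            IdealizedTrace(
                durations=tr.durations, lig=lig, variant=occ.variant,
                record_id=f"rec{k:03d}",
            )
        )
    if not traces:
        raise ValueError("no record in the ensemble contained an opening")
    return traces
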