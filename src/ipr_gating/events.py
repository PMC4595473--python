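"""Ca2+ release-event detection, puff/blip statistics, and ligand sweeps.

A release event is a maximal interval during which at least one channel in
the cluster is open, with all-closed gaps shorter than a separation threshold
bridged into the same event.  Events recruiting more than one channel at
their peak are puffs; single-channel events are blips.  Event life time runs
from event start to the last closing; termination time runs from the moment
of maximal simultaneous openings to the last closing.

The ligand-sweep analysis evaluates the equilibrium observables of the two
variants over (Ca2+, IP3) grids and locates the crossing concentrations that
quantify the mutant's sensitization: the IP3 at which the mutant's Po at
optimal Ca2+ reaches the wild-type's Po measured at 100 nM IP3, and the IP3
at which the mutant's L- and H-mode prevalences cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cluster import ClusterTrace
from .model import modal_prevalences, open_probability
from .params import FluxParams, OccupancyParams
from .states import LigandCondition

__all__ = [
    "ReleaseEvent",
    "detect_events",
    "events_frame",
    "EventStatistics",
    "event_statistics",
    "SweepResult",
    "ligand_sweep",
]


@dataclass(frozen=True)
class ReleaseEvent:
    """One detected Ca2+ release event."""

    start_s: float
    end_s: float
    max_open: int
    t_max_open_s: float
    peak_ca_uM: float     # peak summed excess free Ca2+ at the cluster centre
    peak_dye_uM: float    # peak summed excess bound dye at the observation shell

    @property
    def kind(self) -> str:
        return "blip" if self.max_open == 1 else "puff"

    @property
    def life_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def termination_s(self) -> float:
        return self.end_s - self.t_max_open_s


def detect_events(trace: ClusterTrace, t_sep_s: float = 0.020) -> list[ReleaseEvent]:
    """Segment a cluster recording into release events.

    All-closed gaps shorter than ``t_sep_s`` are bridged; every open sample
    belongs to exactly one event.
    """
    n_open = np.asarray(trace.n_open)
    t = np.asarray(trace.t_s)
    if len(n_open) == 0:
        return []
    dt = trace.t_s[1] - trace.t_s[0] if len(t) > 1 else trace.dt_s
    open_mask = n_open > 0
    if not open_mask.any():
        return []
    # maximal open runs
    edges = np.diff(open_mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if open_mask[0]:
        starts.insert(0, 0)
    if open_mask[-1]:
        ends.append(len(n_open))
    # bridge short gaps
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt < t_sep_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        seg = n_open[s:e]
        k = int(np.argmax(seg))
        events.append(
            ReleaseEvent(
                start_s=float(t[s] - dt),  # sample covers (t-dt, t]
                end_s=float(t[e - 1]),
                max_open=int(seg.max()),
                t_max_open_s=float(t[s + k]),
                peak_ca_uM=float(trace.ca_center_uM[s:e].max()),
                peak_dye_uM=float(trace.dye_signal_uM[s:e].max()),
            )
        )
    return events


def events_frame(events: list[ReleaseEvent]) -> pd.DataFrame:
    """Event table in the export layout."""
    return pd.DataFrame(
        [
            dict(
                kind=ev.kind, start_s=ev.start_s, end_s=ev.end_s,
                life_ms=ev.life_s * 1e3, termination_ms=ev.termination_s * 1e3,
                max_open=ev.max_open, amplitude_ca_uM=ev.peak_ca_uM,
                amplitude_dye_uM=ev.peak_dye_uM,
            )
            for ev in events
        ],
        columns=["kind", "start_s", "end_s", "life_ms", "termination_ms",
                 "max_open", "amplitude_ca_uM", "amplitude_dye_uM"],
    )


@dataclass(frozen=True)
class EventStatistics:
    """Frequencies and distributions of puffs and blips from one recording."""

    duration_s: float
    puff_frequency_hz: float
    blip_frequency_hz: float
    puff_frequency_ci: tuple[float, float]
    blip_frequency_ci: tuple[float, float]
    puff_life_ms: np.ndarray
    puff_termination_ms: np.ndarray
    puff_amplitude_open: np.ndarray   # peak channel count
    puff_amplitude_ca: np.ndarray
    puff_amplitude_dye: np.ndarray
    blip_life_ms: np.ndarray


def event_statistics(
    events: list[ReleaseEvent],
    duration_s: float,
    n_boot: int = 500,
    seed: int = 0,
) -> EventStatistics:
    """Puff/blip frequencies (with bootstrap CIs) and summary distributions."""
    puffs = [e for e in events if e.kind == "puff"]
    blips = [e for e in events if e.kind == "blip"]
    rng = np.random.default_rng(seed)

    def ci(n_events: int) -> tuple[float, float]:
        if n_events == 0 or n_boot <= 0:
            return (0.0, 0.0)
        draws = rng.poisson(n_events, n_boot) / duration_s
        return (float(np.quantile(draws, 0.025)), float(np.quantile(draws, 0.975)))

    return EventStatistics(
        duration_s=duration_s,
        puff_frequency_hz=len(puffs) / duration_s,
        blip_frequency_hz=len(blips) / duration_s,
        puff_frequency_ci=ci(len(puffs)),
        blip_frequency_ci=ci(len(blips)),
        puff_life_ms=np.array([e.life_s * 1e3 for e in puffs]),
        puff_termination_ms=np.array([e.termination_s * 1e3 for e in puffs]),
        puff_amplitude_open=np.array([e.max_open for e in puffs]),
        puff_amplitude_ca=np.array([e.peak_ca_uM for e in puffs]),
        puff_amplitude_dye=np.array([e.peak_dye_uM for e in puffs]),
        blip_life_ms=np.array([e.life_s * 1e3 for e in blips]),
    )


# ---------------------------------------------------------------------------
# Deterministic ligand sweeps and crossing concentrations


@dataclass(frozen=True)
class SweepResult:
    """Observable surfaces of both variants and derived sensitization measures."""

    table: pd.DataFrame            # tidy: variant, ca_uM, ip3_uM, Po, pi_L, pi_I, pi_H
    po_ratio: pd.DataFrame         # ca_uM, ip3_uM, ratio (mutant / wild type)
    max_po_ratio: float
    po_crossing_ip3_uM: float      # mutant Po at Ca=1 uM crosses WT Po(1 uM, 100 nM)
    pi_crossing_ip3_uM: float      # mutant pi_L = pi_H at Ca=1 uM
    peak_po_mutant: float          # max over IP3 of mutant Po at Ca=1 uM


def _crossing(fn, lo: float, hi: float, refine: float = 0.01) -> float:
    """Bisection for fn(I)=0 on a log-IP3 bracket, to ~1% resolution."""
    xlo, xhi = np.log10(lo), np.log10(hi)
    root = brentq(lambda x: fn(10.0**x), xlo, xhi, xtol=np.log10(1 + refine) / 2)
    return float(10.0**root)


def ligand_sweep(
    occ_wt: OccupancyParams,
    occ_mut: OccupancyParams,
    ca_grid: np.ndarray | None = None,
    ip3_grid: np.ndarray | None = None,
) -> SweepResult:
    """Open-probability and prevalence surfaces plus sensitization crossings."""
    ca_grid = np.asarray(ca_grid) if ca_grid is not None else np.geomspace(0.01, 2.0, 40)
    ip3_grid = np.asarray(ip3_grid) if ip3_grid is not None else np.geomspace(1e-3, 1.0, 60)
    rows = []
    ratio_rows = []
    for ca in ca_grid:
        for ip3 in ip3_grid:
            lig = LigandCondition(float(ca), float(ip3))
            po_w = open_probability(occ_wt, lig)
            po_m = open_probability(occ_mut, lig)
            for occ, po in ((occ_wt, po_w), (occ_mut, po_m)):
                pl, pi, ph = modal_prevalences(occ, lig)
                rows.append(dict(variant=occ.variant, ca_uM=ca, ip3_uM=ip3,
                                 Po=po, pi_L=pl, pi_I=pi, pi_H=ph))
            ratio_rows.append(dict(ca_uM=ca, ip3_uM=ip3,
                                   ratio=po_m / po_w if po_w > 0 else np.inf))
    ratio = pd.DataFrame(ratio_rows)
    finite = ratio.ratio[np.isfinite(ratio.ratio)]

    ca1 = LigandCondition(1.0, 0.1)
    po_wt_ref = open_probability(occ_wt, ca1)

    def po_diff(ip3: float) -> float:
        return open_probability(occ_mut, LigandCondition(1.0, ip3)) - po_wt_ref

    def pi_diff(ip3: float) -> float:
        pl, _, ph = modal_prevalences(occ_mut, LigandCondition(1.0, ip3))
        return pl - ph

    ip3_fine = np.geomspace(1e-4, 100.0, 400)
    peak = max(open_probability(occ_mut, LigandCondition(1.0, float(i))) for i in ip3_fine)

    return SweepResult(
        table=pd.DataFrame(rows),
        po_ratio=ratio,
        max_po_ratio=float(finite.max()),
        po_crossing_ip3_uM=_crossing(po_diff, 1e-4, 1.0),
        pi_crossing_ip3_uM=_crossing(pi_diff, 1e-4, 1.0),
        peak_po_mutant=float(peak),
    )
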