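"""Equilibrium observables and generator matrix of the twelve-state IP3R model.

The model is thermodynamic at its core: every state ``s`` with stoichiometry
(m, n) carries an unnormalized equilibrium occupancy

    Z_s = K_s * C**m * I**n,

with C and I the Ca2+ and IP3 concentrations in uM.  All equilibrium
observables (open probability, modal prevalences, mean open/closed times,
modal lifetimes) are ratios of sums of these weights and of the equilibrium
probability fluxes across the open/closed or mode boundaries.

Kinetics enter through the generator matrix Q, whose off-diagonal entries are
transition rates of the form flux-parameter / occupancy-parameter, composed
for multi-step transitions with the harmonic rule
``rsr(x, y) = 1/(1/x + 1/y)`` (reciprocal of sum of reciprocals).  Rates that
formally divide by a ligand power are implemented in an algebraically
equivalent form that stays finite at zero ligand.

Units: uM and ms throughout this module.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import FluxParams, OccupancyParams
from .states import (
    MODE_STATES,
    N_CLOSED,
    N_OPEN,
    N_STATES,
    STATE_INDEX,
    STATE_NAMES,
    STATES,
    LigandCondition,
)

__all__ = [
    "rsr",
    "state_occupancies",
    "open_probability",
    "modal_prevalences",
    "transition_rates",
    "GeneratorMatrix",
    "build_generator",
    "total_flux",
    "mean_times",
    "modal_lifetime",
    "EquilibriumSummary",
    "equilibrium_summary",
    "equilibrium_sweep",
    "stationary_distribution",
]

_OPEN_MASK = np.array([s.is_open for s in STATES])
_STOICH = np.array([(s.ca_bound, s.ip3_bound) for s in STATES], dtype=float)


def rsr(*rates: float) -> float:
    """Harmonic composition of sequential step rates: 1/(1/x + 1/y + ...).

    If any step rate is zero the composite pathway is blocked and the
    composite rate is zero.
    """
    if any(r < 0 for r in rates):
        raise ValueError("rsr arguments must be >= 0")
    if any(r == 0 for r in rates):
        return 0.0
    return 1.0 / sum(1.0 / r for r in rates)


def state_occupancies(
    occ: OccupancyParams, lig: LigandCondition
) -> tuple[np.ndarray, float]:
    """Unnormalized occupancy K_s * C^m * I^n of every state, plus the total Z.

    Returns
    -------
    (z, Z) : 12-vector in canonical state order and its sum.
    """
    k = np.array([occ[s] for s in STATE_NAMES])
    with np.errstate(divide="ignore"):
        # 0**0 = 1 handled by numpy power for integer exponents
        z = k * lig.ca ** _STOICH[:, 0] * lig.ip3 ** _STOICH[:, 1]
    return z, float(z.sum())


def open_probability(occ: OccupancyParams, lig: LigandCondition) -> float:
    """Equilibrium open probability Po = Zo / Z."""
    z, total = state_occupancies(occ, lig)
    return float(z[_OPEN_MASK].sum() / total)


def modal_prevalences(
    occ: OccupancyParams, lig: LigandCondition
) -> tuple[float, float, float]:
    """Equilibrium prevalence (pi_L, pi_I, pi_H) of the three gating modes."""
    z, total = state_occupancies(occ, lig)
    out = []
    for mode in "LIH":
        idx = [STATE_INDEX[s] for s in MODE_STATES[mode]]
        out.append(float(z[idx].sum() / total))
    return tuple(out)


def transition_rates(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition
) -> dict[tuple[str, str], float]:
    """All directed transition rates (ms^-1) of the model at one condition.

    Fifteen reversible pairs: the thirteen tabulated ones plus the two copied
    pairs C04I<->C24I and C00L<->C20L, which reuse the C04I<->C24H rates.
    Backward rates whose printed form divides by a ligand power are evaluated
    in an equivalent form finite at zero ligand, e.g.::

        rsr(a*C, b*C^2) / (K * C^2)  ==  a*b / (K * (a + b*C))
    """
    C, I = lig.ca, lig.ip3
    j = flux
    r: dict[tuple[str, str], float] = {}

    # C04I <-> C24H (two-step Ca2+ binding, harmonically composed)
    a, b = j["j0414"], j["j1424"]
    r["C04I", "C24H"] = rsr(a * C, b * C * C) / occ["C04I"]
    r["C24H", "C04I"] = a * b / (occ["C24H"] * (a + b * C))

    # C24H <-> O24H (gateway of the H mode)
    r["C24H", "O24H"] = j["j2424HH"] / occ["C24H"]
    r["O24H", "C24H"] = j["j2424HH"] / occ["O24H"]

    # O24H <-> C34L
    r["O24H", "C34L"] = j["j2434"] * C / occ["O24H"]
    r["C34L", "O24H"] = j["j2434"] / occ["C34L"]

    # C04I <-> C34L (three-step Ca2+ binding)
    a, b, c = j["j0414IL"], j["j1424IL"], j["j2434IL"]
    r["C04I", "C34L"] = rsr(a * C, b * C * C, c * C**3) / occ["C04I"]
    r["C34L", "C04I"] = 1.0 / (occ["C34L"] * (C * C / a + C / b + 1.0 / c))

    # C04I <-> O14I
    r["C04I", "O14I"] = j["j0414II"] * C / occ["C04I"]
    r["O14I", "C04I"] = j["j0414II"] / occ["O14I"]

    # C24I <-> O24I
    r["C24I", "O24I"] = j["j2424II"] / occ["C24I"]
    r["O24I", "C24I"] = j["j2424II"] / occ["O24I"]

    # O24I <-> O24H (mode switch while open)
    r["O24I", "O24H"] = j["j2424"] / occ["O24I"]
    r["O24H", "O24I"] = j["j2424"] / occ["O24H"]

    # C04I <-> C04L
    r["C04I", "C04L"] = j["j0404"] / occ["C04I"]
    r["C04L", "C04I"] = j["j0404"] / occ["C04L"]

    # C32L <-> C34L
    r["C32L", "C34L"] = j["j3334"] * I * I / occ["C32L"]
    r["C34L", "C32L"] = j["j3334"] / occ["C34L"]

    # C30L <-> C32L
    r["C30L", "C32L"] = j["j3132"] * I * I / occ["C30L"]
    r["C32L", "C30L"] = j["j3132"] / occ["C32L"]

    # C20L <-> C30L
    r["C20L", "C30L"] = j["j2030"] * C / occ["C20L"]
    r["C30L", "C20L"] = j["j2030"] / occ["C30L"]

    # C00L <-> C04I (four-step IP3 binding)
    a, b = j["j0001"], j["j0304"]
    r["C00L", "C04I"] = rsr(a * I, b * I**4)
    r["C04I", "C00L"] = 1.0 / (occ["C04I"] * (I**3 / a + 1.0 / b))

    # C20L <-> C24H; the printed backward rate divides by KC04I, which equals
    # KC24H/KC20L to printed precision, preserving detailed balance.
    a, b = j["j2021"], j["j2324"]
    r["C20L", "C24H"] = rsr(a * I, b * I**4)
    r["C24H", "C20L"] = 1.0 / (occ["C04I"] * (I**3 / a + 1.0 / b))

    # Copied pairs: same rates as C04I <-> C24H.
    r["C04I", "C24I"] = r["C04I", "C24H"]
    r["C24I", "C04I"] = r["C24H", "C04I"]
    r["C00L", "C20L"] = r["C04I", "C24H"]
    r["C20L", "C00L"] = r["C24H", "C04I"]

    for (s, u), v in r.items():
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"non-finite transition rate {s}->{u} = {v} at {lig.label()}")
    return r


@dataclass(frozen=True)
class GeneratorMatrix:
    """The 12x12 generator Q in canonical order, with its open/closed blocks.

    Carries the unnormalized occupancy vector of the evaluation condition so
    that equilibrium entry distributions and fluxes can be formed without
    recomputation.
    """

    Q: np.ndarray
    lig: LigandCondition
    weights: np.ndarray  # unnormalized occupancies, canonical order

    @property
    def Qoo(self) -> np.ndarray:
        return self.Q[:N_OPEN, :N_OPEN]

    @property
    def Qoc(self) -> np.ndarray:
        return self.Q[:N_OPEN, N_OPEN:]

    @property
    def Qco(self) -> np.ndarray:
        return self.Q[N_OPEN:, :N_OPEN]

    @property
    def Qcc(self) -> np.ndarray:
        return self.Q[N_OPEN:, N_OPEN:]

    @property
    def w_open(self) -> np.ndarray:
        return self.weights[:N_OPEN]

    @property
    def w_closed(self) -> np.ndarray:
        return self.weights[N_OPEN:]

    def exit_flux(self) -> float:
        """Total unnormalized open->closed equilibrium flux W_O @ Q_OC @ 1."""
        return float(self.w_open @ self.Qoc @ np.ones(N_CLOSED))


def build_generator(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition
) -> GeneratorMatrix:
    """Assemble the generator matrix Q at one ligand condition."""
    rates = transition_rates(occ, flux, lig)
    Q = np.zeros((N_STATES, N_STATES))
    for (s, u), v in rates.items():
        Q[STATE_INDEX[s], STATE_INDEX[u]] = v
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    z, _ = state_occupancies(occ, lig)
    return GeneratorMatrix(Q=Q, lig=lig, weights=z)


def total_flux(occ: OccupancyParams, flux: FluxParams, lig: LigandCondition) -> float:
    """Total unnormalized equilibrium flux J from open to closed states (ms^-1).

    Explicit per-state sum: each open state's occupancy times its closing
    rates.  Identical to ``build_generator(...).exit_flux()``.
    """
    z, _ = state_occupancies(occ, lig)
    r = transition_rates(occ, flux, lig)
    return float(
        z[STATE_INDEX["O24H"]] * (r["O24H", "C24H"] + r["O24H", "C34L"])
        + z[STATE_INDEX["O24I"]] * r["O24I", "C24I"]
        + z[STATE_INDEX["O14I"]] * r["O14I", "C04I"]
    )


def mean_times(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition
) -> tuple[float, float]:
    """Mean open and closed dwell times (tau_o, tau_c) in ms.

    tau_o = Zo / J and tau_c = Zc / J with J the unnormalized open->closed
    flux; the identity Po = tau_o / (tau_o + tau_c) holds by construction.
    Undefined at zero IP3, where no open state is reachable (J = 0).
    """
    z, _ = state_occupancies(occ, lig)
    J = total_flux(occ, flux, lig)
    if J <= 0.0:
        raise ValueError(f"mean times undefined: open<->closed flux is zero at {lig.label()}")
    zo = float(z[_OPEN_MASK].sum())
    zc = float(z[~_OPEN_MASK].sum())
    return zo / J, zc / J


def _aggregate_exit_flux(
    gen: GeneratorMatrix, members: list[int]
) -> float:
    outside = [i for i in range(N_STATES) if i not in members]
    return float(sum(gen.weights[s] * gen.Q[s, outside].sum() for s in members))


def modal_lifetime(
    occ: OccupancyParams,
    flux: FluxParams,
    lig: LigandCondition,
    mode: str | list[str],
) -> float:
    """Mean lifetime tau^X (ms) of a gating mode or arbitrary state aggregate.

    tau^X = Z^X / J_X where J_X is the total unnormalized flux out of the
    aggregate X.  ``mode`` is 'L', 'I' or 'H', or an explicit list of state
    names.
    """
    names = list(MODE_STATES[mode]) if isinstance(mode, str) else list(mode)
    members = [STATE_INDEX[s] for s in names]
    gen = build_generator(occ, flux, lig)
    zx = float(gen.weights[members].sum())
    if zx <= 0:
        raise ValueError(f"aggregate {names} has zero occupancy at {lig.label()}")
    jx = _aggregate_exit_flux(gen, members)
    if jx <= 0:
        raise ValueError(f"no flux out of aggregate {names}: lifetime undefined")
    return zx / jx


@dataclass(frozen=True)
class EquilibriumSummary:
    """All equilibrium observables of one variant at one ligand condition."""

    lig: LigandCondition
    variant: str
    occupancies: np.ndarray  # unnormalized, canonical order
    Z: float
    Zo: float
    Zc: float
    Po: float
    pi_L: float
    pi_I: float
    pi_H: float
    J: float           # unnormalized open->closed flux, ms^-1 * occupancy
    tau_o_ms: float
    tau_c_ms: float
    tau_L_ms: float
    tau_I_ms: float
    tau_H_ms: float


def equilibrium_summary(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition
) -> EquilibriumSummary:
    z, total = state_occupancies(occ, lig)
    pi_l, pi_i, pi_h = modal_prevalences(occ, lig)
    tau_o, tau_c = mean_times(occ, flux, lig)
    return EquilibriumSummary(
        lig=lig,
        variant=occ.variant,
        occupancies=z,
        Z=total,
        Zo=float(z[_OPEN_MASK].sum()),
        Zc=float(z[~_OPEN_MASK].sum()),
        Po=open_probability(occ, lig),
        pi_L=pi_l,
        pi_I=pi_i,
        pi_H=pi_h,
        J=total_flux(occ, flux, lig),
        tau_o_ms=tau_o,
        tau_c_ms=tau_c,
        tau_L_ms=modal_lifetime(occ, flux, lig, "L"),
        tau_I_ms=modal_lifetime(occ, flux, lig, "I"),
        tau_H_ms=modal_lifetime(occ, flux, lig, "H"),
    )


def equilibrium_sweep(
    occ: OccupancyParams,
    flux: FluxParams,
    ca_uM: np.ndarray,
    ip3_uM: np.ndarray,
) -> pd.DataFrame:
    """Equilibrium observables over a (Ca, IP3) grid, as a tidy DataFrame."""
    rows = []
    for ca in np.atleast_1d(ca_uM):
        for ip3 in np.atleast_1d(ip3_uM):
            s = equilibrium_summary(occ, flux, LigandCondition(float(ca), float(ip3)))
            rows.append(
                dict(
                    variant=s.variant, ca_uM=ca, ip3_uM=ip3, Po=s.Po,
                    pi_L=s.pi_L, pi_I=s.pi_I, pi_H=s.pi_H,
                    tau_o_ms=s.tau_o_ms, tau_c_ms=s.tau_c_ms,
                    tau_L_ms=s.tau_L_ms, tau_I_ms=s.tau_I_ms, tau_H_ms=s.tau_H_ms,
                )
            )
    return pd.DataFrame(rows)


def stationary_distribution(gen: GeneratorMatrix) -> np.ndarray:
    """Stationary distribution of Q via the null space of Q^T.

    Serves as the independent kinetic route to the equilibrium occupancies;
    consistency of the two is the central cross-check between the occupancy
    and flux parameter tables.
    """
    _, _, vt = np.linalg.svd(gen.Q.T)
    p = vt[-1]
    p = p / p.sum()
    if p.min() < -1e-10:
        raise ValueError("stationary distribution has negative components")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()
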