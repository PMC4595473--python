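"""Closed-form dwell-time distributions via sub-generator matrix exponentials.

For a partition of a (sub-)chain into aggregates X and Y, the probability
density of a sojourn in X that started at equilibrium is

    f_X(t) = pi_X @ expm(Q_XX * t) @ Q_XY @ 1_Y,

where Q_XX is the sub-generator restricted to X (its diagonal includes all
exit rates, so it is strictly sub-conservative), Q_XY holds the X->Y rates,
and pi_X is the equilibrium entry distribution: the probability that a sojourn
in X begins in each X state,

    pi_X = (W_Y @ Q_YX) / J,   J = W_Y @ Q_YX @ 1_X,

with W_Y the diagonal of unnormalized equilibrium occupancies of Y.

Two contexts are supported: the full twelve-state chain partitioned into open
vs closed (overall dwell times), and a mode-restricted sub-chain in which only
within-mode transitions are kept (within-mode open/closed dwell times; exits
from the mode are excluded from the sub-generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.optimize import brentq

from .model import GeneratorMatrix, build_generator
from .params import FluxParams, OccupancyParams
from .states import MODE_STATES, STATE_INDEX, STATE_NAMES, LigandCondition

__all__ = [
    "DwellContext",
    "open_closed_partition",
    "mode_partition",
    "aggregate_partition",
]


@dataclass(frozen=True)
class DwellContext:
    """Sub-generator blocks and equilibrium weights for one X/Y partition."""

    names_x: tuple[str, ...]
    names_y: tuple[str, ...]
    Qxx: np.ndarray
    Qxy: np.ndarray
    Qyx: np.ndarray
    Qyy: np.ndarray
    w_x: np.ndarray   # unnormalized occupancies of X states
    w_y: np.ndarray

    @property
    def flux(self) -> float:
        """Total equilibrium X<->Y flux J = W_Y @ Q_YX @ 1."""
        return float(self.w_y @ self.Qyx @ np.ones(len(self.names_x)))

    def entry_distribution(self) -> np.ndarray:
        """Distribution over X states at the moment of entering X."""
        J = self.flux
        if J <= 0:
            raise ValueError("no flux between the aggregates: entry distribution undefined")
        return (self.w_y @ self.Qyx) / J

    def swap(self) -> "DwellContext":
        """The same partition viewed from Y."""
        return DwellContext(
            names_x=self.names_y, names_y=self.names_x,
            Qxx=self.Qyy, Qxy=self.Qyx, Qyx=self.Qxy, Qyy=self.Qxx,
            w_x=self.w_y, w_y=self.w_x,
        )

    def _spectral(self):
        """Cached eigen-expansion of the sub-generator, if well conditioned.

        Returns (lam, a_pdf, a_surv) with f(t) = Re sum a_pdf_k exp(lam_k t)
        and S(t) = Re sum a_surv_k exp(lam_k t), or None when the
        eigenvector basis is too ill-conditioned to trust (the expm path is
        used instead; sub-generators need not be diagonalizable).
        """
        cached = getattr(self, "_spectral_cache", "unset")
        if cached != "unset":
            return cached
        result = None
        try:
            lam, V = np.linalg.eig(self.Qxx)
            if np.linalg.cond(V) < 1e8:
                Vi = np.linalg.inv(V)
                pi = self.entry_distribution().astype(complex)
                exit_rates = (self.Qxy @ np.ones(len(self.names_y))).astype(complex)
                left = pi @ V
                result = (
                    lam,
                    left * (Vi @ exit_rates),
                    left * (Vi @ np.ones(len(self.names_x))),
                )
        except np.linalg.LinAlgError:
            result = None
        object.__setattr__(self, "_spectral_cache", result)
        return result

    def _apply(self, t, which: str) -> np.ndarray | float:
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        if (ts < 0).any():
            raise ValueError("dwell times must be >= 0")
        spec = self._spectral()
        if spec is not None:
            lam, a_pdf, a_surv = spec
            amp = a_pdf if which == "pdf" else a_surv
            out = np.real(np.exp(np.multiply.outer(ts, lam)) @ amp)
        else:
            pi = self.entry_distribution()
            vec = (
                self.Qxy @ np.ones(len(self.names_y))
                if which == "pdf"
                else np.ones(len(self.names_x))
            )
            out = np.array([float(pi @ expm(self.Qxx * ti) @ vec) for ti in ts])
        return out if np.ndim(t) else float(out[0])

    def pdf(self, t) -> np.ndarray | float:
        """Dwell-time density f_X(t) in ms^-1, for scalar or array t."""
        return self._apply(t, "pdf")

    def survival(self, t) -> np.ndarray | float:
        """P(dwell in X longer than t)."""
        return self._apply(t, "survival")

    def pdf_by_expm(self, t) -> np.ndarray | float:
        """Density evaluated by scaling-and-squaring expm, bypassing the
        spectral cache; an internal cross-check of the two routes."""
        pi = self.entry_distribution()
        exit_rates = self.Qxy @ np.ones(len(self.names_y))
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array([float(pi @ expm(self.Qxx * ti) @ exit_rates) for ti in ts])
        return out if np.ndim(t) else float(out[0])

    def mean(self) -> float:
        """Closed-form first moment -pi_X @ Q_XX^-1 @ 1 (ms)."""
        pi = self.entry_distribution()
        ones = np.ones(len(self.names_x))
        try:
            sol = np.linalg.solve(self.Qxx, ones)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular sub-generator: dwell mean undefined") from err
        return float(-pi @ sol)

    def mean_by_quadrature(self, rtol: float = 1e-10) -> float:
        """Independent check of the mean via the tail formula int_0^inf S(t) dt.

        The survival function is smooth and monotone, so adaptive quadrature
        resolves all exponential components reliably.
        """
        scale = self.mean()  # only used to place the integration split
        a, _ = quad(self.survival, 0, scale, limit=400, epsrel=rtol)
        b, _ = quad(self.survival, scale, np.inf, limit=400, epsrel=rtol)
        return a + b

    def median(self) -> float:
        m = self.mean()
        lo, hi = m * 1e-8, m
        while self.survival(hi) > 0.5:
            hi *= 2
        return brentq(lambda t: self.survival(t) - 0.5, lo, hi, xtol=m * 1e-10)

    def pdf_table(self, t_ms: np.ndarray | None = None) -> pd.DataFrame:
        """Density on a log-spaced grid, for plotting against dwell histograms."""
        if t_ms is None:
            m = self.mean()
            t_ms = np.logspace(np.log10(m) - 3, np.log10(m) + 2, 200)
        return pd.DataFrame({"t_ms": t_ms, "density": self.pdf(t_ms)})


def _context_from_blocks(
    Q: np.ndarray, weights: np.ndarray, names: tuple[str, ...],
    x_names: list[str], y_names: list[str],
) -> DwellContext:
    idx = {n: i for i, n in enumerate(names)}
    xi = [idx[n] for n in x_names]
    yi = [idx[n] for n in y_names]
    return DwellContext(
        names_x=tuple(x_names), names_y=tuple(y_names),
        Qxx=Q[np.ix_(xi, xi)], Qxy=Q[np.ix_(xi, yi)],
        Qyx=Q[np.ix_(yi, xi)], Qyy=Q[np.ix_(yi, yi)],
        w_x=weights[xi], w_y=weights[yi],
    )


def open_closed_partition(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition,
    open_side: bool = True,
) -> DwellContext:
    """Overall open (or closed) dwell-time context on the full chain."""
    gen = build_generator(occ, flux, lig)
    x = [s for s in STATE_NAMES if s.startswith("O")]
    y = [s for s in STATE_NAMES if s.startswith("C")]
    ctx = _context_from_blocks(gen.Q, gen.weights, STATE_NAMES, x, y)
    return ctx if open_side else ctx.swap()


def mode_partition(
    occ: OccupancyParams, flux: FluxParams, lig: LigandCondition,
    mode: str, open_side: bool = True,
) -> DwellContext:
    """Within-mode open/closed dwell context on the mode-restricted sub-chain.

    Only transitions among states of the mode populate the sub-generator;
    leaving the mode is not an exit event for within-mode dwells.  For the I
    mode this yields a 4-state sub-chain (X = [O14I, O24I], Y = [C04I, C24I]);
    for the H mode a 2-state chain (X = [O24H], Y = [C24H]).  The L mode has
    no open states, so no open/closed partition exists there.
    """
    members = list(MODE_STATES[mode])
    x = [s for s in members if s.startswith("O")]
    y = [s for s in members if s.startswith("C")]
    if not x or not y:
        raise ValueError(f"mode {mode!r} has no open/closed partition")
    gen = build_generator(occ, flux, lig)
    mi = [STATE_INDEX[s] for s in members]
    sub = gen.Q[np.ix_(mi, mi)].copy()
    # Rebuild the diagonal from within-mode rates only: the sub-chain is
    # conservative inside the mode.
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    ctx = _context_from_blocks(sub, gen.weights[mi], tuple(members), x, y)
    return ctx if open_side else ctx.swap()


def aggregate_partition(
    gen: GeneratorMatrix, x_names: list[str], y_names: list[str]
) -> DwellContext:
    """Arbitrary disjoint aggregate partition on the full-chain generator."""
    if set(x_names) & set(y_names):
        raise ValueError("aggregates must be disjoint")
    if not x_names or not y_names:
        raise ValueError("aggregates must be nonempty")
    return _context_from_blocks(gen.Q, gen.weights, STATE_NAMES, list(x_names), list(y_names))
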