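"""Hybrid stochastic reaction-diffusion simulation of a ten-channel IP3R cluster.

Each channel owns a spherically symmetric radial field of free Ca2+ and free
dye on a hemispherical domain; open channels inject Ca2+ as a point source
spread over a small shell at the origin.  The fields of the individual
channels are solved independently and superposed to give the local Ca2+
concentration at every channel position, which in turn drives each channel's
twelve-state gating.  Diffusion is integrated implicitly (backward Euler on
the tridiagonal finite-volume system); dye binding and the source are applied
pointwise semi-implicitly, which preserves positivity and leaves the resting
buffer equilibrium an exact fixed point.

Superposition convention: the resting concentration is counted once.  Each
field stores the absolute concentration with the far boundary clamped at
rest, and the local Ca2+ at channel i is

    C_i = c_rest + sum_j [ c_j(r_ij) - c_rest ],

with the self term evaluated at the source shell radius.  (Summing ten
absolute fields literally would give ten times rest at rest, which is
unphysical bookkeeping, not chemistry.)

Units in this module: um, s, uM.  The channel model works in ms; rates are
converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import build_generator, transition_rates
from .params import FluxParams, OccupancyParams
from .states import N_OPEN, STATE_INDEX, STATE_NAMES, LigandCondition
from ._kernels import run_cluster_kernel, thomas_factor

__all__ = [
    "FARADAY_C_PER_MOL",
    "ClusterGeometry",
    "BufferParams",
    "SourceParams",
    "RadialGrid",
    "RadialField",
    "FieldStepper",
    "RateTable",
    "local_calcium",
    "step_channels",
    "ClusterTrace",
    "run_cluster",
]

FARADAY_C_PER_MOL = 96485.33212


@dataclass(frozen=True)
class ClusterGeometry:
    """Channel positions of the release site: a 2 x 5 planar array by default.

    ``spacing_um`` is the nearest-neighbor inter-channel distance (120 nm).
    """

    n_channels: int = 10
    spacing_um: float = 0.12

    def positions(self) -> np.ndarray:
        n_cols = (self.n_channels + 1) // 2
        pos = []
        for k in range(self.n_channels):
            row, col = divmod(k, n_cols)
            pos.append((col * self.spacing_um, row * self.spacing_um))
        return np.array(pos)

    def distances(self) -> np.ndarray:
        p = self.positions()
        d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
        return d

    def center(self) -> np.ndarray:
        return self.positions().mean(axis=0)


@dataclass(frozen=True)
class BufferParams:
    """Mobile dye buffer kinetics, diffusion coefficients and resting Ca2+.

    Defaults are standard Ca2+-microdomain modeling values for a
    dextran-conjugated fluorescent indicator; they are configurable and every
    cluster-level statistic depends on them.
    """

    total_uM: float = 40.0        # B_d
    k_on: float = 150.0           # k_d^f, uM^-1 s^-1
    k_off: float = 90.0           # k_d^r, s^-1 (Kd = 0.6 uM)
    D_ca: float = 220.0           # um^2/s, free Ca2+
    D_dye: float = 32.0           # um^2/s
    c_rest: float = 0.07          # uM resting free Ca2+

    def __post_init__(self) -> None:
        vals = (self.total_uM, self.k_on, self.k_off, self.D_ca, self.D_dye, self.c_rest)
        if any(v <= 0 for v in vals):
            raise ValueError("buffer parameters must be positive")

    @property
    def b_rest(self) -> float:
        """Free dye concentration in equilibrium with resting Ca2+."""
        return self.total_uM * self.k_off / (self.k_off + self.k_on * self.c_rest)


@dataclass(frozen=True)
class SourceParams:
    """Single-channel Ca2+ source: current and the shell it is deposited in."""

    current_pA: float = 0.05
    delta_r_um: float = 0.0025    # source shell radius
    r_pore_um: float = 0.0025     # radius of the hemisphere defining deltaV

    def __post_init__(self) -> None:
        if min(self.current_pA, self.delta_r_um, self.r_pore_um) <= 0:
            raise ValueError("source parameters must be positive")

    @property
    def molar_rate(self) -> float:
        """Ion deposition rate I / (2F) in uM * um^3 / s."""
        # pA / (C/mol) = 1e-12 mol/s; 1 mol/um^3 = 1e15 M * um^3 = 1e21 uM um^3
        return self.current_pA * 1e-12 / (2.0 * FARADAY_C_PER_MOL) * 1e21

    @property
    def concentration_rate(self) -> float:
        """J = I / (2 F deltaV) in uM/s, deltaV the hemisphere of r_pore."""
        delta_v = (2.0 / 3.0) * np.pi * self.r_pore_um**3
        return self.molar_rate / delta_v


@dataclass(frozen=True)
class RadialGrid:
    """Node-centred finite-volume radial grid on [0, r_max]."""

    r: np.ndarray  # node radii, strictly increasing

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        object.__setattr__(self, "r", r)
        if (np.diff(r) <= 0).any() or r[0] <= 0:
            raise ValueError("grid radii must be positive and strictly increasing")

    @classmethod
    def uniform(cls, dr_um: float = 0.005, r_max_um: float = 5.0) -> "RadialGrid":
        return cls(r=np.arange(dr_um, r_max_um + dr_um / 2, dr_um))

    @classmethod
    def stretched(cls, r0_um: float = 0.00125, r_max_um: float = 5.0,
                  n: int = 160) -> "RadialGrid":
        """Geometrically stretched grid: fine near the pore, coarse far out."""
        return cls(r=np.geomspace(r0_um, r_max_um, n))

    @property
    def n(self) -> int:
        return len(self.r)

    def faces(self) -> np.ndarray:
        r = self.r
        return np.concatenate(([0.0], 0.5 * (r[1:] + r[:-1]), [r[-1]]))

    def shell_volumes(self) -> np.ndarray:
        """Integral of r^2 dr over each cell (solid-angle factor omitted;
        it cancels everywhere it is used consistently)."""
        f = self.faces()
        return (f[1:] ** 3 - f[:-1] ** 3) / 3.0

    def source_weights(self, delta_r_um: float) -> np.ndarray:
        """Volume fraction of each cell lying inside the source shell."""
        f = self.faces()
        inner = np.minimum(f[:-1], delta_r_um)
        outer = np.minimum(f[1:], delta_r_um)
        return (outer**3 - inner**3) / 3.0 / self.shell_volumes()


@dataclass
class RadialField:
    """Free Ca2+ and free dye profiles of one channel."""

    grid: RadialGrid
    c: np.ndarray   # free Ca2+, uM
    b: np.ndarray   # free dye, uM
    t: float = 0.0

    @classmethod
    def at_rest(cls, grid: RadialGrid, buffers: BufferParams) -> "RadialField":
        return cls(
            grid=grid,
            c=np.full(grid.n, buffers.c_rest),
            b=np.full(grid.n, buffers.b_rest),
        )

    def excess(self) -> np.ndarray:
        return self.c - self.c[-1]

    def value_at(self, r_um: float) -> float:
        """Linear interpolation of free Ca2+ at radius r."""
        return float(np.interp(r_um, self.grid.r, self.c))


def _diffusion_system(grid: RadialGrid, D: float, dt: float):
    """Tridiagonal backward-Euler system (I - dt*D*L) for one species.

    Inner boundary: zero flux at r = 0.  Outer boundary: Dirichlet (last node
    pinned to its current value).
    """
    r = grid.r
    f = grid.faces()
    vol = grid.shell_volumes()
    g = D * f[1:-1] ** 2 / np.diff(r)          # face conductances
    n = grid.n
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = np.ones(n)
    lower[1:] = -dt * g / vol[1:]
    upper[:-1] = -dt * g / vol[:-1]
    diag[:-1] -= upper[:-1]
    diag[1:-1] -= lower[1:-1]
    # Dirichlet at the outer node
    lower[-1] = 0.0
    upper[-1] = 0.0
    diag[-1] = 1.0
    return lower, diag, upper


class FieldStepper:
    """Implicit-diffusion / semi-implicit-reaction integrator for one field.

    One step advances free Ca2+ and free dye by ``dt_s``: backward-Euler
    diffusion on the tridiagonal radial system, then a pointwise
    semi-implicit update of dye binding and the source term.  The resting
    buffer equilibrium is an exact fixed point of the scheme.
    """

    def __init__(self, grid: RadialGrid, buffers: BufferParams,
                 source: SourceParams, dt_s: float = 1e-5):
        if dt_s <= 0:
            raise ValueError("dt must be > 0")
        self.grid = grid
        self.buffers = buffers
        self.source = source
        self.dt = dt_s
        lc, dc, uc = _diffusion_system(grid, buffers.D_ca, dt_s)
        lb, db, ub = _diffusion_system(grid, buffers.D_dye, dt_s)
        self._ca_fac = (lc, *thomas_factor(lc, dc, uc))
        self._dye_fac = (lb, *thomas_factor(lb, db, ub))
        # source density J scaled so the deposited mass equals I/(2F)
        self.src = source.concentration_rate * grid.source_weights(source.delta_r_um)

    def _solve(self, fac, rhs: np.ndarray) -> np.ndarray:
        lower, cp, denom = fac
        n = len(rhs)
        out = np.empty(n)
        out[0] = rhs[0] / denom[0]
        for i in range(1, n):
            out[i] = (rhs[i] - lower[i] * out[i - 1]) / denom[i]
        for i in range(n - 2, -1, -1):
            out[i] -= cp[i] * out[i + 1]
        return out

    def step(self, fld: RadialField, source_on: bool) -> RadialField:
        dt = self.dt
        bp = self.buffers
        # source folded into the implicit diffusion right-hand side, so the
        # near-source profile is the discrete Poisson solution rather than a
        # dt-dependent undiffused spike
        rhs = fld.c + dt * self.src if source_on else fld.c
        c = self._solve(self._ca_fac, rhs)
        b = self._solve(self._dye_fac, fld.b)
        # dye binding, implicit in b then in c; exact at equilibrium
        b = (b + dt * bp.k_off * bp.total_uM) / (1.0 + dt * (bp.k_off + bp.k_on * c))
        c = (c + dt * bp.k_off * (bp.total_uM - b)) / (1.0 + dt * bp.k_on * b)
        if c.min() < 0 or b.min() < 0 or b.max() > bp.total_uM * (1 + 1e-12):
            raise RuntimeError("field step produced unphysical concentrations; reduce dt")
        return RadialField(grid=fld.grid, c=c, b=b, t=fld.t + dt)


def local_calcium(
    fields: list[RadialField],
    geometry: ClusterGeometry,
    source: SourceParams,
    c_rest: float,
) -> np.ndarray:
    """Local Ca2+ at every channel: rest plus superposed excesses (Eq-30 style,
    rest counted once; self term evaluated at the source shell radius)."""
    d = geometry.distances()
    n = geometry.n_channels
    out = np.full(n, c_rest)
    for i in range(n):
        for j in range(n):
            r = source.delta_r_um if i == j else d[i, j]
            out[i] += fields[j].value_at(r) - fields[j].c[-1]
    return out


# ---------------------------------------------------------------------------
# Channel gating at per-channel Ca2+


class RateTable:
    """Directed transition rates tabulated over a log grid of Ca2+.

    Gating inside the cluster runs at fixed IP3 but continuously varying
    local Ca2+; interpolating a precomputed table avoids rebuilding Q at
    every step.  Rates are stored in s^-1.
    """

    def __init__(self, occ: OccupancyParams, flux: FluxParams, ip3_uM: float,
                 c_min: float = 1e-4, c_max: float = 1e4, n: int = 1536):
        self.ip3 = ip3_uM
        self.log_c = np.linspace(np.log10(c_min), np.log10(c_max), n)
        pairs = sorted(transition_rates(occ, flux, LigandCondition(1.0, max(ip3_uM, 1e-30))))
        self.trans_from = np.array([STATE_INDEX[s] for s, _ in pairs], dtype=np.int64)
        self.trans_to = np.array([STATE_INDEX[u] for _, u in pairs], dtype=np.int64)
        self.rates = np.empty((n, len(pairs)))
        for k, lc in enumerate(self.log_c):
            r = transition_rates(occ, flux, LigandCondition(10.0**lc, ip3_uM))
            self.rates[k] = [r[p] * 1e3 for p in pairs]  # ms^-1 -> s^-1
        self.exit = np.zeros((n, len(STATE_NAMES)))
        for k in range(len(pairs)):
            self.exit[:, self.trans_from[k]] += self.rates[:, k]

    def rates_at(self, ca_uM: float) -> np.ndarray:
        lc = np.log10(max(ca_uM, 10.0 ** self.log_c[0]))
        pos = (lc - self.log_c[0]) / (self.log_c[1] - self.log_c[0])
        pos = min(max(pos, 0.0), len(self.log_c) - 1.000001)
        k0 = int(pos)
        f = pos - k0
        return self.rates[k0] * (1.0 - f) + self.rates[k0 + 1] * f


def step_channels(
    states: np.ndarray,
    table: RateTable,
    ca_per_channel: np.ndarray,
    dt_s: float,
    rng: np.random.Generator,
    max_prob: float = 0.1,
) -> np.ndarray:
    """Advance every channel by one first-order step at its local Ca2+.

    Refuses the step if any transition probability r*dt exceeds ``max_prob``.
    (The cluster driver instead uses exact within-step jump sampling; this
    stepper is the simple reference used for clamped-Ca2+ checks.)
    """
    out = states.copy()
    for i, s in enumerate(states):
        r = table.rates_at(float(ca_per_channel[i]))
        mine = np.flatnonzero(table.trans_from == s)
        p = r[mine] * dt_s
        if p.size and p.max() > max_prob:
            raise ValueError(
                f"dt too large: transition probability {p.max():.3g} exceeds {max_prob}"
            )
        u = rng.random()
        acc = 0.0
        for k, pk in zip(mine, p):
            acc += pk
            if u < acc:
                out[i] = table.trans_to[k]
                break
    return out


# ---------------------------------------------------------------------------
# Full cluster run


@dataclass
class ClusterTrace:
    """Recorded output of one cluster simulation."""

    t_s: np.ndarray
    n_open: np.ndarray            # number of simultaneously open channels
    open_bits: np.ndarray         # (n_samples, n_channels) uint8
    ca_center_uM: np.ndarray      # summed excess free Ca2+ at the cluster centre
    dye_signal_uM: np.ndarray     # summed excess bound dye at the observation shell
    lig: LigandCondition
    variant: str
    seed: int
    dt_s: float

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] + (self.t_s[1] - self.t_s[0])) if len(self.t_s) else 0.0


def run_cluster(
    occ: OccupancyParams,
    flux: FluxParams,
    lig: LigandCondition,
    duration_s: float,
    seed: int,
    geometry: ClusterGeometry | None = None,
    buffers: BufferParams | None = None,
    source: SourceParams | None = None,
    grid: RadialGrid | None = None,
    dt_s: float = 5e-5,
    record_dt_s: float = 5e-4,
    obs_radius_um: float = 1.0,
) -> ClusterTrace:
    """Simulate Ca2+ release from a cluster of IP3R channels.

    Interleaves per-channel implicit field steps with exact jump sampling of
    each channel's gating at its superposed local Ca2+.  Fully reproducible
    under a fixed seed.  Channels whose field has relaxed back to rest are
    skipped until they reopen, which makes quiescent stretches cheap.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    geometry = geometry or ClusterGeometry()
    buffers = buffers or BufferParams()
    source = source or SourceParams()
    grid = grid or RadialGrid.stretched()

    table = RateTable(occ, flux, lig.ip3)
    stepper = FieldStepper(grid, buffers, source, dt_s)

    # stationary initial states at resting Ca2+
    gen = build_generator(occ, flux, LigandCondition(buffers.c_rest, lig.ip3))
    w = gen.weights / gen.weights.sum()
    rng = np.random.default_rng(seed)
    states0 = rng.choice(len(w), size=geometry.n_channels, p=w).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    dists = geometry.distances().copy()
    np.fill_diagonal(dists, source.delta_r_um)
    center = geometry.center()
    center_dists = np.sqrt(((geometry.positions() - center) ** 2).sum(1))
    center_dists = np.maximum(center_dists, grid.r[0])

    n_steps = int(round(duration_s / dt_s))
    stride = max(1, int(round(record_dt_s / dt_s)))

    lc_ca, cp_ca, den_ca = stepper._ca_fac
    lc_dy, cp_dy, den_dy = stepper._dye_fac

    (n_open, open_bits, ca_center, dye_sig, status) = run_cluster_kernel(
        n_steps, stride, dt_s,
        grid.r, lc_ca, cp_ca, den_ca, lc_dy, cp_dy, den_dy,
        stepper.src,
        buffers.total_uM, buffers.k_on, buffers.k_off,
        buffers.c_rest, buffers.b_rest,
        dists, center_dists, obs_radius_um,
        table.log_c, table.rates, table.exit,
        table.trans_from, table.trans_to,
        states0, N_OPEN, kernel_seed,
    )
    if status != 0:
        raise RuntimeError("cluster simulation became unstable; reduce dt or refine grid")
    n_rec = len(n_open)
    t = (np.arange(n_rec) + 1) * stride * dt_s
    return ClusterTrace(
        t_s=t, n_open=n_open, open_bits=open_bits,
        ca_center_uM=ca_center, dye_signal_uM=dye_sig,
        lig=lig, variant=occ.variant, seed=seed, dt_s=dt_s,
    )
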