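"""State space of the twelve-state modal gating model of the IP3 receptor.

The channel is described by an aggregated continuous-time Markov chain with
twelve states named ``Cmn<M>`` / ``Omn<M>``, where the leading letter gives the
conductance class (C = closed, O = open), ``m`` is the number of Ca2+ ions and
``n`` the number of IP3 molecules bound, and the trailing letter the gating
mode: L (low activity), I (intermediate), or H (high activity / bursting).

The canonical ordering places the three open states first, then the nine
closed states, so that the generator matrix partitions cleanly into
open/closed blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "State",
    "LigandCondition",
    "STATE_NAMES",
    "OPEN_STATES",
    "CLOSED_STATES",
    "MODE_STATES",
    "STATES",
    "STATE_INDEX",
    "N_STATES",
    "N_OPEN",
    "N_CLOSED",
]


@dataclass(frozen=True)
class State:
    """One channel state: name, gating mode, conductance, ligand stoichiometry."""

    name: str
    mode: str            # 'L', 'I' or 'H'
    conductance: str     # 'open' or 'closed'
    ca_bound: int        # m
    ip3_bound: int       # n

    @classmethod
    def from_name(cls, name: str) -> "State":
        if len(name) != 4 or name[0] not in "CO" or name[3] not in "LIH":
            raise ValueError(f"not a valid state name: {name!r}")
        return cls(
            name=name,
            mode=name[3],
            conductance="open" if name[0] == "O" else "closed",
            ca_bound=int(name[1]),
            ip3_bound=int(name[2]),
        )

    @property
    def is_open(self) -> bool:
        return self.conductance == "open"


# Canonical ordering: open states first, then closed.
OPEN_STATES: tuple[str, ...] = ("O14I", "O24I", "O24H")
CLOSED_STATES: tuple[str, ...] = (
    "C00L", "C20L", "C30L", "C32L", "C34L", "C04L", "C04I", "C24I", "C24H",
)
STATE_NAMES: tuple[str, ...] = OPEN_STATES + CLOSED_STATES

STATES: tuple[State, ...] = tuple(State.from_name(n) for n in STATE_NAMES)
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}

N_STATES = len(STATE_NAMES)
N_OPEN = len(OPEN_STATES)
N_CLOSED = len(CLOSED_STATES)

MODE_STATES: dict[str, tuple[str, ...]] = {
    "L": ("C00L", "C20L", "C30L", "C32L", "C34L", "C04L"),
    "I": ("C04I", "C24I", "O14I", "O24I"),
    "H": ("C24H", "O24H"),
}


@dataclass(frozen=True)
class LigandCondition:
    """Steady cytoplasmic ligand concentrations, in micromolar.

    Attributes
    ----------
    ca : free Ca2+ concentration (uM)
    ip3 : IP3 concentration (uM)
    """

    ca: float
    ip3: float

    def __post_init__(self) -> None:
        if self.ca < 0 or self.ip3 < 0:
            raise ValueError(
                f"ligand concentrations must be >= 0, got ca={self.ca}, ip3={self.ip3}"
            )

    def label(self) -> str:
        return f"ca={self.ca:g}uM,ip3={self.ip3:g}uM"
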