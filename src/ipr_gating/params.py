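"""Occupancy and flux parameter sets for the twelve-state IP3R model.

Two built-in parameter sets are shipped: ``WT`` (channel gating in the
presence of wild-type presenilin-1) and ``M146L`` (the FAD-causing PS1-M146L
mutant).  The mutant differs from wild type in exactly four occupancy
parameters (KC32L, KO14I, KO24H, KO24I) and two flux parameters
(j0414II, j2424HH); everything else is shared.

Units: occupancy parameters are uM^-(m+n) per the state's stoichiometry so
that K * C^m * I^n is dimensionless relative to the reference state C00L
(K = 1).  Flux parameters carry ms^-1 times inverse-uM powers; all channel
kinetics in this package are in uM and ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .states import STATE_NAMES

__all__ = [
    "OccupancyParams",
    "FluxParams",
    "M146L_FREE_OCCUPANCY",
    "M146L_FREE_FLUX",
    "FLUX_NAMES",
    "load_params",
    "save_params",
]

# Occupancy parameters (Table of per-state equilibrium weights), uM^-(m+n).
_K_WT: dict[str, float] = {
    "C00L": 1.0,
    "C20L": 7.061,
    "C30L": 1.778,
    "C32L": 1.504e7,
    "C04L": 1.746e8,
    "C04I": 4.365e7,
    "C24H": 3.082e8,
    "C24I": 3.0823e8,
    "C34L": 1.0319e8,
    "O14I": 6.605e7,
    "O24H": 8.702e8,
    "O24I": 5.856e7,
}

_K_M146L: dict[str, float] = {
    **_K_WT,
    "C32L": 2.749e5,
    "O14I": 8.478e7,
    "O24H": 3.992e9,
    "O24I": 1.006e8,
}

M146L_FREE_OCCUPANCY: tuple[str, ...] = ("C32L", "O14I", "O24H", "O24I")

FLUX_NAMES: tuple[str, ...] = (
    "j0414", "j1424", "j2434", "j0414IL", "j1424IL", "j2434IL", "j2030",
    "j0414II", "j2424II", "j2424", "j0404", "j2424HH", "j3132", "j3334",
    "j0001", "j0304", "j2021", "j2324",
)

# Flux parameters, ms^-1 * uM^-k as printed.
_J_WT: dict[str, float] = {
    "j0414": 1.017e6,      # C04I <-> C24H
    "j1424": 2.840e7,      # C04I <-> C24H
    "j2434": 4.961e5,      # O24H <-> C34L
    "j0414IL": 9.502e8,    # C04I <-> C34L
    "j1424IL": 6.4e5,      # C04I <-> C34L
    "j2434IL": 2.431e3,    # C04I <-> C34L
    "j2030": 2.449e-3,     # C20L <-> C30L
    "j0414II": 5.156e5,    # C04I <-> O14I
    "j2424II": 3.0577e7,   # C24I <-> O24I
    "j2424": 3.301e5,      # O24I <-> O24H
    "j0404": 5.459e4,      # C04I <-> C04L
    "j2424HH": 5.478e7,    # C24H <-> O24H
    "j3132": 2.891e-2,     # C30L <-> C32L
    "j3334": 2.120e3,      # C32L <-> C34L
    "j0001": 1.138e-2,     # C00L <-> C04I
    "j0304": 4.756e10,     # C00L <-> C04I
    "j2021": 8.904e-4,     # C20L <-> C24H
    "j2324": 8.523e6,      # C20L <-> C24H
}

_J_M146L: dict[str, float] = {
    **_J_WT,
    "j0414II": 2.587e7,
    "j2424HH": 1.753e8,
}

M146L_FREE_FLUX: tuple[str, ...] = ("j0414II", "j2424HH")


@dataclass(frozen=True)
class OccupancyParams:
    """Equilibrium occupancy parameters K for the twelve states.

    ``values[s] * C**m * I**n`` is the unnormalized occupancy of state ``s``
    at Ca2+ concentration C and IP3 concentration I (both uM).
    """

    values: dict[str, float]
    variant: str = "custom"

    def __post_init__(self) -> None:
        missing = set(STATE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing occupancy parameters for {sorted(missing)}")
        if self.values["C00L"] != 1.0:
            raise ValueError("KC00L is the reference state and must equal 1")
        bad = [s for s, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"occupancy parameters must be > 0: {bad}")

    def __getitem__(self, state: str) -> float:
        return self.values[state]

    @classmethod
    def wild_type(cls) -> "OccupancyParams":
        return cls(values=dict(_K_WT), variant="WT")

    @classmethod
    def m146l(cls) -> "OccupancyParams":
        return cls(values=dict(_K_M146L), variant="M146L")

    @classmethod
    def for_variant(cls, variant: str) -> "OccupancyParams":
        return {"WT": cls.wild_type, "M146L": cls.m146l}[variant]()

    def with_values(self, variant: str | None = None, **updates: float) -> "OccupancyParams":
        return OccupancyParams(
            values={**self.values, **updates},
            variant=variant or self.variant,
        )


@dataclass(frozen=True)
class FluxParams:
    """Symmetric probability-flux parameters of the reversible transitions."""

    values: dict[str, float]
    variant: str = "custom"

    def __post_init__(self) -> None:
        missing = set(FLUX_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing flux parameters for {sorted(missing)}")
        bad = [n for n, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"flux parameters must be > 0: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @classmethod
    def wild_type(cls) -> "FluxParams":
        return cls(values=dict(_J_WT), variant="WT")

    @classmethod
    def m146l(cls) -> "FluxParams":
        return cls(values=dict(_J_M146L), variant="M146L")

    @classmethod
    def for_variant(cls, variant: str) -> "FluxParams":
        return {"WT": cls.wild_type, "M146L": cls.m146l}[variant]()

    def with_values(self, variant: str | None = None, **updates: float) -> "FluxParams":
        return FluxParams(
            values={**self.values, **updates},
            variant=variant or self.variant,
        )


def save_params(path, occ: OccupancyParams, flux: FluxParams) -> None:
    """Serialize one variant's parameter sets to a YAML config file."""
    doc = {
        "variant": occ.variant,
        "occupancy": {k: float(v) for k, v in occ.values.items()},
        "flux": {k: float(v) for k, v in flux.values.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_params(path) -> tuple[OccupancyParams, FluxParams]:
    """Load a parameter config written by :func:`save_params`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    variant = doc.get("variant", "custom")
    return (
        OccupancyParams(values=dict(doc["occupancy"]), variant=variant),
        FluxParams(values=dict(doc["flux"]), variant=variant),
    )
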