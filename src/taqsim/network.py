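"""Reaction-network state and run configuration records.

The simulator tracks exactly 12 molecular species: the double-stranded
amplicon AA, its two single strands A_for/A_rev, the two primers and the
probe, the primer-template hybrids H1 (A_for.P_rev) and H2 (A_rev.P_for),
the probe hybrids AQ/AQP/H1Q on the forward strand, and the primer dimer PD.
AQP and H1Q are structurally identical ternary hybrids kept as distinct
state entries because they form through different reaction paths.

Cumulative cleaved probe (the fluorescence proxy) is accounted for outside
the 12-species vector: it is not a reacting species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

AVOGADRO = 6.02214076e23  # mol^-1, exact (2019 SI)

#: the 12 tracked species, in state-vector order
SPECIES = (
    "AA",
    "A_for",
    "A_rev",
    "P_for",
    "P_rev",
    "Q",
    "H1",
    "H2",
    "AQ",
    "AQP",
    "H1Q",
    "PD",
)
N_SPECIES = len(SPECIES)
IDX = {name: i for i, name in enumerate(SPECIES)}


def copies_per_uL_to_molar(x: float) -> float:
    """Convert a copy-number concentration (copies/uL) to mol/L."""
    if x < 0:
        raise ValueError("copy concentration must be non-negative")
    return x * 1e6 / AVOGADRO


def molar_to_copies_per_uL(c: float) -> float:
    if c < 0:
        raise ValueError("molar concentration must be non-negative")
    return c * AVOGADRO / 1e6


@dataclass(slots=True)
class SpeciesState:
    """Concentrations (mol/L) of the 12 species plus cleaved-probe tally."""

    AA: float = 0.0
    A_for: float = 0.0
    A_rev: float = 0.0
    P_for: float = 0.0
    P_rev: float = 0.0
    Q: float = 0.0
    H1: float = 0.0
    H2: float = 0.0
    AQ: float = 0.0
    AQP: float = 0.0
    H1Q: float = 0.0
    PD: float = 0.0
    cleavedQ_cum: float = 0.0

    def to_vector(self) -> np.ndarray:
        """The 12-species concentration vector (cleaved probe excluded)."""
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, cleavedQ_cum: float = 0.0) -> "SpeciesState":
        if len(vec) != N_SPECIES:
            raise ValueError(f"state vector must have {N_SPECIES} entries")
        return cls(**dict(zip(SPECIES, map(float, vec))), cleavedQ_cum=cleavedQ_cum)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesState":
        return cls(**d)

    def copy(self) -> "SpeciesState":
        return replace(self)

    # strand/oligo family totals (conserved during annealing)
    def family_totals(self) -> dict:
        return {
            "A_for": self.A_for + self.AA + self.H1 + self.AQ + self.AQP + self.H1Q,
            "A_rev": self.A_rev + self.AA + self.H2,
            "P_for": self.P_for + self.PD + self.H2,
            "P_rev": self.P_rev + self.PD + self.H1 + self.AQP + self.H1Q,
            "Q": self.Q + self.AQ + self.AQP + self.H1Q,
        }


@dataclass(frozen=True)
class ProtocolConfig:
    """Cycling protocol: cycle count plus step times (s) and temperatures (C)."""

    n_cycles: int = 45
    time_denaturation: float = 15.0
    temp_denaturation: float = 95.0
    time_annealing: float = 30.0
    temp_annealing: float = 60.0
    time_extension: float = 30.0
    temp_extension: float = 60.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("time_denaturation", "time_annealing", "time_extension"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def annealing_temp_kelvin(self) -> float:
        return self.temp_annealing + 273.15


@dataclass(frozen=True)
class EnzymeDecayModel:
    """Two-parameter stretched-exponential thermal decay of Taq activity.

    Eff_c = Eff0 * exp(-(k_deg * time_denaturation * c)^beta); Eff0 is fixed
    at 1 (full activity before cycling), k_deg (1/s) sets the decay rate and
    beta the profile shape; beta = 1 recovers first-order decay.
    """

    k_deg: float = 0.0
    beta: float = 1.0
    eff0: float = 1.0

    def __post_init__(self) -> None:
        if self.eff0 != 1.0:
            raise ValueError("eff0 is fixed at 1 (baseline activity)")
        if self.k_deg < 0:
            raise ValueError("k_deg must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


Strandedness = Literal["double", "single_forward", "single_reverse"]


@dataclass(frozen=True)
class InitialConditions:
    """Pre-cycling concentrations.

    The template amount may be given in copies/uL (``template_unit="copies_per_uL"``,
    the usual qPCR bench unit) or mol/L, and is assigned to the AA duplex or to
    one single strand according to ``strandedness``.  Primer and probe
    concentrations are molar.  Everything else starts at zero.
    """

    template: float = 0.0
    template_unit: Literal["copies_per_uL", "M"] = "copies_per_uL"
    strandedness: Strandedness = "double"
    p_for: float = 450e-9
    p_rev: float = 450e-9
    q: float = 150e-9

    def __post_init__(self) -> None:
        for name in ("template", "p_for", "p_rev", "q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.strandedness not in ("double", "single_forward", "single_reverse"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")
        if self.template_unit not in ("copies_per_uL", "M"):
            raise ValueError(f"unknown template unit {self.template_unit!r}")

    @property
    def template_molar(self) -> float:
        if self.template_unit == "copies_per_uL":
            return copies_per_uL_to_molar(self.template)
        return self.template


def init_state(ic: InitialConditions) -> SpeciesState:
    """Map initial conditions onto the 12-species state (dict_conc[0])."""
    state = SpeciesState(P_for=ic.p_for, P_rev=ic.p_rev, Q=ic.q)
    t = ic.template_molar
    if ic.strandedness == "double":
        state.AA = t
    elif ic.strandedness == "single_forward":
        state.A_for = t
    else:
        state.A_rev = t
    return state
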