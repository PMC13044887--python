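"""PCR cycle engine: denaturation, annealing kinetics, elongation.

One PCR cycle is modeled as three sequential operations:

* **denaturation** — heating fully dissociates every hybrid into its
  constituent single strands; an instantaneous, total rearrangement.
* **annealing** — the 12-species mass-action network evolves for
  ``time_annealing`` seconds.  The kinetic system is stiff (species span many
  decades in concentration), so it is integrated with a stiffness-aware
  method (LSODA by default, BDF available) using an analytic Jacobian.
* **elongation** — a fraction Eff_c of each extendable hybrid (H1, H2, AQP,
  H1Q) is instantaneously converted to full duplex AA; the polymerase's
  5'->3' exonuclease cleaves the probe on elongated AQP/H1Q, each cleaved
  probe contributing one arbitrary fluorescence unit (numerically, mol/L of
  cleaved probe).  AQ is never elongated (the probe's 3' end is blocked) and
  PD is inert.

Eff_c follows the two-parameter thermal-decay law of the polymerase; the
extension step has no separate kinetics (elongation is assumed to complete
within the programmed extension time).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    IDX,
    N_SPECIES,
    EnzymeDecayModel,
    InitialConditions,
    ProtocolConfig,
    SpeciesState,
    init_state,
)
from .thermo import RateConstantSet

logger = logging.getLogger("taqsim")

_AA, _AF, _AR, _PF, _PR, _Q, _H1, _H2, _AQ, _AQP, _H1Q, _PD = range(N_SPECIES)


class IntegrationError(RuntimeError):
    """Annealing integration failed; carries solver context for diagnosis."""

    def __init__(self, message: str, state: Optional[np.ndarray] = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-integrator settings for the annealing stage."""

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-26
    n_out: int = 100

    def __post_init__(self) -> None:
        if self.n_out < 2:
            raise ValueError("n_out must be >= 2")


DEFAULT_SOLVER = SolverOptions()


@dataclass
class AnnealingTrace:
    """Species concentrations on a uniform time grid during annealing."""

    t: np.ndarray  # (n_out,)
    y: np.ndarray  # (12, n_out), rows in SPECIES order

    def species(self, name: str) -> np.ndarray:
        return self.y[IDX[name]]

    def family_totals(self) -> dict:
        y = self.y
        return {
            "A_for": y[_AF] + y[_AA] + y[_H1] + y[_AQ] + y[_AQP] + y[_H1Q],
            "A_rev": y[_AR] + y[_AA] + y[_H2],
            "P_for": y[_PF] + y[_PD] + y[_H2],
            "P_rev": y[_PR] + y[_PD] + y[_H1] + y[_AQP] + y[_H1Q],
            "Q": y[_Q] + y[_AQ] + y[_AQP] + y[_H1Q],
        }


@dataclass
class CycleRecord:
    """Post-cycle snapshot: state, enzyme activity, fluorescence bookkeeping."""

    cycle: int
    state: SpeciesState
    eff: float
    dF: float
    F: float
    trace: Optional[AnnealingTrace] = None


# ---------------------------------------------------------------------------
# denaturation
# ---------------------------------------------------------------------------


def denaturation(state: SpeciesState) -> SpeciesState:
    """Complete dissociation of all hybrids into single molecules."""
    out = state.copy()
    out.A_for += state.AA + state.H1 + state.AQ + state.AQP + state.H1Q
    out.A_rev += state.AA + state.H2
    out.P_rev += state.H1 + state.AQP + state.H1Q + state.PD
    out.P_for += state.H2 + state.PD
    out.Q += state.AQ + state.AQP + state.H1Q
    out.AA = out.H1 = out.H2 = out.AQ = out.AQP = out.H1Q = out.PD = 0.0
    return out


# ---------------------------------------------------------------------------
# annealing kinetics
# ---------------------------------------------------------------------------


def annealing_rhs(y: np.ndarray, rates: RateConstantSet) -> np.ndarray:
    """Time derivatives of the 12 species under mass-action annealing kinetics.

    The k1 pair also drives AQ + P_rev <-> AQP and the kQ pair H1 + Q <-> H1Q;
    both ternary hybrids dissociate through both channels, with the pooled
    ([AQP] + [H1Q]) dissociation terms feeding the P_rev/Q/H1/AQ balances.
    The kr_off*[AA] term is carried for completeness but kr_off = 0.
    """
    aa, af, ar, pf, pr, q, h1, h2, aq, aqp, h1q, pd = y
    r = rates
    vr = r.kr_on * af * ar - r.kr_off * aa
    v1 = r.k1_on * af * pr - r.k1_off * h1
    v2 = r.k2_on * ar * pf - r.k2_off * h2
    vQ = r.kQ_on * af * q - r.kQ_off * aq
    vPD = r.kPD_on * pf * pr - r.kPD_off * pd
    form_aqp = r.k1_on * aq * pr
    form_h1q = r.kQ_on * h1 * q
    pool = aqp + h1q
    diss_p = r.k1_off * pool  # releases P_rev, leaves AQ
    diss_q = r.kQ_off * pool  # releases Q, leaves H1

    dy = np.empty(N_SPECIES)
    dy[_AA] = vr
    dy[_AF] = -vr - v1 - vQ
    dy[_AR] = -vr - v2
    dy[_PF] = -v2 - vPD
    dy[_PR] = -v1 - vPD - form_aqp + diss_p
    dy[_Q] = -vQ - form_h1q + diss_q
    dy[_H1] = v1 - form_h1q + diss_q
    dy[_H2] = v2
    dy[_AQ] = vQ - form_aqp + diss_p
    dy[_AQP] = form_aqp - (r.k1_off + r.kQ_off) * aqp
    dy[_H1Q] = form_h1q - (r.kQ_off + r.k1_off) * h1q
    dy[_PD] = vPD
    return dy


def annealing_jacobian(y: np.ndarray, rates: RateConstantSet) -> np.ndarray:
    """Analytic Jacobian of :func:`annealing_rhs` (speeds up stiff solvers)."""
    aa, af, ar, pf, pr, q, h1, h2, aq, aqp, h1q, pd = y
    r = rates
    J = np.zeros((N_SPECIES, N_SPECIES))

    def add(row: int, terms: dict) -> None:
        for col, val in terms.items():
            J[row, col] += val

    # flux partials
    vr = {_AF: r.kr_on * ar, _AR: r.kr_on * af, _AA: -r.kr_off}
    v1 = {_AF: r.k1_on * pr, _PR: r.k1_on * af, _H1: -r.k1_off}
    v2 = {_AR: r.k2_on * pf, _PF: r.k2_on * ar, _H2: -r.k2_off}
    vQ = {_AF: r.kQ_on * q, _Q: r.kQ_on * af, _AQ: -r.kQ_off}
    vPD = {_PF: r.kPD_on * pr, _PR: r.kPD_on * pf, _PD: -r.kPD_off}
    f_aqp = {_AQ: r.k1_on * pr, _PR: r.k1_on * aq}
    f_h1q = {_H1: r.kQ_on * q, _Q: r.kQ_on * h1}
    d_p = {_AQP: r.k1_off, _H1Q: r.k1_off}
    d_q = {_AQP: r.kQ_off, _H1Q: r.kQ_off}

    def sub(terms: dict) -> dict:
        return {k: -v for k, v in terms.items()}

    for t in (vr,):
        add(_AA, t)
    for t in (sub(vr), sub(v1), sub(vQ)):
        add(_AF, t)
    for t in (sub(vr), sub(v2)):
        add(_AR, t)
    for t in (sub(v2), sub(vPD)):
        add(_PF, t)
    for t in (sub(v1), sub(vPD), sub(f_aqp), d_p):
        add(_PR, t)
    for t in (sub(vQ), sub(f_h1q), d_q):
        add(_Q, t)
    for t in (v1, sub(f_h1q), d_q):
        add(_H1, t)
    add(_H2, v2)
    for t in (vQ, sub(f_aqp), d_p):
        add(_AQ, t)
    add(_AQP, f_aqp)
    J[_AQP, _AQP] += -(r.k1_off + r.kQ_off)
    add(_H1Q, f_h1q)
    J[_H1Q, _H1Q] += -(r.kQ_off + r.k1_off)
    add(_PD, vPD)
    return J


def _clip_negatives(y: np.ndarray, solver: SolverOptions) -> np.ndarray:
    """Zero out tiny solver negatives; large negatives indicate a defect.

    The noise floor combines the absolute tolerance with the relative
    tolerance applied to the largest concentration present: stiff solvers
    produce harmless negative excursions on that scale, while anything more
    negative signals a modeling or integration defect.
    """
    scale = float(y.max()) if y.size else 0.0
    floor = -(10.0 * solver.atol + solver.rtol * scale)
    if np.any(y < floor):
        worst = float(y.min())
        raise IntegrationError(
            f"concentration {worst:.3e} M below the numerical-noise floor "
            f"{floor:.1e} M; integration is unreliable",
            state=y,
        )
    return np.where(y < 0.0, 0.0, y)


def annealing(
    state: SpeciesState,
    rates: RateConstantSet,
    time_annealing: float,
    solver: SolverOptions = DEFAULT_SOLVER,
) -> tuple[SpeciesState, AnnealingTrace]:
    """Integrate the annealing network for ``time_annealing`` seconds.

    Returns the final state and a trace on a uniform ``solver.n_out``-point
    grid (100 by default).
    """
    if time_annealing <= 0:
        raise ValueError("time_annealing must be positive")
    y0 = state.to_vector()
    t_eval = np.linspace(0.0, time_annealing, solver.n_out)
    kwargs: dict = {}
    if solver.method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = lambda t, y: annealing_jacobian(y, rates)
    sol = solve_ivp(
        lambda t, y: annealing_rhs(y, rates),
        (0.0, time_annealing),
        y0,
        method=solver.method,
        t_eval=t_eval,
        rtol=solver.rtol,
        atol=solver.atol,
        **kwargs,
    )
    if not sol.success:
        raise IntegrationError(
            f"annealing integration failed ({solver.method}, rtol={solver.rtol}, "
            f"atol={solver.atol}): {sol.message}",
            state=y0,
        )
    y_final = _clip_negatives(sol.y[:, -1].copy(), solver)
    trace = AnnealingTrace(t=sol.t, y=np.maximum(sol.y, 0.0))
    return SpeciesState.from_vector(y_final, state.cleavedQ_cum), trace


# ---------------------------------------------------------------------------
# enzyme decay and elongation
# ---------------------------------------------------------------------------


def taq_efficiency(model: EnzymeDecayModel, c: int, time_denaturation: float) -> float:
    """Polymerase activity Eff_c = exp(-(k_deg * t_den * c)^beta) at cycle c."""
    if c < 0:
        raise ValueError("cycle index must be >= 0")
    x = model.k_deg * time_denaturation * c
    return model.eff0 * math.exp(-(x**model.beta)) if x > 0 else model.eff0


def elongation(state: SpeciesState, eff: float) -> tuple[SpeciesState, float]:
    """Eff-weighted conversion of extendable hybrids into AA.

    A fraction ``eff`` of H1, H2, AQP and H1Q is elongated into AA (the
    remainder stays as hybrid, to be dissociated by the next denaturation);
    primers inside elongated hybrids are consumed into new strands.  Probe
    cleavage on elongated AQP/H1Q yields the fluorescence increment.
    """
    if not 0.0 <= eff <= 1.0:
        raise ValueError(f"Eff must be in [0, 1], got {eff}")
    out = state.copy()
    converted = eff * (state.H1 + state.H2 + state.H1Q + state.AQP)
    dF = eff * (state.AQP + state.H1Q)
    out.AA += converted
    out.H1 *= 1.0 - eff
    out.H2 *= 1.0 - eff
    out.AQP *= 1.0 - eff
    out.H1Q *= 1.0 - eff
    out.cleavedQ_cum += dF
    return out, dF


# ---------------------------------------------------------------------------
# cycle orchestration
# ---------------------------------------------------------------------------


def run_1_cycle(
    state: SpeciesState,
    rates: RateConstantSet,
    protocol: ProtocolConfig,
    enzyme: EnzymeDecayModel,
    c: int,
    solver: SolverOptions = DEFAULT_SOLVER,
    keep_trace: bool = False,
) -> CycleRecord:
    """Denaturation -> annealing -> elongation for 1-based cycle index ``c``."""
    state = denaturation(state)
    state, trace = annealing(state, rates, protocol.time_annealing, solver)
    eff = taq_efficiency(enzyme, c, protocol.time_denaturation)
    state, dF = elongation(state, eff)
    return CycleRecord(
        cycle=c,
        state=state,
        eff=eff,
        dF=dF,
        F=state.cleavedQ_cum,
        trace=trace if keep_trace else None,
    )


def run_PCR(
    ic: InitialConditions | SpeciesState,
    rates: RateConstantSet,
    protocol: ProtocolConfig,
    enzyme: EnzymeDecayModel = EnzymeDecayModel(),
    solver: SolverOptions = DEFAULT_SOLVER,
    keep_traces: bool = False,
) -> list[CycleRecord]:
    """Run ``protocol.n_cycles`` cycles; deterministic for a given input."""
    state = ic if isinstance(ic, SpeciesState) else init_state(ic)
    records: list[CycleRecord] = []
    for c in range(1, protocol.n_cycles + 1):
        rec = run_1_cycle(state, rates, protocol, enzyme, c, solver, keep_trace=keep_traces)
        state = rec.state
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "cycle %d: Eff=%.4f F=%.4e totals=%s",
                c,
                rec.eff,
                rec.F,
                {k: f"{v:.3e}" for k, v in state.family_totals().items()},
            )
        records.append(rec)
    return records


def fluorescence_curve(records: Sequence[CycleRecord]) -> np.ndarray:
    """Cumulative fluorescence F_c per cycle, in cleaved-probe molar units."""
    return np.array([r.F for r in records])


@dataclass(frozen=True)
class PCRSetup:
    """A fully-specified assay run missing only the template amount.

    Bundles rate constants, protocol, enzyme model, oligo concentrations and
    solver options so that dilution series and fitting loops can re-run the
    same reaction at different template inputs.
    """

    rates: RateConstantSet
    protocol: ProtocolConfig = ProtocolConfig()
    enzyme: EnzymeDecayModel = EnzymeDecayModel()
    p_for: float = 450e-9
    p_rev: float = 450e-9
    q: float = 150e-9
    solver: SolverOptions = DEFAULT_SOLVER

    def initial_conditions(
        self, template_copies_per_uL: float, strandedness: str = "double"
    ) -> InitialConditions:
        return InitialConditions(
            template=template_copies_per_uL,
            template_unit="copies_per_uL",
            strandedness=strandedness,  # type: ignore[arg-type]
            p_for=self.p_for,
            p_rev=self.p_rev,
            q=self.q,
        )

    def run(
        self,
        template_copies_per_uL: float,
        strandedness: str = "double",
        keep_traces: bool = False,
    ) -> list[CycleRecord]:
        return run_PCR(
            self.initial_conditions(template_copies_per_uL, strandedness),
            self.rates,
            self.protocol,
            self.enzyme,
            self.solver,
            keep_traces=keep_traces,
        )
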