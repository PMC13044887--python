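"""Global optimization of thermokinetic hyperparameters against dilution data.

The forward model (a full dilution-series simulation) is not differentiable
with respect to the hyperparameter vector, so fitting is posed as a global
optimization problem solved with differential evolution.  The objective is a
scaled mean squared error between simulated and experimental amplification
curves: simulated fluorescence is in molar cleaved-probe units while
experimental fluorescence is in arbitrary instrument units, so each curve is
baseline-subtracted and amplitude-normalized before the squared differences
are averaged.

The fittable hyperparameters are {k_deg, beta, k_on, kr_on, dna_high,
p_for, p_rev, q}: the enzyme-decay pair, the shared oligo association rate,
the reannealing rate, the top template concentration of the series (lower
dilutions follow in exact 10-fold steps) and the oligo concentrations.  In
``primer_probe_ratio`` constraint mode only the probe concentration is free
and the primers follow fixed primer-to-probe ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .engine import PCRSetup, SolverOptions, DEFAULT_SOLVER, fluorescence_curve
from .network import EnzymeDecayModel, ProtocolConfig
from .quantify import AmplificationCurve
from .thermo import AssaySequences, RateConstantSet, build_rate_constants

logger = logging.getLogger("taqsim")

PARAM_NAMES = ("k_deg", "beta", "k_on", "kr_on", "dna_high", "p_for", "p_rev", "q")

#: floor for the penalty assigned to candidates whose forward simulation fails
PENALTY_FLOOR = 1e3


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _normalize(F: np.ndarray, baseline: float, amplitude: float) -> np.ndarray:
    return (F - baseline) / amplitude


def scaled_mse(
    sim: Sequence[AmplificationCurve],
    exp: Sequence[AmplificationCurve],
    scaling: str = "each",
) -> tuple[float, list[float]]:
    """Scaled MSE between matched simulated and experimental curve sets.

    Per curve the experimental baseline (min) is subtracted and the curves
    are amplitude-normalized before the mean squared difference over cycles
    is taken; the objective is the average across curves.  Two scalings are
    provided:

    * ``"each"`` (default): each curve is normalized by its own baseline and
      amplitude.  This makes the objective invariant to affine changes of
      fluorescence units on either side, which is required when comparing
      molar simulated curves to instrument-unit experimental curves.
    * ``"experimental"``: both curves are normalized by the experimental
      baseline/amplitude, appropriate when both sides share one unit system.

    Returns ``(mean, per_curve)``.  Zero-amplitude curves (e.g. NTCs) are
    guarded by comparing raw differences against an amplitude of 1.
    """
    if len(sim) != len(exp):
        raise ValueError(f"curve count mismatch: {len(sim)} vs {len(exp)}")
    if scaling not in ("each", "experimental"):
        raise ValueError(f"unknown scaling {scaling!r}")
    per_curve: list[float] = []
    for s, e in zip(sim, exp):
        if len(s.cycles) != len(e.cycles) or np.any(s.cycles != e.cycles):
            raise ValueError(f"cycle-grid mismatch for curve {e.label!r}")
        amp_e = e.amplitude or 1.0
        en = _normalize(e.F, e.F.min(), amp_e)
        if scaling == "each":
            sn = _normalize(s.F, s.F.min(), s.amplitude or 1.0)
        else:
            sn = _normalize(s.F, e.F.min(), amp_e)
        per_curve.append(float(np.mean((sn - en) ** 2)))
    return float(np.mean(per_curve)), per_curve


# ---------------------------------------------------------------------------
# fit specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerSettings:
    """scipy differential-evolution configuration."""

    strategy: str = "best1bin"
    popsize: int = 20
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    tol: float = 1e-6
    polish: bool = True
    maxiter: int = 1000
    seed: int = 0
    workers: int = 1
    init: str = "latinhypercube"


@dataclass
class FitSpec:
    """Free/fixed hyperparameter split, bounds and optimizer settings.

    ``free`` maps parameter names to (lower, upper) bounds; ``fixed`` maps
    the remaining names to values.  In ``primer_probe_ratio`` mode the
    primer concentrations are slaved to the probe concentration via
    ``ratios = (p_for/q, p_rev/q)`` and must not appear as free parameters.
    """

    free: dict[str, tuple[float, float]]
    fixed: dict[str, float]
    constraint: str = "none"
    ratios: Optional[tuple[float, float]] = None
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    scaling: str = "each"

    def __post_init__(self) -> None:
        if self.constraint not in ("none", "primer_probe_ratio"):
            raise ValueError(f"unknown constraint mode {self.constraint!r}")
        if self.constraint == "primer_probe_ratio":
            if self.ratios is None:
                raise ValueError("primer_probe_ratio mode requires ratios=(p_for/q, p_rev/q)")
            bad = {"p_for", "p_rev"} & set(self.free)
            if bad:
                raise ValueError(f"{sorted(bad)} are ratio-constrained, cannot be free")
        names = set(self.free) | set(self.fixed)
        unknown = names - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        required = set(PARAM_NAMES)
        if self.constraint == "primer_probe_ratio":
            required -= {"p_for", "p_rev"}
        missing = required - names
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def free_names(self) -> list[str]:
        return list(self.free)

    def args_from_vector(self, x: np.ndarray) -> dict[str, float]:
        args = dict(self.fixed)
        args.update(dict(zip(self.free_names, map(float, x))))
        if self.constraint == "primer_probe_ratio":
            assert self.ratios is not None
            args["p_for"] = self.ratios[0] * args["q"]
            args["p_rev"] = self.ratios[1] * args["q"]
        return args


@dataclass
class FitResult:
    """Best hyperparameters with objective, diagnostics and predictions."""

    args: dict[str, float]
    objective: float
    per_curve: list[float]
    converged: bool
    message: str
    n_evaluations: int
    seed: int
    generation_best: list[float]
    predicted: list[AmplificationCurve]
    constraint: str = "none"

    def as_dict(self) -> dict:
        return {
            "args": self.args,
            "objective": self.objective,
            "per_curve": self.per_curve,
            "converged": self.converged,
            "message": self.message,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "generation_best": self.generation_best,
            "constraint": self.constraint,
        }


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


class ForwardModel:
    """Dilution-series simulator parameterized by the hyperparameter vector.

    Sequences, protocol and solver settings are fixed for the duration of a
    fit; duplex free energies are computed once and only the rate pairs are
    rebuilt per candidate (they depend on the candidate only through k_on and
    kr_on).
    """

    def __init__(
        self,
        seqs: AssaySequences,
        protocol: ProtocolConfig,
        n_dilutions: int,
        solver: SolverOptions = DEFAULT_SOLVER,
        dG_PD_override: Optional[float] = None,
        table_id: str = "DNA_NN3",
    ):
        self.seqs = seqs
        self.protocol = protocol
        self.n_dilutions = n_dilutions
        self.solver = solver
        self.table_id = table_id
        # cache the thermodynamic K's via a reference rate build
        ref = build_rate_constants(
            seqs,
            protocol.annealing_temp_kelvin,
            1.0,
            0.0,
            dG_PD_override=dG_PD_override,
            table_id=table_id,
        )
        self._K1 = 1.0 / ref.k1_off
        self._K2 = 1.0 / ref.k2_off
        self._KQ = 1.0 / ref.kQ_off
        self._KPD = (1.0 / ref.kPD_off) if ref.kPD_on > 0 else None
        self._thermo_meta = ref.metadata

    def rates(self, k_on: float, kr_on: float) -> RateConstantSet:
        if self._KPD is None:
            kpd_on = kpd_off = 0.0
        else:
            kpd_on, kpd_off = k_on, k_on / self._KPD
        return RateConstantSet(
            k1_on=k_on,
            k1_off=k_on / self._K1,
            k2_on=k_on,
            k2_off=k_on / self._K2,
            kQ_on=k_on,
            kQ_off=k_on / self._KQ,
            kr_on=kr_on,
            kPD_on=kpd_on,
            kPD_off=kpd_off,
            metadata=self._thermo_meta,
        )

    def dilutions(self, dna_high: float) -> list[float]:
        return [dna_high * 10.0 ** (-i) for i in range(self.n_dilutions)]

    def simulate(self, args: dict[str, float]) -> list[AmplificationCurve]:
        """Amplification curves for the 10-fold series below ``dna_high``."""
        setup = PCRSetup(
            rates=self.rates(args["k_on"], args["kr_on"]),
            protocol=self.protocol,
            enzyme=EnzymeDecayModel(k_deg=args["k_deg"], beta=args["beta"]),
            p_for=args["p_for"],
            p_rev=args["p_rev"],
            q=args["q"],
            solver=self.solver,
        )
        cycles = np.arange(1, self.protocol.n_cycles + 1)
        curves = []
        for conc in self.dilutions(args["dna_high"]):
            F = fluorescence_curve(setup.run(conc))
            curves.append(
                AmplificationCurve(cycles, F, label=f"{conc:g} copies/uL", concentration=conc)
            )
        return curves


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_hyperparameters(
    exp_curves: Sequence[AmplificationCurve],
    model: ForwardModel,
    spec: FitSpec,
) -> FitResult:
    """Differential-evolution fit of the free hyperparameters.

    Every candidate is evaluated by simulating the full dilution series and
    scoring it with :func:`scaled_mse` against the experimental curves (NTC
    curves are excluded).  Candidates whose forward simulation fails receive
    a large finite penalty (10x the worst successful objective so far, with
    a floor) so the optimizer continues.  Deterministic for a fixed seed.
    """
    exp = [c for c in exp_curves if not c.is_ntc]
    if not exp:
        raise ValueError("need at least one non-NTC experimental curve")
    if len(exp) != model.n_dilutions:
        raise ValueError(
            f"model simulates {model.n_dilutions} dilutions but "
            f"{len(exp)} experimental curves were given"
        )
    opt = spec.optimizer
    n_eval = 0
    worst_ok = 0.0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval, worst_ok
        n_eval += 1
        args = spec.args_from_vector(x)
        try:
            sim = model.simulate(args)
            val, _ = scaled_mse(sim, exp, scaling=spec.scaling)
        except Exception as err:  # failed candidate: penalize, keep going
            penalty = max(PENALTY_FLOOR, 10.0 * worst_ok)
            logger.warning("candidate %s failed (%s); penalty %.3g", args, err, penalty)
            return penalty
        worst_ok = max(worst_ok, val)
        return val

    generation_best: list[float] = []

    def callback(xk: np.ndarray, convergence: float = 0.0) -> None:
        args = spec.args_from_vector(xk)
        try:
            val, _ = scaled_mse(model.simulate(args), exp, scaling=spec.scaling)
        except Exception:
            return
        generation_best.append(val)
        logger.info("generation %d: best objective %.6g", len(generation_best), val)

    bounds = [spec.free[name] for name in spec.free_names]
    res = differential_evolution(
        objective,
        bounds,
        strategy=opt.strategy,
        popsize=opt.popsize,
        mutation=opt.mutation,
        recombination=opt.recombination,
        tol=opt.tol,
        polish=opt.polish,
        maxiter=opt.maxiter,
        seed=opt.seed,
        workers=opt.workers,
        init=opt.init,
        callback=callback,
    )
    best_args = spec.args_from_vector(res.x)
    predicted = model.simulate(best_args)
    obj, per_curve = scaled_mse(predicted, exp, scaling=spec.scaling)
    return FitResult(
        args=best_args,
        objective=obj,
        per_curve=per_curve,
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=n_eval,
        seed=opt.seed,
        generation_best=generation_best,
        predicted=predicted,
        constraint=spec.constraint,
    )


@dataclass
class DecayModelComparison:
    """Paired fits with the decay exponent free versus pinned at 1."""

    beta_free: FitResult
    beta_fixed: FitResult
    difference: float  # objective(beta=1) - objective(beta free)

    def as_dict(self) -> dict:
        return {
            "beta_free": self.beta_free.as_dict(),
            "beta_fixed_at_1": self.beta_fixed.as_dict(),
            "objective_difference": self.difference,
            "constraint": self.beta_free.constraint,
        }


def compare_decay_models(
    exp_curves: Sequence[AmplificationCurve],
    model: ForwardModel,
    spec: FitSpec,
) -> DecayModelComparison:
    """Fit twice — stretched-exponential decay (beta free) vs first-order
    decay (beta = 1) — with otherwise identical bounds and stopping criteria.

    A strictly lower beta-free objective on data whose decay departs from
    first order quantifies the extra flexibility of the two-parameter law.
    """
    if "beta" not in spec.free:
        raise ValueError("spec must declare beta as a free parameter")
    free_fixed = {k: v for k, v in spec.free.items() if k != "beta"}
    spec_fixed = FitSpec(
        free=free_fixed,
        fixed={**spec.fixed, "beta": 1.0},
        constraint=spec.constraint,
        ratios=spec.ratios,
        optimizer=spec.optimizer,
        scaling=spec.scaling,
    )
    res_free = fit_hyperparameters(exp_curves, model, spec)
    res_fixed = fit_hyperparameters(exp_curves, model, spec_fixed)
    return DecayModelComparison(
        beta_free=res_free,
        beta_fixed=res_fixed,
        difference=res_fixed.objective - res_free.objective,
    )
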