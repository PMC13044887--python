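"""Amplification-curve quantification: Ct, standard curves, sigmoid descriptors.

Ct values use the second-derivative-maximum method: the cycle threshold is
the cycle of maximum discrete second difference of fluorescence, i.e. the
point of maximum acceleration during the exponential phase.  The same code
path handles simulated and experimental curves.

Standard curves regress Ct against log10 of input concentration over a
dilution series; at perfect doubling efficiency the slope is
-log2(10) = -3.32 cycles per decade.

The five-parameter sigmoid F(c) = Fb + Fm / (1 + exp(Sc*(c - Cs)))**As
summarizes a curve's baseline Fb, final fluorescence intensity (FFI) Fm,
inflection location Cs, slope Sc and asymmetry As.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .engine import PCRSetup, fluorescence_curve

#: default fraction of the batch's maximal amplitude below which a curve is
#: called undetected
MIN_SIGNAL_FRAC = 0.05


@dataclass
class AmplificationCurve:
    """Fluorescence-vs-cycle series with optional input-concentration label."""

    cycles: np.ndarray
    F: np.ndarray
    label: str = ""
    concentration: Optional[float] = None  # copies/uL; 0 marks an NTC

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.F = np.asarray(self.F, dtype=float)
        if self.cycles.shape != self.F.shape:
            raise ValueError("cycles and F must have equal length")
        if len(self.cycles) and np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")

    @property
    def amplitude(self) -> float:
        return float(self.F.max() - self.F.min()) if len(self.F) else 0.0

    @property
    def is_ntc(self) -> bool:
        return self.concentration == 0


@dataclass
class CtResult:
    """Second-derivative-maximum Ct call."""

    ct: Optional[float]
    detected: bool
    second_difference: np.ndarray
    label: str = ""
    concentration: Optional[float] = None


@dataclass
class SigmoidParams:
    """Five-parameter sigmoid fit; Fm is reported as the FFI."""

    Fb: float
    Fm: float
    Cs: float
    Sc: float
    As: float
    residual_norm: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "Fb": self.Fb,
            "Fm": self.Fm,
            "Cs": self.Cs,
            "Sc": self.Sc,
            "As": self.As,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
        }


@dataclass
class StandardCurve:
    """Per-dilution Ct results plus the Ct-vs-log10(concentration) regression."""

    results: list[CtResult]
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    curves: list[AmplificationCurve] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.slope is not None


def extract_ct(
    curve: AmplificationCurve,
    min_signal_frac: float = MIN_SIGNAL_FRAC,
    reference_amplitude: Optional[float] = None,
    abs_floor: float = 0.0,
    interpolate: bool = False,
) -> CtResult:
    """Ct by the second-derivative-maximum method.

    F''(c) is the central second difference F(c+1) - 2F(c) + F(c-1); the Ct
    is the earliest interior cycle maximizing it.  A curve is undetected when
    its amplitude falls below ``min_signal_frac`` of ``reference_amplitude``
    (the largest amplitude in the batch; a lone curve is referenced to its
    own amplitude, so only ``abs_floor`` applies) or below ``abs_floor``.

    ``interpolate=True`` refines the integer argmax by fitting a parabola
    through the three second-difference points around it (off by default:
    the cycle threshold is defined as an argmax over cycles).
    """
    if len(curve.F) < 5:
        raise ValueError("need >= 5 cycles for Ct extraction")
    F = curve.F
    d2 = F[2:] - 2.0 * F[1:-1] + F[:-2]  # aligned with cycles[1:-1]
    amp = curve.amplitude
    ref = amp if reference_amplitude is None else reference_amplitude
    detected = amp > abs_floor and amp >= min_signal_frac * ref and amp > 0.0
    if not detected:
        return CtResult(None, False, d2, curve.label, curve.concentration)
    i = int(np.argmax(d2))  # np.argmax returns the earliest maximum
    ct = float(curve.cycles[1:-1][i])
    if interpolate and 0 < i < len(d2) - 1:
        a, b, c = d2[i - 1], d2[i], d2[i + 1]
        denom = a - 2.0 * b + c
        if denom < 0:
            ct += 0.5 * (a - c) / denom
    return CtResult(ct, True, d2, curve.label, curve.concentration)


def _run_dilution(setup: PCRSetup, conc: float) -> np.ndarray:
    return fluorescence_curve(setup.run(conc))


def standard_curve(
    setup: PCRSetup,
    dilutions_copies_per_uL: Sequence[float],
    min_signal_frac: float = MIN_SIGNAL_FRAC,
    workers: int = 1,
) -> StandardCurve:
    """Simulate a dilution series and regress Ct on log10(concentration).

    Each dilution is an independent run (a concentration of 0 is the NTC),
    so the series parallelizes trivially; results are identical to serial
    execution for any ``workers``.  Undetected curves and the NTC are
    excluded from the ordinary-least-squares regression.
    """
    dilutions = list(dilutions_copies_per_uL)
    if sum(1 for d in dilutions if d > 0) < 2:
        raise ValueError("need >= 2 non-NTC concentrations")
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            curves_F = list(pool.map(_run_dilution, [setup] * len(dilutions), dilutions))
    else:
        curves_F = [_run_dilution(setup, d) for d in dilutions]
    n = setup.protocol.n_cycles
    curves = [
        AmplificationCurve(
            np.arange(1, n + 1),
            F,
            label="NTC" if d == 0 else f"{d:g} copies/uL",
            concentration=d,
        )
        for d, F in zip(dilutions, curves_F)
    ]
    return quantify_batch(curves, min_signal_frac=min_signal_frac)


def quantify_batch(
    curves: Sequence[AmplificationCurve], min_signal_frac: float = MIN_SIGNAL_FRAC
) -> StandardCurve:
    """Batch Ct extraction + standard-curve regression for existing curves."""
    ref = max((c.amplitude for c in curves), default=0.0)
    results = [
        extract_ct(c, min_signal_frac=min_signal_frac, reference_amplitude=ref)
        for c in curves
    ]
    pts = [
        (math.log10(r.concentration), r.ct)
        for r in results
        if r.detected and r.concentration is not None and r.concentration > 0
    ]
    if len(pts) >= 2:
        x, y = zip(*pts)
        reg = stats.linregress(x, y)
        slope, intercept, r2 = reg.slope, reg.intercept, reg.rvalue**2
    else:
        slope = intercept = r2 = None
    return StandardCurve(results, slope, intercept, r2, curves=list(curves))


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------


def sigmoid5(c: np.ndarray, Fb: float, Fm: float, Cs: float, Sc: float, As: float) -> np.ndarray:
    """Five-parameter sigmoid; Sc < 0 gives an increasing curve."""
    z = np.clip(Sc * (c - Cs), -700.0, 700.0)
    return Fb + Fm / (1.0 + np.exp(z)) ** As


def fit_sigmoid(curve: AmplificationCurve) -> SigmoidParams:
    """Bounded trust-region-reflective least-squares fit of the 5P sigmoid.

    Initialization: Fb at the curve minimum, Fm at the amplitude, Cs at the
    second-derivative-maximum Ct (mid-grid fallback), Sc = -0.3 (increasing
    curve), As = 1.  Non-convergence is flagged; parameters from the best
    iterate are still returned.
    """
    if len(curve.F) < 6:
        raise ValueError("need >= 6 points to fit 5 parameters")
    c = curve.cycles.astype(float)
    F = curve.F
    amp = curve.amplitude
    try:
        ct0 = extract_ct(curve).ct
    except ValueError:
        ct0 = None
    cs0 = float(ct0) if ct0 is not None else float(c[len(c) // 2])
    p0 = [float(F.min()), max(amp, 1e-30), cs0, -0.3, 1.0]
    lower = [0.0, 0.0, c[0] - len(c), -10.0, 1e-3]
    upper = [np.inf, np.inf, c[-1] + len(c), 10.0, 1e2]
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, lower, upper)]
    try:
        popt, _ = optimize.curve_fit(
            sigmoid5, c, F, p0=p0, bounds=(lower, upper), method="trf", maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    resid = float(np.linalg.norm(sigmoid5(c, *popt) - F))
    return SigmoidParams(*map(float, popt), residual_norm=resid, converged=converged)
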