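"""Synthetic assays and pseudo-experimental datasets.

Real TaqMan assays are defined by an amplicon and three oligos whose
positions and orientations follow a fixed convention: the forward primer
matches the 5' end of the forward strand, the reverse primer is the reverse
complement of its 3' end, and the probe binds an internal site of the
forward strand (same orientation as the reverse primer).  ``make_assay``
generates random assays honoring that geometry so the whole simulator can
be exercised without any downloaded sequence.

``make_pseudo_experiment`` turns an assay plus a known hyperparameter set
into a noisy dilution-series dataset in the experimental CSV dialect, with
the ground truth stored alongside — the substrate for parameter-recovery
tests.  The noise model is additive Gaussian on fluorescence (scaled to the
plateau) plus an optional affine instrument transform (gain/offset), which
exercises the unit-invariance of the scaled-MSE objective; drift, spikes and
other instrument artifacts are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .engine import SolverOptions, DEFAULT_SOLVER
from .fit import ForwardModel, PARAM_NAMES
from .network import ProtocolConfig
from .quantify import AmplificationCurve
from .thermo import AssaySequences, OligoSequence, reverse_complement

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticAssay:
    """A generated amplicon with primer/probe sites satisfying the geometry
    invariants (oligos are exact substrings up to reverse complement; the
    probe site does not overlap the primer sites)."""

    sequences: AssaySequences
    probe_start: int
    seed: int
    gc_content: float

    @property
    def amplicon(self) -> str:
        return self.sequences.a_for.bases

    def to_fasta(self) -> str:
        s = self.sequences
        return "".join(
            f">{o.name}\n{o.bases}\n" for o in (s.a_for, s.p_for, s.p_rev, s.q)
        )

    def to_config(self) -> dict:
        s = self.sequences
        return {
            "sequences": {
                "A_for": s.a_for.bases,
                "P_for": s.p_for.bases,
                "P_rev": s.p_rev.bases,
                "Q": s.q.bases,
            },
            "seed": self.seed,
            "probe_start": self.probe_start,
            "gc_content": self.gc_content,
        }


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def make_assay(
    seed: int,
    amplicon_length: int = 100,
    primer_length: int = 20,
    probe_length: int = 24,
    gc_bounds: tuple[float, float] = (0.40, 0.60),
    max_tries: int = 1000,
) -> SyntheticAssay:
    """Deterministically generate a synthetic TaqMan assay.

    The amplicon is drawn uniformly over ACGT until its GC content falls in
    ``gc_bounds``; the probe site is placed centrally between the primer
    sites.  Raises for geometrically infeasible length combinations.
    """
    if not 60 <= amplicon_length <= 150:
        raise ValueError("amplicon_length must be in [60, 150]")
    if not 18 <= primer_length <= 25:
        raise ValueError("primer_length must be in [18, 25]")
    if not 20 <= probe_length <= 30:
        raise ValueError("probe_length must be in [20, 30]")
    if amplicon_length < 2 * primer_length + probe_length:
        raise ValueError(
            "amplicon too short for two primer sites plus a non-overlapping probe site"
        )
    lo, hi = gc_bounds
    if not 0 <= lo < hi <= 1:
        raise ValueError("gc_bounds must satisfy 0 <= lo < hi <= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        a_for = "".join(rng.choice(BASES, amplicon_length))
        if lo <= _gc(a_for) <= hi:
            break
    else:
        raise ValueError(f"no amplicon with GC in {gc_bounds} after {max_tries} tries")
    p_for = a_for[:primer_length]
    p_rev = reverse_complement(a_for[-primer_length:])
    # centre the probe in the inter-primer region
    span_lo = primer_length
    span_hi = amplicon_length - primer_length - probe_length
    probe_start = (span_lo + span_hi) // 2
    q = reverse_complement(a_for[probe_start : probe_start + probe_length])
    assay = SyntheticAssay(
        sequences=AssaySequences.from_strings(a_for, p_for, p_rev, q),
        probe_start=probe_start,
        seed=seed,
        gc_content=_gc(a_for),
    )
    _check_assay(assay, primer_length, probe_length)
    return assay


def _check_assay(assay: SyntheticAssay, primer_length: int, probe_length: int) -> None:
    a = assay.amplicon
    s = assay.sequences
    if s.p_for.bases != a[:primer_length]:
        raise AssertionError("P_for is not the amplicon 5' end")
    if reverse_complement(s.p_rev.bases) != a[-primer_length:]:
        raise AssertionError("P_rev does not match the amplicon 3' end")
    site = reverse_complement(s.q.bases)
    start = a.find(site)
    if start < 0:
        raise AssertionError("probe site is not a substring of the amplicon")
    if start < primer_length or start + probe_length > len(a) - primer_length:
        raise AssertionError("probe site overlaps a primer site")


# ---------------------------------------------------------------------------
# pseudo-experiments
# ---------------------------------------------------------------------------


@dataclass
class PseudoExperiment:
    """Engine-simulated dilution series with noise; truth stored alongside."""

    curves: list[AmplificationCurve]
    true_args: dict[str, float]
    assay: SyntheticAssay
    protocol: ProtocolConfig
    noise_sigma: float
    gain: float
    offset: float
    seed: int
    clean: list[AmplificationCurve] = field(default_factory=list)

    def to_csv(self) -> str:
        """Wide experimental-CSV dialect: a `cycle` column, then one
        fluorescence column per curve named by its concentration label."""
        cycles = self.curves[0].cycles
        header = "cycle," + ",".join(c.label for c in self.curves)
        rows = [header]
        for i, cyc in enumerate(cycles):
            rows.append(
                f"{cyc}," + ",".join(repr(float(c.F[i])) for c in self.curves)
            )
        return "\n".join(rows) + "\n"

    def sidecar(self) -> dict:
        return {
            "concentrations": {c.label: c.concentration for c in self.curves},
            "true_args": self.true_args,
            "noise_sigma": self.noise_sigma,
            "gain": self.gain,
            "offset": self.offset,
            "seed": self.seed,
            "n_cycles": self.protocol.n_cycles,
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "curves.csv").write_text(self.to_csv())
        (directory / "curves.json").write_text(json.dumps(self.sidecar(), indent=2))
        (directory / "assay.fasta").write_text(self.assay.to_fasta())
        (directory / "assay.json").write_text(json.dumps(self.assay.to_config(), indent=2))


#: hyperparameters used when a pseudo-experiment does not override them;
#: chosen to sit in the regime the simulator is designed for (realistic oligo
#: association rates, moderate reannealing competition, mild enzyme decay)
DEFAULT_TRUE_ARGS = {
    "k_deg": 1.0e-4,
    "beta": 1.0,
    "k_on": 1.0e6,
    "kr_on": 1.0e7,
    "dna_high": 1.0e7,
    "p_for": 450e-9,
    "p_rev": 450e-9,
    "q": 150e-9,
}


def make_pseudo_experiment(
    assay: SyntheticAssay,
    true_args: Optional[dict[str, float]] = None,
    n_dilutions: int = 3,
    n_cycles: int = 45,
    noise_sigma: float = 0.0,
    gain: float = 1.0,
    offset: float = 0.0,
    seed: int = 0,
    protocol: Optional[ProtocolConfig] = None,
    solver: SolverOptions = DEFAULT_SOLVER,
) -> PseudoExperiment:
    """Simulate a 10-fold dilution series and dress it as experimental data.

    ``noise_sigma`` is the Gaussian noise standard deviation as a fraction of
    the series' plateau (largest fluorescence across curves); the affine
    ``gain``/``offset`` mimic arbitrary instrument units.  Bit-reproducible
    for a fixed seed.
    """
    args = dict(DEFAULT_TRUE_ARGS)
    if true_args:
        unknown = set(true_args) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown hyperparameters {sorted(unknown)}")
        args.update(true_args)
    protocol = protocol or ProtocolConfig(n_cycles=n_cycles)
    model = ForwardModel(assay.sequences, protocol, n_dilutions, solver=solver)
    clean = model.simulate(args)
    rng = np.random.default_rng(seed)
    plateau = max(c.F.max() for c in clean)
    curves = []
    for c in clean:
        noise = rng.normal(0.0, noise_sigma * plateau, size=c.F.shape) if noise_sigma else 0.0
        curves.append(
            AmplificationCurve(
                c.cycles,
                gain * (c.F + noise) + offset,
                label=c.label,
                concentration=c.concentration,
            )
        )
    return PseudoExperiment(
        curves=curves,
        true_args=args,
        assay=assay,
        protocol=protocol,
        noise_sigma=noise_sigma,
        gain=gain,
        offset=offset,
        seed=seed,
        clean=clean,
    )
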