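"""Hybridization thermodynamics and rate constants.

Every binding reaction in the simulator (primer annealing, probe annealing,
amplicon reannealing, primer-dimer formation) is parameterized by a pair
{k_on, k_off}.  Free energies of perfect-match duplexes come from a published
unified nearest-neighbor (NN) table; equilibrium constants follow
K = exp(-dG/RT), and dissociation rates are derived from a single shared
association rate through k_off = k_on / K.  Amplicon reannealing is treated
as irreversible (k_off = 0): the free energy accumulated along a full-length
duplex makes dissociation at annealing temperature negligible.

The primer-dimer free energy cannot be obtained from perfect-match NN sums
(forward and reverse primers are generally not complementary); a pluggable
provider computes it.  The default provider scans every ungapped antiparallel
alignment register of the two primers and NN-scores the best contiguous
complementary run.  An external secondary-structure engine or a user-supplied
constant can be registered instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from Bio.SeqUtils import MeltingTemp as mt

R_GAS = 8.314  # J mol^-1 K^-1
CAL_TO_J = 4.184

#: identifier -> Biopython nearest-neighbor table
NN_TABLES = {
    "DNA_NN1": mt.DNA_NN1,  # Breslauer 1986
    "DNA_NN2": mt.DNA_NN2,  # Sugimoto 1996
    "DNA_NN3": mt.DNA_NN3,  # SantaLucia & Hicks 2004 (unified)
    "DNA_NN4": mt.DNA_NN4,  # SantaLucia 1997
}
DEFAULT_NN_TABLE = "DNA_NN3"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for empty, too-short or non-ACGT sequences."""


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OligoSequence:
    """A single-stranded DNA sequence, 5'->3'.

    IUPAC ambiguity codes are rejected: the kinetic model needs a definite
    perfect-match duplex for every oligo.
    """

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError(f"{self.name or 'sequence'}: empty sequence")
        bad = set(self.bases.upper()) - set("ACGT")
        if bad:
            raise SequenceError(
                f"{self.name or 'sequence'}: non-ACGT characters {sorted(bad)} "
                "(IUPAC ambiguity codes are not supported)"
            )
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, name: Optional[str] = None) -> "OligoSequence":
        return OligoSequence(name or f"{self.name}_rc", reverse_complement(self.bases))


@dataclass(frozen=True)
class HybridizationThermo:
    """Duplex formation thermodynamics at temperature T.

    dH (J/mol) and dS (J/mol/K) are NN-table sums; dG = dH - T*dS and
    K = exp(-dG/(R*T)) with the tabulated 1 M standard state.
    """

    dH: float
    dS: float
    T: float
    table_id: str = DEFAULT_NN_TABLE

    @property
    def dG(self) -> float:
        return self.dH - self.T * self.dS

    @property
    def K(self) -> float:
        return math.exp(-self.dG / (R_GAS * self.T))

    def as_dict(self) -> dict:
        return {
            "dH": self.dH,
            "dS": self.dS,
            "dG": self.dG,
            "K": self.K,
            "T": self.T,
            "table_id": self.table_id,
        }


def _nn_step_params(step: str, table: dict) -> tuple[float, float]:
    """dH/dS increment (kcal, cal/K) for one dinucleotide stack."""
    key = f"{step}/{step.translate(_COMPLEMENT)}"
    if key in table:
        return table[key]
    rc = reverse_complement(step)
    key = f"{rc}/{rc.translate(_COMPLEMENT)}"
    return table[key]


def nn_thermo(
    seq: OligoSequence | str,
    T: float,
    table_id: str = DEFAULT_NN_TABLE,
    salt_molar: Optional[float] = None,
) -> HybridizationThermo:
    """Perfect-match duplex thermodynamics of ``seq`` against its exact
    reverse complement at absolute temperature ``T`` (K).

    dH and dS are accumulated over nearest-neighbor dinucleotide stacks plus
    initiation/terminal terms of the chosen published table.  By default the
    tabulated 1 M Na+ reference state is used; pass ``salt_molar`` to apply
    the unified entropic monovalent-salt correction
    (dS += 0.368 * (N-1) * ln[Na+] cal/mol/K).
    """
    if isinstance(seq, str):
        seq = OligoSequence("seq", seq)
    if len(seq) < 2:
        raise SequenceError(f"{seq.name}: need at least 2 bases for NN thermodynamics")
    if not 273.15 < T < 373.15:
        raise ValueError(f"temperature {T} K outside liquid-water range")
    table = NN_TABLES[table_id]
    b = seq.bases

    dh, ds = table["init"]
    if b == reverse_complement(b):
        sh, ss = table["sym"]
        dh, ds = dh + sh, ds + ss
    # terminal initiation terms (zero in tables that use the global variants)
    for terminal in (b[0], b[-1]):
        key = "init_A/T" if terminal in "AT" else "init_G/C"
        th, ts = table[key]
        dh, ds = dh + th, ds + ts
    if "G" in b or "C" in b:
        th, ts = table["init_oneG/C"]
    else:
        th, ts = table["init_allA/T"]
    dh, ds = dh + th, ds + ts
    for i in range(len(b) - 1):
        sh, ss = _nn_step_params(b[i : i + 2], table)
        dh, ds = dh + sh, ds + ss
    if salt_molar is not None:
        if salt_molar <= 0:
            raise ValueError("salt_molar must be positive")
        ds += 0.368 * (len(b) - 1) * math.log(salt_molar)
    return HybridizationThermo(
        dH=dh * 1000.0 * CAL_TO_J, dS=ds * CAL_TO_J, T=T, table_id=table_id
    )


# ---------------------------------------------------------------------------
# primer-dimer free-energy providers
# ---------------------------------------------------------------------------

#: sentinel returned when no complementary register of >=2 bp exists
NO_STABLE_DIMER = None

PDProvider = Callable[[OligoSequence, OligoSequence, float], Optional[float]]


def primer_dimer_dG(
    p_for: OligoSequence | str,
    p_rev: OligoSequence | str,
    T: float,
    table_id: str = DEFAULT_NN_TABLE,
    provider: Optional[PDProvider] = None,
) -> Optional[float]:
    """Free energy (J/mol) of the most stable forward/reverse primer dimer.

    The default provider enumerates every ungapped antiparallel alignment
    register of the two primers, extracts maximal runs of Watson-Crick
    complementary pairs, NN-scores each run of >=2 bp as a perfect-match
    duplex, and returns the minimum dG.  Returns ``NO_STABLE_DIMER`` (None)
    when no register contains two consecutive complementary pairs; callers
    map that to a disabled PD reaction.
    """
    if isinstance(p_for, str):
        p_for = OligoSequence("P_for", p_for)
    if isinstance(p_rev, str):
        p_rev = OligoSequence("P_rev", p_rev)
    if provider is not None:
        return provider(p_for, p_rev, T)

    a, b = p_for.bases, p_rev.bases
    n, m = len(a), len(b)
    best: Optional[float] = None
    # Antiparallel pairing: a[i] pairs with b[j] on register k when i + j = k.
    for k in range(n + m - 1):
        run_start = None
        i_lo = max(0, k - m + 1)
        i_hi = min(n - 1, k)
        for i in range(i_lo, i_hi + 2):  # sentinel pass at i_hi+1 closes runs
            paired = (
                i <= i_hi and a[i].translate(_COMPLEMENT) == b[k - i]
            )
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                length = i - run_start
                if length >= 2:
                    dg = nn_thermo(a[run_start:i], T, table_id=table_id).dG
                    if best is None or dg < best:
                        best = dg
                run_start = None
    return best


def constant_pd_provider(dG: float) -> PDProvider:
    """Provider returning a user-supplied constant PD free energy."""

    def provider(_p_for: OligoSequence, _p_rev: OligoSequence, _T: float) -> float:
        return dG

    return provider


# ---------------------------------------------------------------------------
# rate constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstantSet:
    """The {k_on, k_off} pairs of the five binding reactions.

    On-rates are in M^-1 s^-1, off-rates in s^-1.  All oligo on-rates share a
    single value; the reannealing on-rate is independent and its off-rate is
    fixed at zero.  Off-rates follow k_off = k_on / K.
    """

    k1_on: float
    k1_off: float  # P_rev + A_for <-> H1 (also AQ + P_rev <-> AQP)
    k2_on: float
    k2_off: float  # P_for + A_rev <-> H2
    kQ_on: float
    kQ_off: float  # Q + A_for <-> AQ (also H1 + Q <-> H1Q)
    kr_on: float
    kr_off: float = 0.0  # A_for + A_rev -> AA, irreversible
    kPD_on: float = 0.0
    kPD_off: float = 0.0  # P_for + P_rev <-> PD
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kr_off != 0.0:
            raise ValueError("kr_off is fixed at 0 (irreversible reannealing)")
        for name in ("k1_on", "k2_on", "kQ_on", "kr_on", "kPD_on"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AssaySequences:
    """The four sequences of a singleplex TaqMan assay.

    ``a_for`` is the amplicon forward strand; ``p_rev`` and the probe ``q``
    anneal to it (both are reverse complements of A_for segments), while
    ``p_for`` anneals to the reverse strand.
    """

    a_for: OligoSequence
    p_for: OligoSequence
    p_rev: OligoSequence
    q: OligoSequence

    @classmethod
    def from_strings(cls, a_for: str, p_for: str, p_rev: str, q: str) -> "AssaySequences":
        return cls(
            OligoSequence("A_for", a_for),
            OligoSequence("P_for", p_for),
            OligoSequence("P_rev", p_rev),
            OligoSequence("Q", q),
        )


def build_rate_constants(
    seqs: AssaySequences,
    T: float,
    k_oligos_on: float,
    kr_on: float,
    dG_PD_override: Optional[float] = None,
    table_id: str = DEFAULT_NN_TABLE,
    pd_provider: Optional[PDProvider] = None,
    salt_molar: Optional[float] = None,
) -> RateConstantSet:
    """Derive the full rate-constant set from sequences at temperature T (K).

    K for each oligo comes from the perfect-match duplex of the oligo against
    its binding site (the oligo length defines the duplex length); K_PD comes
    from the primer-dimer provider.  A missing stable dimer disables the PD
    reaction (kPD_on = 0) rather than mapping to an enormous off-rate, which
    would only add stiffness.
    """
    if k_oligos_on <= 0:
        raise ValueError("k_oligos_on must be positive")
    if kr_on < 0:
        raise ValueError("kr_on must be non-negative")
    th1 = nn_thermo(seqs.p_rev, T, table_id=table_id, salt_molar=salt_molar)
    th2 = nn_thermo(seqs.p_for, T, table_id=table_id, salt_molar=salt_molar)
    thQ = nn_thermo(seqs.q, T, table_id=table_id, salt_molar=salt_molar)
    if dG_PD_override is not None:
        dg_pd: Optional[float] = dG_PD_override
    else:
        dg_pd = primer_dimer_dG(
            seqs.p_for, seqs.p_rev, T, table_id=table_id, provider=pd_provider
        )
    if dg_pd is NO_STABLE_DIMER:
        kpd_on, kpd_off = 0.0, 0.0
        k_pd = None
    else:
        k_pd = math.exp(-dg_pd / (R_GAS * T))
        kpd_on, kpd_off = k_oligos_on, k_oligos_on / k_pd
    meta = {
        "T": T,
        "table_id": table_id,
        "k_oligos_on": k_oligos_on,
        "thermo": {
            "H1": th1.as_dict(),
            "H2": th2.as_dict(),
            "AQ": thQ.as_dict(),
            "PD": {"dG": dg_pd, "K": k_pd, "T": T, "table_id": table_id},
        },
    }
    return RateConstantSet(
        k1_on=k_oligos_on,
        k1_off=k_oligos_on / th1.K,
        k2_on=k_oligos_on,
        k2_off=k_oligos_on / th2.K,
        kQ_on=k_oligos_on,
        kQ_off=k_oligos_on / thQ.K,
        kr_on=kr_on,
        kr_off=0.0,
        kPD_on=kpd_on,
        kPD_off=kpd_off,
        metadata=meta,
    )


def thermo_report(rates: RateConstantSet) -> str:
    """JSON report of per-reaction thermodynamics and rate constants."""
    pairs = {
        "H1": ("k1_on", "k1_off"),
        "H2": ("k2_on", "k2_off"),
        "AQ": ("kQ_on", "kQ_off"),
        "AA": ("kr_on", "kr_off"),
        "PD": ("kPD_on", "kPD_off"),
    }
    out = {}
    for rxn, (on, off) in pairs.items():
        entry = dict(rates.metadata.get("thermo", {}).get(rxn, {}))
        entry["k_on"] = getattr(rates, on)
        entry["k_off"] = getattr(rates, off)
        out[rxn] = entry
    return json.dumps(out, indent=2)
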