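"""Run configuration: schema, unit handling, file readers/writers.

A single config file (YAML or JSON) drives every CLI subcommand.  It mirrors
the simulator's parameter dictionaries: sequences (inline or FASTA path),
initial concentrations (with explicit units), the cycling protocol, the
enzyme-decay model and the thermokinetic settings.  Unknown keys are
rejected with their location so unit mistakes fail loudly rather than
silently simulating the wrong reaction.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .engine import SolverOptions
from .network import EnzymeDecayModel, ProtocolConfig, InitialConditions
from .quantify import AmplificationCurve
from .thermo import DEFAULT_NN_TABLE, NN_TABLES, AssaySequences, OligoSequence


class ConfigError(ValueError):
    """Config-schema violation; the message names the offending key."""


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {
    "M": 1.0,
    "mol/L": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "umol/L": 1e-6,
    "nM": 1e-9,
    "nmol/L": 1e-9,
    "pM": 1e-12,
}

_QTY_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([A-Za-z/_]+)?\s*$")


def parse_concentration(value, key: str = "concentration") -> tuple[float, str]:
    """Parse a concentration into ``(magnitude, unit)``.

    Accepts a bare number (interpreted as mol/L), or a string like
    ``"450 nM"`` / ``"1e7 copies_per_uL"``.  Molar prefixes are converted to
    mol/L; copy-number concentrations are returned in copies/uL.
    """
    if isinstance(value, (int, float)):
        return float(value), "M"
    if not isinstance(value, str):
        raise ConfigError(f"{key}: expected number or 'value unit' string, got {value!r}")
    m = _QTY_RE.match(value)
    if not m:
        raise ConfigError(f"{key}: cannot parse concentration {value!r}")
    mag = float(m.group(1))
    unit = m.group(2) or "M"
    if unit in ("copies/uL", "copies_per_uL", "cp/uL"):
        return mag, "copies_per_uL"
    if unit not in _UNIT_FACTORS:
        raise ConfigError(
            f"{key}: unknown unit {unit!r} (expected one of "
            f"{sorted(_UNIT_FACTORS)} or copies_per_uL)"
        )
    return mag * _UNIT_FACTORS[unit], "M"


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

_ROLES = ("A_for", "P_for", "P_rev", "Q")


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    sequences: AssaySequences
    initial: InitialConditions
    protocol: ProtocolConfig = ProtocolConfig()
    enzyme: EnzymeDecayModel = EnzymeDecayModel()
    k_oligos_on: float = 1e6
    kr_on: float = 1e7
    dG_PD_override: Optional[float] = None
    nn_table: str = DEFAULT_NN_TABLE
    salt_molar: Optional[float] = None
    solver: SolverOptions = SolverOptions()
    seed: int = 0

    def metadata(self) -> dict:
        return {
            "nn_table": self.nn_table,
            "k_oligos_on": self.k_oligos_on,
            "kr_on": self.kr_on,
            "solver": {
                "method": self.solver.method,
                "rtol": self.solver.rtol,
                "atol": self.solver.atol,
                "n_out": self.solver.n_out,
            },
            "seed": self.seed,
        }


def read_fasta_sequences(path: str | Path) -> AssaySequences:
    """Read an assay from FASTA; records must be named A_for/P_for/P_rev/Q."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    missing = [r for r in _ROLES if r not in records]
    if missing:
        raise ConfigError(f"{path}: FASTA missing records {missing} (found {sorted(records)})")
    return AssaySequences.from_strings(*(records[r] for r in _ROLES))


def _require(d: dict, key: str, context: str):
    if key not in d:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return d[key]


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw, base_dir=path.parent)


def config_from_dict(raw: dict, base_dir: Path = Path(".")) -> RunConfig:
    _check_keys(
        raw,
        {"sequences", "concentrations", "protocol", "enzyme", "thermo", "solver", "seed"},
        "config",
    )
    seq_block = _require(raw, "sequences", "config")
    if isinstance(seq_block, str):
        seqs = read_fasta_sequences(base_dir / seq_block)
    else:
        _check_keys(seq_block, set(_ROLES), "config.sequences")
        seqs = AssaySequences.from_strings(*(
            _require(seq_block, r, "config.sequences") for r in _ROLES
        ))

    conc = _require(raw, "concentrations", "config")
    _check_keys(
        conc, {"template", "strandedness", "P_for", "P_rev", "Q"}, "config.concentrations"
    )
    template, template_unit = parse_concentration(
        _require(conc, "template", "config.concentrations"), "config.concentrations.template"
    )
    oligo_molar = {}
    for role in ("P_for", "P_rev", "Q"):
        mag, unit = parse_concentration(
            _require(conc, role, "config.concentrations"), f"config.concentrations.{role}"
        )
        if unit != "M":
            raise ConfigError(f"config.concentrations.{role}: oligo concentrations must be molar")
        oligo_molar[role] = mag
    initial = InitialConditions(
        template=template,
        template_unit=template_unit,  # type: ignore[arg-type]
        strandedness=conc.get("strandedness", "double"),
        p_for=oligo_molar["P_for"],
        p_rev=oligo_molar["P_rev"],
        q=oligo_molar["Q"],
    )

    prot_block = raw.get("protocol", {})
    _check_keys(
        prot_block,
        {
            "n_cycles",
            "time_denaturation",
            "temp_denaturation",
            "time_annealing",
            "temp_annealing",
            "time_extension",
            "temp_extension",
        },
        "config.protocol",
    )
    protocol = ProtocolConfig(**prot_block)

    enz_block = raw.get("enzyme", {})
    _check_keys(enz_block, {"k_deg", "beta"}, "config.enzyme")
    enzyme = EnzymeDecayModel(**enz_block)

    th_block = raw.get("thermo", {})
    _check_keys(
        th_block,
        {"k_oligos_on", "kr_on", "dG_PD", "nn_table", "salt_molar"},
        "config.thermo",
    )
    nn_table = th_block.get("nn_table", DEFAULT_NN_TABLE)
    if nn_table not in NN_TABLES:
        raise ConfigError(f"config.thermo.nn_table: unknown table {nn_table!r}")

    sol_block = raw.get("solver", {})
    _check_keys(sol_block, {"method", "rtol", "atol", "n_out"}, "config.solver")
    solver = SolverOptions(**sol_block)

    return RunConfig(
        sequences=seqs,
        initial=initial,
        protocol=protocol,
        enzyme=enzyme,
        k_oligos_on=th_block.get("k_oligos_on", 1e6),
        kr_on=th_block.get("kr_on", 1e7),
        dG_PD_override=th_block.get("dG_PD"),
        nn_table=nn_table,
        salt_molar=th_block.get("salt_molar"),
        solver=solver,
        seed=raw.get("seed", 0),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """Lossless inverse of :func:`config_from_dict` for inline sequences."""
    s = cfg.sequences
    out = {
        "sequences": {r: getattr(s, r.lower() if r != "Q" else "q").bases for r in _ROLES},
        "concentrations": {
            "template": f"{cfg.initial.template:g} "
            + ("copies_per_uL" if cfg.initial.template_unit == "copies_per_uL" else "M"),
            "strandedness": cfg.initial.strandedness,
            "P_for": cfg.initial.p_for,
            "P_rev": cfg.initial.p_rev,
            "Q": cfg.initial.q,
        },
        "protocol": {
            "n_cycles": cfg.protocol.n_cycles,
            "time_denaturation": cfg.protocol.time_denaturation,
            "temp_denaturation": cfg.protocol.temp_denaturation,
            "time_annealing": cfg.protocol.time_annealing,
            "temp_annealing": cfg.protocol.temp_annealing,
            "time_extension": cfg.protocol.time_extension,
            "temp_extension": cfg.protocol.temp_extension,
        },
        "enzyme": {"k_deg": cfg.enzyme.k_deg, "beta": cfg.enzyme.beta},
        "thermo": {"k_oligos_on": cfg.k_oligos_on, "kr_on": cfg.kr_on, "nn_table": cfg.nn_table},
        "solver": {
            "method": cfg.solver.method,
            "rtol": cfg.solver.rtol,
            "atol": cfg.solver.atol,
            "n_out": cfg.solver.n_out,
        },
        "seed": cfg.seed,
    }
    if cfg.dG_PD_override is not None:
        out["thermo"]["dG_PD"] = cfg.dG_PD_override
    if cfg.salt_molar is not None:
        out["thermo"]["salt_molar"] = cfg.salt_molar
    return out


# ---------------------------------------------------------------------------
# curve CSV dialect
# ---------------------------------------------------------------------------


def curves_to_csv(curves: list[AmplificationCurve], metadata: Optional[dict] = None) -> str:
    """Wide CSV: '#'-prefixed JSON metadata lines, a ``cycle`` column, then
    one fluorescence column per curve (named by label)."""
    buf = io.StringIO()
    if metadata:
        buf.write("# " + json.dumps(metadata) + "\n")
    df = pd.DataFrame({"cycle": curves[0].cycles})
    for c in curves:
        df[c.label or "F"] = c.F
    df.to_csv(buf, index=False)
    return buf.getvalue()


def curves_from_csv(
    text: str, concentrations: Optional[dict[str, float]] = None
) -> list[AmplificationCurve]:
    """Read the wide curve dialect; ``concentrations`` maps column label to
    input copies/uL (0 for NTC), overriding any sidecar metadata."""
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(lines)), float_precision="round_trip")
    if "cycle" not in df.columns:
        raise ConfigError("curve CSV: missing 'cycle' column")
    cycles = df["cycle"].to_numpy()
    curves = []
    for col in df.columns:
        if col == "cycle":
            continue
        conc = (concentrations or {}).get(col)
        curves.append(
            AmplificationCurve(cycles, df[col].to_numpy(), label=col, concentration=conc)
        )
    return curves
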