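"""Reading and writing networks.

cobra-json (the standard COBRA JSON schema with ``metabolites`` /
``reactions`` / ``genes`` arrays) is the canonical format and round-trips
bit-identically. SBML Level 3 + FBC is supported read-only through cobrapy
and covers the core fields only (species, reactions, bounds, objective).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Union

from .model import Metabolite, MetabolicReaction, Network, ValidationError

__all__ = ["read_network", "write_network", "parse_formula", "format_formula"]

_FORMULA_RE = re.compile(r"([A-Z][a-z]*)(\d*\.\d+|\d*)")


class FormatError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a Hill-style formula string (pseudo-elements allowed)."""
    if not formula:
        return {}
    counts: Dict[str, float] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = match.end()
        n = float(match.group(2)) if match.group(2) else 1.0
        counts[match.group(1)] = counts.get(match.group(1), 0.0) + n
    if pos != len(formula):
        raise FormatError(f"cannot parse formula {formula!r} at offset {pos}")
    return counts


def format_formula(formula: Dict[str, float]) -> str:
    parts = []
    for elem in sorted(formula):
        n = formula[elem]
        if n == 0:
            continue
        if n == 1:
            parts.append(elem)
        elif float(n).is_integer():
            parts.append(f"{elem}{int(n)}")
        else:
            parts.append(f"{elem}{n:g}")
    return "".join(parts)


def _network_to_dict(net: Network) -> dict:
    mets = []
    for m in net.metabolites:
        mets.append(
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "charge": m.charge,
                "formula": format_formula(m.formula),
            }
        )
    rxns = []
    for r in net.reactions:
        entry = {
            "id": r.id,
            "name": r.name,
            "metabolites": {k: float(r.stoichiometry[k]) for k in sorted(r.stoichiometry)},
            "lower_bound": float(r.lower_bound),
            "upper_bound": float(r.upper_bound),
            "gene_reaction_rule": "",
            "subsystem": r.subsystem,
            "objective_coefficient": 1.0 if r.id == net.objective_id else 0.0,
            "notes": {
                "keff": float(r.keff),
                "spontaneous": r.spontaneous,
            },
        }
        if r.enzyme_complex_id is not None:
            entry["notes"]["enzyme_complex_id"] = r.enzyme_complex_id
        rxns.append(entry)
    return {
        "id": net.id,
        "compartments": {"c": "cytosol", "e": "extracellular space"},
        "metabolites": mets,
        "reactions": rxns,
        "genes": [],
        "version": "1",
    }


def _network_from_dict(data: dict) -> Network:
    net = Network(id=data.get("id", "model"))
    for m in data.get("metabolites", []):
        net.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=parse_formula(m.get("formula") or ""),
                charge=int(m.get("charge", 0) or 0),
                compartment=m.get("compartment")
                or (m["id"].rsplit("_", 1)[-1] if "_" in m["id"] else "c"),
            )
        )
    objective_id = ""
    for r in data.get("reactions", []):
        notes = r.get("notes") or {}
        rxn = MetabolicReaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            enzyme_complex_id=notes.get("enzyme_complex_id"),
            keff=float(notes.get("keff", 25.0)),
            spontaneous=bool(notes.get("spontaneous", False)),
            subsystem=r.get("subsystem", ""),
        )
        net.add_reaction(rxn)
        if float(r.get("objective_coefficient", 0.0) or 0.0) != 0.0:
            objective_id = r["id"]
    net.objective_id = objective_id
    net.validate()
    return net


def read_network(path: Union[str, Path], format: str = "cobra-json") -> Network:
    """Read a network from ``cobra-json`` or the ``sbml-subset`` dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "cobra-json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"{path}: invalid JSON at line {exc.lineno} column {exc.colno}"
            ) from exc
        if not isinstance(data, dict) or "reactions" not in data:
            raise FormatError(f"{path}: not a cobra-json model (no 'reactions' array)")
        return _network_from_dict(data)
    if format == "sbml-subset":
        return _read_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def _read_sbml(path: Path) -> Network:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML reading requires the optional 'cobra' package") from exc
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
    net = Network(id=cmodel.id or "model")
    for m in cmodel.metabolites:
        net.add_metabolite(
            Metabolite(
                id=m.id,
                name=m.name or "",
                formula=parse_formula(m.formula or ""),
                charge=int(m.charge or 0),
                compartment=m.compartment or m.id.rsplit("_", 1)[-1],
            )
        )
    objective_id = ""
    for r in cmodel.reactions:
        net.add_reaction(
            MetabolicReaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=r.subsystem or "",
            )
        )
        if r.objective_coefficient:
            objective_id = r.id
    net.objective_id = objective_id
    net.validate()
    return net


def write_network(net: Network, path: Union[str, Path], format: str = "cobra-json") -> None:
    """Write ``net`` as cobra-json. Two writes of equal networks are byte-identical."""
    if format != "cobra-json":
        raise ValueError("only cobra-json writing is supported")
    if not net.reactions:
        raise ValidationError("refusing to write a network with no reactions")
    net.validate()
    payload = json.dumps(_network_to_dict(net), indent=1, sort_keys=True)
    Path(path).write_text(payload + "\n")
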