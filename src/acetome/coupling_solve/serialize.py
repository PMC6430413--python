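"""MEProblem JSON serialization.

Schema (version 1): every coefficient, bound, and right-hand side is an
affine pair ``[a, b]`` meaning ``a + b * mu``::

    {
      "schema_version": 1,
      "params": {...},                       # CouplingParams snapshot
      "variables": [{"id", "kind", "lo": [a,b], "hi": [a,b]}, ...],
      "rows": [{"id", "sense", "rhs": [a,b],
                "coeffs": {"var": [a,b], ...}, "provenance"}, ...],
      "metadata": {"rxn_vars", "expr_vars", "conc_vars", "gene_tx",
                   "protein_content", "exchange_ids", "complex_ids"}
    }

A problem loaded from JSON solves identically but carries no network or
annex objects.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

from .assemble import Affine, MEProblem, Row, Variable
from .params import CouplingParams

__all__ = ["me_problem_to_json", "me_problem_from_json"]

SCHEMA_VERSION = 1


def me_problem_to_json(prob: MEProblem, path: Union[str, Path, None] = None) -> str:
    var_ids = [v.id for v in prob.variables]
    payload = {
        "schema_version": SCHEMA_VERSION,
        "params": asdict(prob.params),
        "variables": [
            {"id": v.id, "kind": v.kind, "lo": [v.lo.a, v.lo.b], "hi": [v.hi.a, v.hi.b]}
            for v in prob.variables
        ],
        "rows": [
            {
                "id": r.id,
                "sense": r.sense,
                "rhs": [r.rhs.a, r.rhs.b],
                "coeffs": {k: [aff.a, aff.b] for k, aff in sorted(r.coeffs.items())},
                "provenance": r.provenance,
            }
            for r in prob.rows
        ],
        "metadata": {
            "rxn_vars": {
                rid: [var_ids[f], None if b is None else var_ids[b]]
                for rid, (f, b) in sorted(prob.rxn_vars.items())
            },
            "expr_vars": {eid: var_ids[j] for eid, j in sorted(prob.expr_vars.items())},
            "conc_vars": {sid: var_ids[j] for sid, j in sorted(prob.conc_vars.items())},
            "gene_tx": prob.gene_tx,
            "protein_content": prob.protein_content,
            "exchange_ids": prob.exchange_ids,
            "complex_ids": prob.complex_ids,
        },
    }
    text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def me_problem_from_json(source: Union[str, Path]) -> MEProblem:
    if isinstance(source, Path) or not source.lstrip().startswith("{"):
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {data.get('schema_version')!r}")
    variables = [
        Variable(
            id=v["id"],
            lo=Affine(*v["lo"]),
            hi=Affine(*v["hi"]),
            kind=v["kind"],
        )
        for v in data["variables"]
    ]
    rows = [
        Row(
            id=r["id"],
            coeffs={k: Affine(*ab) for k, ab in r["coeffs"].items()},
            sense=r["sense"],
            rhs=Affine(*r["rhs"]),
            provenance=r.get("provenance", ""),
        )
        for r in data["rows"]
    ]
    vidx = {v.id: i for i, v in enumerate(variables)}
    meta = data["metadata"]
    return MEProblem(
        variables=variables,
        rows=rows,
        net=None,
        annex=None,
        params=CouplingParams(**data["params"]),
        rxn_vars={
            rid: (vidx[f], None if b is None else vidx[b])
            for rid, (f, b) in meta["rxn_vars"].items()
        },
        expr_vars={eid: vidx[v] for eid, v in meta["expr_vars"].items()},
        conc_vars={sid: vidx[v] for sid, v in meta["conc_vars"].items()},
        gene_tx=meta["gene_tx"],
        protein_content=meta["protein_content"],
        exchange_ids=meta["exchange_ids"],
        complex_ids=meta["complex_ids"],
    )
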