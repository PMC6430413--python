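"""Plain flux balance analysis on a :class:`~acetome.netcore.model.Network`.

The LP maximizes the objective reaction's flux subject to steady state
(S v = 0) and bounds, solved with HiGHS through :func:`scipy.optimize.linprog`.
A network whose exchanges are all closed is reported ``optimal`` with
objective 0 (zero growth is feasible on no substrate), not infeasible.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import FluxSolution, Network, ValidationError

__all__ = ["solve_fba", "build_stoichiometric_matrix"]

_FEAS_TOL = 1e-9


def build_stoichiometric_matrix(net: Network):
    """Return (S, met_ids, rxn_ids) with S sparse of shape (m, n)."""
    met_ids = [m.id for m in net.metabolites]
    rxn_ids = [r.id for r in net.reactions]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    S = lil_matrix((len(met_ids), len(rxn_ids)))
    for j, rxn in enumerate(net.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coef
    return S.tocsr(), met_ids, rxn_ids


def solve_fba(
    net: Network,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    objective_id: Optional[str] = None,
    maximize: bool = True,
) -> FluxSolution:
    """Maximize (or minimize) the objective reaction flux at steady state.

    ``extra_bounds`` overrides per-reaction bounds for this solve only; the
    overrides must lie within the declared bounds of the reaction.
    """
    net.validate()
    obj_id = objective_id or net.objective_id
    if not obj_id or not net.has_reaction(obj_id):
        raise ValidationError(f"objective reaction {obj_id!r} not found")

    S, _met_ids, rxn_ids = build_stoichiometric_matrix(net)
    n = len(rxn_ids)
    lo = np.array([r.lower_bound for r in net.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in net.reactions], dtype=float)
    if extra_bounds:
        pos = {rid: j for j, rid in enumerate(rxn_ids)}
        for rid, (new_lo, new_hi) in extra_bounds.items():
            if rid not in pos:
                raise ValidationError(f"extra bound on unknown reaction {rid!r}")
            j = pos[rid]
            if new_lo < lo[j] - _FEAS_TOL or new_hi > hi[j] + _FEAS_TOL:
                raise ValidationError(
                    f"extra bounds for {rid!r} exceed declared bounds"
                )
            lo[j], hi[j] = new_lo, new_hi

    c = np.zeros(n)
    c[rxn_ids.index(obj_id)] = -1.0 if maximize else 1.0

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lo, hi)),
        method="highs",
        options={"primal_feasibility_tolerance": _FEAS_TOL,
                 "dual_feasibility_tolerance": _FEAS_TOL},
    )
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if not res.success:  # pragma: no cover - solver failure surfaces loudly
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(rxn_ids, (float(v) for v in res.x)))
    sign = -1.0 if maximize else 1.0
    return FluxSolution(
        status="optimal", objective_value=sign * float(res.fun), fluxes=fluxes
    )
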