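"""Elemental and charge balancing of reactions.

Charge is tracked as the pseudo-element ``"charge"`` in the residual report.
Exchange, demand, sink, and biomass reactions are exempt: they intentionally
create or destroy matter at the system boundary.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import Network

__all__ = ["check_balances", "reaction_residuals"]

_TOL = 1e-9


def reaction_residuals(net: Network, rxn_id: str) -> Dict[str, float]:
    """Net element/charge production of one reaction (positive = created)."""
    rxn = net.reaction(rxn_id)
    residuals: Dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = net.metabolite(met_id)
        for elem, n in met.formula.items():
            residuals[elem] = residuals.get(elem, 0.0) + coef * n
        residuals["charge"] = residuals.get("charge", 0.0) + coef * met.charge
    return residuals


def check_balances(net: Network) -> List[Tuple[str, str, float]]:
    """Report every element/charge imbalance in non-boundary reactions.

    Returns a list of ``(reaction_id, element_or_"charge", residual)``
    triples; an empty list means every internal reaction conserves each
    element and charge exactly.  Metabolites without a formula make their
    reactions unbalanceable, which is reported explicitly with the entry
    ``(rxn_id, "unbalanceable:<met_id>", nan)`` rather than silently passed.
    """
    violations: List[Tuple[str, str, float]] = []
    for rxn in net.reactions:
        if rxn.balance_exempt:
            continue
        missing = [
            met_id
            for met_id in rxn.stoichiometry
            if not net.metabolite(met_id).has_formula
        ]
        if missing:
            for met_id in sorted(missing):
                violations.append((rxn.id, f"unbalanceable:{met_id}", float("nan")))
            continue
        for elem, resid in sorted(reaction_residuals(net, rxn.id).items()):
            if abs(resid) > _TOL:
                violations.append((rxn.id, elem, resid))
    return violations
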