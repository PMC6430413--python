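"""Growth maximization by bisection over LP feasibility.

The feasibility predicate ``feasible(prob, mu)`` is monotone (down-closed)
in mu for well-posed ME problems; ``maximize_growth`` bisects it to
``mu_tol`` and asserts monotonicity on every observation it makes. The LP
at each probe uses a zero objective; only the final solve at mu* minimizes
total expression flux to pick a parsimonious optimum (a convention — the
solution is not claimed unique).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import linprog

from .assemble import MEProblem
from .params import CouplingParams

__all__ = [
    "MESolution",
    "feasible",
    "maximize_growth",
    "proteome_fractions",
    "protein_activity",
    "MESolveError",
]

_LP_TOL = 1e-9

log = logging.getLogger(__name__)


class MESolveError(RuntimeError):
    pass


@dataclass
class MESolution:
    status: str  # optimal | no_growth
    mu_star: float = 0.0
    fluxes: Dict[str, float] = field(default_factory=dict)
    expression_fluxes: Dict[str, float] = field(default_factory=dict)
    complex_usage: Dict[str, float] = field(default_factory=dict)
    concentrations: Dict[str, float] = field(default_factory=dict)
    proteome_fractions: Dict[str, float] = field(default_factory=dict)
    secretion: Dict[str, float] = field(default_factory=dict)
    iterations: int = 0

    def secretion_of(self, exchange_id: str) -> float:
        return self.secretion.get(exchange_id, 0.0)


def _solve_lp(prob: MEProblem, mu: float, objective: Optional[np.ndarray] = None):
    Aeq, beq, Aub, bub, lo, hi = prob.realize(mu)
    c = objective if objective is not None else np.zeros(prob.n_vars)
    kwargs = dict(
        A_eq=Aeq,
        b_eq=beq,
        A_ub=Aub if Aub.shape[0] else None,
        b_ub=bub if Aub.shape[0] else None,
        bounds=list(zip(lo, hi)),
    )
    res = linprog(
        c,
        method="highs",
        options={
            "primal_feasibility_tolerance": _LP_TOL,
            "dual_feasibility_tolerance": _LP_TOL,
        },
        **kwargs,
    )
    if res.status in (1, 4):
        # presolve can fail to conclude near the feasibility boundary at
        # tight tolerances; retry without it, then with the interior point
        for method, opts in (
            (
                "highs",
                {
                    "presolve": False,
                    "primal_feasibility_tolerance": _LP_TOL,
                    "dual_feasibility_tolerance": _LP_TOL,
                },
            ),
            ("highs", {"presolve": False}),
            ("highs-ipm", {"presolve": False}),
            ("highs-ds", {}),
        ):
            res = linprog(c, method=method, options=opts, **kwargs)
            if res.status not in (1, 4):
                break
    return res


def feasible(prob: MEProblem, mu: float) -> bool:
    """True iff the ME problem instantiated at mu admits a feasible point."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    res = _solve_lp(prob, mu)
    log.debug("feasibility LP at mu=%.9f: status %s", mu, res.status)
    if res.status in (0,):
        return True
    if res.status == 2:
        return False
    if res.status == 3:  # unbounded feasibility problem is still feasible
        return True
    raise MESolveError(f"LP solver failure at mu={mu}: {res.message}")


def _extract_solution(prob: MEProblem, mu: float, x: np.ndarray, iters: int) -> MESolution:
    fluxes: Dict[str, float] = {}
    for rid, (f, b) in prob.rxn_vars.items():
        v = float(x[f])
        if b is not None:
            v -= float(x[b])
        fluxes[rid] = v
    expr_fluxes = {eid: float(x[j]) for eid, j in prob.expr_vars.items()}
    conc = {sid: float(x[j]) for sid, j in prob.conc_vars.items()}
    gene_expr = {
        gid: sum(expr_fluxes.get(tx, 0.0) for tx in tx_ids)
        for gid, tx_ids in prob.gene_tx.items()
    }
    complex_usage = {cid: conc.get(cid, 0.0) for cid in prob.complex_ids}
    secretion = {rid: fluxes[rid] for rid in prob.exchange_ids}
    sol = MESolution(
        status="optimal",
        mu_star=mu,
        fluxes=fluxes,
        expression_fluxes=gene_expr,
        complex_usage=complex_usage,
        concentrations=conc,
        secretion=secretion,
        iterations=iters,
    )
    sol.proteome_fractions = proteome_fractions(sol, prob)
    return sol


def maximize_growth(prob: MEProblem, params: Optional[CouplingParams] = None) -> MESolution:
    """Bisect feasibility over [mu_min, mu_max] and solve at the optimum."""
    params = params or prob.params
    lo, hi = params.mu_min, params.mu_max
    if not feasible(prob, lo):
        return MESolution(status="no_growth", mu_star=0.0)
    if feasible(prob, hi):
        raise MESolveError(
            f"problem is feasible at mu_max={hi}; raise mu_max to bracket mu*"
        )
    iters = 0
    max_feasible, min_infeasible = lo, hi
    while hi - lo > params.mu_tol and iters < params.max_iter:
        mid = 0.5 * (lo + hi)
        if feasible(prob, mid):
            if mid > min_infeasible:
                raise MESolveError(
                    f"non-monotone feasibility: feasible at {mid} but "
                    f"infeasible at {min_infeasible}"
                )
            lo = mid
            max_feasible = max(max_feasible, mid)
        else:
            if mid < max_feasible:
                raise MESolveError(
                    f"non-monotone feasibility: infeasible at {mid} but "
                    f"feasible at {max_feasible}"
                )
            hi = mid
            min_infeasible = min(min_infeasible, mid)
        iters += 1

    if lo <= params.mu_min + params.mu_tol and params.mu_min == 0.0:
        # the bracket collapsed onto mu = 0: at zero growth macromolecule
        # dilution vanishes and enzyme levels are unconstrained, so fluxes
        # from an LP there are not meaningful — report no growth instead
        return MESolution(status="no_growth", mu_star=0.0, iterations=iters)

    # final parsimonious solve at the last feasible mu: minimize total
    # expression flux (with a small metabolic-flux term to suppress
    # degenerate futile cycles)
    c = np.zeros(prob.n_vars)
    for v, j in ((v, j) for j, v in enumerate(prob.variables)):
        if v.kind in ("flux_f", "flux_b"):
            c[j] = 1e-3
    for j in prob.expr_vars.values():
        c[j] = 1.0
    res = _solve_lp(prob, lo, objective=c)
    if res.status != 0:
        # numerically at the edge; back off progressively inside the bracket
        for k in (1, 2, 4, 8, 16, 64):
            trial = max(params.mu_min, lo - k * params.mu_tol)
            res = _solve_lp(prob, trial, objective=c)
            if res.status == 0:
                lo = trial
                break
        else:
            raise MESolveError(f"final solve failed near mu={lo}: {res.message}")
    return _extract_solution(prob, lo, res.x, iters)


# ----------------------------------------------------------------------
def proteome_fractions(sol: MESolution, prob: MEProblem) -> Dict[str, float]:
    """Mass fraction of each protein over total (free + complexed) protein."""
    mass: Dict[str, float] = {}
    for sid, alloc in prob.protein_content.items():
        c = sol.concentrations.get(sid, 0.0)
        if c <= 0:
            continue
        for protein, pm in alloc.items():
            mass[protein] = mass.get(protein, 0.0) + pm * c
    total = sum(mass.values())
    if total <= 0:
        raise MESolveError("zero total protein mass; fractions undefined")
    return {p: m / total for p, m in mass.items()}


def protein_activity(
    sol_limited: MESolution, sol_reference: MESolution, rxn_id: str
) -> float:
    """Flux of a reaction under limitation relative to the reference run."""
    if rxn_id not in sol_limited.fluxes or rxn_id not in sol_reference.fluxes:
        raise MESolveError(f"reaction {rxn_id!r} absent from one of the solutions")
    if set(sol_limited.fluxes) != set(sol_reference.fluxes):
        raise MESolveError("solutions come from different problems")
    v_lim = abs(sol_limited.fluxes[rxn_id])
    v_ref = abs(sol_reference.fluxes[rxn_id])
    if v_ref <= 1e-9:
        if v_lim <= 1e-9:
            return 0.0
        raise MESolveError(
            f"reference flux of {rxn_id!r} is zero but limited flux is {v_lim}"
        )
    return v_lim / v_ref
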