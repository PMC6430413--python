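"""Substrate-uptake and metal-limitation sweeps over ME solutions."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ..coupling_solve import (
    CouplingParams,
    MESolution,
    MESolveError,
    assemble,
    maximize_growth,
    protein_activity,
)
from ..expression.annex import ExpressionAnnex
from ..netcore.model import Network, ValidationError

__all__ = [
    "SweepResult",
    "uptake_sweep",
    "overflow_onset",
    "secretion_ratio",
    "metal_sweep",
    "ONSET_THRESHOLD",
]

#: secretion below this is regarded as LP noise, not true secretion
ONSET_THRESHOLD = 1e-6


@dataclass
class SweepResult:
    swept_id: str
    grid: List[float]
    solutions: List[Optional[MESolution]]
    #: per grid point and metal-dependent reaction: flux relative to reference
    activities: List[Dict[str, float]] = field(default_factory=list)
    reference: Optional[MESolution] = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("sweep grid must be strictly increasing")
        if len(self.grid) != len(self.solutions):
            raise ValueError("one solution record per grid point required")

    def growth(self) -> List[float]:
        return [s.mu_star if s is not None else float("nan") for s in self.solutions]

    def secretions(self, exchange_id: str) -> List[float]:
        return [
            s.secretion.get(exchange_id, 0.0) if s is not None else float("nan")
            for s in self.solutions
        ]

    def solved_points(self) -> List[Tuple[float, MESolution]]:
        return [
            (g, s)
            for g, s in zip(self.grid, self.solutions)
            if s is not None and s.status in ("optimal", "no_growth")
        ]

    def to_json(self) -> str:
        payload = {
            "swept_id": self.swept_id,
            "grid": self.grid,
            "points": [
                None
                if s is None
                else {
                    "status": s.status,
                    "mu_star": s.mu_star,
                    "secretion": {k: s.secretion[k] for k in sorted(s.secretion)},
                    "expression_fluxes": {
                        k: s.expression_fluxes[k]
                        for k in sorted(s.expression_fluxes)
                    },
                }
                for s in self.solutions
            ],
            "activities": self.activities,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _solve_at_cap(
    net: Network,
    annex: ExpressionAnnex,
    params: CouplingParams,
    exchange_id: str,
    cap: float,
) -> MESolution:
    work = net.copy()
    work.reaction(exchange_id).lower_bound = -abs(cap)
    prob = assemble(work, annex, params)
    return maximize_growth(prob, params)


def uptake_sweep(
    net: Network,
    annex: ExpressionAnnex,
    exchange_id: str,
    grid: Sequence[float],
    params: CouplingParams,
) -> SweepResult:
    """Maximize growth at each uptake cap; failures become recorded gaps."""
    if not net.has_reaction(exchange_id):
        raise ValidationError(f"unknown exchange {exchange_id!r}")
    if any(g < 0 for g in grid):
        raise ValueError("uptake magnitudes must be non-negative")
    solutions: List[Optional[MESolution]] = []
    for cap in grid:
        try:
            solutions.append(_solve_at_cap(net, annex, params, exchange_id, cap))
        except MESolveError as exc:
            warnings.warn(f"sweep point {exchange_id}={cap} failed: {exc}")
            solutions.append(None)
    return SweepResult(swept_id=exchange_id, grid=list(grid), solutions=solutions)


def overflow_onset(
    sweep: SweepResult, product_exchange_id: str
) -> Optional[float]:
    """Smallest grid value at which the product is secreted above threshold.

    Returns None if the product is never secreted. A nonzero secretion
    before the onset or a decrease after it is flagged with a warning,
    never silently dropped.
    """
    secretions = sweep.secretions(product_exchange_id)
    if all(s != s or s <= ONSET_THRESHOLD for s in secretions):  # NaN-safe
        return None
    onset_idx = next(
        i for i, s in enumerate(secretions) if s == s and s > ONSET_THRESHOLD
    )
    for i in range(onset_idx):
        if secretions[i] == secretions[i] and secretions[i] > ONSET_THRESHOLD:
            warnings.warn(
                f"{product_exchange_id}: secretion before onset at grid index {i}"
            )
    post = [s for s in secretions[onset_idx:] if s == s]
    if any(b < a - 1e-6 for a, b in zip(post, post[1:])):
        warnings.warn(f"{product_exchange_id}: secretion not non-decreasing after onset")
    return sweep.grid[onset_idx]


def secretion_ratio(
    sol: MESolution, num_exchange_id: str, den_exchange_id: str
) -> Optional[float]:
    """Ratio of secretion fluxes; None when the denominator is ~zero."""
    den = sol.secretion.get(den_exchange_id, 0.0)
    if den <= 1e-9:
        return None
    return sol.secretion.get(num_exchange_id, 0.0) / den


def _metal_dependent_reactions(net: Network, annex: ExpressionAnnex, metal_ex: str):
    """Reactions catalyzed by complexes whose assembly consumes the metal."""
    met_base = metal_ex[len("EX_"):-2]  # e.g. "ni2"
    dependent_complexes = set()
    for cx in annex.complexes:
        for mod in cx.modifications:
            cof = mod.cofactor_metabolite_id
            if cof.startswith(met_base):
                dependent_complexes.add(cx.id)
            elif mod.delivery == "hyp_nickel" and met_base == "ni2":
                dependent_complexes.add(cx.id)
    return [
        r.id
        for r in net.reactions
        if r.enzyme_complex_id in dependent_complexes
    ]


def metal_sweep(
    net: Network,
    annex: ExpressionAnnex,
    metal_exchange_id: str,
    grid: Sequence[float],
    params: CouplingParams,
) -> SweepResult:
    """Growth and protein activity under capped metal uptake.

    The reference is the uncapped optimum; per grid point the activity of
    each metal-dependent reaction is its flux relative to the reference
    (0 for points without growth).
    """
    if not net.has_reaction(metal_exchange_id):
        raise ValidationError(f"unknown exchange {metal_exchange_id!r}")
    targets = _metal_dependent_reactions(net, annex, metal_exchange_id)
    if not targets:
        warnings.warn(
            f"{metal_exchange_id}: metal is not consumed by any modification; "
            "sweep will be flat"
        )
    prob = assemble(net, annex, params)
    reference = maximize_growth(prob, params)
    solutions: List[Optional[MESolution]] = []
    activities: List[Dict[str, float]] = []
    for cap in grid:
        try:
            sol = _solve_at_cap(net, annex, params, metal_exchange_id, cap)
        except MESolveError as exc:
            warnings.warn(f"metal sweep point {cap} failed: {exc}")
            solutions.append(None)
            activities.append({})
            continue
        solutions.append(sol)
        if sol.status != "optimal":
            activities.append({rid: 0.0 for rid in targets})
        else:
            activities.append(
                {rid: protein_activity(sol, reference, rid) for rid in targets}
            )
    return SweepResult(
        swept_id=metal_exchange_id,
        grid=list(grid),
        solutions=solutions,
        activities=activities,
        reference=reference,
    )
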