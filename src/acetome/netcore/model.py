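"""Core metabolic-network data model.

Conventions follow COBRA: exchange fluxes are negative for uptake and
positive for secretion; uptake limits are set as lower bounds. All flux
units are mmol gDW^-1 h^-1 and turnover numbers (``keff``) are s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = [
    "Metabolite",
    "MetabolicReaction",
    "Network",
    "FluxSolution",
    "ValidationError",
    "ELEMENT_MASS",
    "metabolite_mw",
]

COMPARTMENTS = ("c", "e")

#: atomic masses in g mmol^-1 x 1000 (i.e. g mol^-1); pseudo-elements used
#: for lumped carriers get nominal masses so mw stays well-defined.
ELEMENT_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Ni": 58.693,
    "Fe": 55.845,
    "Mg": 24.305,
    "Co": 58.933,
    "Fd": 6000.0,
    "Trx": 12000.0,
    "Cfe": 88000.0,
}


def metabolite_mw(met: "Metabolite") -> float:
    """Molecular weight in g mmol^-1 computed from the formula."""
    grams_per_mol = sum(
        ELEMENT_MASS.get(elem, 0.0) * n for elem, n in met.formula.items()
    )
    return grams_per_mol / 1000.0

#: reaction-id prefixes exempt from elemental/charge balancing
BALANCE_EXEMPT_PREFIXES = ("EX_", "DM_", "SK_", "BIOMASS")


class ValidationError(ValueError):
    """Raised when a model object violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Dict[str, float] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"

    def validate(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not self.id.endswith("_" + self.compartment):
            raise ValidationError(
                f"metabolite {self.id!r}: id suffix does not match "
                f"compartment {self.compartment!r}"
            )
        for elem, n in self.formula.items():
            if n < 0:
                raise ValidationError(
                    f"metabolite {self.id!r}: negative count for element {elem!r}"
                )

    @property
    def has_formula(self) -> bool:
        return bool(self.formula)


@dataclass
class MetabolicReaction:
    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    enzyme_complex_id: Optional[str] = None
    keff: float = 25.0
    spontaneous: bool = False
    name: str = ""
    subsystem: str = ""

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.enzyme_complex_id is not None and self.keff <= 0:
            raise ValidationError(
                f"reaction {self.id!r}: keff must be positive when an enzyme is set"
            )

    @property
    def is_exchange(self) -> bool:
        return self.id.startswith("EX_")

    @property
    def is_demand(self) -> bool:
        return self.id.startswith(("DM_", "SK_", "BIOMASS"))

    @property
    def balance_exempt(self) -> bool:
        return self.id.startswith(BALANCE_EXEMPT_PREFIXES)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def metabolite_ids(self) -> List[str]:
        return list(self.stoichiometry)


@dataclass
class Network:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[MetabolicReaction] = field(default_factory=list)
    objective_id: str = ""
    id: str = "model"

    def __post_init__(self) -> None:
        self._met_index: Dict[str, Metabolite] = {}
        self._rxn_index: Dict[str, MetabolicReaction] = {}
        self.reindex()

    def reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> MetabolicReaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- mutation helpers ------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = met

    def add_reaction(self, rxn: MetabolicReaction) -> None:
        if rxn.id in self._rxn_index:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        rxn = self._rxn_index.pop(rxn_id)
        self.reactions.remove(rxn)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen = set()
        for met in self.metabolites:
            if met.id in seen:
                raise ValidationError(f"duplicate metabolite id {met.id!r}")
            seen.add(met.id)
            met.validate()
        dangling: List[str] = []
        for rxn in self.reactions:
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    dangling.append(met_id)
            if rxn.is_exchange:
                for met_id in rxn.stoichiometry:
                    if met_id in self._met_index and (
                        self._met_index[met_id].compartment != "e"
                    ):
                        raise ValidationError(
                            f"exchange reaction {rxn.id!r} touches non-extracellular "
                            f"metabolite {met_id!r}"
                        )
        if dangling:
            raise ValidationError(
                "dangling metabolite reference(s): " + ", ".join(sorted(set(dangling)))
            )
        if self.objective_id and self.objective_id not in self._rxn_index:
            raise ValidationError(
                f"objective_id {self.objective_id!r} does not resolve to a reaction"
            )

    def exchange_reactions(self) -> List[MetabolicReaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float = 0.0
    fluxes: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]
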