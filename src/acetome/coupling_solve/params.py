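"""Coupling parameters shared by the E-matrix builders and the ME solver."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional


@dataclass
class CouplingParams:
    #: default enzyme turnover, s^-1
    keff_default: float = 25.0
    #: RNA polymerase elongation rate, nt s^-1
    k_rnap: float = 55.0
    #: ribosome elongation rate, aa s^-1
    k_rib: float = 12.0
    #: translation initiations per mRNA per hour
    k_tl: float = 300.0
    #: mRNA degradation rate, h^-1 (~5 min half-life)
    kdeg_mrna: float = 8.3
    #: unmodeled protein proportion of proteome
    unmodeled_fraction: float = 0.35
    #: growth-associated maintenance, mmol ATP gDW^-1
    gam: float = 45.0
    #: non-growth-associated maintenance, mmol ATP gDW^-1 h^-1
    ngam: float = 0.45
    #: macromolecule biomass composition (mass fractions of the 1 gDW budget)
    protein_biomass_fraction: float = 0.65
    rna_biomass_fraction: float = 0.35
    #: membrane constraint: g membrane protein allowed per g lipid synthesis
    membrane_gamma: float = 2.0
    membrane_constraint: bool = True
    #: growth-proportional demands, mmol gDW^-1 (scaled by mu)
    demand_coefficients: Dict[str, float] = field(
        default_factory=lambda: {
            "DM_dna_c": 0.010,
            "DM_murein_c": 0.100,
            "DM_clpn140_c": 0.040,
        }
    )
    #: bisection window and stopping rule
    mu_min: float = 0.0
    mu_max: float = 2.0
    mu_tol: float = 1e-6
    max_iter: int = 60

    def __post_init__(self) -> None:
        if self.keff_default <= 0:
            raise ValueError("keff_default must be positive")
        if not (0.0 <= self.unmodeled_fraction < 1.0):
            raise ValueError("unmodeled_fraction must lie in [0, 1)")
        if self.mu_min >= self.mu_max:
            raise ValueError("mu_min must be below mu_max")
        if self.mu_tol <= 0:
            raise ValueError("mu_tol must be positive")
        total = self.protein_biomass_fraction + self.rna_biomass_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("protein + RNA biomass fractions must sum to 1")

    def with_overrides(self, **kwargs) -> "CouplingParams":
        return replace(self, **kwargs)

    def expression_free(self) -> "CouplingParams":
        """Limit in which expression costs vanish (the M-model limit)."""
        return self.with_overrides(
            keff_default=1e9,
            k_rnap=1e9,
            k_rib=1e9,
            k_tl=1e9,
            kdeg_mrna=0.0,
            unmodeled_fraction=0.0,
            membrane_constraint=False,
        )
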