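"""Assembly of the growth-coupled ME problem.

Every coefficient and bound is affine in the growth rate mu (``a + b*mu``),
so the bilinear ME formulation becomes an ordinary LP once mu is fixed.

Formulation (per gDW):

* metabolite steady-state rows (network + expression reactions);
* one concentration variable per macromolecule species with balance row
  ``synthesis - consumption - degradation - mu * c = 0``;
* degradation-rate rows ``v_deg = kdeg * c`` for unstable mRNA;
* capacity rows ``sum(usage_per_flux * v) <= c`` turning catalysis into
  enzyme demand — equivalently each catalyzed unit of flux consumes its
  complex at ``mu / (3600 keff)`` once growth dilution is applied;
* a biomass-dilution row fixing total macromolecule mass production to
  ``mu`` x 1 gDW, split into protein and RNA mass-fraction rows;
* the unmodeled-protein ratio row;
* growth-proportional demands (DNA, murein, lipid) via affine bounds and
  ATP maintenance with lower bound ``ngam + gam * mu``;
* optionally a single membrane constraint
  ``mu * (membrane protein mass) <= gamma * (lipid mass synthesis flux)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix, lil_matrix

from ..expression.annex import (
    ExpressionAnnex,
    membrane_species_id,
    protein_species_id,
)
from ..expression.build import (
    ExpressionReaction,
    add_carrier_coupling,
    add_dummy_catalyst,
    add_unmodeled_protein,
    build_expression_reactions,
)
from ..netcore.model import Network, ValidationError
from .params import CouplingParams

__all__ = ["Affine", "MEProblem", "assemble", "instantiate"]

# generous but finite caps keep the LP well-scaled
_EXPR_FLUX_CAP = 1e3
_CONC_CAP = 1e2


@dataclass(frozen=True)
class Affine:
    """A scalar of the form a + b * mu."""

    a: float = 0.0
    b: float = 0.0

    def __call__(self, mu: float) -> float:
        return self.a + self.b * mu

    def __add__(self, other: "Affine") -> "Affine":
        return Affine(self.a + other.a, self.b + other.b)

    def scaled(self, factor: float) -> "Affine":
        return Affine(self.a * factor, self.b * factor)

    @property
    def is_constant(self) -> bool:
        return self.b == 0.0


@dataclass
class Variable:
    id: str
    lo: Affine
    hi: Affine
    kind: str  # flux_f | flux_b | expression | concentration


@dataclass
class Row:
    id: str
    coeffs: Dict[str, Affine]
    sense: str  # "E" (==) or "L" (<=)
    rhs: Affine
    provenance: str = ""


@dataclass
class MEProblem:
    variables: List[Variable]
    rows: List[Row]
    net: Optional[Network]
    annex: Optional[ExpressionAnnex]
    params: CouplingParams
    #: rxn id -> (forward var index, backward var index or None)
    rxn_vars: Dict[str, Tuple[int, Optional[int]]] = field(default_factory=dict)
    #: expression reaction id -> var index
    expr_vars: Dict[str, int] = field(default_factory=dict)
    #: species id -> concentration var index
    conc_vars: Dict[str, int] = field(default_factory=dict)
    #: gene id -> list of transcription reaction ids producing its RNA
    gene_tx: Dict[str, List[str]] = field(default_factory=dict)
    #: species id -> {protein gene species: protein mass g/mmol contributed}
    protein_content: Dict[str, Dict[str, float]] = field(default_factory=dict)
    expression_reactions: List[ExpressionReaction] = field(default_factory=list)
    #: exchange reaction ids (for secretion reporting without the network)
    exchange_ids: List[str] = field(default_factory=list)
    #: complex species ids (for usage reporting without the annex)
    complex_ids: List[str] = field(default_factory=list)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def var_index(self, var_id: str) -> int:
        if "_vidx" not in self._cache:
            self._cache["_vidx"] = {v.id: i for i, v in enumerate(self.variables)}
        return self._cache["_vidx"][var_id]

    # -- matrix realization --------------------------------------------
    def _build_matrices(self) -> None:
        vidx = {v.id: i for i, v in enumerate(self.variables)}
        n = len(self.variables)
        eq_rows = [r for r in self.rows if r.sense == "E"]
        ub_rows = [r for r in self.rows if r.sense == "L"]

        def mats(rows):
            A0 = lil_matrix((len(rows), n))
            A1 = lil_matrix((len(rows), n))
            b0 = np.zeros(len(rows))
            b1 = np.zeros(len(rows))
            for i, row in enumerate(rows):
                for var_id, aff in row.coeffs.items():
                    j = vidx[var_id]
                    if aff.a:
                        A0[i, j] = aff.a
                    if aff.b:
                        A1[i, j] = aff.b
                b0[i], b1[i] = row.rhs.a, row.rhs.b
            return A0.tocsr(), A1.tocsr(), b0, b1

        self._cache["eq"] = mats(eq_rows)
        self._cache["ub"] = mats(ub_rows)
        lo0 = np.array([v.lo.a for v in self.variables])
        lo1 = np.array([v.lo.b for v in self.variables])
        hi0 = np.array([v.hi.a for v in self.variables])
        hi1 = np.array([v.hi.b for v in self.variables])
        self._cache["bounds"] = (lo0, lo1, hi0, hi1)

    def realize(self, mu: float):
        """Numeric (A_eq, b_eq, A_ub, b_ub, lo, hi) at a fixed mu."""
        if mu < 0:
            raise ValueError("mu must be non-negative")
        if "eq" not in self._cache:
            self._build_matrices()
        A0, A1, b0, b1 = self._cache["eq"]
        Aeq = (A0 + mu * A1) if A1.nnz else A0
        beq = b0 + mu * b1
        U0, U1, u0, u1 = self._cache["ub"]
        Aub = (U0 + mu * U1) if U1.nnz else U0
        bub = u0 + mu * u1
        lo0, lo1, hi0, hi1 = self._cache["bounds"]
        return Aeq, beq, Aub, bub, lo0 + mu * lo1, hi0 + mu * hi1


def instantiate(prob: MEProblem, mu: float):
    """Evaluate all affine coefficients at mu; deterministic for fixed mu."""
    return prob.realize(mu)


# ----------------------------------------------------------------------
def _species_masses(annex: ExpressionAnnex) -> Dict[str, Tuple[float, float]]:
    """(protein_mass, rna_mass) per species id."""
    return {s.id: (s.protein_mass, s.rna_mass) for s in annex.species}


def _protein_content_map(annex: ExpressionAnnex) -> Dict[str, Dict[str, float]]:
    """Allocate each species' protein mass to base protein species."""
    content: Dict[str, Dict[str, float]] = {}
    for sp in annex.species:
        if sp.kind == "protein" and sp.protein_mass > 0:
            base = sp.id[:-4] if sp.id.endswith("_mem") else sp.id
            content[sp.id] = {base: sp.protein_mass}
    for cx in annex.complexes:
        alloc: Dict[str, float] = {}
        for sid, n in cx.subunit_stoichiometry.items():
            base = sid[:-4] if sid.endswith("_mem") else sid
            if annex.has_species(base) and annex.get_species(base).protein_mass > 0:
                alloc[base] = (
                    alloc.get(base, 0.0) + n * annex.get_species(base).protein_mass
                )
        content[cx.id] = alloc
    # loaded carrier species (e.g. NifU bearing a cluster, Hyp bearing Ni)
    for sp in annex.species:
        if sp.id in content:
            continue
        if sp.kind == "complex" and sp.protein_mass > 0:
            for suffix in ("_ni", "_4fe4s"):
                if sp.id.endswith(suffix):
                    content[sp.id] = {sp.id[: -len(suffix)]: sp.protein_mass}
    return content


def assemble(
    net: Network, annex: ExpressionAnnex, params: CouplingParams
) -> MEProblem:
    """Integrate the metabolic network with its expression annex."""
    net = net.copy()
    annex.validate()
    add_dummy_catalyst(net, annex)
    for rxn in net.reactions:
        if rxn.enzyme_complex_id and not annex.has_complex(rxn.enzyme_complex_id):
            raise ValidationError(
                f"reaction {rxn.id!r}: enzyme complex "
                f"{rxn.enzyme_complex_id!r} not in annex"
            )
    expr_rxns = build_expression_reactions(net, annex, params)
    carrier = add_carrier_coupling(net, annex, params)
    unmod = add_unmodeled_protein(annex, params.unmodeled_fraction)

    variables: List[Variable] = []
    rxn_vars: Dict[str, Tuple[int, Optional[int]]] = {}
    expr_vars: Dict[str, int] = {}
    conc_vars: Dict[str, int] = {}

    def add_var(var: Variable) -> int:
        variables.append(var)
        return len(variables) - 1

    # -- network flux variables (reversibles split) --------------------
    for rxn in net.reactions:
        lo, hi = Affine(rxn.lower_bound), Affine(rxn.upper_bound)
        if rxn.id == net.objective_id:
            lo = hi = Affine(0.0)  # macromolecule dilution replaces biomass
        if rxn.id == "ATPM":
            lo = Affine(params.ngam, params.gam)
        if rxn.id in params.demand_coefficients:
            lo = hi = Affine(0.0, params.demand_coefficients[rxn.id])
        if lo.a < 0:
            f = add_var(Variable(f"{rxn.id}__f", Affine(0.0), hi, "flux_f"))
            b = add_var(
                Variable(f"{rxn.id}__b", Affine(0.0), Affine(-lo.a), "flux_b")
            )
            rxn_vars[rxn.id] = (f, b)
        else:
            f = add_var(Variable(rxn.id, lo, hi, "flux_f"))
            rxn_vars[rxn.id] = (f, None)

    for er in expr_rxns:
        expr_vars[er.id] = add_var(
            Variable(er.id, Affine(0.0), Affine(_EXPR_FLUX_CAP), "expression")
        )
    for sp in annex.species:
        conc_vars[sp.id] = add_var(
            Variable(f"conc_{sp.id}", Affine(0.0), Affine(_CONC_CAP), "concentration")
        )

    var_id = lambda idx: variables[idx].id  # noqa: E731

    # -- rows -----------------------------------------------------------
    rows: List[Row] = []
    met_coeffs: Dict[str, Dict[str, Affine]] = {m.id: {} for m in net.metabolites}

    def met_add(met: str, vid: str, coef: float) -> None:
        cur = met_coeffs[met].get(vid, Affine())
        met_coeffs[met][vid] = cur + Affine(coef)

    for rxn in net.reactions:
        f, b = rxn_vars[rxn.id]
        for met, coef in rxn.stoichiometry.items():
            met_add(met, var_id(f), coef)
            if b is not None:
                met_add(met, var_id(b), -coef)
    for er in expr_rxns:
        for met, coef in er.met_stoich.items():
            if met not in met_coeffs:
                raise ValidationError(
                    f"expression reaction {er.id!r} references unknown "
                    f"metabolite {met!r}"
                )
            met_add(met, er.id, coef)
    for met, coeffs in met_coeffs.items():
        rows.append(Row(f"bal_{met}", coeffs, "E", Affine(), "steady state"))

    # species balance rows: synthesis - consumption - mu*c = 0
    sp_coeffs: Dict[str, Dict[str, Affine]] = {s.id: {} for s in annex.species}
    for er in expr_rxns:
        for sid, coef in er.species_stoich.items():
            if sid not in sp_coeffs:
                raise ValidationError(
                    f"expression reaction {er.id!r} references unknown "
                    f"species {sid!r}"
                )
            cur = sp_coeffs[sid].get(er.id, Affine())
            sp_coeffs[sid][er.id] = cur + Affine(coef)
    for sp in annex.species:
        coeffs = sp_coeffs[sp.id]
        coeffs[f"conc_{sp.id}"] = Affine(0.0, -1.0)
        rows.append(
            Row(f"spbal_{sp.id}", coeffs, "E", Affine(), "macromolecule balance")
        )

    # degradation rate rows: v_deg = kdeg * c
    for er in expr_rxns:
        if er.kind != "degradation":
            continue
        (sid,) = [s for s, c in er.species_stoich.items() if c < 0]
        kdeg = annex.get_species(sid).kdeg
        rows.append(
            Row(
                f"deg_{sid}",
                {er.id: Affine(1.0), f"conc_{sid}": Affine(-kdeg)},
                "E",
                Affine(),
                "first-order degradation",
            )
        )

    # capacity rows: sum(usage * v) <= c
    usage: Dict[str, Dict[str, Affine]] = {}

    def add_usage(species: str, vid: str, per_flux: float) -> None:
        if not annex.has_species(species):
            raise ValidationError(f"capacity usage on unknown species {species!r}")
        cur = usage.setdefault(species, {}).get(vid, Affine())
        usage[species][vid] = cur + Affine(per_flux)

    for er in expr_rxns:
        for sid, per_flux in er.capacity_usage.items():
            add_usage(sid, er.id, per_flux)
    for rxn in net.reactions:
        f, b = rxn_vars[rxn.id]
        if rxn.enzyme_complex_id:
            per_flux = 1.0 / (3600.0 * rxn.keff)
            add_usage(rxn.enzyme_complex_id, var_id(f), per_flux)
            if b is not None:
                add_usage(rxn.enzyme_complex_id, var_id(b), per_flux)
        for sid, signed in carrier.get(rxn.id, {}).items():
            # usage applies to whichever direction produces the reduced form
            if signed > 0:
                add_usage(sid, var_id(f), signed)
            elif b is not None:
                add_usage(sid, var_id(b), -signed)
    for sid, coeffs in usage.items():
        coeffs = dict(coeffs)
        coeffs[f"conc_{sid}"] = Affine(-1.0)
        rows.append(Row(f"cap_{sid}", coeffs, "L", Affine(), "catalytic capacity"))

    # biomass dilution + composition rows
    masses = _species_masses(annex)
    total = {}
    prot = {}
    rna = {}
    for sp in annex.species:
        pm, rm = masses[sp.id]
        vid = f"conc_{sp.id}"
        if pm + rm:
            total[vid] = Affine(0.0, pm + rm)
        if pm:
            prot[vid] = Affine(0.0, pm)
        if rm:
            rna[vid] = Affine(0.0, rm)
    rows.append(Row("biomass_dilution", total, "E", Affine(0.0, 1.0), "mu x 1 gDW"))
    rows.append(
        Row(
            "protein_mass",
            prot,
            "E",
            Affine(0.0, params.protein_biomass_fraction),
            "protein share of macromolecule mass",
        )
    )
    rows.append(
        Row(
            "rna_mass",
            rna,
            "E",
            Affine(0.0, params.rna_biomass_fraction),
            "RNA share of macromolecule mass",
        )
    )

    # unmodeled-protein ratio row over total (free + complexed) protein mass
    content = _protein_content_map(annex)
    unmod_sid = unmod["unmodeled_species"]
    ratio = unmod["ratio"]
    ratio_coeffs: Dict[str, Affine] = {}
    for sid, alloc in content.items():
        vid = f"conc_{sid}"
        unmod_share = alloc.get(unmod_sid, 0.0)
        modeled_share = sum(m for p, m in alloc.items() if p != unmod_sid)
        coef = unmod_share - ratio * modeled_share
        if coef:
            cur = ratio_coeffs.get(vid, Affine())
            ratio_coeffs[vid] = cur + Affine(coef)
    rows.append(
        Row("unmodeled_ratio", ratio_coeffs, "E", Affine(), "unmodeled = f/(1-f) modeled")
    )

    # membrane constraint: mu * membrane protein mass <= gamma * lipid mass flux
    if params.membrane_constraint:
        from ..netcore.model import ELEMENT_MASS, metabolite_mw

        mem_coeffs: Dict[str, Affine] = {}
        for sp in annex.species:
            is_mem = sp.id.endswith("_mem") or (
                annex.has_complex(sp.id) and annex.complex(sp.id).membrane
            )
            if is_mem and sp.protein_mass > 0:
                mem_coeffs[f"conc_{sp.id}"] = Affine(0.0, sp.protein_mass)
        lipid_flux = None
        for rxn in net.reactions:
            produced_lipids = [
                (met, coef)
                for met, coef in rxn.stoichiometry.items()
                if coef > 0 and met.startswith("pg")
            ]
            if produced_lipids:
                met, coef = produced_lipids[0]
                lipid_flux = (rxn.id, coef * metabolite_mw(net.metabolite(met)))
                break
        if mem_coeffs and lipid_flux is not None:
            rxn_id, mass_per_flux = lipid_flux
            f, b = rxn_vars[rxn_id]
            cur = mem_coeffs.get(var_id(f), Affine())
            mem_coeffs[var_id(f)] = cur + Affine(-params.membrane_gamma * mass_per_flux)
            rows.append(
                Row("membrane", mem_coeffs, "L", Affine(), "single bilayer membrane")
            )

    gene_tx: Dict[str, List[str]] = {}
    for tu in annex.transcription_units:
        for gid in tu.gene_ids:
            gene_tx.setdefault(gid, []).append(f"TX_{tu.id}")

    prob = MEProblem(
        variables=variables,
        rows=rows,
        net=net,
        annex=annex,
        params=params,
        rxn_vars=rxn_vars,
        expr_vars=expr_vars,
        conc_vars=conc_vars,
        gene_tx=gene_tx,
        protein_content=content,
        expression_reactions=expr_rxns,
        exchange_ids=[r.id for r in net.reactions if r.is_exchange],
        complex_ids=[cx.id for cx in annex.complexes],
    )
    # invariant: every variable appears in at least one row
    seen = set()
    for row in prob.rows:
        seen.update(row.coeffs)
    missing = [v.id for v in variables if v.id not in seen]
    if missing:
        raise ValidationError(f"variables not constrained by any row: {missing[:5]}")
    return prob
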