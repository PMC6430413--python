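"""Elemental validation of emitted E-matrix reactions.

Macromolecule species get pseudo-formulas derived from their monomer
composition minus one water per bond, so polymerization, degradation,
translocation, loading, and assembly reactions close exactly on elements
and charge.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from ..netcore.model import Network
from .annex import ExpressionAnnex, membrane_species_id, protein_species_id, rna_species_id
from .build import ExpressionReaction, NMP_MET

__all__ = ["species_pseudo_formulas", "check_expression_balances"]

_TOL = 1e-9


def _combine(target: Dict[str, float], source: Dict[str, float], factor: float) -> None:
    for elem, n in source.items():
        target[elem] = target.get(elem, 0.0) + factor * n


def species_pseudo_formulas(
    net: Network, annex: ExpressionAnnex
) -> Dict[str, Tuple[Dict[str, float], float]]:
    """(formula, charge) per macromolecule species id."""
    water = net.metabolite("h2o_c")
    out: Dict[str, Tuple[Dict[str, float], float]] = {}

    for gene in annex.genes:
        formula: Dict[str, float] = {}
        charge = 0.0
        n_res = 0
        for nt, count in gene.nt_composition.items():
            nmp = net.metabolite(NMP_MET[nt])
            _combine(formula, nmp.formula, count)
            charge += nmp.charge * count
            n_res += count
        _combine(formula, water.formula, -(n_res - 1))
        out[rna_species_id(gene.id)] = (formula, charge)
        if gene.rna_type == "mRNA":
            pform: Dict[str, float] = {}
            pcharge = 0.0
            for aa, count in gene.protein_aa_composition.items():
                met = net.metabolite(f"{aa}_c")
                _combine(pform, met.formula, count)
                pcharge += met.charge * count
            _combine(pform, water.formula, -(gene.protein_length_aa - 1))
            pid = protein_species_id(gene.id)
            out[pid] = (pform, pcharge)

    for pid in annex.translocated_protein_ids:
        if pid in out:
            out[membrane_species_id(pid)] = out[pid]

    mach = annex.machinery
    for cx in annex.complexes:
        formula = {}
        charge = 0.0
        for sid, count in cx.subunit_stoichiometry.items():
            base = sid[:-4] if sid.endswith("_mem") else sid
            sub_form, sub_charge = out[base]
            _combine(formula, sub_form, count)
            charge += sub_charge * count
        for mod in cx.modifications:
            if mod.delivery == "isc_suf_fes":
                _combine(formula, {"Fe": 4, "S": 4}, mod.count)
            else:
                cof = net.metabolite(mod.cofactor_metabolite_id)
                _combine(formula, cof.formula, mod.count)
                charge += cof.charge * mod.count
        out[cx.id] = (formula, charge)

    # loaded carrier species
    if mach.ni_carrier_protein_id and mach.ni_carrier_protein_id in out:
        base_form, base_charge = out[mach.ni_carrier_protein_id]
        loaded = dict(base_form)
        _combine(loaded, {"Ni": 1}, 1)
        out[f"{mach.ni_carrier_protein_id}_ni"] = (loaded, base_charge + 2)
    if mach.fes_carrier_protein_id and mach.fes_carrier_protein_id in out:
        base_form, base_charge = out[mach.fes_carrier_protein_id]
        loaded = dict(base_form)
        _combine(loaded, {"Fe": 4, "S": 4}, 1)
        out[f"{mach.fes_carrier_protein_id}_4fe4s"] = (loaded, base_charge)
    return out


def check_expression_balances(
    net: Network,
    annex: ExpressionAnnex,
    reactions: List[ExpressionReaction],
) -> List[Tuple[str, str, float]]:
    """Element/charge residuals of E-matrix reactions; empty when exact."""
    formulas = species_pseudo_formulas(net, annex)
    violations: List[Tuple[str, str, float]] = []
    for rxn in reactions:
        residual: Dict[str, float] = {}
        charge = 0.0
        unbalanceable = False
        for met_id, coef in rxn.met_stoich.items():
            met = net.metabolite(met_id)
            if not met.has_formula:
                violations.append((rxn.id, f"unbalanceable:{met_id}", float("nan")))
                unbalanceable = True
                continue
            _combine(residual, met.formula, coef)
            charge += met.charge * coef
        for sid, coef in rxn.species_stoich.items():
            if sid not in formulas:
                violations.append((rxn.id, f"unbalanceable:{sid}", float("nan")))
                unbalanceable = True
                continue
            form, sp_charge = formulas[sid]
            _combine(residual, form, coef)
            charge += sp_charge * coef
        if unbalanceable:
            continue
        for elem in sorted(residual):
            if abs(residual[elem]) > _TOL:
                violations.append((rxn.id, elem, residual[elem]))
        if abs(charge) > _TOL:
            violations.append((rxn.id, "charge", charge))
    return violations
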