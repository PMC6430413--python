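"""E-matrix reaction builders.

Each builder emits :class:`ExpressionReaction` objects: ordinary reactions
over metabolites and macromolecule species, plus *capacity usages* — the
per-unit-flux machine concentration requirements that the ME assembler
turns into growth-coupled constraints (a machine used at ``u`` per unit
flux is synthesized at ``mu * u`` per unit flux at optimality).

Polymerization bookkeeping keeps every emitted reaction elementally exact:
an RNA chain's pseudo-formula is the sum of its NMP residues minus one
water per bond, so ``n NTP + H2O -> chain + n PPi + n H``; a protein's is
the sum of its residues minus water per peptide bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Mapping, Optional

if TYPE_CHECKING:  # avoids a circular import; only needed for annotations
    from ..coupling_solve.params import CouplingParams
from ..netcore.model import Network
from .annex import (
    AnnexError,
    ComplexSpec,
    ExpressionAnnex,
    GeneSpec,
    MacromoleculeSpecies,
    ModificationSpec,
    TranscriptionUnitSpec,
    COFACTOR_MW,
    membrane_species_id,
    protein_species_id,
    rna_species_id,
)

__all__ = [
    "ExpressionReaction",
    "build_transcription",
    "build_translation",
    "build_complex_assembly",
    "build_translocation",
    "add_unmodeled_protein",
    "add_dummy_catalyst",
    "add_carrier_coupling",
    "build_expression_reactions",
]

NTP_MET = {"A": "atp_c", "C": "ctp_c", "G": "gtp_c", "U": "utp_c"}
NMP_MET = {"A": "amp_c", "C": "cmp_c", "G": "gmp_c", "U": "ump_c"}

#: phosphate-bond equivalents hydrolyzed per amino acid translated
#: (2 for tRNA charging + 2 GTP for elongation, GTP pooled with ATP)
ATP_PER_AA = 4
#: residues translocated per ATP equivalent (ceiling rule)
AA_PER_TRANSLOCATION_ATP = 25


@dataclass
class ExpressionReaction:
    id: str
    kind: str
    met_stoich: Dict[str, float] = field(default_factory=dict)
    species_stoich: Dict[str, float] = field(default_factory=dict)
    capacity_usage: Dict[str, float] = field(default_factory=dict)
    gene_id: Optional[str] = None
    upper_bound: float = 1000.0

    def add_met(self, met_id: str, coef: float) -> None:
        self.met_stoich[met_id] = self.met_stoich.get(met_id, 0.0) + coef
        if self.met_stoich[met_id] == 0.0:
            del self.met_stoich[met_id]


def _hours(keff_per_second: float) -> float:
    return 3600.0 * keff_per_second


# ----------------------------------------------------------------------
def build_transcription(
    tu: TranscriptionUnitSpec,
    genes: Mapping[str, GeneSpec],
    params: CouplingParams,
    machinery=None,
) -> List[ExpressionReaction]:
    """Transcription of one TU plus degradation of its unstable mRNAs.

    The TU reaction consumes NTPs for every member gene (releasing one PPi
    and one proton per nucleotide — two phosphate-bond equivalents each),
    produces each member RNA species, and uses RNA polymerase at
    ``L_nt / (3600 k_rnap)`` per unit flux (diluted at mu by the solver).
    """
    for gid in tu.gene_ids:
        if gid not in genes:
            raise AnnexError(f"transcription unit {tu.id!r}: unknown gene {gid!r}")
    tx = ExpressionReaction(id=f"TX_{tu.id}", kind="transcription")
    total_nt = 0
    for gid in tu.gene_ids:
        gene = genes[gid]
        for nt, n in gene.nt_composition.items():
            tx.add_met(NTP_MET[nt], -float(n))
        tx.add_met("h2o_c", -1.0)  # one chain terminus per processed RNA
        tx.species_stoich[rna_species_id(gid)] = (
            tx.species_stoich.get(rna_species_id(gid), 0.0) + 1.0
        )
        total_nt += gene.length_nt
    tx.add_met("ppi_c", float(total_nt))
    tx.add_met("h_c", float(total_nt))
    if machinery is not None and machinery.rnap_complex_id:
        tx.capacity_usage[machinery.rnap_complex_id] = total_nt / _hours(params.k_rnap)
    reactions = [tx]

    if not tu.stable:
        for gid in tu.gene_ids:
            gene = genes[gid]
            if gene.rna_type != "mRNA" or params.kdeg_mrna <= 0:
                continue
            deg = ExpressionReaction(
                id=f"DEG_{gid}", kind="degradation", gene_id=gid
            )
            deg.species_stoich[rna_species_id(gid)] = -1.0
            deg.add_met("h2o_c", -(gene.length_nt - 1.0))
            for nt, n in gene.nt_composition.items():
                deg.add_met(NMP_MET[nt], float(n))
            reactions.append(deg)
    return reactions


def build_translation(
    gene: GeneSpec, params: CouplingParams, machinery=None
) -> List[ExpressionReaction]:
    """Translation of one mRNA gene into its protein species.

    Consumes amino acids per composition and 4 ATP equivalents per residue;
    uses the ribosome at ``L_aa / (3600 k_rib)``, the mRNA at ``1 / k_tl``
    (so mRNA consumption per translation is ``(mu + kdeg)/k_tl`` after
    growth coupling), and the pooled charged tRNA like an enzyme.
    """
    if gene.rna_type != "mRNA":
        raise AnnexError(f"gene {gene.id!r}: only mRNA genes are translated")
    if not gene.protein_aa_composition:
        raise AnnexError(f"gene {gene.id!r}: missing amino-acid composition")
    L = gene.protein_length_aa
    tl = ExpressionReaction(id=f"TL_{gene.id}", kind="translation", gene_id=gene.id)
    for aa, n in gene.protein_aa_composition.items():
        tl.add_met(f"{aa}_c", -float(n))
    n_atp = ATP_PER_AA * L
    tl.add_met("atp_c", -float(n_atp))
    # hydrolysis water minus the water released per peptide bond
    tl.add_met("h2o_c", -float(n_atp - (L - 1)))
    tl.add_met("adp_c", float(n_atp))
    tl.add_met("pi_c", float(n_atp))
    tl.add_met("h_c", float(n_atp))
    tl.species_stoich[protein_species_id(gene.id)] = 1.0
    if machinery is not None:
        if machinery.ribosome_complex_id:
            tl.capacity_usage[machinery.ribosome_complex_id] = L / _hours(params.k_rib)
        tl.capacity_usage[rna_species_id(gene.id)] = 1.0 / params.k_tl
        if machinery.trna_pool_species_id:
            tl.capacity_usage[machinery.trna_pool_species_id] = L / _hours(
                params.keff_default
            )
    return tl and [tl]


# ----------------------------------------------------------------------
def _ensure_loaded_species(
    annex: ExpressionAnnex, carrier_id: str, suffix: str, cofactor_mw: float
) -> str:
    loaded_id = f"{carrier_id}_{suffix}"
    if not annex.has_species(loaded_id):
        carrier = annex.get_species(carrier_id)
        annex.add_species(
            MacromoleculeSpecies(
                id=loaded_id,
                kind="complex",
                mw=carrier.mw + cofactor_mw,
                protein_mass=carrier.protein_mass,
            )
        )
    return loaded_id


def build_complex_assembly(
    cx: ComplexSpec, annex: ExpressionAnnex, params: CouplingParams
) -> List[ExpressionReaction]:
    """Formation of a complex from subunits plus cofactor loading.

    Metal delivery routes: ``direct`` consumes the cofactor metabolite 1:1
    per count; ``hyp_nickel`` consumes a Hyp-loaded nickel species (loading
    catalyzed by the Hyp machinery); ``isc_suf_fes`` consumes a NifU-borne
    cluster built from iron and IscS-donated sulfur under SufBC catalysis,
    transferred into the complex by ErpA.
    """
    mach = annex.machinery
    asm = ExpressionReaction(id=f"ASM_{cx.id}", kind="assembly")
    for sid, n in cx.subunit_stoichiometry.items():
        use_id = sid
        if cx.membrane and sid in annex.translocated_protein_ids:
            use_id = membrane_species_id(sid)
        asm.species_stoich[use_id] = asm.species_stoich.get(use_id, 0.0) - float(n)
    asm.species_stoich[cx.id] = 1.0

    extra: List[ExpressionReaction] = []
    for mod in cx.modifications:
        mod.validate()
        if mod.delivery == "direct":
            asm.add_met(mod.cofactor_metabolite_id, -float(mod.count))
        elif mod.delivery == "hyp_nickel":
            if not mach.ni_carrier_protein_id:
                raise AnnexError("hyp_nickel delivery requires a Hyp carrier protein")
            loaded = _ensure_loaded_species(
                annex, mach.ni_carrier_protein_id, "ni", COFACTOR_MW["ni2_c"]
            )
            asm.species_stoich[loaded] = (
                asm.species_stoich.get(loaded, 0.0) - float(mod.count)
            )
            asm.species_stoich[mach.ni_carrier_protein_id] = (
                asm.species_stoich.get(mach.ni_carrier_protein_id, 0.0)
                + float(mod.count)
            )
            load = ExpressionReaction(id="HYPLOAD", kind="metal_loading")
            load.add_met(mod.cofactor_metabolite_id, -1.0)
            load.species_stoich[mach.ni_carrier_protein_id] = -1.0
            load.species_stoich[loaded] = 1.0
            if mach.ni_machinery_complex_id:
                load.capacity_usage[mach.ni_machinery_complex_id] = 1.0 / _hours(
                    params.keff_default
                )
            extra.append(load)
        elif mod.delivery == "isc_suf_fes":
            if not mach.fes_carrier_protein_id:
                raise AnnexError("isc_suf_fes delivery requires a carrier protein")
            loaded = _ensure_loaded_species(
                annex, mach.fes_carrier_protein_id, "4fe4s", COFACTOR_MW["4fe4s"]
            )
            asm.species_stoich[loaded] = (
                asm.species_stoich.get(loaded, 0.0) - float(mod.count)
            )
            asm.species_stoich[mach.fes_carrier_protein_id] = (
                asm.species_stoich.get(mach.fes_carrier_protein_id, 0.0)
                + float(mod.count)
            )
            if mach.fes_transfer_complex_id:
                asm.capacity_usage[mach.fes_transfer_complex_id] = (
                    asm.capacity_usage.get(mach.fes_transfer_complex_id, 0.0)
                    + float(mod.count) / _hours(params.keff_default)
                )
            load = ExpressionReaction(id="FESLOAD", kind="metal_loading")
            load.add_met(mach.fes_iron_metabolite_id, -4.0)
            load.add_met(mach.fes_sulfur_metabolite_id, -4.0)
            load.add_met("h_c", 8.0)
            load.species_stoich[mach.fes_carrier_protein_id] = -1.0
            load.species_stoich[loaded] = 1.0
            if mach.fes_loader_complex_id:
                load.capacity_usage[mach.fes_loader_complex_id] = 1.0 / _hours(
                    params.keff_default
                )
            extra.append(load)
    return [asm] + extra


def build_translocation(
    protein_id: str, annex: ExpressionAnnex, params: CouplingParams
) -> List[ExpressionReaction]:
    """Move a cytosolic protein species into the membrane.

    Costs one ATP equivalent per started 25-residue segment (ceiling rule)
    and uses the translocase like an enzyme.
    """
    if not annex.has_species(protein_id):
        raise AnnexError(f"translocation target {protein_id!r}: no such species")
    gene_id = protein_id[len("protein_"):] if protein_id.startswith("protein_") else None
    length = None
    if gene_id and gene_id in annex._genes:
        length = annex.gene(gene_id).protein_length_aa
    if length is None:
        raise AnnexError(f"translocation target {protein_id!r}: unknown length")
    mem_id = membrane_species_id(protein_id)
    if not annex.has_species(mem_id):
        src = annex.get_species(protein_id)
        annex.add_species(
            MacromoleculeSpecies(
                id=mem_id,
                kind="protein",
                mw=src.mw,
                protein_mass=src.protein_mass,
            )
        )
    n_atp = math.ceil(length / AA_PER_TRANSLOCATION_ATP)
    tloc = ExpressionReaction(id=f"TLOC_{protein_id}", kind="translocation")
    tloc.species_stoich[protein_id] = -1.0
    tloc.species_stoich[mem_id] = 1.0
    tloc.add_met("atp_c", -float(n_atp))
    tloc.add_met("h2o_c", -float(n_atp))
    tloc.add_met("adp_c", float(n_atp))
    tloc.add_met("pi_c", float(n_atp))
    tloc.add_met("h_c", float(n_atp))
    mach = annex.machinery
    if mach.translocase_complex_id:
        tloc.capacity_usage[mach.translocase_complex_id] = 1.0 / _hours(
            params.keff_default
        )
    return [tloc]


# ----------------------------------------------------------------------
def add_unmodeled_protein(annex: ExpressionAnnex, f: float) -> dict:
    """Mass-coupling spec tying unmodeled to modeled protein mass.

    Enforces ``(unmodeled mass) = f/(1-f) * (modeled mass)`` at any
    solution; at f=0 the unmodeled protein is forced to zero.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError("unmodeled fraction must lie in [0, 1)")
    if not annex.unmodeled_protein_gene_id:
        raise AnnexError("annex has no unmodeled protein gene")
    return {
        "unmodeled_species": protein_species_id(annex.unmodeled_protein_gene_id),
        "ratio": f / (1.0 - f),
        "fraction": f,
    }


def _is_transport(net: Network, rxn) -> bool:
    comps = {net.metabolite(m).compartment for m in rxn.stoichiometry}
    return len(comps) > 1


def add_dummy_catalyst(net: Network, annex: ExpressionAnnex) -> ExpressionAnnex:
    """Assign the 26-aa dummy complex to orphan enzyme-requiring reactions.

    Orphan transport reactions get the membrane dummy; other orphan
    reactions get the soluble dummy. Exchanges, demands, and reactions
    flagged spontaneous are left alone.
    """
    mach = annex.machinery
    for rxn in net.reactions:
        if rxn.enzyme_complex_id or rxn.spontaneous:
            continue
        if rxn.is_exchange or rxn.is_demand:
            continue
        if _is_transport(net, rxn):
            rxn.enzyme_complex_id = mach.dummy_membrane_complex_id or None
        else:
            rxn.enzyme_complex_id = mach.dummy_complex_id or None
    return annex


def add_carrier_coupling(
    net: Network, annex: ExpressionAnnex, params: CouplingParams
) -> Dict[str, Dict[str, float]]:
    """Usage couplings forcing carrier-protein synthesis under reducing flux.

    For every reaction producing the reduced form of a listed carrier
    (ferredoxin, thioredoxin), the carrier protein is used at
    ``coef / (3600 keff_default)`` per unit flux, so any nonzero reducing
    flux forces nonzero carrier expression; zero flux forces none.
    """
    couplings: Dict[str, Dict[str, float]] = {}
    for carrier in annex.machinery.carriers:
        if not annex.has_species(carrier.protein_species_id):
            raise AnnexError(
                f"carrier protein {carrier.protein_species_id!r}: no such species"
            )
        red, ox = carrier.reduced_metabolite_id, carrier.oxidized_metabolite_id
        if not (net.has_metabolite(red) and net.has_metabolite(ox)):
            raise AnnexError(
                f"carrier {carrier.protein_species_id!r}: redox pair "
                f"{red!r}/{ox!r} missing from network"
            )
        per_unit = 1.0 / _hours(params.keff_default)
        for rxn in net.reactions:
            coef = rxn.stoichiometry.get(red, 0.0)
            if coef == 0.0 or rxn.is_exchange:
                continue
            couplings.setdefault(rxn.id, {})[carrier.protein_species_id] = (
                coef * per_unit
            )
    return couplings


# ----------------------------------------------------------------------
def build_expression_reactions(
    net: Network, annex: ExpressionAnnex, params: CouplingParams
) -> List[ExpressionReaction]:
    """Emit the complete E-matrix reaction set for an annex."""
    annex.validate()
    mach = annex.machinery
    out: Dict[str, ExpressionReaction] = {}

    def push(reactions: List[ExpressionReaction]) -> None:
        for r in reactions:
            out[r.id] = r

    for tu in annex.transcription_units:
        push(build_transcription(tu, annex._genes, params, mach))
    for gene in annex.mrna_genes():
        push(build_translation(gene, params, mach))
    for pid in annex.translocated_protein_ids:
        push(build_translocation(pid, annex, params))
    for cx in annex.complexes:
        push(build_complex_assembly(cx, annex, params))
    return list(out.values())
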