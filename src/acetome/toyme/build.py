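"""Programmatic generation of the toy acetogen model.

``build_toy_acetogen`` emits a :class:`Network` and a matched
:class:`ExpressionAnnex` exhibiting the structural features of an
acetogen ME model at desk scale: Wood-Ljungdahl carbon fixation with
nickel-dependent CODH4/CODH_ACS, acetate and ethanol (AOR_CL + ALCD2x)
branches, Rnf/ATP-synthase energy conservation, Nfn bifurcation, a
cardiolipin synthesis loop shedding glycerol with an ATP-costly recycle
path, Fe-S and Hyp metal-delivery machinery, and minimal
transcription/translation machinery.

Enzyme sizes and turnover numbers are tuned so the proteome constraint
binds within the swept substrate range (the knee of the growth curve);
they are toy values, not organism measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..coupling_solve.params import CouplingParams
from ..expression.annex import (
    AA_RESIDUE_MW,
    CarrierSpec,
    ComplexSpec,
    ExpressionAnnex,
    GeneSpec,
    MachineryConfig,
    MacromoleculeSpecies,
    ModificationSpec,
    NT_RESIDUE_MW,
    TranscriptionUnitSpec,
    WATER_MW,
    protein_species_id,
    rna_species_id,
)
from ..netcore.model import Metabolite, MetabolicReaction, Network
from ..netcore.io import parse_formula, write_network
from .tables import (
    EXCHANGE_DEFAULTS,
    METABOLITE_TABLE,
    REACTION_TABLE,
    reference_stoichiometry,
)

__all__ = ["ToyConfig", "build_toy_acetogen", "write_toy_model", "set_uptake"]

SUBSTRATE_EXCHANGES = {
    "co": "EX_co_e",
    "co2_h2": "EX_co2_e",
    "fructose": "EX_fru_e",
}

# gene id -> (protein length aa, TU id or None for per-gene TU)
# lengths are multiples of 4 so nucleotide composition splits into equal
# quarters, which keeps per-gram polymer costs uniform across genes
_GENES: List[Tuple[str, int]] = [
    ("g_codh4", 400),
    ("g_fdh", 360),
    ("g_fthfl", 320),
    ("g_mthfr5", 300),
    ("g_metr", 280),
    ("g_acs", 440),
    ("g_ptack", 340),
    ("g_aor", 320),
    ("g_alcd", 280),
    ("g_rnf", 360),
    ("g_atps", 400),
    ("g_hydfdn", 380),
    ("g_hyd2", 320),
    ("g_nfn", 340),
    ("g_gapd", 332),
    ("g_pfor", 380),
    ("g_pgs", 464),
    ("g_clpns", 200),
    ("g_glyrec", 240),
    ("g_bio", 400),
    ("g_trdr", 200),
    ("g_trx", 108),
    ("g_fdx", 60),
    ("g_nifu", 128),
    ("g_iscs", 240),
    ("g_sufbc", 280),
    ("g_erpa", 104),
    ("g_hypm", 224),
    ("g_hypc", 100),
    ("g_frut", 260),
    ("g_rpoA", 300),
    ("g_rpsA", 240),
    ("g_rpsB", 200),
    ("g_sec", 320),
    ("g_dummy", 26),
    ("g_unmod", 200),
]

# complex id -> (gene id, subunit count, keff s^-1, membrane, modifications)
_COMPLEXES: List[Tuple[str, str, int, float, bool, List[Tuple[str, int, str]]]] = [
    ("cplx_codh4", "g_codh4", 6, 10.0, False,
     [("ni2_c", 1, "hyp_nickel"), ("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_fdh", "g_fdh", 4, 4.0, False, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_fthfl", "g_fthfl", 4, 3.0, False, []),
    ("cplx_mthfr5", "g_mthfr5", 4, 3.0, False, []),
    ("cplx_metr", "g_metr", 4, 3.0, False, [("cobalt2_c", 1, "direct")]),
    ("cplx_acs", "g_acs", 6, 5.0, False,
     [("ni2_c", 2, "hyp_nickel"), ("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_ptack", "g_ptack", 4, 20.0, False, []),
    ("cplx_aor", "g_aor", 2, 50.0, False, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_alcd", "g_alcd", 2, 50.0, False, []),
    ("cplx_rnf", "g_rnf", 6, 25.0, True, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_atps", "g_atps", 8, 40.0, True, []),
    ("cplx_hydfdn", "g_hydfdn", 4, 20.0, False, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_hyd2", "g_hyd2", 2, 20.0, False, [("ni2_c", 1, "hyp_nickel")]),
    ("cplx_nfn", "g_nfn", 4, 30.0, False, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_gapd", "g_gapd", 4, 30.0, False, []),
    ("cplx_pfor", "g_pfor", 4, 25.0, False, [("4fe4s", 1, "isc_suf_fes")]),
    ("cplx_pgs", "g_pgs", 6, 6.0, False, []),
    ("cplx_clpns", "g_clpns", 2, 10.0, True, []),
    ("cplx_glyrec", "g_glyrec", 4, 4.0, False, []),
    ("cplx_bio", "g_bio", 4, 15.0, False, []),
    ("cplx_trdr", "g_trdr", 2, 25.0, False, []),
    ("cplx_iscs", "g_iscs", 2, 25.0, False, []),
    ("cplx_sufbc", "g_sufbc", 2, 25.0, False, []),
    ("cplx_erpa", "g_erpa", 1, 25.0, False, []),
    ("cplx_hyp", "g_hypm", 2, 25.0, False, []),
    ("cplx_frut", "g_frut", 2, 40.0, True, []),
    ("cplx_sec", "g_sec", 1, 25.0, True, []),
    ("cplx_dummy", "g_dummy", 1, 25.0, False, []),
    ("cplx_dummy_mem", "g_dummy", 1, 25.0, True, []),
]

_OPERONS = {
    "tu_wlp1": ["g_fdh", "g_fthfl", "g_mthfr5", "g_metr"],
    "tu_fes": ["g_nifu", "g_iscs", "g_sufbc", "g_erpa"],
    "tu_hyp": ["g_hypm", "g_hypc"],
}

_MEMBRANE_GENES = {"g_rnf", "g_atps", "g_clpns", "g_frut", "g_sec", "g_dummy"}

#: keff used for the enzyme of each reaction (overrides the table default)
_REACTION_KEFF = {rid: keff for rid, _, _, enz, keff, _, _ in REACTION_TABLE if enz}
_REACTION_ENZYME = {rid: enz for rid, _, _, enz, keff, _, _ in REACTION_TABLE}
_COMPLEX_KEFF = {cid: keff for cid, _, _, keff, _, _ in _COMPLEXES}


@dataclass
class ToyConfig:
    substrates: Tuple[str, ...] = ("co",)
    include_glycerol_loop: bool = True
    include_nickel: bool = True
    n_filler_genes: int = 0
    seed: int = 0
    params: CouplingParams = field(default_factory=CouplingParams)
    extra_modifications: Dict[str, List[ModificationSpec]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError("at least one substrate is required")
        unknown = set(self.substrates) - set(SUBSTRATE_EXCHANGES)
        if unknown:
            raise ValueError(f"unknown substrates: {sorted(unknown)}")
        if not self.include_nickel:
            for cid, mods in self.extra_modifications.items():
                for mod in mods:
                    if mod.cofactor_metabolite_id.startswith("ni2"):
                        raise ValueError(
                            f"nickel-free model cannot carry nickel modification "
                            f"on {cid!r}"
                        )


def _nt_quarters(length_nt: int) -> Dict[str, int]:
    base, rem = divmod(length_nt, 4)
    comp = {"A": base, "C": base, "G": base, "U": base}
    for nt in ("A", "C", "G")[:rem]:
        comp[nt] += 1
    return comp


def _gene(gene_id: str, length_aa: int) -> GeneSpec:
    length_nt = 3 * length_aa
    return GeneSpec(
        id=gene_id,
        rna_type="mRNA",
        nt_composition=_nt_quarters(length_nt),
        length_nt=length_nt,
        protein_aa_composition={"ala": length_aa},
        protein_length_aa=length_aa,
    )


def _rna_mw(comp: Dict[str, int]) -> float:
    return sum(NT_RESIDUE_MW[nt] * n for nt, n in comp.items()) + WATER_MW


def _protein_mw(length_aa: int) -> float:
    return AA_RESIDUE_MW["ala"] * length_aa + WATER_MW


def _biomass_reaction(params: CouplingParams) -> MetabolicReaction:
    """FBA biomass mirroring the ME macromolecule budget.

    Protein as amino-acid pool polymerized at 4 ATP equivalents per
    residue, RNA as an equal-quarters NTP mix, plus the same DNA, murein,
    and cardiolipin demands and GAM that the ME formulation applies.
    """
    n_ala = params.protein_biomass_fraction / AA_RESIDUE_MW["ala"]
    avg_nt = sum(NT_RESIDUE_MW.values()) / 4.0
    n_nt = params.rna_biomass_fraction / avg_nt
    atp_hydrolysis = 4.0 * n_ala + params.gam
    stoich = {
        "ala_c": -n_ala,
        "atp_c": -(atp_hydrolysis + n_nt / 4.0),
        "gtp_c": -n_nt / 4.0,
        "ctp_c": -n_nt / 4.0,
        "utp_c": -n_nt / 4.0,
        "h2o_c": -atp_hydrolysis,
        "adp_c": atp_hydrolysis,
        "pi_c": atp_hydrolysis,
        "h_c": atp_hydrolysis + n_nt,
        "ppi_c": n_nt,
        "dna_c": -0.010,
        "murein_c": -0.100,
        "clpn140_c": -0.040,
    }
    return MetabolicReaction(
        id="BIOMASS",
        name="biomass (macromolecule-budget mirror)",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        spontaneous=True,
        subsystem="Biomass",
    )


def build_toy_acetogen(cfg: ToyConfig) -> Tuple[Network, ExpressionAnnex]:
    params = cfg.params
    rng = np.random.default_rng(cfg.seed)

    # ---------------- network ----------------------------------------
    net = Network(id=f"toy_acetogen_seed{cfg.seed}")
    for base, name, formula, charge, comps in METABOLITE_TABLE:
        for comp in comps:
            net.add_metabolite(
                Metabolite(
                    id=f"{base}_{comp}",
                    name=name,
                    formula=parse_formula(formula),
                    charge=charge,
                    compartment=comp,
                )
            )
    skip: set = set()
    if not cfg.include_glycerol_loop:
        skip.update({"GLYCt", "GLYCDx", "DHAK", "CLPNS140"})
    if not cfg.include_nickel:
        skip.add("NIt")
    for rid, stoich, (lb, ub), enz, keff, spont, subsystem in reference_stoichiometry():
        if rid in skip:
            continue
        net.add_reaction(
            MetabolicReaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                enzyme_complex_id=enz,
                keff=keff,
                spontaneous=spont,
                subsystem=subsystem,
            )
        )
    for ex_id, (lb, ub) in EXCHANGE_DEFAULTS.items():
        met_id = ex_id[len("EX_"):]
        if not cfg.include_nickel and met_id == "ni2_e":
            continue
        net.add_reaction(
            MetabolicReaction(
                id=ex_id,
                stoichiometry={met_id: -1.0},
                lower_bound=lb,
                upper_bound=ub,
                spontaneous=True,
                subsystem="Exchange",
            )
        )
    if "co2_h2" in cfg.substrates:
        net.reaction("EX_h2_e").lower_bound = -1000.0
        net.reaction("EX_h2_e").upper_bound = 1000.0
    biomass = _biomass_reaction(params)
    if not cfg.include_glycerol_loop:
        del biomass.stoichiometry["clpn140_c"]
    net.add_reaction(biomass)
    net.objective_id = "BIOMASS"
    # growth-proportional demands used by the ME formulation (closed in FBA)
    for dm_id, met in (
        ("DM_dna_c", "dna_c"),
        ("DM_murein_c", "murein_c"),
        ("DM_clpn140_c", "clpn140_c"),
    ):
        if met not in {m.id for m in net.metabolites}:
            continue
        if not cfg.include_glycerol_loop and met == "clpn140_c":
            continue
        # closed in the plain network (the FBA biomass covers these);
        # the ME assembler re-opens them with growth-proportional bounds
        net.add_reaction(
            MetabolicReaction(
                id=dm_id,
                stoichiometry={met: -1.0},
                lower_bound=0.0,
                upper_bound=0.0,
                spontaneous=True,
                subsystem="Demand",
            )
        )
    net.reindex()
    net.validate()

    # ---------------- annex ------------------------------------------
    genes: List[GeneSpec] = [_gene(gid, L) for gid, L in _GENES]
    filler_ids: List[str] = []
    for i in range(cfg.n_filler_genes):
        L = int(100 + 4 * rng.integers(0, 26))
        gid = f"g_fill{i}"
        genes.append(_gene(gid, L))
        filler_ids.append(gid)
    genes.append(
        GeneSpec(
            id="rrna",
            rna_type="rRNA",
            nt_composition=_nt_quarters(1600),
            length_nt=1600,
        )
    )
    genes.append(
        GeneSpec(
            id="trna",
            rna_type="tRNA",
            nt_composition=_nt_quarters(76),
            length_nt=76,
        )
    )
    gene_map = {g.id: g for g in genes}

    tus: List[TranscriptionUnitSpec] = []
    in_operon = set()
    for tu_id, members in _OPERONS.items():
        tus.append(
            TranscriptionUnitSpec(
                id=tu_id, gene_ids=list(members), terminator="rho_dependent"
            )
        )
        in_operon.update(members)
    for i, g in enumerate(genes):
        if g.id in in_operon or g.rna_type != "mRNA":
            continue
        tus.append(
            TranscriptionUnitSpec(
                id=f"tu_{g.id}",
                gene_ids=[g.id],
                terminator="rho_dependent" if i % 2 else "rho_independent",
            )
        )
    tus.append(
        TranscriptionUnitSpec(
            id="tu_stable",
            gene_ids=["rrna", "trna"],
            terminator="rho_independent",
            stable=True,
        )
    )

    species: List[MacromoleculeSpecies] = []
    stable_ids = {"rrna", "trna"}
    for g in genes:
        mw = _rna_mw(g.nt_composition)
        kdeg = params.kdeg_mrna if (g.rna_type == "mRNA") else 0.0
        if g.id in stable_ids:
            kdeg = 0.0
        species.append(
            MacromoleculeSpecies(
                id=rna_species_id(g.id), kind="RNA", mw=mw, kdeg=kdeg, rna_mass=mw
            )
        )
        if g.rna_type == "mRNA":
            pmw = _protein_mw(g.protein_length_aa)
            species.append(
                MacromoleculeSpecies(
                    id=protein_species_id(g.id),
                    kind="protein",
                    mw=pmw,
                    protein_mass=pmw,
                )
            )

    from ..expression.annex import COFACTOR_MW

    complexes: List[ComplexSpec] = []
    species_by_id = {s.id: s for s in species}

    def complex_spec(cid, gid, n_sub, membrane, mods) -> ComplexSpec:
        mod_specs = []
        for cof, count, delivery in mods:
            if not cfg.include_nickel and delivery == "hyp_nickel":
                continue
            met = "4fe4s" if delivery == "isc_suf_fes" else cof
            mod_specs.append(
                ModificationSpec(
                    cofactor_metabolite_id=cof if delivery != "isc_suf_fes" else "4fe4s",
                    count=count,
                    delivery=delivery,
                )
            )
        return ComplexSpec(
            id=cid,
            subunit_stoichiometry={protein_species_id(gid): n_sub},
            modifications=mod_specs,
            membrane=membrane,
        )

    for cid, gid, n_sub, keff, membrane, mods in _COMPLEXES:
        cx = complex_spec(cid, gid, n_sub, membrane, mods)
        for extra in cfg.extra_modifications.get(cid, []):
            cx.modifications.append(extra)
        complexes.append(cx)
        pmass = n_sub * species_by_id[protein_species_id(gid)].protein_mass
        cof_mass = sum(
            COFACTOR_MW.get(
                "4fe4s" if m.delivery == "isc_suf_fes" else m.cofactor_metabolite_id,
                0.0,
            )
            * m.count
            for m in cx.modifications
        )
        species.append(
            MacromoleculeSpecies(
                id=cid, kind="complex", mw=pmass + cof_mass, protein_mass=pmass
            )
        )
    # ribosome: rRNA + two proteins, with a direct Mg modification standing
    # in for rRNA modification chemistry; tRNA pool likewise
    ribo = ComplexSpec(
        id="cplx_ribo",
        subunit_stoichiometry={
            rna_species_id("rrna"): 1,
            protein_species_id("g_rpsA"): 1,
            protein_species_id("g_rpsB"): 1,
        },
        modifications=[ModificationSpec("mg2_c", 2, "direct")],
    )
    complexes.append(ribo)
    ribo_pm = (
        species_by_id[protein_species_id("g_rpsA")].protein_mass
        + species_by_id[protein_species_id("g_rpsB")].protein_mass
    )
    ribo_rm = species_by_id[rna_species_id("rrna")].rna_mass
    species.append(
        MacromoleculeSpecies(
            id="cplx_ribo",
            kind="complex",
            mw=ribo_pm + ribo_rm + 2 * COFACTOR_MW["mg2_c"],
            protein_mass=ribo_pm,
            rna_mass=ribo_rm,
        )
    )
    # RNA polymerase: homodimer of rpoA
    rnap = ComplexSpec(
        id="cplx_rnap",
        subunit_stoichiometry={protein_species_id("g_rpoA"): 2},
    )
    complexes.append(rnap)
    rnap_pm = 2 * species_by_id[protein_species_id("g_rpoA")].protein_mass
    species.append(
        MacromoleculeSpecies(
            id="cplx_rnap", kind="complex", mw=rnap_pm, protein_mass=rnap_pm
        )
    )
    trna_pool = ComplexSpec(
        id="trna_pool",
        subunit_stoichiometry={rna_species_id("trna"): 1},
        modifications=[ModificationSpec("mg2_c", 1, "direct")],
    )
    complexes.append(trna_pool)
    trna_rm = species_by_id[rna_species_id("trna")].rna_mass
    species.append(
        MacromoleculeSpecies(
            id="trna_pool",
            kind="complex",
            mw=trna_rm + COFACTOR_MW["mg2_c"],
            rna_mass=trna_rm,
        )
    )

    machinery = MachineryConfig(
        rnap_complex_id="cplx_rnap",
        ribosome_complex_id="cplx_ribo",
        trna_pool_species_id="trna_pool",
        translocase_complex_id="cplx_sec",
        dummy_complex_id="cplx_dummy",
        dummy_membrane_complex_id="cplx_dummy_mem",
        fes_carrier_protein_id=protein_species_id("g_nifu"),
        fes_loader_complex_id="cplx_sufbc",
        fes_transfer_complex_id="cplx_erpa",
        fes_sulfur_metabolite_id="sdon_c",
        fes_iron_metabolite_id="fe2_c",
        ni_carrier_protein_id=protein_species_id("g_hypc") if cfg.include_nickel else "",
        ni_machinery_complex_id="cplx_hyp" if cfg.include_nickel else "",
        carriers=[
            CarrierSpec(protein_species_id("g_fdx"), "fd_red_c", "fd_ox_c"),
            CarrierSpec(protein_species_id("g_trx"), "trdrd_c", "trdox_c"),
        ],
    )

    annex = ExpressionAnnex(
        genes=genes,
        transcription_units=tus,
        species=species,
        complexes=complexes,
        translocated_protein_ids=[
            protein_species_id(g) for g in sorted(_MEMBRANE_GENES)
        ],
        unmodeled_protein_gene_id="g_unmod",
        dummy_protein_gene_id="g_dummy",
        machinery=machinery,
    )
    annex.validate()
    return net, annex


def set_uptake(net: Network, exchange_id: str, magnitude: float) -> None:
    """Cap uptake of an exchange at ``magnitude`` (COBRA sign convention)."""
    rxn = net.reaction(exchange_id)
    rxn.lower_bound = -abs(magnitude)


def write_toy_model(cfg: ToyConfig, outdir) -> Dict[str, str]:
    """Write network, annex, and a config echo; byte-stable for a fixed cfg."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, annex = build_toy_acetogen(cfg)
    net_path = outdir / "network.json"
    annex_path = outdir / "annex.json"
    write_network(net, net_path)
    annex.to_json(annex_path)
    import json as _json
    from dataclasses import asdict

    echo = {
        "substrates": list(cfg.substrates),
        "include_glycerol_loop": cfg.include_glycerol_loop,
        "include_nickel": cfg.include_nickel,
        "n_filler_genes": cfg.n_filler_genes,
        "seed": cfg.seed,
        "params": asdict(cfg.params),
    }
    (outdir / "config.json").write_text(_json.dumps(echo, indent=1, sort_keys=True) + "\n")
    return {"network": str(net_path), "annex": str(annex_path)}
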