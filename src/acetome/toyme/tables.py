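"""Reference stoichiometry of the toy acetogen.

This constant table is the single source of truth for the toy network.
Every internal reaction is elementally and charge exact (verified by the
balance checker in tests). Two net balances are structural invariants of
the table and must survive any edit:

* CO to acetate:  4 co + 2 h2o -> ac + 2 co2
* CO to ethanol:  6 co + 3 h2o -> etoh + 4 co2

Pseudo-elements (Fd, Trx, Cfe) stand for the lumped carrier scaffolds of
ferredoxin, thioredoxin, and the corrinoid iron-sulfur protein.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

__all__ = [
    "METABOLITE_TABLE",
    "REACTION_TABLE",
    "EXCHANGE_DEFAULTS",
    "WLP_REACTIONS",
    "GLYCEROL_LOOP_REACTIONS",
    "NICKEL_REACTIONS",
    "reference_stoichiometry",
]

# id (without compartment suffix), name, formula string, charge, compartments
METABOLITE_TABLE: List[Tuple[str, str, str, int, str]] = [
    ("co", "carbon monoxide", "CO", 0, "ce"),
    ("co2", "carbon dioxide", "CO2", 0, "ce"),
    ("h2", "hydrogen", "H2", 0, "ce"),
    ("h2o", "water", "H2O", 0, "ce"),
    ("h", "proton", "H", 1, "ce"),
    ("for", "formate", "CHO2", -1, "c"),
    ("ac", "acetate", "C2H3O2", -1, "ce"),
    ("etoh", "ethanol", "C2H6O", 0, "ce"),
    ("acald", "acetaldehyde", "C2H4O", 0, "c"),
    ("coa", "coenzyme A", "C21H32N7O16P3S", -4, "c"),
    ("accoa", "acetyl-CoA", "C23H34N7O17P3S", -4, "c"),
    ("pyr", "pyruvate", "C3H3O3", -1, "c"),
    ("fru", "fructose", "C6H12O6", 0, "ce"),
    ("atp", "ATP", "C10H12N5O13P3", -4, "c"),
    ("adp", "ADP", "C10H12N5O10P2", -3, "c"),
    ("amp", "AMP", "C10H12N5O7P", -2, "c"),
    ("gtp", "GTP", "C10H12N5O14P3", -4, "c"),
    ("gmp", "GMP", "C10H12N5O8P", -2, "c"),
    ("ctp", "CTP", "C9H12N3O14P3", -4, "c"),
    ("cmp", "CMP", "C9H12N3O8P", -2, "c"),
    ("utp", "UTP", "C9H11N2O15P3", -4, "c"),
    ("ump", "UMP", "C9H11N2O9P", -2, "c"),
    ("pi", "phosphate", "HO4P", -2, "ce"),
    ("ppi", "pyrophosphate", "HO7P2", -3, "c"),
    ("nad", "NAD+", "C21H26N7O14P2", -1, "c"),
    ("nadh", "NADH", "C21H27N7O14P2", -2, "c"),
    ("nadp", "NADP+", "C21H25N7O17P3", -3, "c"),
    ("nadph", "NADPH", "C21H26N7O17P3", -4, "c"),
    ("fd_ox", "oxidized ferredoxin", "Fd", 0, "c"),
    ("fd_red", "reduced ferredoxin", "Fd", -2, "c"),
    ("trdox", "oxidized thioredoxin", "Trx", 0, "c"),
    ("trdrd", "reduced thioredoxin", "TrxH2", 0, "c"),
    ("thf", "tetrahydrofolate", "C19H21N7O6", -2, "c"),
    ("mlthf", "5,10-methylene-THF", "C20H21N7O6", -2, "c"),
    ("5mthf", "5-methyl-THF", "C20H23N7O6", -2, "c"),
    ("cfesp", "corrinoid Fe-S protein", "Cfe", -1, "c"),
    ("mecfesp", "methyl corrinoid Fe-S protein", "CfeCH3", 0, "c"),
    ("nh4", "ammonium", "H4N", 1, "ce"),
    ("ala", "amino-acid pool (alanine equivalent)", "C3H7NO2", 0, "c"),
    ("dhap", "dihydroxyacetone phosphate", "C3H5O6P", -2, "c"),
    ("dha", "dihydroxyacetone", "C3H6O3", 0, "c"),
    ("glyc", "glycerol", "C3H8O3", 0, "ce"),
    ("pg140", "phosphatidylglycerol (n-C14:0)", "C34H66O10P", -1, "c"),
    ("clpn140", "cardiolipin (n-C14:0)", "C65H124O17P2", -2, "c"),
    ("h2s", "hydrogen sulfide", "H2S", 0, "ce"),
    ("sdon", "activated sulfur donor", "H2S", 0, "c"),
    ("so4", "sulfate", "O4S", -2, "ce"),
    ("ni2", "nickel(II)", "Ni", 2, "ce"),
    ("fe2", "iron(II)", "Fe", 2, "ce"),
    ("mg2", "magnesium(II)", "Mg", 2, "ce"),
    ("cobalt2", "cobalt(II)", "Co", 2, "ce"),
    ("murein", "murein monomer equivalent", "C13H21N3O6", 0, "c"),
    ("dna", "DNA equivalent (tetranucleotide)", "C38H41N15O29P4", -8, "c"),
]

# id, stoichiometry (suffixed met ids), (lb, ub), enzyme complex id or None,
# keff s^-1, spontaneous, subsystem
_R = Tuple[str, Dict[str, float], Tuple[float, float], object, float, bool, str]
REACTION_TABLE: List[_R] = [
    # --- Wood-Ljungdahl pathway -------------------------------------------
    ("CODH4",
     {"co_c": -1, "h2o_c": -1, "fd_ox_c": -1, "co2_c": 1, "fd_red_c": 1, "h_c": 2},
     (-1000, 1000), "cplx_codh4", 9.0, False, "WLP"),
    ("FDH",
     {"co2_c": -1, "fd_red_c": -1, "h_c": -1, "for_c": 1, "fd_ox_c": 1},
     (-1000, 1000), "cplx_fdh", 5.0, False, "WLP"),
    ("FTHFL",
     {"for_c": -1, "thf_c": -1, "atp_c": -1, "nadph_c": -1, "h_c": -1,
      "mlthf_c": 1, "adp_c": 1, "pi_c": 1, "nadp_c": 1, "h2o_c": 1},
     (0, 1000), "cplx_fthfl", 2.6, False, "WLP"),
    # electron-bifurcating: the exergonic methylene reduction drives
    # endergonic ferredoxin reduction (2 NADH in, 1 Fd_red out)
    ("MTHFR5",
     {"mlthf_c": -1, "nadh_c": -2, "fd_ox_c": -1, "5mthf_c": 1, "nad_c": 2,
      "fd_red_c": 1},
     (0, 1000), "cplx_mthfr5", 2.6, False, "WLP"),
    ("METR",
     {"5mthf_c": -1, "cfesp_c": -1, "h_c": -1, "thf_c": 1, "mecfesp_c": 1},
     (0, 1000), "cplx_metr", 2.6, False, "WLP"),
    ("CODH_ACS",
     {"mecfesp_c": -1, "co_c": -1, "coa_c": -1, "accoa_c": 1, "cfesp_c": 1,
      "h_c": 1},
     (0, 1000), "cplx_acs", 4.0, False, "WLP"),
    # --- acetate / ethanol branches ---------------------------------------
    ("PTA_ACK",
     {"accoa_c": -1, "adp_c": -1, "pi_c": -1, "ac_c": 1, "atp_c": 1,
      "coa_c": 1},
     (0, 1000), "cplx_ptack", 8.0, False, "Fermentation"),
    ("AOR_CL",
     {"ac_c": -1, "fd_red_c": -1, "h_c": -3, "acald_c": 1, "fd_ox_c": 1,
      "h2o_c": 1},
     (0, 1000), "cplx_aor", 50.0, False, "Fermentation"),
    ("ALCD2x",
     {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
     (0, 1000), "cplx_alcd", 50.0, False, "Fermentation"),
    # --- energy conservation ----------------------------------------------
    ("RNF",
     {"fd_red_c": -1, "nad_c": -1, "h_c": -3, "fd_ox_c": 1, "nadh_c": 1,
      "h_e": 2},
     (-1000, 1000), "cplx_rnf", 15.0, False, "Energy"),
    ("ATPS4r",
     {"adp_c": -1, "pi_c": -1, "h_e": -4, "atp_c": 1, "h2o_c": 1, "h_c": 3},
     (-1000, 1000), "cplx_atps", 20.0, False, "Energy"),
    ("HYDFDN2r",
     {"h2_c": -2, "fd_ox_c": -1, "nad_c": -1, "fd_red_c": 1, "nadh_c": 1,
      "h_c": 3},
     (0, 1000), "cplx_hydfdn", 40.0, False, "Energy"),
    ("HYD2",
     {"h2_c": -1, "nadp_c": -1, "nadph_c": 1, "h_c": 1},
     (0, 1000), "cplx_hyd2", 40.0, False, "Energy"),
    ("FRNDPR2r",
     {"nadph_c": -2, "fd_ox_c": -1, "nad_c": -1, "nadp_c": 2, "fd_red_c": 1,
      "nadh_c": 1, "h_c": 1},
     (-1000, 1000), "cplx_nfn", 15.0, False, "Energy"),
    # --- glycolysis / gluconeogenesis -------------------------------------
    ("GAPD",
     {"fru_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2, "pyr_c": 2,
      "atp_c": 2, "nadh_c": 2, "h2o_c": 2, "h_c": 2},
     (0, 1000), "cplx_gapd", 6.0, False, "Glycolysis"),
    ("PFOR",
     {"pyr_c": -1, "coa_c": -1, "fd_ox_c": -1, "accoa_c": 1, "co2_c": 1,
      "fd_red_c": 1, "h_c": 1},
     (-1000, 1000), "cplx_pfor", 8.0, False, "Glycolysis"),
    ("GNG",
     {"pyr_c": -1, "atp_c": -2, "nadh_c": -1, "h2o_c": -1, "dhap_c": 1,
      "adp_c": 2, "pi_c": 1, "nad_c": 1},
     (0, 1000), "cplx_gapd", 6.0, False, "Glycolysis"),
    # --- lipids and the glycerol loop -------------------------------------
    ("PGSYN",
     {"accoa_c": -14, "atp_c": -12, "nadph_c": -24, "nadh_c": -2, "h_c": -15,
      "dhap_c": -2, "pg140_c": 1, "coa_c": 14, "adp_c": 12, "pi_c": 13,
      "nadp_c": 24, "nad_c": 2},
     (0, 1000), "cplx_pgs", 5.0, False, "Lipids"),
    ("CLPNS140",
     {"pg140_c": -2, "clpn140_c": 1, "glyc_c": 1},
     (0, 1000), "cplx_clpns", 8.0, False, "Lipids"),
    # reductive glycerol formation (G3P dehydrogenase + phosphatase, lumped):
    # the cell's carbon-costly electron overflow valve
    ("GLYCP",
     {"dhap_c": -1, "nadh_c": -1, "h_c": -1, "h2o_c": -1, "glyc_c": 1,
      "nad_c": 1, "pi_c": 1},
     (0, 1000), "cplx_gapd", 15.0, False, "Lipids"),
    ("GLYCDx",
     {"glyc_c": -1, "nad_c": -1, "dha_c": 1, "nadh_c": 1, "h_c": 1},
     (0, 1000), "cplx_glyrec", 0.5, False, "Lipids"),
    ("DHAK",
     {"dha_c": -1, "atp_c": -1, "dhap_c": 1, "adp_c": 1, "h_c": 1},
     (0, 1000), "cplx_glyrec", 0.5, False, "Lipids"),
    # --- biosynthesis ------------------------------------------------------
    ("AASYN",
     {"pyr_c": -1, "nh4_c": -1, "nadph_c": -1, "h_c": -1, "ala_c": 1,
      "nadp_c": 1, "h2o_c": 1},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("AMPSYN",
     {"pyr_c": -3, "nh4_c": -5, "co2_c": -1, "atp_c": -8, "amp_c": 1,
      "adp_c": 8, "pi_c": 7, "h_c": 10},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("GMPSYN",
     {"pyr_c": -3, "nh4_c": -5, "co2_c": -1, "atp_c": -8, "nad_c": -1,
      "h2o_c": -1, "gmp_c": 1, "adp_c": 8, "pi_c": 7, "nadh_c": 1,
      "h_c": 11},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("UMPSYN",
     {"pyr_c": -3, "nh4_c": -2, "atp_c": -4, "ump_c": 1, "adp_c": 4,
      "pi_c": 3, "h_c": 3},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("CMPSYN",
     {"ump_c": -1, "nh4_c": -1, "atp_c": -1, "cmp_c": 1, "adp_c": 1,
      "pi_c": 1, "h_c": 2},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("ADK",
     {"amp_c": -1, "atp_c": -1, "adp_c": 2},
     (-1000, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("GMPK",
     {"gmp_c": -1, "atp_c": -2, "gtp_c": 1, "adp_c": 2},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("UMPK",
     {"ump_c": -1, "atp_c": -2, "utp_c": 1, "adp_c": 2},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("CMPK",
     {"cmp_c": -1, "atp_c": -2, "ctp_c": 1, "adp_c": 2},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("MUREINS",
     {"ala_c": -3, "accoa_c": -2, "atp_c": -1, "murein_c": 1, "coa_c": 2,
      "adp_c": 1, "pi_c": 1, "h2o_c": 1, "h_c": 1},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("DNAS",
     {"atp_c": -1, "gtp_c": -1, "ctp_c": -1, "utp_c": -1, "h2o_c": -1,
      "dna_c": 1, "ppi_c": 4, "h_c": 4},
     (0, 1000), "cplx_bio", 10.0, False, "Biosynthesis"),
    ("PPA",
     {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1},
     (0, 1000), None, 25.0, False, "Biosynthesis"),
    # --- sulfur and redox carriers ----------------------------------------
    ("TRDR",
     {"trdox_c": -1, "nadph_c": -1, "h_c": -1, "trdrd_c": 1, "nadp_c": 1},
     (0, 1000), "cplx_trdr", 25.0, False, "Sulfur"),
    ("SO4R",
     {"so4_c": -1, "trdrd_c": -1, "nadph_c": -3, "h_c": -5, "h2s_c": 1,
      "trdox_c": 1, "nadp_c": 3, "h2o_c": 4},
     (0, 1000), "cplx_trdr", 25.0, False, "Sulfur"),
    ("SULF_DON",
     {"h2s_c": -1, "sdon_c": 1},
     (0, 1000), "cplx_iscs", 25.0, False, "Sulfur"),
    # --- maintenance -------------------------------------------------------
    ("ATPM",
     {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
     (0.45, 1000), None, 25.0, True, "Maintenance"),
    # --- transport ---------------------------------------------------------
    ("COt", {"co_e": -1, "co_c": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("CO2t", {"co2_e": -1, "co2_c": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("H2t", {"h2_e": -1, "h2_c": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("H2Ot", {"h2o_e": -1, "h2o_c": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("H2St", {"h2s_e": -1, "h2s_c": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("ETOHt", {"etoh_c": -1, "etoh_e": 1}, (-1000, 1000), None, 25.0, True, "Transport"),
    ("FRUt", {"fru_e": -1, "fru_c": 1}, (0, 1000), "cplx_frut", 20.0, False, "Transport"),
    ("ACt",
     {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1},
     (0, 1000), None, 25.0, False, "Transport"),
    ("GLYCt", {"glyc_c": -1, "glyc_e": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("NH4t", {"nh4_e": -1, "nh4_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("PIt", {"pi_e": -1, "pi_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("SO4t", {"so4_e": -1, "so4_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("NIt", {"ni2_e": -1, "ni2_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("FE2t", {"fe2_e": -1, "fe2_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("MGt", {"mg2_e": -1, "mg2_c": 1}, (0, 1000), None, 25.0, False, "Transport"),
    ("COBALTt",
     {"cobalt2_e": -1, "cobalt2_c": 1},
     (0, 1000), None, 25.0, False, "Transport"),
]

# exchange id -> default (lb, ub); substrates get opened by the builder
EXCHANGE_DEFAULTS: Dict[str, Tuple[float, float]] = {
    "EX_co_e": (0, 1000),
    "EX_co2_e": (-1000, 1000),
    "EX_h2_e": (0, 0),
    "EX_fru_e": (0, 1000),
    "EX_h2o_e": (-1000, 1000),
    "EX_h_e": (0, 1000),
    "EX_nh4_e": (-1000, 1000),
    "EX_pi_e": (-1000, 1000),
    "EX_h2s_e": (-1000, 0),
    "EX_so4_e": (0, 0),
    "EX_ni2_e": (-1000, 1000),
    "EX_fe2_e": (-1000, 1000),
    "EX_mg2_e": (-1000, 1000),
    "EX_cobalt2_e": (-1000, 1000),
    "EX_ac_e": (0, 1000),
    "EX_etoh_e": (0, 1000),
    "EX_glyc_e": (0, 1000),
}

WLP_REACTIONS = ["CODH4", "FDH", "FTHFL", "MTHFR5", "METR", "CODH_ACS"]
GLYCEROL_LOOP_REACTIONS = ["GLYCt", "GLYCDx", "DHAK", "CLPNS140"]
NICKEL_REACTIONS = ["CODH4", "CODH_ACS", "HYD2"]


def reference_stoichiometry() -> List[_R]:
    """The immutable toy reaction table (deep copy; edits cannot leak back)."""
    return [
        (rid, dict(stoich), tuple(bounds), enz, keff, spont, subsystem)
        for rid, stoich, bounds, enz, keff, spont, subsystem in REACTION_TABLE
    ]
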