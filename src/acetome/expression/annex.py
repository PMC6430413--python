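"""Expression-annex data model: the E-side of a ME model.

The annex lists genes, transcription units, macromolecule species,
complexes and their cofactor modifications, plus the machinery wiring
(RNA polymerase, ribosome, tRNA pool, translocase, metal-delivery
carriers). It is serialized as a versioned JSON schema (see
``ExpressionAnnex.to_json`` / ``from_json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

__all__ = [
    "GeneSpec",
    "TranscriptionUnitSpec",
    "MacromoleculeSpecies",
    "ModificationSpec",
    "ComplexSpec",
    "CarrierSpec",
    "MachineryConfig",
    "ExpressionAnnex",
    "AnnexError",
    "rna_species_id",
    "protein_species_id",
    "membrane_species_id",
    "NT_RESIDUE_MW",
    "AA_RESIDUE_MW",
    "WATER_MW",
]

ANNEX_SCHEMA_VERSION = 1

#: monophosphate residue masses, g mmol^-1 (NMP minus water)
NT_RESIDUE_MW = {"A": 0.3292, "C": 0.3052, "G": 0.3452, "U": 0.3062}
#: amino-acid residue masses, g mmol^-1 (free aa minus water)
AA_RESIDUE_MW = {"ala": 0.07108}
WATER_MW = 0.01802

#: cofactor masses, g mmol^-1 (small relative to macromolecules)
COFACTOR_MW = {
    "ni2_c": 0.0587,
    "fe2_c": 0.0558,
    "mg2_c": 0.0243,
    "cobalt2_c": 0.0589,
    "4fe4s": 0.3518,
}


class AnnexError(ValueError):
    """Raised when an annex object violates a structural invariant."""


def rna_species_id(gene_id: str) -> str:
    return f"rna_{gene_id}"


def protein_species_id(gene_id: str) -> str:
    return f"protein_{gene_id}"


def membrane_species_id(protein_id: str) -> str:
    return f"{protein_id}_mem"


@dataclass
class GeneSpec:
    id: str
    rna_type: str  # mRNA | rRNA | tRNA
    nt_composition: Dict[str, int]
    length_nt: int
    protein_aa_composition: Optional[Dict[str, int]] = None
    protein_length_aa: Optional[int] = None

    def validate(self) -> None:
        if self.rna_type not in ("mRNA", "rRNA", "tRNA"):
            raise AnnexError(f"gene {self.id!r}: unknown rna_type {self.rna_type!r}")
        if self.length_nt != sum(self.nt_composition.values()):
            raise AnnexError(
                f"gene {self.id!r}: length_nt {self.length_nt} != sum of "
                f"nt_composition {sum(self.nt_composition.values())}"
            )
        if set(self.nt_composition) - {"A", "C", "G", "U"}:
            raise AnnexError(f"gene {self.id!r}: nt_composition keys must be A/C/G/U")
        is_coding = self.rna_type == "mRNA"
        has_protein = self.protein_aa_composition is not None
        if is_coding != has_protein:
            raise AnnexError(
                f"gene {self.id!r}: protein fields must be present iff rna_type=mRNA"
            )
        if has_protein:
            if self.protein_length_aa != sum(self.protein_aa_composition.values()):
                raise AnnexError(
                    f"gene {self.id!r}: protein_length_aa inconsistent with composition"
                )
            if self.protein_length_aa <= 0:
                raise AnnexError(f"gene {self.id!r}: zero-length protein")

    @property
    def rna_mw(self) -> float:
        mw = sum(NT_RESIDUE_MW[nt] * n for nt, n in self.nt_composition.items())
        return mw + WATER_MW  # terminal residue keeps its water

    @property
    def protein_mw(self) -> Optional[float]:
        if self.protein_aa_composition is None:
            return None
        mw = sum(
            AA_RESIDUE_MW[aa] * n for aa, n in self.protein_aa_composition.items()
        )
        return mw + WATER_MW


@dataclass
class TranscriptionUnitSpec:
    id: str
    gene_ids: List[str]
    terminator: str = "rho_dependent"  # or rho_independent (metadata only)
    stable: bool = False

    def validate(self, genes: Dict[str, GeneSpec]) -> None:
        if not self.gene_ids:
            raise AnnexError(f"transcription unit {self.id!r}: no member genes")
        if self.terminator not in ("rho_dependent", "rho_independent"):
            raise AnnexError(
                f"transcription unit {self.id!r}: bad terminator {self.terminator!r}"
            )
        for gid in self.gene_ids:
            if gid not in genes:
                raise AnnexError(
                    f"transcription unit {self.id!r}: unknown gene {gid!r}"
                )
        if self.stable:
            bad = [g for g in self.gene_ids if genes[g].rna_type == "mRNA"]
            if bad:
                raise AnnexError(
                    f"transcription unit {self.id!r}: stable=true requires all member "
                    f"genes rRNA/tRNA; offending: {bad}"
                )


@dataclass
class MacromoleculeSpecies:
    id: str
    kind: str  # RNA | protein | complex
    mw: float  # g mmol^-1
    kdeg: float = 0.0  # h^-1
    #: mass split used by composition/ratio constraints
    rna_mass: float = 0.0
    protein_mass: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("RNA", "protein", "complex"):
            raise AnnexError(f"species {self.id!r}: unknown kind {self.kind!r}")
        if self.mw <= 0:
            raise AnnexError(f"species {self.id!r}: mw must be positive")
        if self.kdeg < 0:
            raise AnnexError(f"species {self.id!r}: negative kdeg")
        if self.kind in ("protein", "complex") and self.kdeg != 0:
            raise AnnexError(f"species {self.id!r}: proteins/complexes have kdeg 0")


@dataclass
class ModificationSpec:
    cofactor_metabolite_id: str
    count: int = 1
    delivery: str = "direct"  # direct | hyp_nickel | isc_suf_fes

    def validate(self) -> None:
        if self.count < 1:
            raise AnnexError("modification count must be >= 1")
        if self.delivery not in ("direct", "hyp_nickel", "isc_suf_fes"):
            raise AnnexError(f"unknown delivery {self.delivery!r}")
        if self.delivery == "hyp_nickel" and not self.cofactor_metabolite_id.startswith(
            "ni2"
        ):
            raise AnnexError("hyp_nickel delivery is only valid for nickel (ni2_*)")
        if self.delivery == "isc_suf_fes" and "fe" not in self.cofactor_metabolite_id:
            raise AnnexError("isc_suf_fes delivery is only valid for Fe-S clusters")


@dataclass
class ComplexSpec:
    id: str
    subunit_stoichiometry: Dict[str, int]  # species id (protein or RNA) -> count
    modifications: List[ModificationSpec] = field(default_factory=list)
    membrane: bool = False

    def validate(self) -> None:
        if not self.subunit_stoichiometry:
            raise AnnexError(f"complex {self.id!r}: no subunits")
        for sid, n in self.subunit_stoichiometry.items():
            if n < 1:
                raise AnnexError(f"complex {self.id!r}: subunit count < 1 for {sid!r}")
        for mod in self.modifications:
            mod.validate()


@dataclass
class CarrierSpec:
    """A redox carrier protein with its reduced/oxidized metabolite pair."""

    protein_species_id: str
    reduced_metabolite_id: str
    oxidized_metabolite_id: str


@dataclass
class MachineryConfig:
    rnap_complex_id: str = ""
    ribosome_complex_id: str = ""
    trna_pool_species_id: str = ""
    translocase_complex_id: str = ""
    dummy_complex_id: str = ""
    dummy_membrane_complex_id: str = ""
    # Fe-S delivery (NifU carrier, IscS sulfur donor, SufBC loader, ErpA transfer)
    fes_carrier_protein_id: str = ""
    fes_loader_complex_id: str = ""
    fes_transfer_complex_id: str = ""
    fes_sulfur_metabolite_id: str = "sdon_c"
    fes_iron_metabolite_id: str = "fe2_c"
    # nickel delivery (Hyp carrier + machinery)
    ni_carrier_protein_id: str = ""
    ni_machinery_complex_id: str = ""
    carriers: List[CarrierSpec] = field(default_factory=list)


@dataclass
class ExpressionAnnex:
    genes: List[GeneSpec] = field(default_factory=list)
    transcription_units: List[TranscriptionUnitSpec] = field(default_factory=list)
    species: List[MacromoleculeSpecies] = field(default_factory=list)
    complexes: List[ComplexSpec] = field(default_factory=list)
    translocated_protein_ids: List[str] = field(default_factory=list)
    unmodeled_protein_gene_id: str = ""
    dummy_protein_gene_id: str = ""
    dummy_protein_length_aa: int = 26
    machinery: MachineryConfig = field(default_factory=MachineryConfig)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        self._genes = {g.id: g for g in self.genes}
        self._tus = {t.id: t for t in self.transcription_units}
        self._species = {s.id: s for s in self.species}
        self._complexes = {c.id: c for c in self.complexes}

    def gene(self, gid: str) -> GeneSpec:
        return self._genes[gid]

    def tu(self, tid: str) -> TranscriptionUnitSpec:
        return self._tus[tid]

    def get_species(self, sid: str) -> MacromoleculeSpecies:
        return self._species[sid]

    def has_species(self, sid: str) -> bool:
        return sid in self._species

    def complex(self, cid: str) -> ComplexSpec:
        return self._complexes[cid]

    def has_complex(self, cid: str) -> bool:
        return cid in self._complexes

    def add_species(self, sp: MacromoleculeSpecies) -> None:
        if sp.id in self._species:
            raise AnnexError(f"duplicate species id {sp.id!r}")
        self.species.append(sp)
        self._species[sp.id] = sp

    def add_complex(self, cx: ComplexSpec) -> None:
        if cx.id in self._complexes:
            raise AnnexError(f"duplicate complex id {cx.id!r}")
        self.complexes.append(cx)
        self._complexes[cx.id] = cx

    def mrna_genes(self) -> List[GeneSpec]:
        return [g for g in self.genes if g.rna_type == "mRNA"]

    def stable_gene_ids(self) -> set:
        out = set()
        for tu in self.transcription_units:
            if tu.stable:
                out.update(tu.gene_ids)
        return out

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.dummy_protein_length_aa != 26:
            raise AnnexError("dummy_protein_length_aa must be 26")
        if not self.unmodeled_protein_gene_id:
            raise AnnexError("unmodeled protein gene is required")
        if self.unmodeled_protein_gene_id not in self._genes:
            raise AnnexError(
                f"unmodeled protein gene {self.unmodeled_protein_gene_id!r} not in genes"
            )
        for g in self.genes:
            g.validate()
        for t in self.transcription_units:
            t.validate(self._genes)
        for s in self.species:
            s.validate()
        for c in self.complexes:
            c.validate()
            for sid in c.subunit_stoichiometry:
                base = sid[:-4] if sid.endswith("_mem") else sid
                if base not in self._species:
                    raise AnnexError(
                        f"complex {c.id!r}: unknown subunit species {sid!r}"
                    )
        if self.dummy_protein_gene_id:
            dummy = self._genes.get(self.dummy_protein_gene_id)
            if dummy is None:
                raise AnnexError("dummy protein gene not found")
            if dummy.protein_length_aa != self.dummy_protein_length_aa:
                raise AnnexError(
                    f"dummy protein must be {self.dummy_protein_length_aa} aa"
                )

    # -- JSON ----------------------------------------------------------
    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "schema_version": ANNEX_SCHEMA_VERSION,
            "genes": [asdict(g) for g in self.genes],
            "transcription_units": [asdict(t) for t in self.transcription_units],
            "species": [asdict(s) for s in self.species],
            "complexes": [asdict(c) for c in self.complexes],
            "translocated_protein_ids": list(self.translocated_protein_ids),
            "unmodeled_protein_gene_id": self.unmodeled_protein_gene_id,
            "dummy_protein_gene_id": self.dummy_protein_gene_id,
            "dummy_protein_length_aa": self.dummy_protein_length_aa,
            "machinery": asdict(self.machinery),
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ExpressionAnnex":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        if data.get("schema_version") != ANNEX_SCHEMA_VERSION:
            raise AnnexError(
                f"unsupported annex schema version {data.get('schema_version')!r}"
            )
        mach = data.get("machinery", {})
        carriers = [CarrierSpec(**c) for c in mach.pop("carriers", [])]
        annex = cls(
            genes=[GeneSpec(**g) for g in data["genes"]],
            transcription_units=[
                TranscriptionUnitSpec(**t) for t in data["transcription_units"]
            ],
            species=[MacromoleculeSpecies(**s) for s in data["species"]],
            complexes=[
                ComplexSpec(
                    id=c["id"],
                    subunit_stoichiometry=c["subunit_stoichiometry"],
                    modifications=[ModificationSpec(**m) for m in c["modifications"]],
                    membrane=c["membrane"],
                )
                for c in data["complexes"]
            ],
            translocated_protein_ids=list(data.get("translocated_protein_ids", [])),
            unmodeled_protein_gene_id=data.get("unmodeled_protein_gene_id", ""),
            dummy_protein_gene_id=data.get("dummy_protein_gene_id", ""),
            dummy_protein_length_aa=int(data.get("dummy_protein_length_aa", 26)),
            machinery=MachineryConfig(carriers=carriers, **mach),
        )
        annex.validate()
        return annex
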