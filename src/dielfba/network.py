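"""Compartmented metabolic networks: domain types, SBML I/O, and a reduced
synthetic plant core network.

The synthetic network (:func:`build_toy_core`) is a deliberately small
(~100 reactions) but route-complete stand-in for a genome-scale plant core
model. It spans cytosol (c), plastid (p), mitochondrion (m), peroxisome (x),
vacuole (v) and extracellular space (e) and contains every pathway the diel
C3/CAM analysis traverses: lumped light reactions, Rubisco carboxylase and
oxygenase, a lumped Calvin-Benson-Bassham route, photorespiration with Gly
decarboxylase, PEPC, cytosolic and mitochondrial ICDH/aconitase, citrate
synthase (mitochondrial and peroxisomal), malic enzymes, malate
dehydrogenases, the proline cycle, nitrate assimilation, starch/sucrose
turnover, vacuolar transporters for all storable solutes, phloem export at a
fixed sucrose:amino-acid composition, and maintenance sinks.

Bookkeeping is carbon/nitrogen/energy-balanced (every non-exchange reaction
conserves C, N, phosphate groups, redox-cofactor and CoA moieties, and photon
count); protons, oxygen and water are not tracked. Full charge balance is
delegated to curated SBML models read via :func:`read_sbml`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ToyOptions",
    "build_toy_core",
    "read_sbml",
    "write_sbml",
    "check_mass_consistency",
    "REQUIRED_ROLES",
    "TAG_EXCHANGE",
    "TAG_VACUOLAR_TRANSPORT",
]

COMPARTMENTS = ("cytosol", "plastid", "mitochondrion", "peroxisome", "vacuole",
                "extracellular")

# Role tags. Every tag except vacuolar-transport and exchange refers to exactly
# one reaction per network.
TAG_EXCHANGE = "exchange"
TAG_VACUOLAR_TRANSPORT = "vacuolar-transport"

#: Tags the diel assembly needs to resolve before a network can be expanded.
REQUIRED_ROLES = (
    "PHLOEM_EXPORT",
    "NITRATE_UPTAKE",
    "CO2_UPTAKE",
    "RUBISCO_CARB",
    "RUBISCO_OXY",
    "ATP_MAINT",
    "NADPH_MAINT",
    "LIGHT_UPTAKE",
)

_CO2_PATTERN = re.compile(r"(co2|hco3|carbon.?dioxide|bicarbonate)", re.IGNORECASE)


@dataclass
class Metabolite:
    id: str
    name: str
    compartment: str
    carries_carbon: bool = False
    is_co2_species: bool = False
    n_carbon: int = 0
    n_nitrogen: int = 0

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for metabolite {self.id}"
            )
        if self.n_carbon > 0:
            self.carries_carbon = True
        if self.is_co2_species and not self.carries_carbon:
            raise ValueError(f"CO2 species {self.id} must carry carbon")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry over metabolite ids.

    Negative coefficients are substrates, positive are products. Bounds are
    fluxes in umol m-2 s-1.
    """

    id: str
    stoichiometry: dict
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    tags: set = field(default_factory=set)
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        self.tags = set(self.tags)

    @property
    def is_exchange(self) -> bool:
        return TAG_EXCHANGE in self.tags


class MetabolicNetwork:
    """Compartmented stoichiometric model with tagged roles and storables.

    ``storables`` is the list of metabolite ids eligible for diel linker
    reactions: starch in the plastid plus sugars, carboxylic acids, amino
    acids and nitrate in the vacuole.
    """

    def __init__(self, metabolites: Iterable[Metabolite],
                 reactions: Iterable[Reaction],
                 storables: Iterable[str] = ()):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.storables = list(storables)
        self._met_index = {}
        for i, met in enumerate(self.metabolites):
            if met.id in self._met_index:
                raise ValueError(f"duplicate metabolite id {met.id}")
            self._met_index[met.id] = i
        self._rxn_index = {}
        for j, rxn in enumerate(self.reactions):
            if rxn.id in self._rxn_index:
                raise ValueError(f"duplicate reaction id {rxn.id}")
            self._rxn_index[rxn.id] = j
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
        for met_id in self.storables:
            if met_id not in self._met_index:
                raise ValueError(f"storable {met_id} is not a network metabolite")

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def find_all_by_tag(self, tag: str) -> list:
        return [r for r in self.reactions if tag in r.tags]

    def find_by_tag(self, tag: str) -> Reaction:
        hits = self.find_all_by_tag(tag)
        if not hits:
            raise KeyError(f"no reaction carries tag {tag!r}")
        if len(hits) > 1 and tag not in (TAG_VACUOLAR_TRANSPORT, TAG_EXCHANGE):
            raise ValueError(
                f"tag {tag!r} must be unique but matches {[r.id for r in hits]}"
            )
        return hits[0]

    def missing_roles(self, roles=REQUIRED_ROLES) -> list:
        return [t for t in roles if not self.find_all_by_tag(t)]

    def validate_tags(self, roles=REQUIRED_ROLES) -> None:
        missing = self.missing_roles(roles)
        if missing:
            raise ValueError(f"network is missing required role tags: {missing}")

    # -- matrix ----------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[r.lower_bound, r.upper_bound] for r in self.reactions])

    def copy(self) -> "MetabolicNetwork":
        mets = [Metabolite(**vars(m)) for m in self.metabolites]
        rxns = [
            Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                     set(r.tags), r.name)
            for r in self.reactions
        ]
        return MetabolicNetwork(mets, rxns, list(self.storables))

    def __repr__(self):
        return (f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, {len(self.storables)} storables>")


# ---------------------------------------------------------------------------
# Synthetic plant core network
# ---------------------------------------------------------------------------

@dataclass
class ToyOptions:
    """Feature flags for the synthetic core network.

    icdh_reversible : allow mitochondrial ICDH to run in the carboxylating
        (reverse) direction. When false its lower bound is 0.
    phloem_sucrose_fraction : molar sucrose fraction of phloem sap (the rest
        is a generic amino acid); the analysis is robust to this composition.
    include_mitochondria : disabling removes the mitochondrial compartment
        (only meaningful for error-path checks).
    """

    icdh_reversible: bool = True
    phloem_sucrose_fraction: float = 0.8
    include_mitochondria: bool = True

    def __post_init__(self):
        if not 0.0 < self.phloem_sucrose_fraction < 1.0:
            raise ValueError("phloem_sucrose_fraction must lie in (0, 1)")


class _Builder:
    def __init__(self):
        self.mets: dict[str, Metabolite] = {}
        self.rxns: list[Reaction] = []

    def met(self, mid, comp, c=0, n=0, co2=False, name=""):
        self.mets[mid] = Metabolite(
            id=mid, name=name or mid, compartment=comp,
            carries_carbon=c > 0, is_co2_species=co2, n_carbon=c, n_nitrogen=n,
        )

    def rxn(self, rid, stoich, lb=0.0, ub=1000.0, tags=(), name=""):
        for mid in stoich:
            if mid not in self.mets:
                raise KeyError(f"{rid}: unknown metabolite {mid}")
        rxn = Reaction(rid, dict(stoich), lb, ub, set(tags), name or rid)
        if not rxn.is_exchange:
            # carbon / nitrogen conservation guard at build time
            for attr in ("n_carbon", "n_nitrogen"):
                bal = sum(
                    coeff * getattr(self.mets[mid], attr)
                    for mid, coeff in stoich.items()
                )
                if abs(bal) > 1e-9:
                    raise ValueError(f"{rid} does not balance {attr}: {bal}")
        self.rxns.append(rxn)

    def transport(self, rid, src, dst, lb=-1000.0, ub=1000.0, tags=()):
        self.rxn(rid, {src: -1, dst: 1}, lb, ub, tags)


def build_toy_core(options: ToyOptions | None = None) -> MetabolicNetwork:
    """Build the reduced synthetic plant core network.

    Every flux route of the diel C3/CAM analysis is expressible as a feasible
    path: daytime Calvin-Benson-Bassham fixation with 3:1 photorespiration,
    nocturnal PEPC fixation into vacuolar malate, the
    isocitrate-citrate-Pro-2OG cycle (nocturnal carboxylation of 2-oxoglutarate
    by reverse mitochondrial ICDH fed by proline degradation, daytime
    decarboxylation by cytosolic ICDH and proline resynthesis), starch/sucrose
    turnover, and nitrate assimilation into a phloem amino-acid pool.
    """
    opt = options or ToyOptions()
    if not opt.include_mitochondria:
        raise ValueError(
            "the core network requires the mitochondrial compartment "
            "(ICDH_m, citrate synthase and the proline cycle live there)"
        )
    b = _Builder()

    # ---- metabolites ---------------------------------------------------
    for comp_suffix, comp in (("c", "cytosol"), ("p", "plastid"),
                              ("m", "mitochondrion"), ("x", "peroxisome")):
        b.met(f"CO2_{comp_suffix}", comp, c=1, co2=True, name="carbon dioxide")
    b.met("CO2_e", "extracellular", c=1, co2=True, name="carbon dioxide")
    b.met("HCO3_c", "cytosol", c=1, co2=True, name="bicarbonate")
    b.met("O2_e", "extracellular", name="oxygen")
    b.met("H2O_e", "extracellular", name="water")
    b.met("PHOTON_p", "plastid", name="photon")
    b.met("PHOTON_DISS_e", "extracellular", name="dissipated quantum")

    for c_ in ("c", "p", "m"):
        comp = {"c": "cytosol", "p": "plastid", "m": "mitochondrion"}[c_]
        b.met(f"ATP_{c_}", comp, c=10, name="ATP")
        b.met(f"ADP_{c_}", comp, c=10, name="ADP")
        b.met(f"Pi_{c_}", comp, name="orthophosphate")
    for c_ in ("c", "p"):
        comp = {"c": "cytosol", "p": "plastid"}[c_]
        b.met(f"NADPH_{c_}", comp, c=21, name="NADPH")
        b.met(f"NADP_{c_}", comp, c=21, name="NADP+")
    for c_ in ("c", "m", "x"):
        comp = {"c": "cytosol", "m": "mitochondrion", "x": "peroxisome"}[c_]
        b.met(f"NADH_{c_}", comp, c=21, name="NADH")
        b.met(f"NAD_{c_}", comp, c=21, name="NAD+")
    for c_ in ("c", "m", "x"):
        comp = {"c": "cytosol", "m": "mitochondrion", "x": "peroxisome"}[c_]
        b.met(f"COA_{c_}", comp, c=21, name="coenzyme A")
        b.met(f"ACCOA_{c_}", comp, c=23, name="acetyl-CoA")

    b.met("RUBP_p", "plastid", c=5, name="ribulose-1,5-bisphosphate")
    b.met("PGA_p", "plastid", c=3, name="3-phosphoglycerate")
    b.met("PGLYC_p", "plastid", c=2, name="2-phosphoglycolate")
    b.met("TP_p", "plastid", c=3, name="triose phosphate")
    b.met("TP_c", "cytosol", c=3, name="triose phosphate")
    b.met("STARCH_p", "plastid", c=6, name="starch (glucosyl unit)")
    b.met("GLYCLT_p", "plastid", c=2, name="glycolate")
    b.met("GLYCLT_x", "peroxisome", c=2, name="glycolate")
    b.met("GLX_x", "peroxisome", c=2, name="glyoxylate")
    b.met("GLY_x", "peroxisome", c=2, n=1, name="glycine")
    b.met("GLY_m", "mitochondrion", c=2, n=1, name="glycine")
    b.met("SER_m", "mitochondrion", c=3, n=1, name="serine")
    b.met("SER_x", "peroxisome", c=3, n=1, name="serine")
    b.met("HPYR_x", "peroxisome", c=3, name="hydroxypyruvate")
    b.met("GLYCERATE_x", "peroxisome", c=3, name="glycerate")
    b.met("GLYCERATE_p", "plastid", c=3, name="glycerate")

    b.met("PGA_c", "cytosol", c=3, name="3-phosphoglycerate")
    b.met("PEP_c", "cytosol", c=3, name="phosphoenolpyruvate")
    b.met("PYR_c", "cytosol", c=3, name="pyruvate")
    b.met("PYR_m", "mitochondrion", c=3, name="pyruvate")
    b.met("OAA_c", "cytosol", c=4, name="oxaloacetate")
    b.met("OAA_m", "mitochondrion", c=4, name="oxaloacetate")
    b.met("OAA_x", "peroxisome", c=4, name="oxaloacetate")
    for c_ in ("c", "m", "x", "v"):
        comp = {"c": "cytosol", "m": "mitochondrion", "x": "peroxisome",
                "v": "vacuole"}[c_]
        b.met(f"MAL_{c_}", comp, c=4, name="malate")
    for c_ in ("c", "m", "x", "v"):
        comp = {"c": "cytosol", "m": "mitochondrion", "x": "peroxisome",
                "v": "vacuole"}[c_]
        b.met(f"CIT_{c_}", comp, c=6, name="citrate")
    for c_ in ("c", "m", "v"):
        comp = {"c": "cytosol", "m": "mitochondrion", "v": "vacuole"}[c_]
        b.met(f"ICIT_{c_}", comp, c=6, name="isocitrate")
    for c_ in ("c", "m", "p", "x"):
        comp = {"c": "cytosol", "m": "mitochondrion", "p": "plastid",
                "x": "peroxisome"}[c_]
        b.met(f"AKG_{c_}", comp, c=5, name="2-oxoglutarate")
    for c_ in ("c", "m", "p", "x", "v"):
        comp = {"c": "cytosol", "m": "mitochondrion", "p": "plastid",
                "x": "peroxisome", "v": "vacuole"}[c_]
        b.met(f"GLU_{c_}", comp, c=5, n=1, name="glutamate")
    b.met("ASP_c", "cytosol", c=4, n=1, name="aspartate")
    b.met("ASP_v", "vacuole", c=4, n=1, name="aspartate")
    b.met("ASN_c", "cytosol", c=4, n=2, name="asparagine")
    b.met("ASN_v", "vacuole", c=4, n=2, name="asparagine")
    b.met("PRO_c", "cytosol", c=5, n=1, name="proline")
    b.met("PRO_m", "mitochondrion", c=5, n=1, name="proline")
    b.met("PRO_v", "vacuole", c=5, n=1, name="proline")
    b.met("P5C_c", "cytosol", c=5, n=1, name="1-pyrroline-5-carboxylate")
    b.met("P5C_m", "mitochondrion", c=5, n=1, name="1-pyrroline-5-carboxylate")
    b.met("AA_c", "cytosol", c=5, n=1, name="phloem amino-acid pool")
    b.met("AA_v", "vacuole", c=5, n=1, name="phloem amino-acid pool")

    b.met("SUC_c", "cytosol", c=12, name="sucrose")
    b.met("SUC_v", "vacuole", c=12, name="sucrose")
    b.met("GLC_c", "cytosol", c=6, name="glucose")
    b.met("GLC_v", "vacuole", c=6, name="glucose")
    b.met("FRU_c", "cytosol", c=6, name="fructose")
    b.met("FRU_v", "vacuole", c=6, name="fructose")

    b.met("NO3_e", "extracellular", n=1, name="nitrate")
    b.met("NO3_c", "cytosol", n=1, name="nitrate")
    b.met("NO3_p", "plastid", n=1, name="nitrate")
    b.met("NO3_v", "vacuole", n=1, name="nitrate")
    for c_ in ("c", "p", "m", "x"):
        comp = {"c": "cytosol", "p": "plastid", "m": "mitochondrion",
                "x": "peroxisome"}[c_]
        b.met(f"NH4_{c_}", comp, n=1, name="ammonium")

    # ---- exchanges -----------------------------------------------------
    b.rxn("EX_PHOTON", {"PHOTON_p": 1}, 0, 1000, tags={TAG_EXCHANGE, "LIGHT_UPTAKE"},
          name="photon uptake (bounded by the diel light curve)")
    b.rxn("EX_PHOTON_DISS", {"PHOTON_DISS_e": -1}, 0, 8000, tags={TAG_EXCHANGE})
    b.rxn("EX_CO2_UPTAKE", {"CO2_e": 1}, 0, 1000,
          tags={TAG_EXCHANGE, "CO2_UPTAKE"},
          name="stomatal CO2 uptake (transpiration-costed)")
    b.rxn("EX_CO2_EFFLUX", {"CO2_e": -1}, 0, 1000,
          tags={TAG_EXCHANGE, "CO2_EFFLUX"},
          name="net CO2 efflux (no transpiration cost)")
    b.rxn("EX_NO3", {"NO3_e": 1}, 0, 1000, tags={TAG_EXCHANGE, "NITRATE_UPTAKE"})
    b.rxn("EX_O2", {"O2_e": 1}, -1000, 1000, tags={TAG_EXCHANGE})
    b.rxn("EX_H2O", {"H2O_e": 1}, -1000, 1000, tags={TAG_EXCHANGE})

    # ---- light reactions (lumped) -------------------------------------
    # Linear electron flow: 8 photons -> 3 ATP + 2 NADPH; cyclic: 2 photons -> 1 ATP.
    b.rxn("LEF_p", {"PHOTON_p": -8, "ADP_p": -3, "Pi_p": -3, "NADP_p": -2,
                    "ATP_p": 3, "NADPH_p": 2, "PHOTON_DISS_e": 8},
          0, 1000, name="linear electron flow (lumped)")
    b.rxn("CEF_p", {"PHOTON_p": -2, "ADP_p": -1, "Pi_p": -1,
                    "ATP_p": 1, "PHOTON_DISS_e": 2},
          0, 1000, name="cyclic electron flow (lumped)")

    # ---- Calvin-Benson-Bassham + starch -------------------------------
    b.rxn("RBC_CARB", {"RUBP_p": -1, "CO2_p": -1, "PGA_p": 2}, 0, 1000,
          tags={"RUBISCO_CARB"}, name="Rubisco carboxylase")
    b.rxn("RBC_OXY", {"RUBP_p": -1, "PGA_p": 1, "PGLYC_p": 1}, 0, 1000,
          tags={"RUBISCO_OXY"}, name="Rubisco oxygenase")
    b.rxn("PGA_RED_p", {"PGA_p": -1, "ATP_p": -1, "NADPH_p": -1,
                        "TP_p": 1, "ADP_p": 1, "NADP_p": 1, "Pi_p": 1},
          -1000, 1000, name="phosphoglycerate reduction")
    b.rxn("RUBP_REGEN_p", {"TP_p": -5, "ATP_p": -3, "RUBP_p": 3, "ADP_p": 3,
                           "Pi_p": 2}, 0, 1000, name="RuBP regeneration (lumped)")
    b.rxn("STARCH_SYN_p", {"TP_p": -2, "ATP_p": -1, "STARCH_p": 1, "ADP_p": 1,
                           "Pi_p": 3}, 0, 1000, name="starch synthesis")
    b.rxn("STARCH_DEG_p", {"STARCH_p": -1, "ATP_p": -1, "Pi_p": -1, "TP_p": 2,
                           "ADP_p": 1}, 0, 1000, name="starch degradation")
    b.transport("TPT_pc", "TP_p", "TP_c")

    # ---- photorespiration ---------------------------------------------
    b.rxn("PGP_p", {"PGLYC_p": -1, "GLYCLT_p": 1, "Pi_p": 1}, 0, 1000,
          name="phosphoglycolate phosphatase")
    b.transport("GLYCLT_px", "GLYCLT_p", "GLYCLT_x", lb=0)
    b.rxn("GOX_GGT_x", {"GLYCLT_x": -1, "GLU_x": -1, "GLY_x": 1, "AKG_x": 1},
          0, 1000, name="glycolate oxidase + Glu:glyoxylate aminotransferase (lumped)")
    b.transport("GLY_xm", "GLY_x", "GLY_m", lb=0)
    b.rxn("GDC_m", {"GLY_m": -2, "NAD_m": -1, "SER_m": 1, "CO2_m": 1,
                    "NH4_m": 1, "NADH_m": 1}, 0, 1000,
          tags={"GDC"}, name="glycine decarboxylase system")
    b.transport("SER_mx", "SER_m", "SER_x", lb=0)
    b.rxn("SER_DEAM_x", {"SER_x": -1, "HPYR_x": 1, "NH4_x": 1}, 0, 1000,
          name="serine deamination (lumped)")
    b.rxn("HPR_x", {"HPYR_x": -1, "NADH_x": -1, "GLYCERATE_x": 1, "NAD_x": 1},
          0, 1000, name="hydroxypyruvate reductase")
    b.transport("GLYCERATE_xp", "GLYCERATE_x", "GLYCERATE_p", lb=0)
    b.rxn("GLYK_p", {"GLYCERATE_p": -1, "ATP_p": -1, "PGA_p": 1, "ADP_p": 1},
          0, 1000, name="glycerate kinase")
    b.transport("NH4_xc", "NH4_x", "NH4_c")
    b.transport("GLU_cx", "GLU_c", "GLU_x")
    b.transport("AKG_xc", "AKG_x", "AKG_c")

    # ---- sucrose / hexoses --------------------------------------------
    b.rxn("SUC_SYN_c", {"TP_c": -4, "SUC_c": 1, "Pi_c": 4}, 0, 1000,
          name="sucrose synthesis (lumped)")
    b.rxn("INV_c", {"SUC_c": -1, "GLC_c": 1, "FRU_c": 1}, 0, 1000,
          name="invertase")
    b.rxn("HXK_GLC_c", {"GLC_c": -1, "ATP_c": -2, "TP_c": 2, "ADP_c": 2},
          0, 1000, name="glucose -> triose phosphate (lumped glycolysis upper)")
    b.rxn("HXK_FRU_c", {"FRU_c": -1, "ATP_c": -2, "TP_c": 2, "ADP_c": 2},
          0, 1000, name="fructose -> triose phosphate (lumped glycolysis upper)")

    # ---- glycolysis / PEP ---------------------------------------------
    b.rxn("GAPDH_PGK_c", {"TP_c": -1, "NAD_c": -1, "ADP_c": -1, "Pi_c": -1,
                          "PGA_c": 1, "NADH_c": 1, "ATP_c": 1}, -1000, 1000,
          name="GAPDH + phosphoglycerate kinase")
    b.rxn("ENO_c", {"PGA_c": -1, "PEP_c": 1}, -1000, 1000,
          name="phosphoglycerate mutase + enolase")
    b.rxn("PK_c", {"PEP_c": -1, "ADP_c": -1, "PYR_c": 1, "ATP_c": 1}, 0, 1000,
          name="pyruvate kinase")
    b.rxn("CA_c", {"CO2_c": -1, "HCO3_c": 1}, -1000, 1000,
          name="carbonic anhydrase")
    b.rxn("PEPC_c", {"PEP_c": -1, "HCO3_c": -1, "OAA_c": 1, "Pi_c": 1}, 0, 1000,
          tags={"PEPC"}, name="PEP carboxylase")

    # ---- TCA cycle and anaplerosis ------------------------------------
    b.transport("PYR_cm", "PYR_c", "PYR_m")
    b.rxn("PDH_m", {"PYR_m": -1, "NAD_m": -1, "COA_m": -1, "ACCOA_m": 1,
                    "CO2_m": 1, "NADH_m": 1}, 0, 1000,
          name="pyruvate dehydrogenase")
    b.rxn("CS_m", {"ACCOA_m": -1, "OAA_m": -1, "CIT_m": 1, "COA_m": 1}, 0, 1000,
          tags={"CS_M"}, name="citrate synthase (mitochondrial)")
    b.rxn("ACO_m", {"CIT_m": -1, "ICIT_m": 1}, -1000, 1000,
          tags={"ACONITASE_M"}, name="aconitase (mitochondrial)")
    icdh_lb = -1000.0 if opt.icdh_reversible else 0.0
    b.rxn("ICDH_m", {"ICIT_m": -1, "NAD_m": -1, "AKG_m": 1, "CO2_m": 1,
                     "NADH_m": 1}, icdh_lb, 1000,
          tags={"ICDH_M"}, name="isocitrate dehydrogenase (mitochondrial)")
    b.rxn("AKGDH_MDH_m", {"AKG_m": -1, "NAD_m": -2, "ADP_m": -1, "Pi_m": -1,
                          "MAL_m": 1, "CO2_m": 1, "NADH_m": 2, "ATP_m": 1},
          0, 1000, name="2OG -> malate (lumped 2OG dehydrogenase branch)")
    b.rxn("MDH_m", {"MAL_m": -1, "NAD_m": -1, "OAA_m": 1, "NADH_m": 1},
          -1000, 1000, name="malate dehydrogenase (mitochondrial)")
    b.rxn("ME_NAD_m", {"MAL_m": -1, "NAD_m": -1, "PYR_m": 1, "CO2_m": 1,
                       "NADH_m": 1}, 0, 1000, name="NAD-malic enzyme")
    b.transport("OAA_cm", "OAA_c", "OAA_m")
    b.transport("MAL_cm", "MAL_c", "MAL_m")
    b.transport("CIT_mc", "CIT_m", "CIT_c")
    b.transport("ICIT_mc", "ICIT_m", "ICIT_c")
    b.transport("AKG_cm", "AKG_c", "AKG_m")
    b.transport("GLU_cm", "GLU_c", "GLU_m")
    b.transport("PRO_cm", "PRO_c", "PRO_m")

    # ---- cytosolic organic-acid metabolism -----------------------------
    b.rxn("MDH_c", {"OAA_c": -1, "NADH_c": -1, "MAL_c": 1, "NAD_c": 1},
          -1000, 1000, name="malate dehydrogenase (cytosolic)")
    b.rxn("ACO_c", {"CIT_c": -1, "ICIT_c": 1}, -1000, 1000,
          tags={"ACONITASE_C"}, name="aconitase (cytosolic)")
    b.rxn("ICDH_c", {"ICIT_c": -1, "NADP_c": -1, "AKG_c": 1, "CO2_c": 1,
                     "NADPH_c": 1}, -1000, 1000,
          tags={"ICDH_C"}, name="isocitrate dehydrogenase (cytosolic, NADP)")
    b.rxn("ME_NADP_c", {"MAL_c": -1, "NADP_c": -1, "PYR_c": 1, "CO2_c": 1,
                        "NADPH_c": 1}, 0, 1000, name="NADP-malic enzyme")
    b.rxn("ACL_c", {"CIT_c": -1, "ATP_c": -1, "COA_c": -1, "ACCOA_c": 1,
                    "OAA_c": 1, "ADP_c": 1, "Pi_c": 1}, 0, 1000,
          name="ATP-citrate lyase")
    b.rxn("ASPAT_c", {"OAA_c": -1, "GLU_c": -1, "ASP_c": 1, "AKG_c": 1},
          -1000, 1000, tags={"ASP_AT"}, name="aspartate aminotransferase")
    b.rxn("ASN_SYN_c", {"ASP_c": -1, "NH4_c": -1, "ATP_c": -1, "ASN_c": 1,
                        "ADP_c": 1, "Pi_c": 1}, 0, 1000,
          name="asparagine synthesis")
    b.rxn("AA_SYN_c", {"AKG_c": -1, "NH4_c": -1, "NADPH_c": -1, "AA_c": 1,
                       "NADP_c": 1}, 0, 1000,
          name="phloem amino-acid pool synthesis (lumped)")

    # ---- peroxisomal citrate branch -----------------------------------
    b.rxn("ACCOA_SHUTTLE_cx", {"ACCOA_c": -1, "COA_x": -1, "ACCOA_x": 1,
                               "COA_c": 1}, -1000, 1000,
          name="acetyl-CoA/CoA antiport (cytosol/peroxisome)")
    b.rxn("CS_x", {"ACCOA_x": -1, "OAA_x": -1, "CIT_x": 1, "COA_x": 1}, 0, 1000,
          tags={"CS_X"}, name="citrate synthase (peroxisomal)")
    b.rxn("MDH_x", {"MAL_x": -1, "NAD_x": -1, "OAA_x": 1, "NADH_x": 1},
          -1000, 1000, name="malate dehydrogenase (peroxisomal)")
    b.transport("OAA_cx", "OAA_c", "OAA_x")
    b.transport("MAL_cx", "MAL_c", "MAL_x")
    b.transport("CIT_xc", "CIT_x", "CIT_c")

    # ---- proline cycle -------------------------------------------------
    b.rxn("P5CS_c", {"GLU_c": -1, "ATP_c": -1, "NADPH_c": -1, "P5C_c": 1,
                     "ADP_c": 1, "Pi_c": 1, "NADP_c": 1}, 0, 1000,
          tags={"P5CS"}, name="P5C synthetase")
    b.rxn("P5CR_c", {"P5C_c": -1, "NADPH_c": -1, "PRO_c": 1, "NADP_c": 1},
          0, 1000, tags={"P5CR"}, name="P5C reductase")
    b.rxn("PRODH_m", {"PRO_m": -1, "NAD_m": -1, "P5C_m": 1, "NADH_m": 1},
          0, 1000, tags={"PRODH"}, name="proline dehydrogenase")
    b.rxn("P5CDH_m", {"P5C_m": -1, "NAD_m": -1, "GLU_m": 1, "NADH_m": 1},
          0, 1000, tags={"P5CDH"}, name="P5C dehydrogenase")
    b.rxn("GDH_m", {"GLU_m": -1, "NAD_m": -1, "AKG_m": 1, "NH4_m": 1,
                    "NADH_m": 1}, -1000, 1000, tags={"GDH"},
          name="glutamate dehydrogenase")
    b.transport("NH4_mc", "NH4_m", "NH4_c")

    # ---- nitrate assimilation -----------------------------------------
    b.transport("NO3_ec", "NO3_e", "NO3_c", lb=0)
    b.transport("NO3_cp", "NO3_c", "NO3_p")
    b.rxn("NR_NIR_p", {"NO3_p": -1, "NADPH_p": -4, "NH4_p": 1, "NADP_p": 4},
          0, 1000, name="nitrate + nitrite reductase (lumped)")
    b.rxn("GS_GOGAT_p", {"AKG_p": -1, "NH4_p": -1, "ATP_p": -1, "NADPH_p": -1,
                         "GLU_p": 1, "ADP_p": 1, "Pi_p": 1, "NADP_p": 1},
          0, 1000, name="GS/GOGAT (lumped)")
    b.transport("GLU_pc", "GLU_p", "GLU_c")
    b.transport("AKG_cp", "AKG_c", "AKG_p")
    b.transport("NH4_cp", "NH4_c", "NH4_p")

    # ---- energy shuttles and maintenance ------------------------------
    b.rxn("OXPHOS_m", {"NADH_m": -1, "ADP_m": -2.5, "Pi_m": -2.5, "NAD_m": 1,
                       "ATP_m": 2.5}, 0, 1000,
          name="oxidative phosphorylation (lumped, P/O 2.5)")
    b.rxn("NADH_SHUTTLE_cm", {"NADH_c": -1, "NAD_m": -1, "NAD_c": 1,
                              "NADH_m": 1}, -1000, 1000,
          name="malate/OAA redox shuttle (lumped)")
    b.rxn("NADPH_SHUTTLE_cp", {"NADPH_p": -1, "NADP_c": -1, "NADP_p": 1,
                               "NADPH_c": 1}, -1000, 1000,
          name="plastid/cytosol redox shuttle (lumped)")
    b.rxn("ANT_m", {"ATP_m": -1, "ADP_c": -1, "ADP_m": 1, "ATP_c": 1},
          -1000, 1000, name="adenine nucleotide translocator (mitochondrial)")
    b.rxn("ANT_p", {"ATP_p": -1, "ADP_c": -1, "ADP_p": 1, "ATP_c": 1},
          -1000, 1000, name="adenine nucleotide translocator (plastidial)")
    b.transport("PI_cp", "Pi_c", "Pi_p")
    b.transport("PI_cm", "Pi_c", "Pi_m")
    b.rxn("ATP_MAINT_c", {"ATP_c": -1, "ADP_c": 1, "Pi_c": 1}, 0, 1000,
          tags={"ATP_MAINT"}, name="ATP maintenance sink")
    b.rxn("NADPH_MAINT_c", {"NADPH_c": -1, "NADP_c": 1}, 0, 1000,
          tags={"NADPH_MAINT"}, name="NADPH maintenance sink")

    # ---- CO2 transport -------------------------------------------------
    b.transport("CO2_ec", "CO2_e", "CO2_c")
    b.transport("CO2_cp", "CO2_c", "CO2_p")
    b.transport("CO2_cm", "CO2_c", "CO2_m")
    b.transport("CO2_cx", "CO2_c", "CO2_x")
    # CO2 produced in the peroxisome does not occur in this lump set, but the
    # pool and transporter keep the compartment closed for budget reporting.

    # ---- vacuolar transporters ----------------------------------------
    vac_pairs = [
        ("MAL", "MAL_c", "MAL_v"), ("CIT", "CIT_c", "CIT_v"),
        ("ICIT", "ICIT_c", "ICIT_v"), ("GLC", "GLC_c", "GLC_v"),
        ("FRU", "FRU_c", "FRU_v"), ("SUC", "SUC_c", "SUC_v"),
        ("GLU", "GLU_c", "GLU_v"), ("ASP", "ASP_c", "ASP_v"),
        ("ASN", "ASN_c", "ASN_v"), ("PRO", "PRO_c", "PRO_v"),
        ("AA", "AA_c", "AA_v"), ("NO3", "NO3_c", "NO3_v"),
    ]
    for stem, src, dst in vac_pairs:
        b.transport(f"VAC_{stem}", src, dst, tags={TAG_VACUOLAR_TRANSPORT})

    # ---- phloem export -------------------------------------------------
    f_suc = opt.phloem_sucrose_fraction
    b.rxn("PHLOEM_EXPORT",
          {"SUC_c": -f_suc, "AA_c": -(1.0 - f_suc), "ATP_c": -1.0,
           "ADP_c": 1.0, "Pi_c": 1.0},
          0, 1000, tags={TAG_EXCHANGE, "PHLOEM_EXPORT"},
          name="phloem loading and export (fixed sap composition)")

    storables = ["STARCH_p", "GLC_v", "FRU_v", "SUC_v", "MAL_v", "CIT_v",
                 "ICIT_v", "GLU_v", "ASP_v", "ASN_v", "PRO_v", "AA_v", "NO3_v"]
    return MetabolicNetwork(list(b.mets.values()), b.rxns, storables)


# ---------------------------------------------------------------------------
# Consistency and feasibility checks
# ---------------------------------------------------------------------------

def check_mass_consistency(net: MetabolicNetwork, tol: float = 1e-9) -> bool:
    """Test stoichiometric consistency: does a strictly positive metabolite
    weighting ``w`` exist with ``w^T S = 0`` over all non-exchange reactions?

    Extracellular species may take any non-negative weight (boundary
    conditions), every other metabolite must get weight >= 1. Failure means
    some internal reaction combination creates mass from nothing.
    """
    S = net.stoichiometric_matrix()
    internal_cols = [j for j, r in enumerate(net.reactions) if not r.is_exchange]
    A = S[:, internal_cols].T.tocsc()  # rows: internal reactions, cols: metabolites
    n_mets = len(net.metabolites)
    lb = np.ones(n_mets)
    for i, met in enumerate(net.metabolites):
        if met.compartment == "extracellular":
            lb[i] = 0.0
    res = linprog(
        c=np.zeros(n_mets),
        A_eq=A, b_eq=np.zeros(A.shape[0]),
        bounds=list(zip(lb, np.full(n_mets, 1e6))),
        method="highs",
    )
    return bool(res.status == 0)


def has_nonzero_steady_flux(net: MetabolicNetwork, tol: float = 1e-6) -> bool:
    """Check that S v = 0 admits a nonzero feasible flux vector.

    Maximizes CO2 uptake subject to steady state and bounds; any optimum above
    ``tol`` certifies a carbon-carrying feasible mode.
    """
    S = net.stoichiometric_matrix()
    bnds = net.bounds
    c = np.zeros(len(net.reactions))
    c[net.reaction_index(net.find_by_tag("CO2_UPTAKE").id)] = -1.0
    res = linprog(c=c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(map(tuple, bnds)), method="highs")
    return bool(res.status == 0 and -res.fun > tol)


# ---------------------------------------------------------------------------
# SBML I/O (via cobrapy)
# ---------------------------------------------------------------------------

#: Default mapping from SBML compartment ids/names to the compartment enum.
DEFAULT_COMPARTMENT_PATTERNS = {
    "cytosol": r"^(c$|cyt)",
    "plastid": r"^(p$|plast|chloroplast)",
    "mitochondrion": r"^(m$|mit)",
    "peroxisome": r"^(x$|per)",
    "vacuole": r"^(v$|vac)",
    "extracellular": r"^(e$|ext|out|boundary|env)",
}

#: Default id-pattern rules assigning role tags to SBML reactions.
DEFAULT_TAG_PATTERNS = {
    "PEPC": r"(pepc|PEPCARBOX)",
    "ICDH_M": r"(icdh|isocit).*_m\b",
    "ICDH_C": r"(icdh|isocit).*_c\b",
    "RUBISCO_CARB": r"(rbc|rubisco).*(carb|c\b)",
    "RUBISCO_OXY": r"(rbc|rubisco).*(oxy|o\b)",
    "GDC": r"(gdc|glycine.?decarb|gly.*cleav)",
    "PHLOEM_EXPORT": r"(phloem)",
    "NITRATE_UPTAKE": r"(no3|nitrate).*(tx|uptake|ex)",
    "CO2_UPTAKE": r"(co2).*(tx|uptake|ex)",
    "ATP_MAINT": r"(atp).*(maint|ase_su)",
    "NADPH_MAINT": r"(nadph).*(maint|ox)",
    "LIGHT_UPTAKE": r"(photon|light)",
}

#: Storable name patterns (metabolite name regex, storage compartment).
DEFAULT_STORABLE_PATTERNS = [
    (r"^starch", "plastid"),
    (r"^glucose", "vacuole"), (r"^fructose", "vacuole"), (r"^sucrose", "vacuole"),
    (r"^(l-)?malate", "vacuole"), (r"^citrate", "vacuole"),
    (r"^isocitrate", "vacuole"), (r"^nitrate", "vacuole"),
    (r"^(l-)?(alanine|arginine|asparagine|aspartate|cysteine|glutamate|"
     r"glutamine|glycine|histidine|isoleucine|leucine|lysine|methionine|"
     r"phenylalanine|proline|serine|threonine|tryptophan|tyrosine|valine)",
     "vacuole"),
]


class SBMLParseError(ValueError):
    pass


class TagConfigurationError(ValueError):
    pass


def _map_compartment(raw: str, patterns: Mapping[str, str]) -> str:
    for comp, pat in patterns.items():
        if re.search(pat, raw, re.IGNORECASE):
            return comp
    raise SBMLParseError(f"cannot map SBML compartment {raw!r} to the compartment enum")


def _carbon_nitrogen(formula: str | None):
    if not formula:
        return 0, 0
    c = re.search(r"C(\d*)(?![a-z])", formula)
    n = re.search(r"N(\d*)(?![a-z])", formula)
    cnt = lambda m: (int(m.group(1)) if m.group(1) else 1) if m else 0
    return cnt(c), cnt(n)


def read_sbml(path, tag_patterns: Mapping[str, str] | None = None,
              compartment_patterns: Mapping[str, str] | None = None,
              storable_patterns=None,
              required_roles=REQUIRED_ROLES) -> MetabolicNetwork:
    """Read a compartmented SBML model (Level 3 FBC preferred, Level 2
    accepted) into a :class:`MetabolicNetwork`.

    Role tags are assigned by configurable regular-expression rules on
    reaction ids/names; required roles that resolve to no reaction are
    reported in a :class:`TagConfigurationError` listing the patterns tried.
    """
    import cobra.io

    tag_patterns = dict(DEFAULT_TAG_PATTERNS if tag_patterns is None else tag_patterns)
    compartment_patterns = dict(
        DEFAULT_COMPARTMENT_PATTERNS if compartment_patterns is None
        else compartment_patterns
    )
    storable_patterns = (DEFAULT_STORABLE_PATTERNS if storable_patterns is None
                         else storable_patterns)
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several io error types
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc

    mets = []
    for met in model.metabolites:
        comp_raw = met.compartment or ""
        comp_name = model.compartments.get(comp_raw) or comp_raw
        comp = _map_compartment(str(comp_name) or str(comp_raw), compartment_patterns)
        n_c, n_n = _carbon_nitrogen(met.formula)
        ident = f"{met.id} {met.name or ''}"
        mets.append(Metabolite(
            id=met.id, name=met.name or met.id, compartment=comp,
            carries_carbon=n_c > 0 or bool(_CO2_PATTERN.search(ident)),
            is_co2_species=bool(_CO2_PATTERN.search(ident)),
            n_carbon=n_c, n_nitrogen=n_n,
        ))
    met_by_id = {m.id: m for m in mets}

    rxns = []
    for rxn in model.reactions:
        tags = set()
        if rxn.boundary:
            tags.add(TAG_EXCHANGE)
        ident = f"{rxn.id} {rxn.name or ''}"
        for tag, pat in tag_patterns.items():
            if re.search(pat, ident, re.IGNORECASE):
                tags.add(tag)
        comps = {met_by_id[m.id].compartment for m in rxn.metabolites}
        if "vacuole" in comps and len(comps) > 1:
            tags.add(TAG_VACUOLAR_TRANSPORT)
        rxns.append(Reaction(
            id=rxn.id,
            stoichiometry={m.id: coeff for m, coeff in rxn.metabolites.items()},
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            tags=tags, name=rxn.name or rxn.id,
        ))

    storables = []
    for met in mets:
        for pat, comp in storable_patterns:
            if met.compartment == comp and re.search(pat, met.name, re.IGNORECASE):
                storables.append(met.id)
                break

    net = MetabolicNetwork(mets, rxns, storables)
    missing = net.missing_roles(required_roles)
    if missing:
        tried = {t: tag_patterns.get(t, "<no pattern>") for t in missing}
        raise TagConfigurationError(
            f"no reaction matches the required role patterns {tried}; "
            "adjust the tag-pattern configuration"
        )
    return net


_COMP_SHORT = {"cytosol": "c", "plastid": "p", "mitochondrion": "m",
               "peroxisome": "x", "vacuole": "v", "extracellular": "e"}


def write_sbml(net: MetabolicNetwork, path) -> None:
    """Write a network as SBML Level 3 + FBC via cobrapy."""
    import cobra
    import cobra.io

    model = cobra.Model("dielfba_network")
    model.compartments = {_COMP_SHORT[c]: c for c in COMPARTMENTS}
    cobra_mets = {}
    for met in net.metabolites:
        cm = cobra.Metabolite(
            met.id, name=met.name, compartment=_COMP_SHORT[met.compartment],
        )
        formula = ""
        if met.n_carbon:
            formula += f"C{met.n_carbon}"
        if met.n_nitrogen:
            formula += f"N{met.n_nitrogen}"
        cm.formula = formula or None
        cobra_mets[met.id] = cm
    model.add_metabolites(list(cobra_mets.values()))
    cobra_rxns = []
    for rxn in net.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        cobra_rxns.append(cr)
    model.add_reactions(cobra_rxns)
    for rxn, cr in zip(net.reactions, cobra_rxns):
        cr.add_metabolites({cobra_mets[mid]: coeff
                            for mid, coeff in rxn.stoichiometry.items()})
    cobra.io.write_sbml_model(model, str(path))
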