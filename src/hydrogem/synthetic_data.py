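"""Desk-scale synthetic inputs: a core dark-fermentation network and tables.

The core network emulates the fermentative metabolism of an
*Ethanoligenens*-like hydrogen producer: glucose uptake, Embden-Meyerhof
glycolysis, the pyruvate node (ferredoxin oxidoreductase and formate lyase +
formate-hydrogen lyase), the ATP-yielding acetate branch, the NADH-consuming
ethanol branch, lactate, ferredoxin- and NADH-dependent hydrogenases, and an
anaplerotic PEP -> oxaloacetate -> 2-oxoglutarate -> glutamate/glutamine
branch. All internal and transport reactions are elementally and charge
balanced; the toy biomass and exchanges are the only unbalanced
pseudo-reactions.

The stoichiometry fixes three analytic hydrogen-yield anchors on glucose
(mol H2 per mol glucose): 4 when all acetyl-CoA leaves as acetate and both
hydrogenases run, 2 when NADH can only be reoxidised by the ethanol branch,
and 3 when ethanol:acetate coupling is imposed but carbon may leave as
glutamate/glutamine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cobra import Gene, Metabolite, Model, Reaction
from cobra.core.gene import GPR

from hydrogem.biomass_builder import MacroComposition, MonomerProfile
from hydrogem.ec_builder import EcConfig, EnzymeTable, enzyme_fraction_f
from hydrogem.model_core import reaction_kind
from hydrogem.phenotype import PhenotypeTable, carbon_source_growth

__all__ = [
    "build_core_network",
    "degrade_model",
    "synth_enzyme_tables",
    "reference_enzyme_table",
    "synth_composition",
    "synth_phenotype_table",
    "GLUCOSE_UPTAKE_DEFAULT",
]

GLUCOSE_UPTAKE_DEFAULT = 10.0  # mmol gDW-1 h-1

# id -> (name, formula, charge); compartment suffix appended separately
_SPECIES = {
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "fru": ("D-fructose", "C6H12O6", 0),
    "xyl__D": ("D-xylose", "C5H10O5", 0),
    "g6p": ("D-glucose 6-phosphate", "C6H11O9P", -2),
    "f6p": ("D-fructose 6-phosphate", "C6H11O9P", -2),
    "fdp": ("D-fructose 1,6-bisphosphate", "C6H10O12P2", -4),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P", -2),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    "13dpg": ("1,3-bisphospho-D-glycerate", "C3H4O10P2", -4),
    "3pg": ("3-phospho-D-glycerate", "C3H4O7P", -3),
    "2pg": ("2-phospho-D-glycerate", "C3H4O7P", -3),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "actp": ("acetyl phosphate", "C2H3O5P", -2),
    "ac": ("acetate", "C2H3O2", -1),
    "acald": ("acetaldehyde", "C2H4O", 0),
    "etoh": ("ethanol", "C2H6O", 0),
    "lac__L": ("L-lactate", "C3H5O3", -1),
    "for": ("formate", "CHO2", -1),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("orthophosphate", "HO4P", -2),
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
    "co2": ("carbon dioxide", "CO2", 0),
    "h2": ("dihydrogen", "H2", 0),
    "fdox": ("oxidised ferredoxin", "Fe8S8", 0),
    "fdrd": ("reduced ferredoxin", "Fe8S8", -2),
    "nh4": ("ammonium", "H4N", 1),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    "cit": ("citrate", "C6H5O7", -3),
    "icit": ("isocitrate", "C6H5O7", -3),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "gln__L": ("L-glutamine", "C5H10N2O3", 0),
}

REV = (-1000.0, 1000.0)
FWD = (0.0, 1000.0)

# rid: (stoichiometry on cytosolic/extracellular species, bounds, gpr string)
_CORE_REACTIONS = {
    # glucose uptake and glycolysis
    "GLCt": ({"glc__D_e": -1, "glc__D_c": 1}, FWD, "g_glcT"),
    "HEX1": ({"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, FWD, "g_hex1"),
    "PGI": ({"g6p_c": -1, "f6p_c": 1}, REV, "g_pgi"),
    "PFK": ({"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, FWD, "g_pfk"),
    "FBA": ({"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, REV, "g_fba"),
    "TPI": ({"dhap_c": -1, "g3p_c": 1}, REV, "g_tpi"),
    "GAPD": ({"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1, "nadh_c": 1, "h_c": 1}, REV, "g_gapd"),
    "PGK": ({"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1}, REV, "g_pgk"),
    "PGM": ({"3pg_c": -1, "2pg_c": 1}, REV, "g_pgm"),
    "ENO": ({"2pg_c": -1, "pep_c": 1, "h2o_c": 1}, REV, "g_eno"),
    "PYK": ({"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1}, FWD, "g_pyk"),
    # pyruvate node
    "PFOR": ({"pyr_c": -1, "coa_c": -1, "fdox_c": -1,
              "accoa_c": 1, "co2_c": 1, "fdrd_c": 1, "h_c": 1}, FWD, "g_pfor"),
    # acetate branch (substrate-level ATP)
    "PTA": ({"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1}, REV, "g_pta"),
    "ACK": ({"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, REV, "g_ack"),
    # ethanol branch (NADH sink)
    "ALDH": ({"accoa_c": -1, "nadh_c": -1, "h_c": -1, "acald_c": 1, "coa_c": 1, "nad_c": 1}, REV, "g_aldh"),
    "ADH": ({"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1}, REV, "g_adh1 or g_adh2"),
    # hydrogenases
    "HYDF": ({"fdrd_c": -1, "h_c": -2, "h2_c": 1, "fdox_c": 1}, FWD, "g_hydA and g_hydB"),
    "HYDN": ({"nadh_c": -1, "h_c": -1, "h2_c": 1, "nad_c": 1}, FWD, "g_hydN"),
    # anaplerosis and glutamate/glutamine biosynthesis
    "PPC": ({"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1, "h_c": 1}, FWD, "g_ppc"),
    "CS": ({"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1, "h_c": 1}, FWD, "g_cs"),
    "ACONT": ({"cit_c": -1, "icit_c": 1}, REV, "g_acn"),
    "ICDH": ({"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1}, FWD, "g_icd"),
    "GDH": ({"akg_c": -1, "nh4_c": -1, "nadph_c": -1, "h_c": -1,
             "glu__L_c": 1, "h2o_c": 1, "nadp_c": 1}, FWD, "g_gdh"),
    "GLNS": ({"glu__L_c": -1, "nh4_c": -1, "atp_c": -1,
              "gln__L_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1}, FWD, "g_glns"),
    # maintenance
    "ATPM": ({"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, (0.81, 1000.0), ""),
    # transport
    "H2t": ({"h2_c": -1, "h2_e": 1}, REV, ""),
    "CO2t": ({"co2_c": -1, "co2_e": 1}, REV, ""),
    "ACt": ({"ac_c": -1, "ac_e": 1}, FWD, "g_acT"),
    "ETOHt": ({"etoh_c": -1, "etoh_e": 1}, REV, ""),
    "FORt": ({"for_c": -1, "for_e": 1}, FWD, ""),
    "GLUt": ({"glu__L_c": -1, "glu__L_e": 1}, FWD, "g_gluT"),
    "GLNt": ({"gln__L_c": -1, "gln__L_e": 1}, FWD, "g_glnT"),
    "NH4t": ({"nh4_e": -1, "nh4_c": 1}, FWD, ""),
    "PIt": ({"pi_e": -1, "pi_c": 1}, FWD, ""),
    "H2Ot": ({"h2o_e": -1, "h2o_c": 1}, REV, ""),
    "Ht": ({"h_e": -1, "h_c": 1}, REV, ""),
}

_LACTATE_REACTIONS = {
    "LDH": ({"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__L_c": 1, "nad_c": 1}, REV, "g_ldh"),
    "LACt": ({"lac__L_c": -1, "lac__L_e": 1}, FWD, ""),
}

_PFL_REACTIONS = {
    "PFL": ({"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1}, FWD, "g_pfl"),
    "FHL": ({"for_c": -1, "h_c": -1, "h2_c": 1, "co2_c": 1}, FWD, "g_fhlA and g_fhlB"),
}

# non-phosphorylating GAPDH + transhydrogenase: an ATP-free bypass of the
# PGK step; deleting PGK then removes two substrate-level ATP per glucose
_ATP_BYPASS_REACTIONS = {
    "GAPN": ({"g3p_c": -1, "nadp_c": -1, "h2o_c": -1,
              "3pg_c": 1, "nadph_c": 1, "h_c": 2}, FWD, "g_gapn"),
    "THD": ({"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1}, FWD, "g_thd"),
}

_ALT_SUGAR_REACTIONS = {
    # fructose is catabolised; xylose is transported but has no pathway
    "FRUt": ({"fru_e": -1, "fru_c": 1}, FWD, "g_fruT"),
    "FRUK": ({"fru_c": -1, "atp_c": -1, "f6p_c": 1, "adp_c": 1, "h_c": 1}, FWD, "g_fruK"),
    "XYLt": ({"xyl__D_e": -1, "xyl__D_c": 1}, FWD, "g_xylT"),
}

# exchange id -> (species, lower bound); upper bound 1000
_EXCHANGES = {
    "EX_glc__D_e": ("glc__D", -GLUCOSE_UPTAKE_DEFAULT),
    "EX_fru_e": ("fru", 0.0),
    "EX_xyl__D_e": ("xyl__D", 0.0),
    "EX_h2_e": ("h2", 0.0),
    "EX_co2_e": ("co2", 0.0),
    "EX_ac_e": ("ac", 0.0),
    "EX_etoh_e": ("etoh", 0.0),
    "EX_lac__L_e": ("lac__L", 0.0),
    "EX_for_e": ("for", 0.0),
    "EX_glu__L_e": ("glu__L", 0.0),   # closed by default; opened per scenario
    "EX_gln__L_e": ("gln__L", 0.0),
    "EX_nh4_e": ("nh4", -1000.0),
    "EX_pi_e": ("pi", -1000.0),
    "EX_h2o_e": ("h2o", -1000.0),
    "EX_h_e": ("h", -1000.0),
}

# Toy biomass: precursor drains sized so that the unconstrained model grows at
# roughly 0.5 1/h at a glucose uptake of 10 mmol/gDW/h (an arbitrary, fixed
# fixture choice, not a measured value). ATP demand dominates, so growth is
# energy-limited, which is what makes acetate overflow the growth-optimal
# strategy and gives the PGK knockout its hydrogen phenotype.
BIOMASS_COEFFS = {
    "g6p_c": -0.3,
    "pep_c": -0.2,
    "pyr_c": -0.4,
    "accoa_c": -2.5,
    # NADPH demand matches the AKG-coupled ICDH supply exactly, so growth is
    # redox-feasible with or without the GAPN/transhydrogenase bypass
    "akg_c": -1.2,
    "nadph_c": -1.2,
    "atp_c": -70.0,
    "h2o_c": -70.0,
    "adp_c": 70.0,
    "pi_c": 70.0,
    "h_c": 70.0,
    "coa_c": 2.5,
    "nadp_c": 1.2,
}

BIOMASS_ID = "BIOMASS"


def _metabolite(species: str, compartment: str) -> Metabolite:
    name, formula, charge = _SPECIES[species]
    return Metabolite(
        f"{species}_{compartment}", name=name, formula=formula,
        charge=charge, compartment=compartment,
    )


def build_core_network(
    include_amino_acids: bool = True,
    include_lactate: bool = True,
    include_pfl: bool = True,
    include_atp_bypass: bool = True,
    include_alt_sugars: bool = True,
    glucose_uptake: float = GLUCOSE_UPTAKE_DEFAULT,
) -> Model:
    """Build the core fermentation network fixture.

    Toggles drop the glutamate/glutamine branch, the lactate branch, the
    pyruvate-formate-lyase + formate-hydrogen-lyase route, the ATP-free
    PGK bypass (GAPN + transhydrogenase), or the alternative-sugar uptake
    systems. The returned model grows on glucose and is mass- and
    charge-balanced in every internal and transport reaction.
    """
    amino_acid_ids = {"PPC", "CS", "ACONT", "ICDH", "GDH", "GLNS",
                      "GLUt", "GLNt"}
    tables = [
        {k: v for k, v in _CORE_REACTIONS.items()
         if include_amino_acids or k not in amino_acid_ids},
    ]
    if include_lactate:
        tables.append(_LACTATE_REACTIONS)
    if include_pfl:
        tables.append(_PFL_REACTIONS)
    if include_atp_bypass:
        tables.append(_ATP_BYPASS_REACTIONS)
    if include_alt_sugars:
        tables.append(_ALT_SUGAR_REACTIONS)

    model = Model("core_ferm")
    mets: dict[str, Metabolite] = {}

    def get_met(mid: str) -> Metabolite:
        if mid not in mets:
            species, compartment = mid.rsplit("_", 1)
            mets[mid] = _metabolite(species, compartment)
        return mets[mid]

    reactions = []
    for table in tables:
        for rid, (stoich, bounds, gpr) in table.items():
            rxn = Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
            rxn.add_metabolites({get_met(m): c for m, c in stoich.items()})
            if gpr:
                rxn.gpr = GPR.from_string(gpr)
            reactions.append(rxn)

    for rid, (species, lb) in _EXCHANGES.items():
        if species in ("glu__L", "gln__L") and not include_amino_acids:
            continue
        if species == "lac__L" and not include_lactate:
            continue
        if species in ("fru", "xyl__D") and not include_alt_sugars:
            continue
        lb = -glucose_uptake if rid == "EX_glc__D_e" else lb
        rxn = Reaction(rid, lower_bound=lb, upper_bound=1000.0)
        rxn.add_metabolites({get_met(f"{species}_e"): -1})
        reactions.append(rxn)

    biomass = Reaction(BIOMASS_ID, lower_bound=0.0, upper_bound=1000.0)
    biomass.add_metabolites({get_met(m): c for m, c in BIOMASS_COEFFS.items()})
    # the protein-synthesis machinery (ribosome analog) catalyses biomass
    # formation, so the enzyme-constrained variant charges growth itself
    # against the shared pool
    biomass.gpr = GPR.from_string("g_ribo")
    reactions.append(biomass)

    model.add_reactions(reactions)
    model.objective = BIOMASS_ID
    model.compartments = {"c": "cytosol", "e": "extracellular"}
    return model


def _essential_internal_reactions(model: Model, threshold: float = 0.05) -> list[str]:
    """Gene-bearing internal reactions whose single removal drops growth below threshold."""
    essential = []
    for rxn in model.reactions:
        if reaction_kind(rxn) != "internal" or not rxn.genes:
            continue
        with model:
            rxn.knock_out()
            growth = model.slim_optimize(error_value=0.0)
        if not np.isfinite(growth) or growth < threshold:
            essential.append(rxn.id)
    return essential


def degrade_model(
    model: Model, n_remove: int, seed: int, growth_threshold: float = 0.05
) -> tuple[Model, set[str]]:
    """Remove ``n_remove`` growth-essential biosynthetic reactions at random.

    Sampling is restricted to gene-bearing internal reactions that are
    individually essential for growth above ``growth_threshold``, so every
    degraded model is guaranteed to need gap-filling. Deterministic per seed.
    """
    candidates = _essential_internal_reactions(model, growth_threshold)
    if n_remove > len(candidates):
        raise ValueError(
            f"n_remove={n_remove} exceeds the {len(candidates)} essential candidates"
        )
    rng = np.random.default_rng(seed)
    removed = set(rng.choice(sorted(candidates), size=n_remove, replace=False).tolist())
    degraded = model.copy()
    degraded.remove_reactions([degraded.reactions.get_by_id(r) for r in removed])
    return degraded, removed


# Curated turnover numbers (1/s) for the reference enzyme table. The contrast
# that matters is physiological: the ferredoxin hydrogenase is fast, the
# NADH-dependent hydrogenase (thermodynamically uphill) is slow, so under an
# enzyme-pool constraint NADH reoxidation via ethanol is the cheap strategy.
_REFERENCE_KCATS = {
    "GLCt": 150.0, "HEX1": 25.0, "PGI": 30.0, "PFK": 25.0, "FBA": 20.0,
    "TPI": 60.0, "GAPD": 25.0, "PGK": 30.0, "PGM": 30.0, "ENO": 25.0,
    "PYK": 30.0, "PFOR": 15.0, "PFL": 8.0, "FHL": 25.0, "PTA": 40.0,
    "ACK": 40.0, "ALDH": 30.0, "ADH": 40.0, "LDH": 5.0, "HYDF": 80.0,
    "HYDN": 5.0, "PPC": 12.0, "CS": 15.0, "ACONT": 20.0, "ICDH": 15.0,
    "GDH": 25.0, "GLNS": 10.0, "GAPN": 15.0, "THD": 10.0,
    "ACt": 100.0, "GLUt": 50.0, "GLNt": 50.0, "FRUt": 100.0, "FRUK": 25.0,
    "XYLt": 100.0, "BIOMASS": 1.0,
}
_REFERENCE_MW_KDA = 55.0
_REFERENCE_RIBOSOME_MW_KDA = 2000.0  # protein-synthesis machinery lump
_REFERENCE_PHANTOM_WEIGHT = 0.25  # share of expression carried by non-model genes


def reference_enzyme_table(model: Model) -> tuple[EnzymeTable, EcConfig]:
    """Deterministic curated kinetic table for the core fixture.

    Every GPR-bearing reaction gets the curated kcat above (both directions),
    a common 55 kDa subunit mass, monomeric stoichiometry, and a uniform
    expression weight; a phantom non-model expression share keeps the enzyme
    mass fraction f below 1.
    """
    rows = []
    for rxn in model.reactions:
        base = rxn.id
        kcat = _REFERENCE_KCATS.get(base)
        if kcat is None or not rxn.genes:
            continue
        mw = _REFERENCE_RIBOSOME_MW_KDA if base == "BIOMASS" else _REFERENCE_MW_KDA
        for gene in sorted(g.id for g in rxn.genes):
            for direction in ("fwd", "rev"):
                rows.append(
                    {"gene_id": gene, "reaction_id": base, "direction": direction,
                     "kcat_s": kcat, "mw_kda": mw, "subunits": 1,
                     "expression_weight": 1.0}
                )
    table = EnzymeTable(pd.DataFrame(rows))
    model_genes = sorted({g.id for g in model.genes})
    weights = {g: 1.0 for g in model_genes}
    total = sum(weights.values())
    weights["phantom_nonmodel"] = total * _REFERENCE_PHANTOM_WEIGHT / (
        1.0 - _REFERENCE_PHANTOM_WEIGHT
    )
    f = enzyme_fraction_f(weights, model_genes)
    config = EcConfig(ptot=0.56, f=f, sigma=0.5)
    return table, config


def synth_enzyme_tables(model: Model, seed: int) -> tuple[EnzymeTable, EcConfig]:
    """Random kinetic tables with realistic spread, deterministic per seed.

    kcat is log-normal with median 10 1/s and sigma of one decade; molecular
    weights are uniform on 20-200 kDa; expression weights are Dirichlet over
    model genes plus ten phantom genes outside the model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_mw = {}
    gene_sub = {}
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        if not rxn.genes:
            continue
        for gene in sorted(g.id for g in rxn.genes):
            if gene not in gene_mw:
                gene_mw[gene] = float(rng.uniform(20.0, 200.0))
                gene_sub[gene] = int(rng.choice([1, 1, 2, 4]))
            for direction in ("fwd", "rev"):
                kcat = float(10.0 * 10 ** rng.normal(0.0, 1.0))
                rows.append(
                    {"gene_id": gene, "reaction_id": rxn.id, "direction": direction,
                     "kcat_s": kcat, "mw_kda": gene_mw[gene],
                     "subunits": gene_sub[gene], "expression_weight": np.nan}
                )
    model_genes = sorted({g.id for g in model.genes})
    phantom = [f"phantom_{i}" for i in range(10)]
    all_genes = model_genes + phantom
    weight_values = rng.dirichlet(np.ones(len(all_genes)))
    weights = dict(zip(all_genes, weight_values.tolist()))
    frame = pd.DataFrame(rows)
    frame["expression_weight"] = frame["gene_id"].map(weights)
    f = enzyme_fraction_f(weights, model_genes)
    return EnzymeTable(frame), EcConfig(ptot=0.56, f=f, sigma=0.5)


def make_universal_db(
    model: Model,
    required_ids: set[str] | list[str],
    n_decoys: int = 20,
    seed: int = 0,
) -> "UniversalDb":
    """Universal gap-filling database: required reactions plus decoys.

    Decoys alternate between dead-end conversions (a real metabolite into a
    novel orphan species, so they can never carry steady-state flux) and
    redundant duplicates of reactions still present in the model (flux-capable
    but never necessary). Deterministic per seed.
    """
    from hydrogem.gapfill import UniversalDb

    rng = np.random.default_rng(seed)
    reactions = [model.reactions.get_by_id(rid).copy() for rid in sorted(required_ids)]
    internal = sorted(
        r.id for r in model.reactions
        if reaction_kind(r) == "internal" and r.id not in set(required_ids)
    )
    cyto = sorted(m.id for m in model.metabolites if m.compartment == "c")
    for i in range(n_decoys):
        if i % 2 == 0:
            substrate = model.metabolites.get_by_id(str(rng.choice(cyto)))
            orphan = Metabolite(
                f"decoy_met_{i}_c", name=f"decoy species {i}",
                compartment="c", charge=0,
            )
            rxn = Reaction(f"DECOY_{i}", lower_bound=0.0, upper_bound=1000.0)
            rxn.add_metabolites({substrate.copy(): -1, orphan: 1})
        else:
            template = model.reactions.get_by_id(str(rng.choice(internal)))
            rxn = template.copy()
            rxn.id = f"DECOY_{i}"
            rxn.gene_reaction_rule = ""
        reactions.append(rxn)
    return UniversalDb(reactions=reactions)


#: Mean macromolecular mass fractions (g/gDW) used by the composition
#: generator; protein/DNA/RNA/glycogen at fermentative-anaerobe-like levels
#: and the remainder split in iAF1260-like proportions.
COMPOSITION_MEANS = {
    "protein": 0.55, "dna": 0.031, "rna": 0.12, "glycogen": 0.06,
    "lipid": 0.091, "cell_wall": 0.083, "lps": 0.034, "ions": 0.01,
    "soluble_pool": 0.021,
}


def synth_composition(seed: int, rel_sd: float = 0.05) -> tuple[MacroComposition, MonomerProfile]:
    """Draw a macromolecular composition and monomer profiles, seeded.

    Fractions are jittered around :data:`COMPOSITION_MEANS` with the given
    relative spread and renormalised to sum to one; monomer mole fractions
    are Dirichlet draws.
    """
    rng = np.random.default_rng(seed)
    fractions = {}
    for key, mean in COMPOSITION_MEANS.items():
        fractions[key] = max(float(rng.normal(mean, rel_sd * mean)), 1e-4)
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}
    macro = MacroComposition(**fractions)

    from hydrogem.biomass_builder import AMINO_ACIDS, DNTPS, NTPS

    aa = rng.dirichlet(np.full(len(AMINO_ACIDS), 5.0))
    dntp = rng.dirichlet(np.full(4, 5.0))
    ntp = rng.dirichlet(np.full(4, 5.0))
    monomer = MonomerProfile(
        amino_acid_fractions=dict(zip(AMINO_ACIDS, aa.tolist())),
        dntp_fractions=dict(zip(DNTPS, dntp.tolist())),
        ntp_fractions=dict(zip(NTPS, ntp.tolist())),
    )
    return macro, monomer


def synth_phenotype_table(
    model: Model,
    sources: list[tuple[str, str]] | None = None,
    seed: int = 0,
    flip_rate: float = 0.0,
    uptake: float = 10.0,
) -> PhenotypeTable:
    """Emulate a carbon-source growth assay with a known label-noise rate.

    ``sources`` is a list of (source name, exchange reaction id); by default
    every carbon-bearing exchange of the model is assayed. The observed call
    is the FBA-simulated call XOR a Bernoulli(flip_rate) flip, seeded.
    """
    if sources is None:
        sources = []
        for rxn in model.reactions:
            if reaction_kind(rxn) != "exchange":
                continue
            met = next(iter(rxn.metabolites))
            if met.formula and "C" in met.elements and met.id not in ("co2_e",):
                sources.append((met.name, rxn.id))
    rng = np.random.default_rng(seed)
    rows = []
    for name, exchange_id in sources:
        grows, _ = carbon_source_growth(model, exchange_id, uptake=uptake)
        observed = bool(grows) ^ bool(rng.random() < flip_rate)
        rows.append({"source_name": name, "exchange_reaction_id": exchange_id,
                     "observed_growth": observed})
    return PhenotypeTable(
        pd.DataFrame(rows),
        provenance="synthetic assay: simulated call XOR Bernoulli flips",
    )
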