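"""Biomass pseudo-reaction construction from macromolecular composition.

The biomass equation drains precursor monomers R_i with coefficients S_i
(mmol per gDW) and releases byproducts B_j (polymerisation water,
pyrophosphate, ADP/Pi from growth-associated maintenance) with coefficients
S_j, producing one gram of the biomass pseudo-species X per unit flux:

    sum_i S_i R_i  ->  X + sum_j S_j B_j

normalised so that the net mass, (sum_i S_i M_i - sum_j S_j M_j)/1000,
equals exactly 1 g per gDW, with M the molecular weights in g/mol.

Per-monomer coefficients follow from the polymer mass fraction and monomer
mole fractions: S_i = 1000 * f_polymer * x_i / sum_k x_k * M_residue,k, where
the residue weight is the free-monomer weight minus one water for protein and
glycogen bonds, and minus pyrophosphate for the NTP/dNTP condensations.

Energy terms: growth-associated maintenance (GAM) appears inside the biomass
equation as an element-balanced ATP hydrolysis (default 26.48 mmol ATP/gDW);
non-growth maintenance (NGAM) is a separate ATPM reaction whose lower bound
(default 0.81 mmol ATP/gDW/h) forces baseline ATP expenditure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from cobra import Metabolite, Reaction

from hydrogem.model_core import formula_weight

__all__ = [
    "MacroComposition",
    "MonomerProfile",
    "MaintenanceParams",
    "BiomassEquation",
    "AMINO_ACIDS",
    "NTPS",
    "DNTPS",
    "DEFAULT_MW_TABLE",
    "load_mw_table",
    "monomer_fractions_from_cds",
    "build_biomass",
    "normalize_biomass",
]

WATER_MW = formula_weight("H2O")

AMINO_ACIDS = [
    "ala__L", "arg__L", "asn__L", "asp__L", "cys__L", "gln__L", "glu__L",
    "gly", "his__L", "ile__L", "leu__L", "lys__L", "met__L", "phe__L",
    "pro__L", "ser__L", "thr__L", "trp__L", "tyr__L", "val__L",
]
NTPS = ["atp", "gtp", "ctp", "utp"]
DNTPS = ["datp", "dgtp", "dctp", "dttp"]

# neutral free amino acids; nucleotides as the physiological anions so the
# GAM hydrolysis terms cancel exactly in the Eq.-2 mass ledger
_MONOMER_FORMULAS = {
    "ala__L": "C3H7NO2", "arg__L": "C6H14N4O2", "asn__L": "C4H8N2O3",
    "asp__L": "C4H7NO4", "cys__L": "C3H7NO2S", "gln__L": "C5H10N2O3",
    "glu__L": "C5H9NO4", "gly": "C2H5NO2", "his__L": "C6H9N3O2",
    "ile__L": "C6H13NO2", "leu__L": "C6H13NO2", "lys__L": "C6H14N2O2",
    "met__L": "C5H11NO2S", "phe__L": "C9H11NO2", "pro__L": "C5H9NO2",
    "ser__L": "C3H7NO3", "thr__L": "C4H9NO3", "trp__L": "C11H12N2O2",
    "tyr__L": "C9H11NO3", "val__L": "C5H11NO2",
    "atp": "C10H12N5O13P3", "gtp": "C10H12N5O14P3",
    "ctp": "C9H12N3O14P3", "utp": "C9H11N2O15P3",
    "datp": "C10H12N5O12P3", "dgtp": "C10H12N5O13P3",
    "dctp": "C9H12N3O13P3", "dttp": "C10H13N2O14P3",
    "glucosyl": "C6H12O6",
    "ppi": "HO7P2", "h2o": "H2O", "adp": "C10H12N5O10P2",
    "pi": "HO4P", "h": "H",
}

# lumped macromolecular fractions carried as single pseudo-species with a
# nominal molar mass; only the mass they carry matters for Eq.-2 closure
_LUMP_MW = {
    "lipid": 700.0, "cell_wall": 950.0, "lps": 1500.0,
    "ions": 55.0, "soluble_pool": 300.0,
}

DEFAULT_MW_TABLE: dict[str, float] = {
    mid: formula_weight(f) for mid, f in _MONOMER_FORMULAS.items()
}
DEFAULT_MW_TABLE.update(_LUMP_MW)

_DNA_BASE_TO_DNTP = {"A": "datp", "C": "dctp", "G": "dgtp", "T": "dttp"}
_RNA_BASE_TO_NTP = {"A": "atp", "C": "ctp", "G": "gtp", "T": "utp"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def load_mw_table(path: str | Path) -> dict[str, float]:
    """Read a monomer molecular-weight table (TSV: monomer_id, mw_g_per_mol)."""
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["monomer_id"], frame["mw_g_per_mol"].astype(float)))


@dataclass(frozen=True)
class MacroComposition:
    """Macromolecular mass fractions in g per gDW."""

    protein: float
    dna: float
    rna: float
    glycogen: float
    lipid: float
    cell_wall: float
    lps: float
    ions: float
    soluble_pool: float

    FIELDS = ("protein", "dna", "rna", "glycogen", "lipid", "cell_wall",
              "lps", "ions", "soluble_pool")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}

    def total(self) -> float:
        return sum(self.as_dict().values())

    def validate(self) -> None:
        for name, value in self.as_dict().items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"fraction {name}={value} outside [0, 1]")
        if not 0.97 <= self.total() <= 1.03:
            raise ValueError(
                f"composition sums to {self.total():.4f}, outside [0.97, 1.03]"
            )

    def normalized(self) -> "MacroComposition":
        self.validate()
        total = self.total()
        return replace(self, **{k: v / total for k, v in self.as_dict().items()})


@dataclass(frozen=True)
class MonomerProfile:
    """Mole fractions of protein, DNA, and RNA monomers (each group sums to 1)."""

    amino_acid_fractions: Mapping[str, float]
    dntp_fractions: Mapping[str, float]
    ntp_fractions: Mapping[str, float]

    def validate(self) -> None:
        for label, group, keys in (
            ("amino_acid", self.amino_acid_fractions, AMINO_ACIDS),
            ("dntp", self.dntp_fractions, DNTPS),
            ("ntp", self.ntp_fractions, NTPS),
        ):
            if any(v < 0 for v in group.values()):
                raise ValueError(f"negative {label} fraction")
            if set(group) - set(keys):
                raise ValueError(f"unknown {label} monomers {set(group) - set(keys)}")
            if abs(sum(group.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} fractions sum to {sum(group.values())}")


@dataclass(frozen=True)
class MaintenanceParams:
    """ATP maintenance: GAM in mmol/gDW, NGAM in mmol/gDW/h."""

    gam: float = 26.48
    ngam: float = 0.81

    def validate(self) -> None:
        if self.gam <= 0 or self.ngam <= 0:
            raise ValueError("maintenance parameters must be positive")


@dataclass
class BiomassEquation:
    """Precursor/byproduct coefficients of the biomass pseudo-reaction (mmol/gDW).

    ``precursors``/``byproducts`` hold the biosynthetic monomer terms;
    ``maintenance`` holds the GAM/NGAM energy terms separately (the GAM ATP
    hydrolysis is element-balanced, so it carries no net mass and is merged
    with the monomer terms only when the reaction is materialised).
    """

    precursors: dict[str, float]
    byproducts: dict[str, float]
    biomass_species: str = "X"
    maintenance: MaintenanceParams | None = None

    def net_mass(self, mw_table: Mapping[str, float]) -> float:
        """Net grams carried per unit flux: (sum S_i M_i - sum S_j M_j)/1000."""
        try:
            consumed = sum(s * mw_table[m] for m, s in self.precursors.items())
            produced = sum(s * mw_table[m] for m, s in self.byproducts.items())
        except KeyError as exc:
            raise KeyError(f"molecular weight missing for monomer {exc}") from exc
        return (consumed - produced) / 1000.0


def monomer_fractions_from_cds(cds_fasta: str | Path, molecule: str) -> dict[str, float]:
    """Nucleotide mole fractions from coding sequences.

    For DNA the counts are pooled over both strands (A=T and G=C enforced by
    counting each base together with its complement); for RNA the
    coding-strand counts are used with T read as U. ``N`` bases are skipped.
    """
    if molecule not in ("dna", "rna"):
        raise ValueError(f"molecule must be 'dna' or 'rna', got {molecule!r}")
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    n_records = 0
    for record in SeqIO.parse(str(cds_fasta), "fasta"):
        n_records += 1
        for base in str(record.seq).upper():
            if base == "N":
                continue
            if base not in counts:
                raise ValueError(f"non-nucleotide character {base!r} in {record.id}")
            counts[base] += 1
    if n_records == 0 or sum(counts.values()) == 0:
        raise ValueError("empty FASTA input")
    if molecule == "dna":
        counts = {
            b: counts[b] + counts[_COMPLEMENT[b]] for b in counts
        }
        mapping = _DNA_BASE_TO_DNTP
    else:
        mapping = _RNA_BASE_TO_NTP
    total = sum(counts.values())
    fractions: dict[str, float] = {}
    for base, monomer in mapping.items():
        fractions[monomer] = fractions.get(monomer, 0.0) + counts[base] / total
    return fractions


def _polymer_coefficients(
    mass_fraction: float,
    mole_fractions: Mapping[str, float],
    mw_table: Mapping[str, float],
    leaving_group: str,
) -> tuple[dict[str, float], float]:
    """Monomer coefficients for one polymer plus the leaving-group coefficient.

    S_i = 1000 * f * x_i / sum_k x_k * (M_k - M_leaving); one leaving-group
    molecule (water or PPi) is released per residue incorporated.
    """
    leaving_mw = mw_table[leaving_group]
    missing = [m for m in mole_fractions if m not in mw_table]
    if missing:
        raise KeyError(f"molecular weight missing for monomers {missing}")
    residue_mass = sum(
        x * (mw_table[m] - leaving_mw) for m, x in mole_fractions.items()
    )
    if residue_mass <= 0:
        raise ValueError("non-positive mean residue mass")
    scale = 1000.0 * mass_fraction / residue_mass
    coeffs = {m: scale * x for m, x in mole_fractions.items() if x > 0}
    return coeffs, scale * sum(mole_fractions.values())


def build_biomass(
    macro: MacroComposition,
    monomer: MonomerProfile,
    mw_table: Mapping[str, float] | None = None,
    maintenance: MaintenanceParams = MaintenanceParams(),
) -> tuple[BiomassEquation, list[Reaction]]:
    """Construct the biomass equation and its model reactions.

    Returns the normalised :class:`BiomassEquation` together with two cobra
    reactions: the biomass pseudo-reaction (with GAM embedded) and the ATPM
    maintenance reaction whose lower bound is the NGAM.
    """
    mw_table = dict(DEFAULT_MW_TABLE if mw_table is None else mw_table)
    maintenance.validate()
    monomer.validate()
    macro = macro.normalized()
    if macro.total() <= 0:
        raise ValueError("zero total composition")

    precursors: dict[str, float] = {}
    byproducts: dict[str, float] = {}

    def accumulate(target: dict[str, float], coeffs: Mapping[str, float]) -> None:
        for m, s in coeffs.items():
            target[m] = target.get(m, 0.0) + s

    # polymers: protein and glycogen release water, DNA/RNA release PPi
    for mass_fraction, fractions, leaving in (
        (macro.protein, monomer.amino_acid_fractions, "h2o"),
        (macro.glycogen, {"glucosyl": 1.0}, "h2o"),
        (macro.dna, monomer.dntp_fractions, "ppi"),
        (macro.rna, monomer.ntp_fractions, "ppi"),
    ):
        if mass_fraction <= 0:
            continue
        coeffs, released = _polymer_coefficients(
            mass_fraction, fractions, mw_table, leaving
        )
        accumulate(precursors, coeffs)
        accumulate(byproducts, {leaving: released})

    # lumped fractions enter as free pseudo-species
    for lump in ("lipid", "cell_wall", "lps", "ions", "soluble_pool"):
        mass_fraction = getattr(macro, lump)
        if mass_fraction <= 0:
            continue
        if lump not in mw_table:
            raise KeyError(f"molecular weight missing for monomer {lump!r}")
        accumulate(precursors, {lump: 1000.0 * mass_fraction / mw_table[lump]})

    equation = BiomassEquation(precursors=precursors, byproducts=byproducts)
    equation = normalize_biomass(equation, mw_table)
    equation.maintenance = maintenance

    reactions = _equation_to_reactions(equation, maintenance)
    return equation, reactions


def normalize_biomass(
    equation: BiomassEquation, mw_table: Mapping[str, float]
) -> BiomassEquation:
    """Scale all coefficients by the single factor giving net mass 1 g/gDW."""
    if any(s <= 0 for s in equation.precursors.values()) or any(
        s < 0 for s in equation.byproducts.values()
    ):
        raise ValueError("biomass coefficients must be positive")
    net = equation.net_mass(mw_table)
    if net <= 0:
        raise ValueError(f"non-positive net biomass mass {net}")
    scale = 1.0 / net
    return BiomassEquation(
        precursors={m: s * scale for m, s in equation.precursors.items()},
        byproducts={m: s * scale for m, s in equation.byproducts.items()},
        biomass_species=equation.biomass_species,
    )


def _equation_to_reactions(
    equation: BiomassEquation, maintenance: MaintenanceParams
) -> list[Reaction]:
    """Materialise the equation as cobra reactions (cytosolic species ids)."""

    def met(mid: str, **kwargs) -> Metabolite:
        formula = _MONOMER_FORMULAS.get(mid)
        return Metabolite(
            f"{mid}_c", formula=formula, compartment="c", **kwargs
        )

    cache: dict[str, Metabolite] = {}

    def get(mid: str) -> Metabolite:
        if mid not in cache:
            cache[mid] = met(mid)
        return cache[mid]

    biomass = Reaction("BIOMASS_hydrogem", lower_bound=0.0, upper_bound=1000.0)
    stoich: dict[Metabolite, float] = {}
    for mid, s in equation.precursors.items():
        stoich[get(mid)] = stoich.get(get(mid), 0.0) - s
    for mid, s in equation.byproducts.items():
        stoich[get(mid)] = stoich.get(get(mid), 0.0) + s
    # GAM: element-balanced ATP hydrolysis, merged into the reaction only
    gam = maintenance.gam
    for mid, s in (("atp", -gam), ("h2o", -gam), ("adp", gam), ("pi", gam),
                   ("h", gam)):
        stoich[get(mid)] = stoich.get(get(mid), 0.0) + s
    x = Metabolite("biomass_X_c", formula="X", compartment="c", charge=0)
    stoich[x] = 1.0
    biomass.add_metabolites(stoich)

    atpm = Reaction("ATPM", lower_bound=maintenance.ngam, upper_bound=1000.0)
    atpm.add_metabolites(
        {get("atp"): -1, get("h2o"): -1, get("adp"): 1, get("pi"): 1, get("h"): 1}
    )
    return [biomass, atpm]
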