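"""Core model containers, standard-format I/O, and mass/charge auditing.

The in-memory container is :class:`cobra.Model` (metabolites, reactions,
genes, FBC bounds/objective/GPRs), which this module wraps with a stricter
validation layer and a deterministic elemental/charge audit.

Conventions
-----------
* Two compartments: ``c`` (cytosol) and ``e`` (extracellular); metabolite ids
  carry a ``_c``/``_e`` suffix.
* Exchange reactions touch exactly one extracellular species; demand
  reactions are prefixed ``DM_``.
* Formulas are Hill-notation element symbols with optional integer counts.
  A missing formula, or one containing the pseudo-element ``X`` (lumped
  macromolecules, biomass), marks the metabolite unauditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.core.gene import GPR
from cobra.io import (
    load_json_model,
    read_sbml_model,
    save_json_model,
    write_sbml_model,
)

__all__ = [
    "ModelFormatError",
    "ModelIntegrityError",
    "read_model",
    "write_model",
    "reaction_kind",
    "check_balance",
    "BalanceReport",
    "evaluate_gpr",
    "formula_to_counts",
    "formula_weight",
]

VALID_COMPARTMENTS = {"c", "e"}

#: Monoisotopic-free average atomic masses (g/mol) for the elements that occur
#: in fermentation-scale metabolic models.
ELEMENT_MASS: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "Na": 22.990, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Cl": 35.45, "Zn": 65.38, "Mn": 54.938, "Cu": 63.546,
    "Co": 58.933, "Mo": 95.95, "Se": 78.971, "Ni": 58.693,
    # pseudo-element for lumped species; weight undefined on purpose
    "X": float("nan"),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelFormatError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


class ModelIntegrityError(ValueError):
    """Raised when references inside a model do not resolve."""


def formula_to_counts(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula into element -> count.

    Raises ``ValueError`` on anything that is not a sequence of element
    symbols with optional positive integer counts.
    """
    if not formula:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def formula_weight(formula: str) -> float:
    """Molecular weight in g/mol from a Hill-notation formula."""
    counts = formula_to_counts(formula)
    unknown = set(counts) - set(ELEMENT_MASS)
    if unknown:
        raise ValueError(f"unknown elements {sorted(unknown)} in {formula!r}")
    return sum(ELEMENT_MASS[el] * n for el, n in counts.items())


def _validate(model: cobra.Model) -> None:
    """Enforce the container invariants beyond what cobra itself checks."""
    seen = set()
    for met in model.metabolites:
        if met.id in seen:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id}")
        seen.add(met.id)
        if met.compartment not in VALID_COMPARTMENTS:
            raise ModelIntegrityError(
                f"metabolite {met.id}: compartment {met.compartment!r} "
                f"not in {sorted(VALID_COMPARTMENTS)}"
            )
        if met.charge is not None and not float(met.charge).is_integer():
            raise ModelIntegrityError(
                f"metabolite {met.id}: non-integer charge {met.charge!r}"
            )
        if met.formula:
            try:
                formula_to_counts(met.formula)
            except ValueError as exc:
                raise ModelFormatError(f"metabolite {met.id}: {exc}") from exc
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelIntegrityError(
                f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        if not rxn.metabolites:
            raise ModelIntegrityError(f"reaction {rxn.id}: empty stoichiometry")
        for gid in (rxn.gpr.genes if rxn.gpr else set()):
            if gid not in gene_ids:
                raise ModelIntegrityError(
                    f"reaction {rxn.id}: GPR references unknown gene {gid}"
                )


def read_model(path: str | Path, dialect: str = "json") -> cobra.Model:
    """Read a metabolic model from SBML (Level 3 + FBC) or JSON.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"sbml-fbc"`` or ``"json"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("sbml-fbc", "json"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "sbml-fbc":
            model = read_sbml_model(str(path))
        else:
            model = load_json_model(str(path))
    except Exception as exc:  # libsbml / json decoding errors
        raise ModelFormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    _validate(model)
    return model


def write_model(model: cobra.Model, path: str | Path, dialect: str = "json") -> Path:
    """Write a model to SBML-FBC or JSON after validating its invariants."""
    _validate(model)
    path = Path(path)
    if dialect == "sbml-fbc":
        write_sbml_model(model, str(path))
    elif dialect == "json":
        save_json_model(model, str(path), sort=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def reaction_kind(reaction: cobra.Reaction) -> str:
    """Classify a reaction as internal/transport/exchange/demand/biomass/maintenance."""
    rid = reaction.id
    mets = reaction.metabolites
    compartments = {m.compartment for m in mets}
    if len(mets) == 1:
        met = next(iter(mets))
        if met.compartment == "e":
            return "exchange"
        if rid.startswith(("DM_", "SK_")):
            return "demand"
    lowered = rid.lower()
    if "biomass" in lowered or any("biomass" in (m.id.lower()) for m in mets):
        return "biomass"
    if rid.upper().startswith("ATPM"):
        return "maintenance"
    if len(compartments) > 1:
        return "transport"
    return "internal"


@dataclass
class BalanceReport:
    """Per-reaction elemental/charge audit of a model.

    ``rows`` maps reaction id -> (element deltas, charge delta, flagged,
    auditable). A reaction is flagged iff it is auditable, not of an exempt
    kind, and any element or charge delta is non-zero.
    """

    element_deltas: dict[str, dict[str, float]]
    charge_deltas: dict[str, float]
    flagged: list[str]
    unauditable: list[str]
    exempt_kinds: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_imbalanced(self) -> int:
        return len(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for rid, deltas in self.element_deltas.items():
            records.append(
                {
                    "reaction_id": rid,
                    "element_deltas": ";".join(
                        f"{el}:{d:g}" for el, d in sorted(deltas.items()) if d != 0
                    ),
                    "charge_delta": self.charge_deltas[rid],
                    "flag": rid in set(self.flagged),
                }
            )
        for rid in self.unauditable:
            records.append(
                {"reaction_id": rid, "element_deltas": "unauditable",
                 "charge_delta": float("nan"), "flag": False}
            )
        return pd.DataFrame.from_records(
            records, columns=["reaction_id", "element_deltas", "charge_delta", "flag"]
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


DEFAULT_EXEMPT_KINDS = frozenset({"exchange", "demand", "biomass"})


def check_balance(
    model: cobra.Model,
    exempt_kinds: Iterable[str] = DEFAULT_EXEMPT_KINDS,
) -> BalanceReport:
    """Audit elemental and charge balance of every non-exempt reaction.

    Reactions whose metabolites lack a formula or charge (or use the pseudo
    element ``X``) are reported as unauditable rather than imbalanced.
    """
    exempt = frozenset(exempt_kinds)
    element_deltas: dict[str, dict[str, float]] = {}
    charge_deltas: dict[str, float] = {}
    flagged: list[str] = []
    unauditable: list[str] = []
    for rxn in model.reactions:
        if reaction_kind(rxn) in exempt:
            continue
        deltas: dict[str, float] = {}
        charge = 0.0
        auditable = True
        for met, coeff in rxn.metabolites.items():
            if not met.formula or met.charge is None:
                auditable = False
                break
            counts = formula_to_counts(met.formula)
            if "X" in counts:
                auditable = False
                break
            for el, n in counts.items():
                deltas[el] = deltas.get(el, 0.0) + coeff * n
            charge += coeff * met.charge
        if not auditable:
            unauditable.append(rxn.id)
            continue
        deltas = {el: d for el, d in deltas.items() if abs(d) > 1e-9}
        charge = 0.0 if abs(charge) < 1e-9 else charge
        element_deltas[rxn.id] = deltas
        charge_deltas[rxn.id] = charge
        if deltas or charge != 0.0:
            flagged.append(rxn.id)
    return BalanceReport(
        element_deltas=element_deltas,
        charge_deltas=charge_deltas,
        flagged=flagged,
        unauditable=unauditable,
        exempt_kinds=exempt,
    )


def evaluate_gpr(
    rule: GPR | str,
    deleted_genes: Iterable[str] = (),
    known_genes: Iterable[str] | None = None,
) -> bool:
    """Evaluate a gene-protein-reaction boolean rule under gene deletions.

    A present gene is true and a deleted one false; ``and`` models a required
    complex, ``or`` isozymes. An empty rule (spontaneous or orphan reaction)
    evaluates to true. If ``known_genes`` is given, referencing a gene outside
    it raises :class:`ModelIntegrityError`.
    """
    gpr = GPR.from_string(rule) if isinstance(rule, str) else rule
    referenced = gpr.genes
    if known_genes is not None:
        unknown = set(referenced) - set(known_genes)
        if unknown:
            raise ModelIntegrityError(f"GPR references unknown genes {sorted(unknown)}")
    return gpr.eval(knockouts=set(deleted_genes))
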