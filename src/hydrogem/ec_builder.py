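"""Enzyme-constrained model construction (single-pool, sMOMENT-style).

Each catalysed reaction direction gets an enzyme cost MW/kcat in
g.h/mmol (molecular weight of the catalysing unit over its turnover number);
a single pseudo-metabolite represents the shared enzyme pool, produced by a
source reaction capped at ptot * f * sigma g enzyme per gDW and consumed by
every costed reaction in proportion to its flux, so that in any feasible
state

    sum_i cost_i * v_i  <=  ptot * f * sigma .

ptot is the measured total protein content (g/gDW), f the mass fraction of
that protein that is enzymatic (estimated from relative expression weights),
and sigma the average in-vivo saturation of enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from cobra import Metabolite, Model, Reaction
from cobra.core.gene import GPR
from ast import And, BoolOp, Expression, Name, Or

__all__ = [
    "EnzymeEntry",
    "EnzymeTable",
    "EcConfig",
    "EcModel",
    "ParameterizationError",
    "split_reversible",
    "reaction_enzyme_cost",
    "enzyme_fraction_f",
    "build_ec_model",
    "calibrate_kcat",
    "as_cobra",
]

POOL_METABOLITE_ID = "enzyme_pool_c"
POOL_SUPPLY_ID = "PROT_POOL_supply"
KCAT_SCALE = 3600.0  # s^-1 -> h^-1


class ParameterizationError(ValueError):
    """Raised when an enzyme cost cannot be computed from the given entries."""


@dataclass(frozen=True)
class EnzymeEntry:
    """Kinetic and mass parameters of one gene product for one reaction direction."""

    gene_id: str
    mw: float  # kDa == g/mmol
    subunit_count: int = 1
    kcat: float | None = None  # s^-1
    expression_weight: float = 0.0

    def validate(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.gene_id}: non-positive molecular weight")
        if self.subunit_count < 1:
            raise ValueError(f"{self.gene_id}: subunit count must be >= 1")
        if self.kcat is not None and self.kcat <= 0:
            raise ValueError(f"{self.gene_id}: non-positive kcat")
        if self.expression_weight < 0:
            raise ValueError(f"{self.gene_id}: negative expression weight")


class EnzymeTable:
    """Table of per-(reaction, direction, gene) enzyme parameters.

    Backed by a DataFrame with columns gene_id, reaction_id, direction
    (fwd/rev), kcat_s, mw_kda, subunits, expression_weight — the on-disk TSV
    layout.
    """

    COLUMNS = ["gene_id", "reaction_id", "direction", "kcat_s", "mw_kda",
               "subunits", "expression_weight"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"enzyme table missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    def entries_for(self, reaction_id: str, direction: str = "fwd") -> dict[str, EnzymeEntry]:
        rows = self.frame[
            (self.frame["reaction_id"] == reaction_id)
            & (self.frame["direction"] == direction)
        ]
        entries = {}
        for _, row in rows.iterrows():
            entries[row["gene_id"]] = EnzymeEntry(
                gene_id=row["gene_id"],
                mw=float(row["mw_kda"]),
                subunit_count=int(row["subunits"]),
                kcat=None if pd.isna(row["kcat_s"]) else float(row["kcat_s"]),
                expression_weight=0.0 if pd.isna(row["expression_weight"])
                else float(row["expression_weight"]),
            )
        return entries

    def expression_weights(self) -> dict[str, float]:
        grouped = self.frame.groupby("gene_id")["expression_weight"].first()
        return {g: float(w) for g, w in grouped.items() if pd.notna(w)}

    def with_kcat(self, reaction_id: str, direction: str, gene_id: str | None,
                  kcat: float) -> "EnzymeTable":
        frame = self.frame.copy()
        mask = (frame["reaction_id"] == reaction_id) & (frame["direction"] == direction)
        if gene_id is not None:
            mask &= frame["gene_id"] == gene_id
        frame.loc[mask, "kcat_s"] = kcat
        return EnzymeTable(frame)


@dataclass(frozen=True)
class EcConfig:
    """Enzyme-pool parameters: pool = ptot * f * sigma (g enzyme per gDW)."""

    ptot: float = 0.56
    f: float = 1.0
    sigma: float = 0.5

    @property
    def pool(self) -> float:
        return self.ptot * self.f * self.sigma

    def validate(self) -> None:
        for name in ("ptot", "f", "sigma"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name}={value} outside (0, 1]")


@dataclass
class EcModel:
    """An irreversible model with per-reaction enzyme costs and a shared pool."""

    model: Model
    enzyme_cost: dict[str, float]
    config: EcConfig
    split_map: dict[str, str] = field(default_factory=dict)
    uncosted: list[str] = field(default_factory=list)
    calibration_log: list[dict] = field(default_factory=list)

    @property
    def pool(self) -> float:
        return self.config.pool

    def copy(self) -> "EcModel":
        return EcModel(
            model=self.model.copy(),
            enzyme_cost=dict(self.enzyme_cost),
            config=self.config,
            split_map=dict(self.split_map),
            uncosted=list(self.uncosted),
            calibration_log=list(self.calibration_log),
        )

    def enzyme_usage(self, fluxes: Mapping[str, float]) -> dict[str, float]:
        """Per-reaction enzyme mass use (g/gDW) for a flux vector."""
        return {
            rid: cost * fluxes.get(rid, 0.0)
            for rid, cost in self.enzyme_cost.items()
        }


def as_cobra(model: Model | EcModel) -> Model:
    """Accept either a plain cobra model or an EcModel wrapper."""
    return model.model if isinstance(model, EcModel) else model


def split_reversible(model: Model) -> Model:
    """Split every reversible non-exchange reaction into fwd/rev halves.

    A reaction with bounds (lb < 0, ub > 0) becomes ``id_fwd`` with (0, ub)
    and ``id_rev`` with (0, -lb) and negated stoichiometry; a pure-reverse
    reaction becomes ``id_rev`` alone. Exchanges are exempt. The mapping from
    split ids back to originals is stored in ``model.notes['reversible_split']``.
    """
    from hydrogem.model_core import reaction_kind

    split = model.copy()
    mapping: dict[str, str] = {}
    new_reactions = []
    to_remove = []
    for rxn in list(split.reactions):
        if rxn.lower_bound >= 0 or reaction_kind(rxn) == "exchange":
            continue
        if rxn.upper_bound > 0:
            fwd = Reaction(f"{rxn.id}_fwd", lower_bound=0.0, upper_bound=rxn.upper_bound)
            fwd.add_metabolites(dict(rxn.metabolites))
            fwd.gpr = rxn.gpr
            new_reactions.append(fwd)
            mapping[fwd.id] = rxn.id
        rev = Reaction(f"{rxn.id}_rev", lower_bound=0.0, upper_bound=-rxn.lower_bound)
        rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        rev.gpr = rxn.gpr
        new_reactions.append(rev)
        mapping[rev.id] = rxn.id
        to_remove.append(rxn)
    objective_ids = {r.id for r in split.reactions if r.objective_coefficient}
    split.remove_reactions(to_remove)
    split.add_reactions(new_reactions)
    if objective_ids:
        # re-point the objective if the objective reaction itself was split
        remaining = {r.id for r in split.reactions}
        targets = [
            rid if rid in remaining else f"{rid}_fwd"
            for rid in objective_ids
        ]
        split.objective = {split.reactions.get_by_id(t): 1.0 for t in targets}
    split.notes["reversible_split"] = mapping
    return split


def _gpr_cost(node, entries: Mapping[str, EnzymeEntry]) -> float:
    """Cost in g.h/mmol of one GPR subtree: AND sums complex mass, OR takes min."""
    if isinstance(node, (GPR, Expression)):
        body = node.body
        if isinstance(body, list):
            if not body:
                return 0.0
            body = body[0]
        return _gpr_cost(body, entries)
    if isinstance(node, Name):
        entry = entries.get(node.id)
        if entry is None or entry.kcat is None:
            raise ParameterizationError(f"missing mw/kcat for gene {node.id}")
        entry.validate()
        return (entry.subunit_count * entry.mw) / (entry.kcat * KCAT_SCALE)
    if isinstance(node, BoolOp):
        if isinstance(node.op, Or):
            errors = []
            costs = []
            for child in node.values:
                try:
                    costs.append(_gpr_cost(child, entries))
                except ParameterizationError as exc:
                    errors.append(str(exc))
            if not costs:
                raise ParameterizationError("; ".join(errors))
            return min(costs)
        if isinstance(node.op, And):
            # complex: total mass is the sum of subunit masses; the slowest
            # member limits turnover
            mass = 0.0
            kcats = []
            for child in node.values:
                if isinstance(child, Name):
                    entry = entries.get(child.id)
                    if entry is None or entry.kcat is None:
                        raise ParameterizationError(
                            f"missing mw/kcat for gene {child.id}"
                        )
                    entry.validate()
                    mass += entry.subunit_count * entry.mw
                    kcats.append(entry.kcat)
                else:
                    # nested boolean inside a complex: cost of the subtree
                    # expressed back as an equivalent mass at unit kcat
                    sub = _gpr_cost(child, entries)
                    mass += sub * KCAT_SCALE
                    kcats.append(1.0)
            return mass / (min(kcats) * KCAT_SCALE)
    raise ParameterizationError(f"unsupported GPR node {node!r}")


def reaction_enzyme_cost(
    reaction: Reaction | None,
    gpr: GPR | str | None,
    entries: Mapping[str, EnzymeEntry],
) -> float:
    """Enzyme cost (g.h/mmol) of one reaction direction.

    AND complexes sum subunit_count*mw over members and turn over at the
    slowest member's kcat; OR isozymes take the cheapest branch; an empty GPR
    costs nothing (the reaction is left unconstrained).
    """
    if gpr is None and reaction is not None:
        gpr = reaction.gpr
    if gpr is None:
        return 0.0
    if isinstance(gpr, str):
        gpr = GPR.from_string(gpr)
    if not gpr.genes:
        return 0.0
    return _gpr_cost(gpr, entries)


def enzyme_fraction_f(
    expression_weights: Mapping[str, float],
    model_gene_ids: Iterable[str],
) -> float:
    """Share of total expression weight carried by genes present in the model."""
    weights = {g: w for g, w in expression_weights.items()}
    if any(w < 0 for w in weights.values()):
        raise ValueError("expression weights must be non-negative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all expression weights are zero")
    model_genes = set(model_gene_ids)
    in_model = sum(w for g, w in weights.items() if g in model_genes)
    if in_model <= 0:
        raise ValueError("no model gene carries positive weight")
    return in_model / total


def build_ec_model(
    model: Model,
    entries: EnzymeTable,
    config: EcConfig,
) -> EcModel:
    """Attach enzyme costs and the shared pool constraint to a model.

    The model is split into irreversible directions first. Reactions whose
    GPR cannot be parameterised (no kcat on any branch) are left uncosted and
    counted in ``EcModel.uncosted``.
    """
    config.validate()
    work = split_reversible(model)
    split_map = dict(work.notes.get("reversible_split", {}))

    pool_met = Metabolite(
        POOL_METABOLITE_ID, name="shared enzyme pool", compartment="c"
    )
    supply = Reaction(POOL_SUPPLY_ID, lower_bound=0.0, upper_bound=config.pool)
    supply.add_metabolites({pool_met: 1.0})
    work.add_reactions([supply])

    costs: dict[str, float] = {}
    uncosted: list[str] = []
    for rxn in work.reactions:
        if rxn.id == POOL_SUPPLY_ID or not rxn.gpr or not rxn.gpr.genes:
            continue
        base = split_map.get(rxn.id, rxn.id)
        direction = "rev" if rxn.id.endswith("_rev") and base != rxn.id else "fwd"
        try:
            cost = reaction_enzyme_cost(rxn, rxn.gpr, entries.entries_for(base, direction))
        except ParameterizationError:
            uncosted.append(rxn.id)
            continue
        if cost > 0:
            rxn.add_metabolites({pool_met: -cost})
            costs[rxn.id] = cost
    return EcModel(
        model=work, enzyme_cost=costs, config=config,
        split_map=split_map, uncosted=uncosted,
    )


def calibrate_kcat(
    ecmodel: EcModel,
    measured_growth: float,
    substrate_uptake: float,
    max_rounds: int = 50,
    tol: float = 0.05,
    substrate_exchange: str = "EX_glc__D_e",
) -> EcModel:
    """Relax bottleneck kcats until predicted growth matches measurement.

    While the predicted growth rate falls short of ``measured_growth`` by more
    than ``tol`` (relative), the reaction holding the largest share of the
    enzyme pool at the optimum gets its kcat doubled (its pool cost halved).
    The audit trail of adjustments is stored in ``calibration_log``.
    """
    if measured_growth <= 0:
        raise ValueError("measured growth must be positive")
    work = ecmodel.copy()
    pool_met = work.model.metabolites.get_by_id(POOL_METABOLITE_ID)
    exchange = work.model.reactions.get_by_id(substrate_exchange)
    exchange.lower_bound = -abs(substrate_uptake)

    for round_index in range(max_rounds):
        solution = work.model.optimize()
        mu = 0.0 if solution.status != "optimal" else solution.objective_value
        gap = (measured_growth - mu) / measured_growth
        if gap <= tol:
            break
        usage = work.enzyme_usage(solution.fluxes)
        bottleneck = max(usage, key=usage.get)
        if usage[bottleneck] <= 0:
            break  # pool not limiting; kcats cannot close the gap
        rxn = work.model.reactions.get_by_id(bottleneck)
        old_cost = work.enzyme_cost[bottleneck]
        new_cost = old_cost / 2.0
        rxn.add_metabolites({pool_met: old_cost - new_cost}, combine=True)
        work.enzyme_cost[bottleneck] = new_cost
        work.calibration_log.append(
            {"round": round_index, "reaction_id": bottleneck,
             "cost_before": old_cost, "cost_after": new_cost, "growth": mu}
        )
    final = work.model.slim_optimize(error_value=0.0)
    work.calibration_log.append(
        {"round": "final", "reaction_id": None, "cost_before": None,
         "cost_after": None, "growth": final}
    )
    return work
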