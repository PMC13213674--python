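"""In-silico genetic screens: single-gene knockouts and FSEOF target scans.

Knockouts use GPR semantics (a reaction is lost only when its boolean rule
evaluates false under the deletion) and a lexicographic objective — maximise
growth, then maximise hydrogen with a parsimonious tie-break — so the
reported hydrogen flux is the best the mutant can do at its own growth
optimum.

FSEOF (flux scanning with enforced objective flux) fixes the target exchange
at stepwise-increasing levels between its value at the growth optimum and a
fraction of its theoretical maximum, re-maximises growth at each level, and
classifies each reaction's parsimonious flux trajectory as amplify (co-
increasing: an overexpression candidate), attenuate (anti-correlated: a
repression/knockout candidate) or mixed, with an FVA overlay at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cobra import Model

from hydrogem.ec_builder import EcModel, as_cobra
from hydrogem.fba_engine import fba, fva
from hydrogem.model_core import evaluate_gpr

__all__ = [
    "KnockoutScreenResult",
    "FseofResult",
    "UPTAKE_CONDITIONS",
    "knockout_screen",
    "fseof",
]

#: default low/high carbon uptake magnitudes (mmol glucose /gDW/h)
UPTAKE_CONDITIONS = {"low_carbon": 5.0, "high_carbon": 20.0}

WT_LABEL = "WT"


@dataclass
class KnockoutScreenResult:
    """Per-gene growth and hydrogen outcomes of a knockout screen."""

    table: pd.DataFrame  # columns: gene, growth_rate, h2_yield, deltas, flags
    condition: str
    uptake: float

    def row(self, gene: str) -> pd.Series:
        return self.table.set_index("gene").loc[gene]

    def to_tsv(self, path: str | Path) -> Path:
        self.table.to_csv(path, sep="\t", index=False)
        return Path(path)


def _lexicographic_growth_then_target(
    m: Model, growth_rxn: str, target_rxn: str, growth_tol: float = 1e-9
) -> tuple[float, float]:
    """Max growth, then max target at that growth, parsimonious tie-break."""
    with m:
        m.objective = m.reactions.get_by_id(growth_rxn)
        mu = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(mu) or mu < growth_tol:
            return 0.0, 0.0
        m.reactions.get_by_id(growth_rxn).lower_bound = mu * (1 - 1e-6)
        result = fba(m, target_rxn, "max", parsimonious=True)
        target = result.objective_value if result.status == "optimal" else 0.0
    return float(mu), float(target)


def _knockout_reactions(m: Model, deleted: set[str]) -> list[str]:
    """Reactions whose GPR evaluates false under the deletion."""
    lost = []
    for rxn in m.reactions:
        if rxn.gpr and rxn.gpr.genes and not evaluate_gpr(rxn.gpr, deleted):
            lost.append(rxn.id)
    return lost


def knockout_screen(
    model: Model | EcModel,
    gene_ids: Iterable[str] | None = None,
    uptake_condition: str | float = "low_carbon",
    substrate_exchange: str = "EX_glc__D_e",
    growth_rxn: str | None = None,
    h2_exchange: str = "EX_h2_e",
) -> KnockoutScreenResult:
    """Screen single-gene deletions for growth and hydrogen production.

    ``uptake_condition`` is either a named condition (low_carbon/high_carbon)
    or an uptake magnitude. Essential knockouts are recorded with zero growth
    and zero yield and flagged.
    """
    m = as_cobra(model)
    if isinstance(uptake_condition, str):
        condition = uptake_condition
        uptake = UPTAKE_CONDITIONS[uptake_condition]
    else:
        condition = f"uptake_{uptake_condition:g}"
        uptake = float(uptake_condition)
    if gene_ids is None:
        gene_ids = sorted(g.id for g in m.genes)
    if growth_rxn is None:
        growth_rxn = next(r.id for r in m.reactions if r.objective_coefficient)

    rows = []
    with m:
        m.reactions.get_by_id(substrate_exchange).lower_bound = -uptake
        wt_mu, wt_h2 = _lexicographic_growth_then_target(m, growth_rxn, h2_exchange)
        wt_yield = wt_h2 / uptake
        rows.append({
            "gene": WT_LABEL, "growth_rate": wt_mu, "h2_yield": wt_yield,
            "delta_growth": 0.0, "delta_h2": 0.0, "essential": False,
            "condition": condition,
        })
        for gene in gene_ids:
            lost = _knockout_reactions(m, {gene})
            with m:
                for rid in lost:
                    m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
                mu, h2 = _lexicographic_growth_then_target(m, growth_rxn, h2_exchange)
            h2_yield = h2 / uptake if mu > 0 else 0.0
            rows.append({
                "gene": gene, "growth_rate": mu, "h2_yield": h2_yield,
                "delta_growth": (mu - wt_mu) / wt_mu if wt_mu else 0.0,
                "delta_h2": (h2_yield - wt_yield) / wt_yield if wt_yield else 0.0,
                "essential": mu <= 1e-9,
                "condition": condition,
            })
    return KnockoutScreenResult(table=pd.DataFrame(rows), condition=condition,
                                uptake=uptake)


@dataclass
class FseofResult:
    """Flux trajectories, classifications, and FVA overlay per target level."""

    levels: list[float]
    trajectories: pd.DataFrame  # index reaction id, one column per level
    classification: dict[str, str]
    fva_ranges: dict[float, pd.DataFrame] = field(default_factory=dict)
    target_reaction: str = ""

    def targets(self, kind: str = "amplify") -> list[str]:
        return sorted(r for r, c in self.classification.items() if c == kind)

    def to_long_frame(self) -> pd.DataFrame:
        """Heatmap-ready long table: (reaction, relative target level, flux)."""
        records = []
        top = self.levels[-1] if self.levels and self.levels[-1] else 1.0
        for rid, row in self.trajectories.iterrows():
            for level, value in zip(self.levels, row.values):
                records.append({
                    "reaction_id": rid,
                    "relative_target_level": level / top if top else 0.0,
                    "flux": value,
                    "classification": self.classification[rid],
                })
        return pd.DataFrame(records)

    def to_tsv(self, path: str | Path) -> Path:
        self.to_long_frame().to_csv(path, sep="\t", index=False)
        return Path(path)


def _classify_trajectory(values: np.ndarray, tol: float = 1e-6) -> str:
    """amplify: |v| non-decreasing with constant sign; attenuate: decreasing."""
    if len(values) <= 1:
        return "amplify"
    signs = {np.sign(v) for v in values if abs(v) > tol}
    magnitudes = np.abs(values)
    diffs = np.diff(magnitudes)
    constant_sign = len(signs) <= 1
    if constant_sign and np.all(diffs >= -tol):
        return "amplify"
    if np.all(diffs <= tol) and magnitudes[-1] < magnitudes[0] - tol:
        return "attenuate"
    return "mixed"


def fseof(
    model: Model | EcModel,
    growth_rxn: str,
    target_exchange: str,
    k_levels: int = 10,
    max_fraction: float = 0.9,
    reactions: Sequence[str] | None = None,
    fva_growth_fraction: float = 0.99,
    run_fva: bool = True,
) -> FseofResult:
    """Scan metabolic responses to enforced increases of a target flux."""
    m = as_cobra(model)
    base = fba(m, growth_rxn, "max", parsimonious=True)
    if base.status != "optimal":
        raise RuntimeError("growth optimum required before FSEOF")
    v_base = base.fluxes.get(target_exchange, 0.0)
    top = fba(m, target_exchange, "max")
    if top.status != "optimal" or top.objective_value <= 0:
        raise RuntimeError("target flux unreachable")
    v_top = max_fraction * top.objective_value
    if k_levels == 1 or v_top <= v_base + 1e-9:
        # no headroom above the growth optimum: degenerate single-point scan
        levels = [v_base]
    else:
        levels = np.linspace(v_base, v_top, k_levels).tolist()
    if reactions is None:
        reactions = [r.id for r in m.reactions]

    target = m.reactions.get_by_id(target_exchange)
    columns = {}
    fva_ranges: dict[float, pd.DataFrame] = {}
    achieved_levels = []
    for level in levels:
        with m:
            target.bounds = (level, level)
            mu = fba(m, growth_rxn, "max")
            if mu.status != "optimal":
                break  # truncate the grid at the first infeasible level
            flux = fba(m, growth_rxn, "max", parsimonious=True)
            columns[level] = {rid: flux.fluxes.get(rid, 0.0) for rid in reactions}
            if run_fva:
                m.reactions.get_by_id(growth_rxn).lower_bound = (
                    fva_growth_fraction * mu.objective_value
                )
                fva_ranges[level] = fva(m, reactions, fraction_of_optimum=0.0).ranges
            achieved_levels.append(level)
    trajectories = pd.DataFrame(columns)[achieved_levels]
    trajectories = trajectories.loc[list(reactions)]
    classification = {
        rid: _classify_trajectory(trajectories.loc[rid].to_numpy())
        for rid in trajectories.index
    }
    return FseofResult(
        levels=achieved_levels,
        trajectories=trajectories,
        classification=classification,
        fva_ranges=fva_ranges,
        target_reaction=target_exchange,
    )
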