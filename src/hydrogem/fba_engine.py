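"""Linear-programming core: FBA, FVA, yields, flux-ratio coupling, envelopes.

All solves go through the model's optlang/GLPK interface. The flux-vector
contract is on objective values only; where a unique vector is needed
(reports, scan trajectories) a parsimonious (minimum-total-flux) secondary
objective is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from cobra import Model
from cobra.flux_analysis import flux_variability_analysis, pfba

from hydrogem.ec_builder import EcModel, as_cobra

__all__ = [
    "FluxResult",
    "FvaResult",
    "ParetoCurve",
    "UndefinedYieldError",
    "fba",
    "fva",
    "molar_yield",
    "add_ratio_constraint",
    "production_envelope",
    "hydrogen_yield_scenario",
    "set_uptake",
]

FEASIBILITY_TOL = 1e-9


class UndefinedYieldError(ZeroDivisionError):
    """Raised when a molar yield is requested at zero substrate uptake."""


@dataclass
class FluxResult:
    """One LP solution: objective value, flux vector, solver status."""

    objective_value: float | None
    fluxes: dict[str, float]
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")


@dataclass
class FvaResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    ranges: pd.DataFrame  # index reaction id, columns minimum/maximum
    fraction_of_optimum: float

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])


@dataclass
class ParetoCurve:
    """Growth grid vs maximum target flux/yield: the production envelope."""

    points: list[tuple[float, float]]  # (growth rate, max target value)
    growth_reaction: str = ""
    target_reaction: str = ""

    def growth_grid(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def target_values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def is_concave(self, tol: float = 1e-6) -> bool:
        """Upper envelope concavity: second differences non-positive."""
        g = self.growth_grid()
        t = self.target_values()
        if len(g) < 3:
            return True
        slopes = np.diff(t) / np.diff(g)
        return bool(np.all(np.diff(slopes) <= tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["growth_rate", "max_target"])


def set_uptake(model: Model | EcModel, uptake: float,
               exchange_id: str = "EX_glc__D_e") -> None:
    """Set the substrate uptake bound (mmol/gDW/h, positive magnitude)."""
    as_cobra(model).reactions.get_by_id(exchange_id).lower_bound = -abs(uptake)


def fba(
    model: Model | EcModel,
    objective_id: str | None = None,
    direction: str = "max",
    parsimonious: bool = False,
) -> FluxResult:
    """Solve one flux-balance problem.

    With ``parsimonious=True`` the stated objective value is fixed and total
    flux is minimised, yielding a reproducible vector; the reported objective
    value is always that of the primary objective.
    """
    m = as_cobra(model)
    with m:
        if objective_id is not None:
            m.objective = m.reactions.get_by_id(objective_id)
        m.objective_direction = direction
        if parsimonious:
            try:
                solution = pfba(m)
            except Exception:
                return FluxResult(None, {}, "infeasible")
            objective_rxn = next(
                r.id for r in m.reactions if r.objective_coefficient
            )
            return FluxResult(
                float(solution.fluxes[objective_rxn]),
                solution.fluxes.to_dict(),
                "optimal",
            )
        solution = m.optimize()
        if solution.status != "optimal":
            return FluxResult(None, {}, solution.status)
        return FluxResult(
            float(solution.objective_value), solution.fluxes.to_dict(), "optimal"
        )


def fva(
    model: Model | EcModel,
    reaction_ids: Sequence[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> FvaResult:
    """Flux ranges for each reaction at the given fraction of the optimum."""
    m = as_cobra(model)
    reaction_list = None if reaction_ids is None else list(reaction_ids)
    ranges = flux_variability_analysis(
        m, reaction_list=reaction_list, fraction_of_optimum=fraction_of_optimum
    )
    return FvaResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def molar_yield(
    flux_result: FluxResult,
    product_exchange: str,
    substrate_exchange: str,
) -> float:
    """Product secretion over substrate uptake magnitude (mol per mol)."""
    uptake = flux_result.fluxes.get(substrate_exchange, 0.0)
    if abs(uptake) < 1e-9:
        raise UndefinedYieldError(
            f"no substrate uptake through {substrate_exchange}"
        )
    return flux_result.fluxes.get(product_exchange, 0.0) / abs(uptake)


def add_ratio_constraint(
    model: Model | EcModel,
    numerator_rxn: str,
    denominator_rxn: str,
    rho_min: float,
    rho_max: float,
) -> Model:
    """Couple two secretion fluxes: rho_min <= v_num / v_den <= rho_max.

    Implemented as the linear rows v_num - rho_max*v_den <= 0 and
    v_num - rho_min*v_den >= 0, which are trivially satisfied when both
    fluxes vanish. Both reactions must be irreversible (split reversible
    secretion first). Mutates and returns the underlying model.
    """
    if not 0 < rho_min <= rho_max:
        raise ValueError(f"need 0 < rho_min <= rho_max, got [{rho_min}, {rho_max}]")
    m = as_cobra(model)
    num = m.reactions.get_by_id(numerator_rxn)
    den = m.reactions.get_by_id(denominator_rxn)
    for rxn in (num, den):
        if rxn.lower_bound < 0:
            raise ValueError(
                f"{rxn.id} is reversible; split it before ratio coupling"
            )
    upper = m.problem.Constraint(
        num.flux_expression - rho_max * den.flux_expression,
        ub=0.0, name=f"ratio_upper_{numerator_rxn}_{denominator_rxn}",
    )
    lower = m.problem.Constraint(
        num.flux_expression - rho_min * den.flux_expression,
        lb=0.0, name=f"ratio_lower_{numerator_rxn}_{denominator_rxn}",
    )
    m.add_cons_vars([upper, lower])
    return m


def production_envelope(
    model: Model | EcModel,
    growth_rxn: str,
    target_exchange: str,
    n_points: int = 20,
) -> ParetoCurve:
    """Maximum target flux along a uniform growth grid [0, mu_max].

    At each grid point growth is fixed (lexicographic: growth first, then
    target); infeasible points are recorded as absent.
    """
    m = as_cobra(model)
    base = fba(m, growth_rxn, "max")
    if base.status != "optimal":
        raise RuntimeError(f"base growth FBA {base.status}")
    mu_max = base.objective_value
    grid = [0.0] if n_points == 1 else np.linspace(0.0, mu_max, n_points)
    points = []
    growth = m.reactions.get_by_id(growth_rxn)
    for g in grid:
        with m:
            growth.bounds = (g, g)
            m.objective = m.reactions.get_by_id(target_exchange)
            value = m.slim_optimize(error_value=np.nan)
        if np.isfinite(value):
            points.append((float(g), float(value)))
    return ParetoCurve(points=points, growth_reaction=growth_rxn,
                       target_reaction=target_exchange)


def _disable(m: Model, base_id: str) -> None:
    """Zero the bounds of a reaction and of its fwd/rev split halves."""
    for rid in (base_id, f"{base_id}_fwd", f"{base_id}_rev"):
        if rid in m.reactions:
            m.reactions.get_by_id(rid).bounds = (0.0, 0.0)


def hydrogen_yield_scenario(
    model: Model | EcModel,
    scenario: str,
    uptake: float = 10.0,
    rho: tuple[float, float] = (1.0, 2.0),
    substrate_exchange: str = "EX_glc__D_e",
    h2_exchange: str = "EX_h2_e",
) -> FluxResult:
    """Maximise hydrogen under one of the canonical fermentation scenarios.

    ``acetate_only``
        Ethanol and lactate secretion closed: all acetyl-CoA leaves as
        acetate and both hydrogenases run (theoretical 4 mol/mol).
    ``ethanol_type``
        NADH-dependent hydrogenase and lactate disabled, so the ethanol
        branch is the only NADH sink (2 mol/mol, ferredoxin H2 only).
    ``ratio_coupled``
        Ethanol:acetate secretion coupled within ``rho``; amino-acid
        exchanges closed (2 mol/mol at the ratio-1 corner).
    ``ratio_amino_open``
        Ratio coupling plus open glutamate/glutamine secretion, diverting
        PEP/acetyl-CoA carbon and sparing NADH (3 mol/mol).
    """
    m = as_cobra(model).copy()
    m.reactions.get_by_id(substrate_exchange).lower_bound = -abs(uptake)
    # theoretical-yield scenarios are zero-growth fermentation states: the
    # biomass drain is closed so it cannot act as a hidden electron sink
    for rxn in m.reactions:
        if rxn.objective_coefficient:
            rxn.bounds = (0.0, 0.0)
    for ex in ("EX_glu__L_e", "EX_gln__L_e"):
        if ex in m.reactions:
            m.reactions.get_by_id(ex).upper_bound = 0.0
    if scenario == "acetate_only":
        for ex in ("EX_etoh_e", "EX_lac__L_e"):
            if ex in m.reactions:
                m.reactions.get_by_id(ex).upper_bound = 0.0
    elif scenario == "ethanol_type":
        _disable(m, "HYDN")
        _disable(m, "LDH")
    elif scenario in ("ratio_coupled", "ratio_amino_open"):
        if scenario == "ratio_amino_open":
            for ex in ("EX_glu__L_e", "EX_gln__L_e"):
                m.reactions.get_by_id(ex).upper_bound = 1000.0
        add_ratio_constraint(m, "EX_etoh_e", "EX_ac_e", rho[0], rho[1])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return fba(m, h2_exchange, "max")
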