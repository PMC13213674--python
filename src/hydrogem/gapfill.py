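"""Targeted gap-filling of biomass-precursor biosynthesis.

A degraded network that cannot make one or more biomass precursors is
repaired against a universal candidate database: all candidates are added
with a per-reaction flux penalty, total penalised candidate flux is minimised
subject to a minimum biomass flux, candidates carrying flux are retained, and
the retained set is pruned greedily (any reaction whose removal keeps growth
above threshold is dropped). Candidate reversibility can be assigned from
standard Gibbs free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cobra import Model, Reaction

from hydrogem.ec_builder import as_cobra

__all__ = [
    "UniversalDb",
    "GapfillResult",
    "producibility_report",
    "gapfill_biomass",
    "reversibility_from_dg",
]

PRODUCIBILITY_EPS = 1e-6
UNIVERSAL_PREFIX = "U_"

#: Conserved-moiety carriers: net synthesis of the loaded form is impossible
#: at steady state (the moiety is never created), so the producibility probe
#: drains the loaded species while returning its free carrier.
MOIETY_PARTNERS = {
    "accoa_c": "coa_c",
    "atp_c": "adp_c",
    "gtp_c": "gdp_c",
    "nadh_c": "nad_c",
    "nadph_c": "nadp_c",
    "fdrd_c": "fdox_c",
}


def reversibility_from_dg(
    dg0: float | None, threshold: float = 30.0
) -> tuple[float, float]:
    """Bounds from a standard Gibbs free energy (kJ/mol).

    |dG| within the threshold: reversible; strongly exergonic: forward only;
    strongly endergonic: reverse only; unknown: reversible.
    """
    if dg0 is None:
        return (-1000.0, 1000.0)
    if abs(dg0) <= threshold:
        return (-1000.0, 1000.0)
    if dg0 < 0:
        return (0.0, 1000.0)
    return (-1000.0, 0.0)


@dataclass
class UniversalDb:
    """Candidate reactions for gap-filling, ids namespaced with ``U_``."""

    reactions: list[Reaction]
    dg0: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        renamed = []
        for rxn in self.reactions:
            if not rxn.id.startswith(UNIVERSAL_PREFIX):
                dg = self.dg0.pop(rxn.id, None)
                rxn.id = f"{UNIVERSAL_PREFIX}{rxn.id}"
                if dg is not None:
                    self.dg0[rxn.id] = dg
            renamed.append(rxn)
        self.reactions = renamed
        for rxn in self.reactions:
            dg = self.dg0.get(rxn.id)
            if dg is not None:
                rxn.bounds = reversibility_from_dg(dg)

    @property
    def ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    @classmethod
    def from_model_reactions(
        cls,
        source: Model,
        reaction_ids: Iterable[str],
        dg0: Mapping[str, float] | None = None,
    ) -> "UniversalDb":
        rxns = [source.reactions.get_by_id(rid).copy() for rid in reaction_ids]
        return cls(reactions=rxns, dg0=dict(dg0 or {}))


@dataclass
class GapfillResult:
    """Outcome of one gap-filling run."""

    added_reaction_ids: list[str]
    producibility_before: dict[str, bool]
    producibility_after: dict[str, bool]
    iterations: int
    success: bool
    blocked_precursors: list[str] = field(default_factory=list)
    model: Model | None = None

    def to_tsv(self, path: str | Path) -> Path:
        import pandas as pd

        rows = [{"added_reaction_id": rid} for rid in self.added_reaction_ids]
        pd.DataFrame(rows, columns=["added_reaction_id"]).to_csv(
            path, sep="\t", index=False
        )
        return Path(path)


def _biomass_reaction(model: Model):
    candidates = [r for r in model.reactions if r.objective_coefficient > 0]
    if not candidates:
        raise ValueError("model has no objective reaction")
    return candidates[0]


def biomass_precursors(model: Model) -> list[str]:
    """Metabolite ids consumed by the biomass reaction (energy carriers included)."""
    biomass = _biomass_reaction(model)
    return sorted(m.id for m, c in biomass.metabolites.items() if c < 0)


def producibility_report(
    model: Model,
    precursor_ids: Iterable[str] | None = None,
    epsilon: float = PRODUCIBILITY_EPS,
    moiety_partners: Mapping[str, str] | None = None,
) -> dict[str, bool]:
    """Can the network synthesise each precursor from the open medium?

    Each precursor gets a temporary demand reaction that is maximised; it is
    producible iff the optimum exceeds ``epsilon``. Precursors listed in
    ``moiety_partners`` (carrier-bound species such as acetyl-CoA, ATP,
    NAD(P)H) are probed as loaded-form turnover: the demand drains the loaded
    species and returns its free carrier. The model is untouched on return.
    """
    m = as_cobra(model)
    if precursor_ids is None:
        precursor_ids = biomass_precursors(m)
    if moiety_partners is None:
        moiety_partners = MOIETY_PARTNERS
    report: dict[str, bool] = {}
    for met_id in precursor_ids:
        met = m.metabolites.get_by_id(met_id)
        partner_id = moiety_partners.get(met_id)
        with m:
            demand = Reaction(f"DM_{met_id}__probe", lower_bound=0.0,
                              upper_bound=1000.0)
            m.add_reactions([demand])
            stoich = {met: -1.0}
            if partner_id is not None and partner_id in m.metabolites:
                stoich[m.metabolites.get_by_id(partner_id)] = 1.0
            demand.add_metabolites(stoich)
            m.objective = demand
            optimum = m.slim_optimize(error_value=0.0)
        report[met_id] = bool(optimum > epsilon)
    return report


def gapfill_biomass(
    model: Model,
    universal: UniversalDb,
    penalty_weights: Mapping[str, float] | None = None,
    max_iter: int = 10,
    growth_threshold: float = 0.05,
    epsilon: float = PRODUCIBILITY_EPS,
) -> GapfillResult:
    """Add a minimal set of universal reactions until biomass can be formed.

    Penalised-flux relaxation: every candidate joins the model, total
    penalised candidate flux is minimised subject to biomass >= threshold;
    flux-carrying candidates are retained and greedily pruned. Pre-existing
    model reactions are never touched.
    """
    if not universal.reactions:
        raise ValueError("universal database is empty")
    penalties = dict(penalty_weights or {})
    work = model.copy()
    biomass = _biomass_reaction(work)
    precursors = biomass_precursors(work)
    before = producibility_report(work, precursors, epsilon)

    candidates = [r.copy() for r in universal.reactions]
    work.add_reactions(candidates)

    retained = set(universal.ids)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # penalised LP: minimise sum penalty * |v_candidate| s.t. growth >= threshold
        with work:
            biomass.lower_bound = growth_threshold
            expression = sum(
                penalties.get(rid, 1.0)
                * (
                    work.reactions.get_by_id(rid).forward_variable
                    + work.reactions.get_by_id(rid).reverse_variable
                )
                for rid in sorted(retained)
            )
            work.objective = work.problem.Objective(expression, direction="min")
            solution = work.optimize()
            if solution.status != "optimal":
                blocked = [
                    met for met, ok in producibility_report(
                        work, precursors, epsilon
                    ).items() if not ok
                ]
                return GapfillResult(
                    added_reaction_ids=[], producibility_before=before,
                    producibility_after=before, iterations=iterations,
                    success=False, blocked_precursors=blocked,
                )
            carrying = {
                rid for rid in retained
                if abs(solution.fluxes[rid]) > epsilon
            }
        # drop candidates the LP did not use
        work.remove_reactions(
            [work.reactions.get_by_id(rid) for rid in retained - carrying]
        )
        retained = carrying
        # greedy pruning: drop any retained reaction not needed for growth
        pruned = True
        while pruned:
            pruned = False
            for rid in sorted(retained):
                rxn = work.reactions.get_by_id(rid)
                with work:
                    rxn.bounds = (0.0, 0.0)
                    growth = work.slim_optimize(error_value=0.0)
                if growth >= growth_threshold - 1e-9:
                    work.remove_reactions([rxn])
                    retained.discard(rid)
                    pruned = True
        # stability check: does the retained set still support growth?
        growth = work.slim_optimize(error_value=0.0)
        if growth >= growth_threshold - 1e-9:
            break

    after = producibility_report(work, precursors, epsilon)
    success = all(after.values())
    return GapfillResult(
        added_reaction_ids=sorted(retained),
        producibility_before=before,
        producibility_after=after,
        iterations=iterations,
        success=success,
        blocked_precursors=[m for m, ok in after.items() if not ok],
        model=work,
    )
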