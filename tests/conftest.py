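"""Shared fixtures: the core fermentation network and derived models."""

import pytest
from cobra import Metabolite, Model, Reaction

from hydrogem import synthetic_data
from hydrogem.ec_builder import build_ec_model


@pytest.fixture(scope="session")
def core_model():
    """Full-featured core fermentation network (session-scoped, read-only)."""
    return synthetic_data.build_core_network()


@pytest.fixture()
def core_model_copy(core_model):
    return core_model.copy()


@pytest.fixture(scope="session")
def reference_ec(core_model):
    """Enzyme-constrained core model with the curated kinetic table."""
    table, config = synthetic_data.reference_enzyme_table(core_model)
    return build_ec_model(core_model, table, config)


@pytest.fixture(scope="session")
def chain_model():
    """Minimal linear chain A -> B -> C with uptake capped at 5."""
    m = Model("chain")
    a = Metabolite("a_c", formula="C", charge=0, compartment="c")
    b = Metabolite("b_c", formula="C", charge=0, compartment="c")
    c_ = Metabolite("c_c", formula="C", charge=0, compartment="c")
    a_e = Metabolite("a_e", formula="C", charge=0, compartment="e")
    c_e = Metabolite("c_e", formula="C", charge=0, compartment="e")
    rxns = []
    ex_a = Reaction("EX_a_e", lower_bound=-5.0, upper_bound=1000.0)
    ex_a.add_metabolites({a_e: -1})
    t_a = Reaction("At", lower_bound=0.0, upper_bound=1000.0)
    t_a.add_metabolites({a_e: -1, a: 1})
    r1 = Reaction("R1", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({a: -1, b: 1})
    r2 = Reaction("R2", lower_bound=0.0, upper_bound=1000.0)
    r2.add_metabolites({b: -1, c_: 1})
    t_c = Reaction("Ct", lower_bound=0.0, upper_bound=1000.0)
    t_c.add_metabolites({c_: -1, c_e: 1})
    ex_c = Reaction("EX_c_e", lower_bound=0.0, upper_bound=1000.0)
    ex_c.add_metabolites({c_e: -1})
    blocked = Metabolite("dead_c", formula="C", charge=0, compartment="c")
    r_blocked = Reaction("BLOCKED", lower_bound=0.0, upper_bound=1000.0)
    r_blocked.add_metabolites({a: -1, blocked: 1})
    m.add_reactions([ex_a, t_a, r1, r2, t_c, ex_c, r_blocked])
    m.objective = "EX_c_e"
    return m
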