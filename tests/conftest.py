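"""Shared fixtures: tiny hand-built FBA networks and one generated community."""

import pytest

from fluxcord import (
    CommunitySpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    Scenario,
    SpeciesSpec,
    generate_counts,
    generate_models,
    trio_spec,
)


def build_model(name, metabolites, reactions, biomass=None):
    model = MetabolicModel(species_name=name, biomass_reaction_id=biomass)
    for mid, comp in metabolites:
        model.add_metabolite(Metabolite(id=mid, compartment=comp))
    for rxn in reactions:
        model.add_reaction(rxn)
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """EX_A --(uptake<=10)--> CONV --> EX_B; maximizing export gives flux 10 everywhere."""
    model = build_model(
        "chain",
        [("A[e]", "e"), ("B[e]", "e")],
        [
            Reaction("EX_A", {"A[e]": -1}, -10, 1000, gene_ids={"gA"}),
            Reaction("CONV", {"A[e]": -1, "B[e]": 1}, 0, 1000, gene_ids={"gC"}),
            Reaction("EX_B", {"B[e]": -1}, 0, 1000, gene_ids={"gB"}),
        ],
    )
    scenario = Scenario("export_B", exchange_bounds={"EX_A": (-10, 0)}, objective={"EX_B": 1})
    return model, scenario


@pytest.fixture
def parallel_model():
    """Two routes A->B: one direct reaction vs. a two-step detour; parsimony picks the short one."""
    model = build_model(
        "parallel",
        [("A[e]", "e"), ("A[c]", "c"), ("X[c]", "c"), ("B[c]", "c"), ("B[e]", "e")],
        [
            Reaction("EX_A", {"A[e]": -1}, -10, 0),
            Reaction("T_A", {"A[e]": -1, "A[c]": 1}, 0, 1000),
            Reaction("DIRECT", {"A[c]": -1, "B[c]": 1}, 0, 1000),
            Reaction("LONG1", {"A[c]": -1, "X[c]": 1}, 0, 1000),
            Reaction("LONG2", {"X[c]": -1, "B[c]": 1}, 0, 1000),
            Reaction("T_B", {"B[c]": -1, "B[e]": 1}, 0, 1000),
            Reaction("EX_B", {"B[e]": -1}, 0, 1000),
        ],
    )
    scenario = Scenario("export_B", exchange_bounds={"EX_A": (-10, 0)}, objective={"EX_B": 1})
    return model, scenario


@pytest.fixture
def futile_model():
    """A chain plus a two-reaction internal cycle that can spin without mass effect."""
    model = build_model(
        "futile",
        [("A[e]", "e"), ("A[c]", "c"), ("Y[c]", "c"), ("B[e]", "e")],
        [
            Reaction("EX_A", {"A[e]": -1}, -10, 0),
            Reaction("T_A", {"A[e]": -1, "A[c]": 1}, 0, 1000),
            Reaction("CYC1", {"A[c]": -1, "Y[c]": 1}, 0, 1000),
            Reaction("CYC2", {"Y[c]": -1, "A[c]": 1}, 0, 1000),
            Reaction("T_B", {"A[c]": -1, "B[e]": 1}, 0, 1000),
            Reaction("EX_B", {"B[e]": -1}, 0, 1000),
        ],
    )
    scenario = Scenario("export_B", exchange_bounds={"EX_A": (-10, 0)}, objective={"EX_B": 1})
    return model, scenario


@pytest.fixture(scope="session")
def trio():
    spec = trio_spec(seed=11)
    return spec, generate_models(spec)


@pytest.fixture(scope="session")
def trio_counts(trio):
    spec, builds = trio
    return generate_counts(spec, builds)


def single_species_spec(seed, core="linear_fixation", n_background=60, **kwargs):
    defaults = dict(
        seed=seed,
        species=(SpeciesSpec("Solo_sp_TEST", core, n_background_reactions=n_background),),
    )
    defaults.update(kwargs)
    return CommunitySpec(**defaults)
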