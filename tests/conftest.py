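import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aromflux import MetabolicModel, Metabolite, Reaction  # noqa: E402
from aromflux.synthetic import ToySpec, make_toy_model  # noqa: E402

# session-scoped builds, copied per test to keep mutation-safety
_CACHE: dict = {}


def _toy(key, **kwargs):
    if key not in _CACHE:
        _CACHE[key] = make_toy_model(ToySpec(**kwargs))
    return _CACHE[key].copy()


@pytest.fixture
def toy_model():
    """Default four-substrate funneling model, native THF demethylation."""
    return _toy("default")


@pytest.fixture
def toy_model_variant():
    """Factory: funneling model for a given demethylase variant."""
    def make(variant="native_THF", substrates=("glucose", "vanillic",
                                               "syringic", "p-HBA")):
        return _toy((variant, tuple(substrates)), substrates=tuple(substrates),
                    demethylase=variant)
    return make


@pytest.fixture
def chain_model():
    """EX_A -> A -> B -> 0.5 biomass linear chain with uptake cap 1."""
    m = MetabolicModel(id="chain")
    m.add_metabolite(Metabolite(id="A_e", compartment="e", formula="C2H4O2"))
    m.add_metabolite(Metabolite(id="A_c", compartment="c", formula="C2H4O2"))
    m.add_metabolite(Metabolite(id="B_c", compartment="c", formula="C2H4O2"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                            lower_bound=-1.0, kind="exchange"))
    m.add_reaction(Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                            lower_bound=0.0, kind="transport"))
    m.add_reaction(Reaction(id="CONV", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                            lower_bound=0.0))
    m.add_reaction(Reaction(id="GROWTH", stoichiometry={"B_c": -2.0},
                            lower_bound=0.0, kind="biomass",
                            gene_association="bioZ"))
    m.objective = "GROWTH"
    return m
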