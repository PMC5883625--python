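import pytest

from pmaflux.model_core import MetabolicModel, Metabolite, Reaction, build_reduced_model


@pytest.fixture(scope="session")
def reduced_model() -> MetabolicModel:
    return build_reduced_model()


def make_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_glc (lb −uptake) → A → B → EX_B, objective EX_B.

    The uptake exchange reuses the id of the packaged glucose exchange so the
    route-scan machinery can address it.
    """
    mets = [
        Metabolite("A", "species A", "cytosol", {"C": 1, "H": 2, "O": 1}),
        Metabolite("B", "species B", "cytosol", {"C": 1, "H": 2, "O": 1}),
    ]
    rxns = [
        Reaction("EX_glc", "uptake", {"A": -1.0}, -uptake, 0.0, "exchange"),
        Reaction("AB", "conversion", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", "secretion", {"B": -1.0}, 0.0, 1000.0, "exchange"),
    ]
    model = MetabolicModel(mets, rxns, objective_id="EX_B")
    model.validate()
    return model


@pytest.fixture()
def chain_model() -> MetabolicModel:
    return make_chain_model()
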