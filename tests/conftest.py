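import numpy as np
import pytest

from serflux import synth
from serflux.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_A(<=10) -> A -> B -> biomass; optimum 10."""
    return synth.toy_network("chain")


@pytest.fixture
def parallel_model() -> MetabolicModel:
    return synth.toy_network("parallel")


@pytest.fixture
def serine_model() -> MetabolicModel:
    return synth.serine_toy_model()


@pytest.fixture
def producer_consumer_model() -> MetabolicModel:
    """Independent serine producer and consumer with envelopes [0,3] each.

    P makes S from A (capped at 3); D degrades S to W (capped at 3); a free
    S exchange decouples them, and biomass runs off B independently, so the
    net production P - D ranges over [-3, 3].  All bounds finite so the
    vertex-enumeration oracle applies.
    """
    mets = [Metabolite(m) for m in ["A", "S", "W", "B"]]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -10.0, 100.0),
        Reaction("P", {"A": -1.0, "S": 1.0}, 0.0, 3.0),  # producer
        Reaction("D", {"S": -1.0, "W": 1.0}, 0.0, 3.0),  # consumer
        Reaction("EX_S", {"S": -1.0}, -10.0, 10.0),
        Reaction("EX_W", {"W": -1.0}, 0.0, 100.0),
        Reaction("EX_B", {"B": -1.0}, -10.0, 100.0),
        Reaction("BIOMASS", {"B": -1.0}, 0.0, 100.0),
    ]
    return MetabolicModel(mets, rxns, set(), "BIOMASS")
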