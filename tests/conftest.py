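import logging

import pytest

from gemreduce import apply_medium, build_core_network
from gemreduce.lumping import LumpingConfig, generate_lumps
from gemreduce.synthetic import ToyGemSpec, make_toy_gem

# the extracellular attachment legitimately warns about secretion products
# unreachable from other subsystems' chains; keep test output clean
logging.getLogger("gemreduce.expand").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy():
    """Default planted toy model with its ground truth (seed 1)."""
    model, truth = make_toy_gem(ToyGemSpec(seed=1))
    return model, truth


@pytest.fixture(scope="session")
def toy_core(toy):
    model, truth = toy
    return build_core_network(model, truth.selection, truth.cofactors)


@pytest.fixture(scope="session")
def toy_lumping(toy, toy_core):
    model, truth = toy
    return generate_lumps(
        model, toy_core, truth.medium, truth.cofactors, LumpingConfig(),
        condition="base",
    )


@pytest.fixture(scope="session")
def toy_fed(toy):
    """Toy model with the medium applied."""
    model, truth = toy
    return apply_medium(model, truth.medium)
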