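import numpy as np
import pytest

from gtpase_dora import (
    FeedbackLogic,
    Kinetics,
    KineticParameters,
    ModelSpec,
)

ALL_SPECS = [
    ModelSpec(kinetics=k, feedback_logic=l)
    for k in Kinetics
    for l in FeedbackLogic
]


@pytest.fixture
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture
def ma_spec() -> ModelSpec:
    return ModelSpec()


@pytest.fixture
def hill_spec() -> ModelSpec:
    return ModelSpec(kinetics=Kinetics.HILL)


def random_params(rng: np.random.Generator, logic=FeedbackLogic.NONE,
                  lo: float = 1e-2, hi: float = 1e1) -> KineticParameters:
    """Log-uniform random parameter set; feedback strength drawn on its own
    stated range when the logic uses it."""
    names = list(KineticParameters().to_dict())
    d = {n: float(10 ** rng.uniform(np.log10(lo), np.log10(hi))) for n in names}
    d["k_feedback"] = (
        float(10 ** rng.uniform(-1, 2.6)) if logic is not FeedbackLogic.NONE else 0.0
    )
    return KineticParameters(**d)
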