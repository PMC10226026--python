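import numpy as np
import pandas as pd
import pytest

from pemem import build_design, counterbalance_assignment, make_synthetic_study
from pemem.design import combine_phases, generate_encoding_schedule, \
    generate_learning_schedule


@pytest.fixture(scope="session")
def exp1():
    return build_design("EXP1")


@pytest.fixture(scope="session")
def exp2():
    return build_design("EXP2")


@pytest.fixture(scope="session")
def exp2_schedule(exp2):
    """One subject's pooled learning+encoding schedule for Experiment 2."""
    assignment = counterbalance_assignment(0, exp2)
    learn = generate_learning_schedule(exp2, assignment, 40, seed=0)
    enc = generate_encoding_schedule(exp2, assignment, seed=0)
    return combine_phases(learn, enc)


@pytest.fixture(scope="session")
def small_study(exp2):
    """Six-subject Experiment 2 study with a strong PE x PO memory effect."""
    return make_synthetic_study(
        6, exp2,
        memory_coefficients={"b0": 0.0, "b_pe": 0.0, "b_po": 0.0, "b_pe_po": 1.5},
        seed=11,
    )


@pytest.fixture(scope="session")
def exp1_study(exp1):
    return make_synthetic_study(3, exp1, seed=13)
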