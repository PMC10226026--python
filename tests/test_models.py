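"""Learning-rule mathematics: Q updates, softmax, prediction errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pemem.models import (MODELS, QTable, feedback_vector, get_model,
                          init_q_table, run_model, signed_pe, softmax_probs,
                          unsigned_pe)


@pytest.mark.parametrize("J,expected", [(3, 1 / 3), (2, 0.5), (1, 1.0)])
def test_initialization_is_uniform_prior(J, expected):
    qt = init_q_table(J, 4)
    assert np.allclose(qt.values, expected)
    assert (qt.t == 0).all()


def test_init_rejects_nonpositive_dims():
    with pytest.raises(ValueError):
        init_q_table(0, 3)


def test_feedback_vector_is_one_hot():
    assert feedback_vector(1, 3).tolist() == [0, 1, 0]
    assert feedback_vector(0, 1).tolist() == [1]
    with pytest.raises(IndexError):
        feedback_vector(3, 3)


def test_first_context_trial_overwrites_prior_for_dlri():
    qt = init_q_table(3, 2)
    qt.step_instructive(MODELS["dLRI"], context=1, presented=2)
    assert qt.values[:, 1].tolist() == [0, 0, 1]
    assert qt.values[:, 0].tolist() == [1 / 3] * 3  # other contexts untouched


def test_flri_hand_update():
    qt = init_q_table(2, 1)
    qt.step_instructive(MODELS["fLRI"], 0, presented=0, alpha=0.2)
    assert qt.values[:, 0] == pytest.approx([0.6, 0.4])


def test_evaluative_updates_only_chosen_entry():
    qt = init_q_table(2, 1)
    qt.step_evaluative(0, chosen=0, correct=True, alpha=0.2)
    assert qt.values[:, 0] == pytest.approx([0.6, 0.5])
    qt2 = init_q_table(2, 1)
    qt2.step_evaluative(0, chosen=0, correct=False, alpha=0.2)
    assert qt2.values[:, 0] == pytest.approx([0.4, 0.5])
    qt3 = init_q_table(2, 1)
    qt3.step_evaluative(0, chosen=1, correct=False, alpha=0.0)
    assert qt3.values[:, 0] == pytest.approx([0.5, 0.5])


@given(st.lists(st.integers(0, 2), min_size=1, max_size=60))
@settings(deadline=None, max_examples=50)
def test_dlri_tracks_running_category_frequencies(seq):
    """The decaying-rate instructive rule is a running mean of one-hots."""
    qt = init_q_table(3, 1)
    for t, j in enumerate(seq, start=1):
        qt.step_instructive(MODELS["dLRI"], 0, j)
        freq = np.bincount(seq[:t], minlength=3) / t
        assert np.allclose(qt.values[:, 0], freq)


@given(st.lists(st.integers(0, 2), min_size=1, max_size=60),
       st.floats(0.0, 1.0))
@settings(deadline=None, max_examples=50)
def test_q_values_bounded(seq, alpha):
    qt = init_q_table(3, 1)
    for j in seq:
        qt.step_instructive(MODELS["fLRI"], 0, j, alpha)
        assert ((qt.values >= 0) & (qt.values <= 1)).all()


def test_dflri_with_alpha_one_equals_dlri():
    rng = np.random.default_rng(0)
    seq = rng.integers(0, 3, 40)
    a, b = init_q_table(3, 1), init_q_table(3, 1)
    for j in seq:
        a.step_instructive(MODELS["dLRI"], 0, int(j))
        b.step_instructive(MODELS["dfLRI"], 0, int(j), alpha=1.0)
    assert np.allclose(a.values, b.values)


def test_softmax_flat_and_symmetric():
    assert softmax_probs(np.array([0.9, 0.2, 0.4]), 0.0) == pytest.approx([1 / 3] * 3)
    assert softmax_probs(np.array([0.7, 0.7]), 4.2) == pytest.approx([0.5, 0.5])


def test_softmax_translation_invariance():
    q = np.array([0.1, 0.5, 0.9])
    assert np.allclose(softmax_probs(q, 3.0), softmax_probs(q + 7.0, 3.0))


def test_softmax_deterministic_regime():
    p = softmax_probs(np.array([1.0, 0.0, 0.0]), 10.0)
    assert p[0] == pytest.approx(0.99991, abs=1e-5)
    assert p[1] == pytest.approx(4.5e-5, abs=1e-5)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_softmax_rejects_negative_beta():
    with pytest.raises(ValueError):
        softmax_probs(np.array([0.5, 0.5]), -1.0)


def test_unsigned_pe_examples():
    assert unsigned_pe(np.array([0.5, 0.5]), 0) == pytest.approx(0.5)
    assert unsigned_pe(np.full(3, 1 / 3), 2) == pytest.approx(2 / 3)
    assert unsigned_pe(np.array([1.0, 0.0]), 0) == 0.0


def test_signed_pe_examples():
    q = np.array([0.5, 0.5])
    assert signed_pe(q, 0, True) == pytest.approx(0.5)
    assert signed_pe(q, 0, False) == pytest.approx(-0.5)
    assert signed_pe(np.array([1.0, 0.0]), 0, True) == 0.0


def _toy_schedule(seq, context=0):
    return pd.DataFrame(dict(
        phase="LEARNING", context=context, condition="x",
        category_shown=seq, is_filler=0,
        object_id=[f"o{i}" for i in range(len(seq))],
    ))


def test_run_model_frozen_values_give_constant_pe():
    sched = _toy_schedule([0, 1, 2, 0, 1])
    traj = run_model(sched, [0] * 5, "fLRI", dict(alpha=0.0, beta=2.0))
    assert np.allclose(traj["pe_unsigned"], 1 - 1 / 3)


def test_run_model_dlri_matches_frequency_oracle():
    rng = np.random.default_rng(5)
    seq = rng.integers(0, 3, 50).tolist()
    traj = run_model(_toy_schedule(seq), seq, "dLRI", dict(beta=1.0))
    for i in range(1, len(seq)):
        freq = np.bincount(seq[:i], minlength=3)[seq[i]] / i
        assert traj["q_presented"].iloc[i] == pytest.approx(freq)


def test_run_model_rejects_misaligned_choices():
    with pytest.raises(ValueError, match="length"):
        run_model(_toy_schedule([0, 1]), [0], "fLRI", dict(alpha=0.1, beta=1.0))


def test_unknown_model_name_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        get_model("qLearner")
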