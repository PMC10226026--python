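"""Delta-rule learning models, softmax choice, and prediction errors.

Four Rescorla-Wagner variants of context -> object-category learning are
implemented.  Each maintains a category-by-context matrix of expected values
Q, initialized at 1/J (J = number of categories), and updates the row of the
trial's context from a prediction error delta = r - Q:

* ``dLRI``  - instructive, learning rate 1/t (t = per-context trial count);
  equivalent to a running mean of the one-hot presentation vectors, i.e. the
  delta-rule form of the optimal Dirichlet-multinomial learner.
* ``dfLRI`` - instructive, learning rate alpha/t (alpha free per subject).
* ``fLRI``  - instructive, constant free learning rate alpha.
* ``fLRE``  - evaluative: only the *chosen* category's value is updated, with
  reward r = 1 if the choice was correct and 0 otherwise.

Instructive models update all J entries toward the one-hot vector of the
presented category, regardless of the agent's choice.  Choices are generated
or evaluated with a softmax over the context's Q row with inverse temperature
beta.

The trial-level quantities used by the memory analysis are the *unsigned*
prediction error 1 - Q[presented] (computed on the pre-update row) and the
*signed* prediction error r - Q[chosen] with r = correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHA_BOUNDS = (0.0, 1.0)
BETA_BOUNDS = (0.0, 10.0)


@dataclass(frozen=True)
class ModelSpec:
    """One learning model: free parameters, bounds and feedback mode."""

    name: str
    free_params: tuple[str, ...]
    feedback: str  # "instructive" | "evaluative"
    decaying: bool  # learning rate scaled by 1/t

    @property
    def k(self) -> int:
        """Number of free parameters (the BIC penalty k_m)."""
        return len(self.free_params)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        table = {"alpha": ALPHA_BOUNDS, "beta": BETA_BOUNDS}
        return tuple(table[p] for p in self.free_params)


MODELS: dict[str, ModelSpec] = {
    "dLRI": ModelSpec("dLRI", ("beta",), "instructive", True),
    "dfLRI": ModelSpec("dfLRI", ("alpha", "beta"), "instructive", True),
    "fLRI": ModelSpec("fLRI", ("alpha", "beta"), "instructive", False),
    "fLRE": ModelSpec("fLRE", ("alpha", "beta"), "evaluative", False),
}

#: Fixed comparison order, also the tie-break order after parameter count.
MODEL_ORDER = ("dLRI", "dfLRI", "fLRI", "fLRE")


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; expected one of {sorted(MODELS)}"
        ) from None


class QTable:
    """Expected values Q[category, context] with per-context trial counters.

    Entries start at 1/J and stay in [0, 1] under any admissible update
    sequence.  The counter ``t`` of a context is advanced *before* the
    update, so the first trial of a context has t = 1 (a decaying-rate model
    then overwrites the prior completely).
    """

    def __init__(self, n_categories: int, n_contexts: int):
        if n_categories < 1 or n_contexts < 1:
            raise ValueError("n_categories and n_contexts must be positive")
        self.n_categories = n_categories
        self.n_contexts = n_contexts
        self.values = np.full((n_categories, n_contexts), 1.0 / n_categories)
        self.t = np.zeros(n_contexts, dtype=int)

    def row(self, context: int) -> np.ndarray:
        """Current Q values of all categories in ``context`` (a copy)."""
        return self.values[:, context].copy()

    def step_instructive(
        self, model: ModelSpec, context: int, presented: int, alpha: float = 1.0
    ) -> np.ndarray:
        """Advance t, update all entries of the context row; return delta."""
        if not 0 <= presented < self.n_categories:
            raise IndexError(f"category {presented} out of range")
        self.t[context] += 1
        if model.decaying:
            base = 1.0 / self.t[context]
            rate = base if model.name == "dLRI" else alpha * base
        else:
            rate = alpha
        r = feedback_vector(presented, self.n_categories)
        delta = r - self.values[:, context]
        self.values[:, context] += rate * delta
        return delta

    def step_evaluative(
        self, context: int, chosen: int, correct: bool, alpha: float
    ) -> float:
        """Advance t, update only the chosen entry with r = correctness."""
        if not 0 <= chosen < self.n_categories:
            raise IndexError(f"category {chosen} out of range")
        self.t[context] += 1
        r = 1.0 if correct else 0.0
        delta = r - self.values[chosen, context]
        self.values[chosen, context] += alpha * delta
        return delta


def init_q_table(n_categories: int, n_contexts: int) -> QTable:
    """Fresh table with every entry 1/n_categories and counters at zero."""
    return QTable(n_categories, n_contexts)


def feedback_vector(presented: int, n_categories: int) -> np.ndarray:
    """One-hot feedback r: 1 at the presented category, 0 elsewhere."""
    if not 0 <= presented < n_categories:
        raise IndexError(
            f"presented category {presented} out of range for J={n_categories}"
        )
    r = np.zeros(n_categories)
    r[presented] = 1.0
    return r


def softmax_probs(q_row: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities P_j = exp(beta Q_j) / sum_n exp(beta Q_n).

    beta = 0 yields the uniform distribution; the max-shift guard makes the
    result invariant to adding a constant to all Q values.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q_row, dtype=float)
    z = beta * q
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def unsigned_pe(q_row: np.ndarray, presented: int) -> float:
    """Unsigned prediction error: 1 - Q[presented] on the pre-update row."""
    return 1.0 - float(q_row[presented])


def signed_pe(q_row: np.ndarray, chosen: int, correct: bool) -> float:
    """Signed prediction error: r - Q[chosen], r = 1 if correct else 0."""
    r = 1.0 if correct else 0.0
    return r - float(q_row[chosen])


def run_model(
    schedule: pd.DataFrame,
    choices: np.ndarray,
    model: ModelSpec | str,
    params: dict[str, float],
) -> pd.DataFrame:
    """Replay a pooled learning+encoding schedule under fixed parameters.

    ``choices`` must align row-for-row with ``schedule``; they drive fLRE
    updates and the evaluation of choice probabilities, while instructive
    updates depend only on the presented categories.  Filler trials are
    processed like any other (they update Q).  Returns the schedule joined
    with per-trial model quantities, all computed on the *pre-update* Q row:
    ``q_presented``, ``pe_unsigned``, ``pe_signed``, ``p_chosen``,
    ``prediction_outcome`` (1 correct / 0 incorrect).
    """
    if isinstance(model, str):
        model = get_model(model)
    choices = np.asarray(choices, dtype=int)
    if len(choices) != len(schedule):
        raise ValueError(
            f"choices length {len(choices)} != schedule length {len(schedule)}"
        )
    alpha = params.get("alpha", 1.0)
    beta = params["beta"]
    contexts = schedule["context"].to_numpy()
    shown = schedule["category_shown"].to_numpy()
    J = int(shown.max()) + 1
    C = int(contexts.max()) + 1
    qt = init_q_table(J, C)

    n = len(schedule)
    q_pres = np.empty(n)
    pe_u = np.empty(n)
    pe_s = np.empty(n)
    p_cho = np.empty(n)
    po = np.empty(n, dtype=int)
    for i in range(n):
        c, j, a = int(contexts[i]), int(shown[i]), int(choices[i])
        row = qt.row(c)
        probs = softmax_probs(row, beta)
        correct = a == j
        q_pres[i] = row[j]
        pe_u[i] = unsigned_pe(row, j)
        pe_s[i] = signed_pe(row, a, correct)
        p_cho[i] = probs[a]
        po[i] = int(correct)
        if model.feedback == "instructive":
            qt.step_instructive(model, c, j, alpha)
        else:
            qt.step_evaluative(c, a, correct, alpha)

    out = schedule.copy()
    out["category_chosen"] = choices
    out["accuracy"] = po
    out["q_presented"] = q_pres
    out["pe_unsigned"] = pe_u
    out["pe_signed"] = pe_s
    out["p_chosen"] = p_cho
    out["prediction_outcome"] = po
    return out
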