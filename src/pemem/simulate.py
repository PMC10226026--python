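"""Softmax RL agents and the generative recognition-memory model.

``simulate_agent`` plays a trial schedule with one of the four learning
models; ``simulate_recognition`` draws old/new judgements from the logistic
subsequent-memory model

    p(hit) = logit^-1( b0_j + b1_j PE + b2_j PO + b3_j PE*PO )

with subject-level random effects on every term (PO contrast-coded +0.5
correct / -0.5 incorrect) and a constant false-alarm rate for distractors;
``make_synthetic_study`` chains schedules, agents, trajectories and
recognition into a fully seeded end-to-end fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import EXPERIMENT_CODES, ExperimentDesign, combine_phases, \
    counterbalance_assignment, generate_encoding_schedule, generate_learning_schedule
from .models import ModelSpec, get_model, run_model

#: Fixed-effect defaults for the generative memory model: intercept, PE,
#: prediction outcome, PE x PO (log-odds units).
DEFAULT_COEFFICIENTS = {"b0": 0.66, "b_pe": -0.12, "b_po": 0.10, "b_pe_po": 1.87}

#: Subject random-effect standard deviations, same term order.
DEFAULT_RE_SDS = (0.55, 0.17, 0.03, 0.18)

#: Probability of calling a never-seen distractor "old".
DEFAULT_FA_RATE = 0.30


def sample_agent_params(model: ModelSpec, rng: np.random.Generator) -> dict:
    """alpha ~ U(0,1), beta ~ Exp(1) truncated to the fitting bound of 10."""
    params = {}
    for p in model.free_params:
        if p == "alpha":
            params[p] = float(rng.uniform())
        else:
            b = rng.exponential(1.0)
            while b > 10.0:
                b = rng.exponential(1.0)
            params[p] = float(b)
    return params


def simulate_agent(
    model: ModelSpec | str,
    params: dict[str, float],
    schedule: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample choices trial by trial from the model's softmax policy.

    The Q table is updated after each trial's category is revealed
    (instructively, or evaluatively from the sampled choice for fLRE).
    Returns the schedule with ``category_chosen`` and ``accuracy`` columns.
    """
    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)
    alpha = params.get("alpha", 1.0)
    beta = params["beta"]
    contexts = schedule["context"].to_numpy(dtype=int).tolist()
    shown = schedule["category_shown"].to_numpy(dtype=int).tolist()
    J = max(shown) + 1
    C = max(contexts) + 1
    q0 = 1.0 / J
    Q = [[q0] * J for _ in range(C)]
    tcount = [0] * C
    evaluative = model.feedback == "evaluative"
    decaying = model.decaying
    is_dlri = model.name == "dLRI"
    unif = rng.random(len(contexts))

    choices = []
    for i, (c, j) in enumerate(zip(contexts, shown)):
        row = Q[c]
        m = max(row)
        es = [exp(beta * (q - m)) for q in row]
        z = sum(es)
        # inverse-CDF draw over J <= 3 categories
        u = unif[i] * z
        acc = 0.0
        a = J - 1
        for k in range(J):
            acc += es[k]
            if u <= acc:
                a = k
                break
        choices.append(a)
        tcount[c] += 1
        if evaluative:
            r = 1.0 if a == j else 0.0
            row[a] += alpha * (r - row[a])
        else:
            rate = ((1.0 if is_dlri else alpha) / tcount[c]) if decaying else alpha
            for k in range(J):
                row[k] += rate * ((1.0 if k == j else 0.0) - row[k])

    out = schedule.copy()
    out["category_chosen"] = choices
    out["accuracy"] = (out["category_chosen"] == out["category_shown"]).astype(int)
    return out


def simulate_recognition(
    encoding_pe_records: pd.DataFrame,
    coefficients: dict[str, float] | None = None,
    random_effect_sds=DEFAULT_RE_SDS,
    fa_rate: float = DEFAULT_FA_RATE,
    seed: int | np.random.Generator = 0,
    n_new_distractors: int = 0,
    immediate_fraction: float = 1.0,
) -> pd.DataFrame:
    """Generate old/new responses for every subject's encoding items.

    Each non-filler encoding item becomes one "old" recognition trial whose
    hit probability follows the logistic memory model evaluated at the item's
    unsigned PE and prediction outcome, with per-subject random effects drawn
    from ``random_effect_sds``.  ``n_new_distractors`` never-seen items per
    subject are answered "old" with probability ``fa_rate``.  A seeded random
    ``immediate_fraction`` of old items is flagged as the immediate-test
    subsample (all distractors are flagged).
    """
    if not 0.0 < fa_rate < 1.0:
        raise ValueError("fa_rate must be in (0, 1)")
    required = {"subject", "object_id", "pe_unsigned", "prediction_outcome", "is_filler"}
    missing = required - set(encoding_pe_records.columns)
    if missing:
        raise ValueError(f"encoding records missing fields: {sorted(missing)}")
    coef = dict(DEFAULT_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    rng = np.random.default_rng(seed)
    sds = np.asarray(random_effect_sds, dtype=float)

    rows = []
    for subject, grp in encoding_pe_records.groupby("subject", sort=True):
        old = grp[grp["is_filler"] == 0]
        u = rng.normal(0.0, sds)
        pe = old["pe_unsigned"].to_numpy()
        po = np.where(old["prediction_outcome"].to_numpy() == 1, 0.5, -0.5)
        eta = (
            (coef["b0"] + u[0])
            + (coef["b_pe"] + u[1]) * pe
            + (coef["b_po"] + u[2]) * po
            + (coef["b_pe_po"] + u[3]) * pe * po
        )
        hit = (rng.random(len(old)) < expit(eta)).astype(int)
        n_old = len(old)
        n_imm = int(round(immediate_fraction * n_old))
        imm = np.zeros(n_old, dtype=int)
        imm[rng.choice(n_old, size=n_imm, replace=False)] = 1
        for i, (oid, h) in enumerate(zip(old["object_id"], hit)):
            rows.append(
                dict(subject=subject, object_id=oid, status="old",
                     response=int(h), immediate_subset=int(imm[i]))
            )
        fa = (rng.random(n_new_distractors) < fa_rate).astype(int)
        for k in range(n_new_distractors):
            rows.append(
                dict(subject=subject, object_id=f"D{k}", status="new",
                     response=int(fa[k]), immediate_subset=1)
            )
    return pd.DataFrame(
        rows, columns=["subject", "object_id", "status", "response",
                       "immediate_subset"]
    )


def simulate_memory_table(
    n_subjects: int,
    n_items: int,
    coefficients: dict[str, float] | None = None,
    random_effect_sds=DEFAULT_RE_SDS,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw item-level hits directly from the logistic memory model.

    A lightweight generator for calibration and coverage studies: per
    subject, PE ~ U(0,1) and prediction outcome +-0.5 with equal probability,
    random effects on all four terms, hit ~ Bernoulli(logit^-1(eta)).
    Returns an analysis-ready table (subject, pe, po, hit).
    """
    coef = dict(DEFAULT_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    rng = np.random.default_rng(seed)
    sds = np.asarray(random_effect_sds, dtype=float)
    frames = []
    for s in range(n_subjects):
        u = rng.normal(0.0, sds)
        pe = rng.uniform(size=n_items)
        po = rng.choice([-0.5, 0.5], size=n_items)
        eta = (
            (coef["b0"] + u[0])
            + (coef["b_pe"] + u[1]) * pe
            + (coef["b_po"] + u[2]) * po
            + (coef["b_pe_po"] + u[3]) * pe * po
        )
        hit = (rng.random(n_items) < expit(eta)).astype(int)
        frames.append(pd.DataFrame(dict(subject=s, pe=pe, po=po, hit=hit)))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticStudy:
    """End-to-end synthetic dataset: schedules, choices, PE, recognition."""

    design: ExperimentDesign
    trials: pd.DataFrame  # all subjects, learning+encoding, with trajectories
    recognition: pd.DataFrame
    true_params: pd.DataFrame  # subject, model, alpha, beta
    coefficients: dict[str, float]
    random_effect_sds: tuple
    fa_rate: float
    seed: int


def make_synthetic_study(
    n_subjects: int,
    design: ExperimentDesign,
    agent_model: str = "fLRI",
    agent_params: dict[str, float] | None = None,
    memory_coefficients: dict[str, float] | None = None,
    random_effect_sds=DEFAULT_RE_SDS,
    fa_rate: float = DEFAULT_FA_RATE,
    n_learning_per_context: int = 40,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a whole study, reproducible from one master seed.

    Per-subject random streams are derived as ``default_rng([seed, subject])``
    so adding subjects never perturbs existing ones.  Agent parameters are
    drawn per subject from the priors (alpha ~ U(0,1), beta ~ Exp(1)
    truncated at 10) unless ``agent_params`` pins them.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    model = get_model(agent_model)
    coef = dict(DEFAULT_COEFFICIENTS)
    if memory_coefficients:
        coef.update(memory_coefficients)

    all_trials = []
    all_true = []
    rec_frames = []
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, s])
        assignment = counterbalance_assignment(s, design)
        learn = generate_learning_schedule(
            design, assignment, n_learning_per_context, rng
        )
        enc = generate_encoding_schedule(design, assignment, rng)
        sched = combine_phases(learn, enc)
        params = dict(agent_params) if agent_params else sample_agent_params(model, rng)
        rec = simulate_agent(model, params, sched, rng)
        traj = run_model(rec, rec["category_chosen"].to_numpy(), model, params)
        traj.insert(0, "subject", s)
        traj.insert(1, "experiment", design.experiment_id)
        all_trials.append(traj)
        all_true.append(dict(subject=s, model=model.name, **params))
        enc_records = traj[traj["phase"] == "ENCODING"]
        rec_frames.append(
            simulate_recognition(
                enc_records,
                coef,
                random_effect_sds,
                fa_rate,
                rng,
                n_new_distractors=design.n_new_distractors,
                immediate_fraction=design.immediate_fraction,
            )
        )
    return SyntheticStudy(
        design=design,
        trials=pd.concat(all_trials, ignore_index=True),
        recognition=pd.concat(rec_frames, ignore_index=True),
        true_params=pd.DataFrame(all_true),
        coefficients=coef,
        random_effect_sds=tuple(np.asarray(random_effect_sds, dtype=float)),
        fa_rate=fa_rate,
        seed=seed,
    )
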