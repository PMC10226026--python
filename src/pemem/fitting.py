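"""Maximum-likelihood fitting, BIC model comparison, and recovery checks.

Per subject, the negative log-likelihood of the observed category choices is
minimized over the model's free parameters (alpha in [0, 1], beta in [0, 10])
with a bounded local optimizer started from five random points drawn from the
priors alpha ~ U(0,1), beta ~ Exp(1) truncated at the fitting bound.  Models
are compared per subject with BIC = -2 LL + k ln(T) (natural log; T = number
of modelled choice trials, learning and encoding pooled, fillers included)
and evidence for the winning model is graded from the BIC gap to the
runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import MODEL_ORDER, MODELS, ModelSpec, get_model

#: Choice probabilities are floored at this constant inside the log so the
#: objective stays finite for arbitrarily extreme parameters.
PROB_FLOOR = 1e-12

EVIDENCE_LABELS = ("weak", "positive", "strong", "very strong")


@dataclass(frozen=True)
class SubjectData:
    """Choice data of one subject in fitting-ready array form."""

    contexts: np.ndarray  # int, per trial
    shown: np.ndarray  # int, presented category per trial
    chosen: np.ndarray  # int, chosen category per trial
    n_categories: int
    n_contexts: int

    @property
    def n_trials(self) -> int:
        return len(self.contexts)


def prepare_subject_data(trials: pd.DataFrame, n_categories: int | None = None,
                         n_contexts: int | None = None) -> SubjectData:
    """Extract fitting arrays from a per-trial table (one subject)."""
    if n_categories is None:
        n_categories = int(trials["category_shown"].max()) + 1
    if n_contexts is None:
        n_contexts = int(trials["context"].max()) + 1
    return SubjectData(
        contexts=trials["context"].to_numpy(dtype=int),
        shown=trials["category_shown"].to_numpy(dtype=int),
        chosen=trials["category_chosen"].to_numpy(dtype=int),
        n_categories=n_categories,
        n_contexts=n_contexts,
    )


def negative_log_likelihood(
    params: np.ndarray | dict[str, float],
    model: ModelSpec | str,
    data: SubjectData,
) -> float:
    """-sum_t log p(choice_t | history, params, model) over all trials.

    The hot loop is written with plain Python floats: category counts are
    tiny (J <= 3) and per-trial numpy dispatch would dominate the runtime of
    the recovery procedures.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(params, dict):
        theta = [params[p] for p in model.free_params]
    else:
        theta = list(np.asarray(params, dtype=float))
    if model.name == "dLRI":
        alpha, beta = 1.0, theta[0]
    else:
        alpha, beta = theta[0], theta[1]

    J, C = data.n_categories, data.n_contexts
    q0 = 1.0 / J
    Q = [[q0] * J for _ in range(C)]
    tcount = [0] * C
    contexts = data.contexts.tolist()
    shown = data.shown.tolist()
    chosen = data.chosen.tolist()
    evaluative = model.feedback == "evaluative"
    decaying = model.decaying
    is_dlri = model.name == "dLRI"

    nll = 0.0
    for c, j, a in zip(contexts, shown, chosen):
        row = Q[c]
        m = max(row)
        es = [exp(beta * (q - m)) for q in row]
        p = es[a] / sum(es)
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        nll -= log(p)
        tcount[c] += 1
        if evaluative:
            r = 1.0 if a == j else 0.0
            row[a] += alpha * (r - row[a])
        else:
            if decaying:
                rate = (1.0 if is_dlri else alpha) / tcount[c]
            else:
                rate = alpha
            for k in range(J):
                row[k] += rate * ((1.0 if k == j else 0.0) - row[k])
    return nll


def sample_start(model: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a starting point from the priors, truncated to the bounds."""
    vals = []
    for p in model.free_params:
        if p == "alpha":
            vals.append(rng.uniform(0.0, 1.0))
        else:
            b = rng.exponential(1.0)
            while b > 10.0:
                b = rng.exponential(1.0)
            vals.append(b)
    return np.array(vals)


@dataclass
class FitResult:
    """Best-of-restarts MLE for one subject and model."""

    subject: object
    model: str
    params: dict[str, float]
    log_likelihood: float
    bic: float
    n_trials: int
    n_restarts: int
    restart_objectives: list[float] = field(default_factory=list)
    converged: bool = True


def bic(log_likelihood: float, k: int, n_trials: int) -> float:
    """BIC = -2 LL + k ln(T); lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return -2.0 * log_likelihood + k * log(n_trials)


def fit_mle(
    data: SubjectData,
    model: ModelSpec | str,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    subject: object = None,
) -> FitResult:
    """Bounded MLE, best of ``n_restarts`` prior-sampled starting points."""
    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)
    best = None
    objectives: list[float] = []
    any_success = False
    for _ in range(n_restarts):
        x0 = sample_start(model, rng)
        res = minimize(
            negative_log_likelihood,
            x0,
            args=(model, data),
            method="L-BFGS-B",
            bounds=model.bounds,
        )
        objectives.append(float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {n_restarts} restarts failed for model {model.name}: "
            f"objectives={objectives}"
        )
    params = dict(zip(model.free_params, (float(v) for v in best.x)))
    ll = -float(best.fun)
    return FitResult(
        subject=subject,
        model=model.name,
        params=params,
        log_likelihood=ll,
        bic=bic(ll, model.k, data.n_trials),
        n_trials=data.n_trials,
        n_restarts=n_restarts,
        restart_objectives=objectives,
        converged=any_success,
    )


def evidence_label(delta_bic: float) -> str:
    """Grade the BIC gap between best and second-best model.

    Bands: [0, 2) weak, [2, 6) positive, [6, 10) strong, [10, inf) very
    strong; boundary values fall in the higher band.
    """
    if delta_bic < 0:
        raise ValueError("delta_bic must be >= 0")
    if delta_bic < 2:
        return "weak"
    if delta_bic < 6:
        return "positive"
    if delta_bic < 10:
        return "strong"
    return "very strong"


def _model_rank(name: str) -> tuple[int, int]:
    # ties: fewer parameters first, then fixed model order
    return (MODELS[name].k, MODEL_ORDER.index(name))


@dataclass
class ModelComparison:
    """Per-model summary plus per-subject winners and evidence labels."""

    table: pd.DataFrame  # model, mean_bic, se_bic, n_best, n_very_strong
    per_subject: pd.DataFrame  # subject, best_model, delta_bic, evidence


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """BIC comparison table across subjects; all four models required."""
    df = pd.DataFrame(
        dict(subject=f.subject, model=f.model, bic=f.bic) for f in fits
    )
    subjects = df["subject"].unique()
    missing = [
        (s, m)
        for s in subjects
        for m in MODEL_ORDER
        if not ((df["subject"] == s) & (df["model"] == m)).any()
    ]
    if missing:
        raise ValueError(f"missing model fits: {missing}")

    rows = []
    for s in subjects:
        sub = df[df["subject"] == s].set_index("model")["bic"]
        # sort by BIC, break ties by parameter count then fixed order
        ordered = sorted(MODEL_ORDER, key=lambda m: (sub[m], *_model_rank(m)))
        best, second = ordered[0], ordered[1]
        delta = float(sub[second] - sub[best])
        rows.append(
            dict(
                subject=s,
                best_model=best,
                delta_bic=delta,
                evidence=evidence_label(delta),
            )
        )
    per_subject = pd.DataFrame(rows)

    summary = []
    for m in MODEL_ORDER:
        bics = df.loc[df["model"] == m, "bic"].to_numpy()
        won = per_subject["best_model"] == m
        summary.append(
            dict(
                model=m,
                mean_bic=float(bics.mean()),
                se_bic=float(bics.std(ddof=1) / np.sqrt(len(bics)))
                if len(bics) > 1
                else 0.0,
                n_best=int(won.sum()),
                n_very_strong=int(
                    (won & (per_subject["evidence"] == "very strong")).sum()
                ),
            )
        )
    return ModelComparison(table=pd.DataFrame(summary), per_subject=per_subject)


def learnable_contexts(design) -> list[int]:
    """Contexts with a dominant category (used for recovery simulations)."""
    return [
        c.context
        for c in design.contexts
        if c.condition in ("0.80-0.20", "0.90-0.10", "0.70-0.30")
    ]


def _recovery_schedule(design, assignment, n_learning: int, rng):
    from .design import combine_phases, generate_encoding_schedule, generate_learning_schedule

    learn = generate_learning_schedule(design, assignment, n_learning, rng)
    enc = generate_encoding_schedule(design, assignment, rng)
    sched = combine_phases(learn, enc)
    keep = sched["context"].isin(learnable_contexts(design))
    return sched[keep].reset_index(drop=True)


@dataclass
class RecoveryReport:
    """True vs fitted parameters over simulated agents."""

    model: str
    pairs: pd.DataFrame  # agent, param, true, fitted
    correlations: dict[str, float]


def parameter_recovery(
    model: ModelSpec | str,
    design,
    n_agents: int,
    seed: int = 0,
    n_learning_per_context: int = 40,
    n_restarts: int = 5,
) -> RecoveryReport:
    """Simulate agents with known prior-sampled parameters, refit, correlate.

    Only the learnable (dominant-category) contingency conditions are
    simulated: 0.80-0.20 in Experiment 1, 0.90-0.10 and 0.70-0.30 in
    Experiment 2.
    """
    from .design import counterbalance_assignment
    from .simulate import simulate_agent

    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)
    rows = []
    for agent in range(n_agents):
        assignment = counterbalance_assignment(agent, design)
        sched = _recovery_schedule(design, assignment, n_learning_per_context, rng)
        true = dict(zip(model.free_params, sample_start(model, rng)))
        rec = simulate_agent(model, true, sched, rng)
        data = prepare_subject_data(
            rec, design.n_categories, len(design.contexts)
        )
        fit = fit_mle(data, model, n_restarts=n_restarts, seed=rng, subject=agent)
        for p in model.free_params:
            rows.append(
                dict(agent=agent, param=p, true=true[p], fitted=fit.params[p])
            )
    pairs = pd.DataFrame(rows, columns=["agent", "param", "true", "fitted"])
    corr = {}
    for p in model.free_params:
        sub = pairs[pairs["param"] == p]
        if len(sub) >= 2:
            corr[p] = float(np.corrcoef(sub["true"], sub["fitted"])[0, 1])
    return RecoveryReport(model=model.name, pairs=pairs, correlations=corr)


def model_recovery(
    design,
    n_reps: int = 100,
    seed: int = 0,
    n_learning_per_context: int = 40,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Confusion matrix generating-model x BIC-best-fitting model.

    Each repetition simulates one agent per generating model (parameters from
    the priors), fits all four models, and records the winner; rows sum to
    ``n_reps``.
    """
    from .design import counterbalance_assignment
    from .simulate import simulate_agent

    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        0, index=list(MODEL_ORDER), columns=list(MODEL_ORDER), dtype=int
    )
    for rep in range(n_reps):
        assignment = counterbalance_assignment(rep, design)
        sched = _recovery_schedule(design, assignment, n_learning_per_context, rng)
        for gen_name in MODEL_ORDER:
            gen = MODELS[gen_name]
            true = dict(zip(gen.free_params, sample_start(gen, rng)))
            rec = simulate_agent(gen, true, sched, rng)
            data = prepare_subject_data(
                rec, design.n_categories, len(design.contexts)
            )
            fits = [
                fit_mle(data, m, n_restarts=n_restarts, seed=rng, subject=rep)
                for m in MODEL_ORDER
            ]
            best = min(fits, key=lambda f: (f.bic, *_model_rank(f.model)))
            counts.loc[gen_name, best.model] += 1
    return counts
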