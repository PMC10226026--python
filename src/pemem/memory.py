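"""Recognition-memory scoring and the PE x prediction-outcome analysis.

Pipeline: score old/new judgements into hits, false alarms and d'
(= z(HR) - z(FAR), log-linear correction); exclude at-chance responders with
a per-subject permutation test; join each non-filler encoding item's
model-derived unsigned prediction error and prediction outcome to its later
hit/miss; and fit the mixed-effects logistic model

    logit p(hit_ij) = b0_j + b1_j PE_ij + b2_j PO_ij + b3_j PE_ij * PO_ij

with subject random effects on all four terms (unstructured covariance),
prediction outcome contrast-coded +0.5 correct / -0.5 incorrect, plus
optional subject-level covariates (fLRI learning rate, experiment +-0.5) as
fixed effects only.  Follow-ups: simple PE slopes within each prediction
outcome, quartile-binned PE with Bonferroni-corrected contrasts, and the
signed-PE variant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import EXPERIMENT_CODES
from .glmm import DEFAULT_ENGINE, MixedModelResult, fit_mixed_model, fit_mixed_models
from .models import get_model, run_model


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' = z(HR) - z(FAR); rates must be strictly inside (0, 1)."""
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def dprime_from_counts(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> float:
    """d' with the log-linear extreme-rate correction (+0.5 per cell)."""
    hr = (hits + 0.5) / (hits + misses + 1.0)
    far = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    return dprime_from_rates(hr, far)


def score_recognition(recognition: pd.DataFrame) -> pd.DataFrame:
    """Per-subject counts, rates and d' from an old/new response table.

    Expects columns ``subject``, ``status`` ("old"/"new") and binary
    ``response`` (1 = "old" judgement).  Raises if any subject lacks old or
    new trials.
    """
    rows = []
    for subject, grp in recognition.groupby("subject", sort=True):
        old = grp[grp["status"] == "old"]
        new = grp[grp["status"] == "new"]
        if len(old) == 0 or len(new) == 0:
            raise ValueError(f"subject {subject}: needs both old and new trials")
        hits = int(old["response"].sum())
        misses = len(old) - hits
        fa = int(new["response"].sum())
        cr = len(new) - fa
        rows.append(
            dict(
                subject=subject,
                hits=hits,
                misses=misses,
                false_alarms=fa,
                correct_rejections=cr,
                hit_rate=hits / len(old),
                fa_rate=fa / len(new),
                dprime=dprime_from_counts(hits, misses, fa, cr),
            )
        )
    return pd.DataFrame(rows)


def permutation_exclusion(
    recognition: pd.DataFrame,
    n_perm: int = 5000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Flag subjects whose d' does not beat a permutation null.

    For each subject the response vector is permuted against the old/new
    labels ``n_perm`` times; the subject is included iff the observed d'
    reaches the given percentile of their own null distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for subject, grp in recognition.groupby("subject", sort=True):
        is_old = (grp["status"] == "old").to_numpy()
        resp = grp["response"].to_numpy(dtype=int)
        n_old = int(is_old.sum())
        n_new = int((~is_old).sum())
        if n_old == 0 or n_new == 0:
            raise ValueError(f"subject {subject}: needs both old and new trials")
        hits = int(resp[is_old].sum())
        obs = dprime_from_counts(hits, n_old - hits, int(resp[~is_old].sum()),
                                 n_new - int(resp[~is_old].sum()))
        perm = rng.permuted(np.tile(resp, (n_perm, 1)), axis=1)
        hits_p = perm[:, is_old].sum(axis=1)
        fa_p = perm[:, ~is_old].sum(axis=1)
        hr = (hits_p + 0.5) / (n_old + 1.0)
        far = (fa_p + 0.5) / (n_new + 1.0)
        null = norm.ppf(hr) - norm.ppf(far)
        threshold = float(np.percentile(null, percentile))
        # a degenerate null (e.g. a constant responder: every permutation
        # yields the same d') carries no evidence of discrimination
        spread = bool(null.max() > null.min())
        rows.append(
            dict(subject=subject, dprime=obs, threshold=threshold,
                 included=bool(obs >= threshold) and spread)
        )
    return pd.DataFrame(rows)


def derive_trial_pe(
    trials: pd.DataFrame, fitted_params: pd.DataFrame, model: str = "fLRI"
) -> pd.DataFrame:
    """Replay each subject's choices under their best-fitting parameters.

    ``fitted_params`` needs columns ``subject`` and the model's free
    parameters (e.g. ``alpha``, ``beta``).  Returns the pooled trajectory
    table with per-trial PE columns.
    """
    spec = get_model(model)
    by_subject = fitted_params.set_index("subject")
    out = []
    for subject, grp in trials.groupby("subject", sort=True):
        params = {p: float(by_subject.loc[subject, p]) for p in spec.free_params}
        traj = run_model(
            grp.drop(columns=[c for c in ("q_presented", "pe_unsigned", "pe_signed",
                                          "p_chosen", "prediction_outcome")
                              if c in grp.columns]),
            grp["category_chosen"].to_numpy(),
            spec,
            params,
        )
        out.append(traj)
    return pd.concat(out, ignore_index=True)


def _quartile_bins(pe: np.ndarray) -> np.ndarray:
    # rank-based quartiles: bin sizes differ by at most 1 when values distinct
    order = pe.argsort(kind="stable")
    ranks = np.empty(len(pe), dtype=int)
    ranks[order] = np.arange(1, len(pe) + 1)
    return np.ceil(4.0 * ranks / len(pe)).astype(int)


def build_analysis_table(
    trajectories: pd.DataFrame,
    recognition: pd.DataFrame,
    fitted_params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per non-filler old item in the immediate recognition test.

    Joins each item's encoding-phase PE and prediction outcome with its
    recognition hit/miss.  Filler items never enter; prediction outcome and
    experiment are contrast-coded +-0.5; ``alpha`` is the subject's fitted
    fLRI learning rate when ``fitted_params`` is given.  Raises listing any
    tested old item without a matching encoding trial.
    """
    enc = trajectories[
        (trajectories["phase"] == "ENCODING") & (trajectories["is_filler"] == 0)
    ]
    old = recognition[
        (recognition["status"] == "old") & (recognition["immediate_subset"] == 1)
    ]
    merged = old.merge(
        enc[["subject", "object_id", "experiment", "pe_unsigned", "pe_signed",
             "prediction_outcome"]],
        on=["subject", "object_id"],
        how="left",
        validate="one_to_one",
    )
    unmatched = merged[merged["pe_unsigned"].isna()]
    if len(unmatched):
        ids = list(unmatched[["subject", "object_id"]].itertuples(index=False, name=None))
        raise ValueError(f"old items without encoding trials: {ids[:20]}")

    table = pd.DataFrame(
        dict(
            subject=merged["subject"],
            object_id=merged["object_id"],
            hit=merged["response"].astype(int),
            pe=merged["pe_unsigned"],
            pe_signed=merged["pe_signed"],
            po=np.where(merged["prediction_outcome"] == 1, 0.5, -0.5),
            experiment=merged["experiment"].map(EXPERIMENT_CODES),
        )
    )
    if fitted_params is not None:
        alpha = fitted_params.set_index("subject")["alpha"]
        table["alpha"] = table["subject"].map(alpha)
    table["pe_bin"] = (
        table.groupby("subject")["pe"].transform(lambda s: _quartile_bins(s.to_numpy()))
    )
    return table


_RANDOM_PART = re.compile(r"\(([^|]+)\|\s*subject\s*\)")


def _validate_random_terms(table: pd.DataFrame, formula: str) -> None:
    """Reject random slopes on covariates that do not vary within subjects."""
    for match in _RANDOM_PART.finditer(formula):
        terms = re.split(r"[+*]", match.group(1))
        for term in (t.strip() for t in terms):
            if term in ("", "1", "0"):
                continue
            for var in re.split(r":", term):
                var = var.strip()
                if var not in table.columns:
                    continue
                within = table.groupby("subject")[var].nunique()
                if (within <= 1).all():
                    raise ValueError(
                        f"{var!r} is a between-subject covariate and cannot "
                        "carry a random slope"
                    )


def _memory_formula(table: pd.DataFrame, spec: str) -> str:
    if spec == "basic":
        return "hit ~ pe * po + (1 + pe * po | subject)"
    if spec == "full":
        fixed = ["pe", "po"]
        for cov in ("alpha", "experiment"):
            if cov in table.columns and table[cov].nunique() > 1:
                fixed.append(cov)
        return f"hit ~ {' * '.join(fixed)} + (1 + pe * po | subject)"
    return spec  # custom lme4-style formula


def fit_mixed_logistic(
    table: pd.DataFrame,
    formula_spec: str = "basic",
    engine: str = DEFAULT_ENGINE,
) -> MixedModelResult:
    """Mixed logistic subsequent-memory model.

    ``formula_spec`` may be ``"basic"`` (PE, PO and their interaction),
    ``"full"`` (adds learning rate and experiment — and every interaction —
    as fixed effects only), or a custom lme4-style formula.  Random effects:
    intercept, PE, PO and PE x PO per subject with unstructured covariance.
    """
    if table["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    for var in ("pe", "po"):
        if (table.groupby("subject")[var].nunique() <= 1).all():
            raise ValueError(f"no within-subject variation in {var!r}")
    formula = _memory_formula(table, formula_spec)
    _validate_random_terms(table, formula)
    return fit_mixed_model(table, formula, "binomial", engine=engine)


def simple_slopes(
    table: pd.DataFrame, engine: str = DEFAULT_ENGINE
) -> dict[str, MixedModelResult]:
    """PE slope on memory fitted separately for correct and incorrect trials.

    Each subset gets a random intercept and PE slope per subject.  Under the
    +-0.5 coding of the full model, the implied subset slopes are
    b1 + b3/2 (correct) and b1 - b3/2 (incorrect).
    """
    jobs = []
    keys = []
    for key, sign in (("correct", 0.5), ("incorrect", -0.5)):
        sub = table[table["po"] == sign]
        if sub.empty:
            raise ValueError(f"no {key}-prediction trials")
        if sub["subject"].nunique() < 2:
            raise ValueError(f"{key} subset has fewer than 2 subjects")
        jobs.append((sub, "hit ~ pe + (1 + pe | subject)", "binomial"))
        keys.append(key)
    results = fit_mixed_models(jobs, engine=engine)
    return dict(zip(keys, results))


def bonferroni(p: float, k: int) -> float:
    """Bonferroni-corrected p-value, p * k capped at 1."""
    return min(1.0, p * k)


@dataclass
class BinnedPEResult:
    """Quartile-binned PE analysis: cell hit rates, model, corrected contrasts."""

    bin_hit_rates: pd.DataFrame  # subject, pe_bin, po, hit_rate, n
    model: MixedModelResult
    contrasts: pd.DataFrame  # term, estimate, se, z, p, p_corrected
    n_dropped_subjects: int


def binned_pe_analysis(
    table: pd.DataFrame, engine: str = DEFAULT_ENGINE
) -> BinnedPEResult:
    """Hit rate over within-subject PE quartiles, linear mixed model.

    Subjects with fewer than 4 distinct PE values cannot be binned and are
    dropped with a warning.  Binned PE enters as a categorical factor; the
    planned contrasts (each quartile against the first) are Bonferroni
    corrected by the number of comparisons in the model.
    """
    distinct = table.groupby("subject")["pe"].nunique()
    bad = distinct[distinct < 4].index
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} subject(s) with < 4 distinct PE values: "
            f"{list(bad)[:10]}"
        )
    kept = table[~table["subject"].isin(bad)]
    cells = (
        kept.groupby(["subject", "pe_bin", "po"], as_index=False)
        .agg(hit_rate=("hit", "mean"), n=("hit", "size"))
    )
    cells["bin"] = "Q" + cells["pe_bin"].astype(str)
    model = fit_mixed_model(cells, "hit_rate ~ bin + (1 | subject)", "gaussian",
                            engine=engine)
    contrasts = model.fixed[model.fixed["term"].str.startswith("bin")].copy()
    k = len(contrasts)
    contrasts["p_corrected"] = [bonferroni(p, k) for p in contrasts["p"]]
    return BinnedPEResult(
        bin_hit_rates=cells,
        model=model,
        contrasts=contrasts.reset_index(drop=True),
        n_dropped_subjects=len(bad),
    )


def signed_pe_analysis(
    table: pd.DataFrame, engine: str = DEFAULT_ENGINE
) -> MixedModelResult:
    """Memory model with the signed PE (r - Q of the chosen category)."""
    if "pe_signed" not in table.columns:
        raise ValueError("analysis table lacks a 'pe_signed' column")
    data = table.rename(columns={"pe_signed": "spe"})
    return fit_mixed_model(
        data, "hit ~ spe + (1 + spe | subject)", "binomial", engine=engine
    )
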