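"""Bridge to R mixed-effects engines (glmmTMB, lme4) over Rscript.

The model specification — formula, family, contrast coding, unstructured
random-effect covariance — is owned by the calling module; R only maximizes
the Laplace-approximated marginal likelihood and returns estimates, standard
errors and variance components.  Wald inference (z = estimate/SE, chi-square
= z^2 with 1 df, normal-approximation CIs, odds ratios for logistic models)
is computed here.

Jobs are batched into a single R session: R startup and library loading cost
seconds, so replicate studies (e.g. coverage simulations) should submit all
datasets in one call to :func:`fit_mixed_models`.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_ENGINE = "glmmTMB"


class MixedModelError(RuntimeError):
    """Raised when the R engine fails or does not converge cleanly."""


@dataclass
class MixedModelResult:
    """One fitted mixed model: Wald-style fixed-effect table + variance components."""

    fixed: pd.DataFrame  # term, estimate, se, ci_low, ci_high, z, wald_chi2, p, odds_ratio
    random: pd.DataFrame  # term, sd, variance
    re_correlation: pd.DataFrame | None
    residual_sd: float | None
    formula: str
    family: str
    engine: str
    converged: bool
    n_obs: int
    n_groups: int

    def coef(self, term: str) -> pd.Series:
        row = self.fixed[self.fixed["term"] == term]
        if row.empty:
            raise KeyError(
                f"term {term!r} not in model; terms: {list(self.fixed['term'])}"
            )
        return row.iloc[0]


def _r_script_path() -> Path:
    return Path(resources.files("pemem") / "r" / "mixed_fit.R")


def _aslist(x) -> list:
    # jsonlite auto-unboxes length-1 vectors to scalars
    return list(x) if isinstance(x, (list, tuple)) else [x]


def _inference_table(terms, estimates, ses, family: str) -> pd.DataFrame:
    terms = _aslist(terms)
    est = np.asarray(_aslist(estimates), dtype=float)
    se = np.asarray(_aslist(ses), dtype=float)
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2.0 * norm.sf(np.abs(z))
    crit = norm.ppf(0.975)
    df = pd.DataFrame(
        dict(
            term=list(terms),
            estimate=est,
            se=se,
            ci_low=est - crit * se,
            ci_high=est + crit * se,
            z=z,
            wald_chi2=z**2,
            p=p,
        )
    )
    if family == "binomial":
        df["odds_ratio"] = np.exp(est)
    return df


def fit_mixed_models(
    jobs: list[tuple[pd.DataFrame, str, str]],
    engine: str = DEFAULT_ENGINE,
    allow_nonconverged: bool = True,
) -> list[MixedModelResult]:
    """Fit a batch of mixed models in one R session.

    Each job is ``(data, formula, family)`` with family ``"binomial"``
    (logit link) or ``"gaussian"``.  The grouping factor in every formula
    must be ``subject``.  Raises :class:`MixedModelError` if R fails on a
    job, or (when ``allow_nonconverged`` is false) if the optimizer reports a
    non-positive-definite fit.
    """
    if engine not in ("glmmTMB", "lme4"):
        raise ValueError(f"unknown engine {engine!r}")
    with tempfile.TemporaryDirectory(prefix="pemem_glmm_") as tmp:
        tmpdir = Path(tmp)
        manifest = []
        for i, (data, formula, family) in enumerate(jobs):
            if family not in ("binomial", "gaussian"):
                raise ValueError(f"unknown family {family!r}")
            path = tmpdir / f"job_{i:03d}.csv"
            data.to_csv(path, index=False)
            manifest.append(
                dict(data=str(path), formula=formula, family=family, engine=engine)
            )
        jobs_path = tmpdir / "jobs.json"
        out_path = tmpdir / "out.json"
        jobs_path.write_text(json.dumps(manifest))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_r_script_path()), str(jobs_path), str(out_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise MixedModelError(
                f"Rscript failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        raw = json.loads(out_path.read_text())

    results = []
    for (data, formula, family), res in zip(jobs, raw):
        if not res.get("ok"):
            raise MixedModelError(
                f"engine {engine} failed for formula {formula!r}: {res.get('error')}"
            )
        if not res["converged"] and not allow_nonconverged:
            raise MixedModelError(
                f"model did not converge cleanly: {formula!r} (engine {engine})"
            )
        re_terms = _aslist(res.get("re_terms") or [])
        re_sd = np.asarray(_aslist(res.get("re_sd") or []), dtype=float)
        random = pd.DataFrame(dict(term=re_terms, sd=re_sd, variance=re_sd**2))
        corr = res.get("re_corr")
        re_corr = (
            pd.DataFrame(np.asarray(corr, dtype=float), index=re_terms, columns=re_terms)
            if corr is not None and len(re_terms) > 1
            else None
        )
        results.append(
            MixedModelResult(
                fixed=_inference_table(res["terms"], res["estimate"], res["se"], family),
                random=random,
                re_correlation=re_corr,
                residual_sd=res.get("sigma"),
                formula=formula,
                family=family,
                engine=engine,
                converged=bool(res["converged"]),
                n_obs=int(res["n_obs"]),
                n_groups=int(res["n_groups"]),
            )
        )
    return results


def fit_mixed_model(
    data: pd.DataFrame, formula: str, family: str, engine: str = DEFAULT_ENGINE
) -> MixedModelResult:
    """Single-model convenience wrapper around :func:`fit_mixed_models`."""
    return fit_mixed_models([(data, formula, family)], engine=engine)[0]
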