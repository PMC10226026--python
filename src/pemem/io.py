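"""Delimited-text readers/writers, study configuration, and the pipeline.

All tables are UTF-8 comma-separated with a header row and booleans as 0/1.
Canonical per-trial columns: subject, experiment, phase, trial, context,
context_trial, condition, category_shown, category_chosen, accuracy,
is_filler, object_id.  Recognition columns: subject, object_id, status,
response, immediate_subset.  External datasets are adapted purely through a
column mapping (external name -> canonical name); nothing about their native
schema is assumed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "subject", "experiment", "phase", "trial", "context", "context_trial",
    "condition", "category_shown", "category_chosen", "accuracy",
    "is_filler", "object_id",
]

RECOGNITION_COLUMNS = ["subject", "object_id", "status", "response",
                       "immediate_subset"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trial_table(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-trial table, renaming external headers to the canon.

    ``column_mapping`` maps external column names to canonical ones.  Raises
    naming any canonical column that is still missing after renaming, and on
    unknown phase labels.
    """
    df = pd.read_csv(path)
    if column_mapping:
        df = df.rename(columns=column_mapping)
    required = [c for c in TRIAL_COLUMNS if c not in ("experiment",)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {missing}")
    bad_phase = set(df["phase"].unique()) - {"LEARNING", "ENCODING"}
    if bad_phase:
        raise ValueError(f"unknown phase label(s): {sorted(bad_phase)}")
    return df


def read_recognition_table(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_mapping:
        df = df.rename(columns=column_mapping)
    missing = [c for c in RECOGNITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recognition table missing column(s): {missing}")
    bad = set(df["status"].unique()) - {"old", "new"}
    if bad:
        raise ValueError(f"unknown status label(s): {sorted(bad)}")
    return df


@dataclass
class StudyConfig:
    """Everything a full simulate -> fit -> analyze run needs."""

    experiment: str = "EXP2"
    n_subjects: int = 10
    seed: int = 0
    models: tuple = ("dLRI", "dfLRI", "fLRI", "fLRE")
    n_restarts: int = 5
    n_learning_per_context: int = 40
    agent_model: str = "fLRI"
    memory_coefficients: dict = field(default_factory=dict)
    fa_rate: float = 0.30
    exclusion: bool = True
    n_permutations: int = 5000
    pe_variant: str = "unsigned"  # unsigned | signed | binned
    formula_spec: str = "basic"
    engine: str = "glmmTMB"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["models"] = list(d["models"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str
    seed: int
    outputs: dict  # filename -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def run_pipeline(config: StudyConfig, outdir: str | Path) -> RunManifest:
    """simulate -> fit -> compare -> derive PE -> analyze, writing all tables.

    Stages run in order; a failure aborts with the stage named.  Identical
    config + seed reproduce byte-identical outputs.
    """
    from . import __version__
    from .design import build_design
    from .fitting import compare_models, fit_mle, prepare_subject_data
    from .memory import (binned_pe_analysis, build_analysis_table,
                         derive_trial_pe, fit_mixed_logistic,
                         permutation_exclusion, score_recognition,
                         signed_pe_analysis, simple_slopes)
    from .simulate import make_synthetic_study

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = write_table(df, outdir / name)
        outputs[name] = file_digest(p)

    stage = "simulate"
    try:
        design = build_design(config.experiment)
        study = make_synthetic_study(
            config.n_subjects,
            design,
            agent_model=config.agent_model,
            memory_coefficients=config.memory_coefficients or None,
            fa_rate=config.fa_rate,
            n_learning_per_context=config.n_learning_per_context,
            seed=config.seed,
        )
        emit("trials.csv", study.trials[[c for c in TRIAL_COLUMNS
                                         if c in study.trials.columns]])
        emit("recognition.csv", study.recognition)
        emit("true_params.csv", study.true_params)

        stage = "fit"
        fits = []
        for subject, grp in study.trials.groupby("subject"):
            data = prepare_subject_data(grp, design.n_categories,
                                        len(design.contexts))
            for m in config.models:
                fits.append(fit_mle(data, m, n_restarts=config.n_restarts,
                                    seed=[config.seed, int(subject), 1],
                                    subject=subject))
        fit_table = pd.DataFrame(
            dict(subject=f.subject, model=f.model,
                 alpha=f.params.get("alpha"), beta=f.params.get("beta"),
                 log_likelihood=f.log_likelihood, bic=f.bic,
                 n_trials=f.n_trials, converged=int(f.converged))
            for f in fits
        )
        emit("fits.csv", fit_table)

        stage = "compare"
        comparison = compare_models(fits)
        emit("model_comparison.csv", comparison.table)
        emit("model_comparison_subjects.csv", comparison.per_subject)

        stage = "derive-pe"
        flri = fit_table[fit_table["model"] == "fLRI"][["subject", "alpha", "beta"]]
        traj = derive_trial_pe(study.trials, flri, model="fLRI")
        emit("trajectories.csv", traj)

        stage = "analyze"
        scores = score_recognition(study.recognition)
        emit("recognition_scores.csv", scores)
        if config.exclusion:
            flags = permutation_exclusion(study.recognition,
                                          n_perm=config.n_permutations,
                                          seed=[config.seed, 2])
            emit("exclusion.csv", flags)
            keep = set(flags.loc[flags["included"], "subject"])
        else:
            keep = set(study.recognition["subject"].unique())
        table = build_analysis_table(
            traj[traj["subject"].isin(keep)],
            study.recognition[study.recognition["subject"].isin(keep)],
            flri,
        )
        emit("analysis_table.csv", table)
        if len(keep) >= 2:
            if config.pe_variant == "signed":
                result = signed_pe_analysis(table, engine=config.engine)
                emit("memory_model.csv", result.fixed)
                emit("memory_model_random.csv", result.random)
            elif config.pe_variant == "binned":
                binned = binned_pe_analysis(table, engine=config.engine)
                emit("binned_hit_rates.csv", binned.bin_hit_rates)
                emit("memory_model.csv", binned.model.fixed)
                emit("binned_contrasts.csv", binned.contrasts)
            else:
                result = fit_mixed_logistic(table, config.formula_spec,
                                            engine=config.engine)
                emit("memory_model.csv", result.fixed)
                emit("memory_model_random.csv", result.random)
                slopes = simple_slopes(table, engine=config.engine)
                emit("simple_slopes.csv", pd.concat(
                    [slopes[k].fixed.assign(subset=k) for k in slopes],
                    ignore_index=True,
                ))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    config.to_yaml(outdir / "config.yaml")
    outputs["config.yaml"] = file_digest(outdir / "config.yaml")
    manifest = RunManifest(config=asdict(config), version=__version__,
                           seed=config.seed, outputs=outputs)
    manifest.write(outdir / "manifest.json")
    return manifest
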