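"""Experimental designs and trial-schedule generation.

Two experiments share a structure: six scene contexts, each probabilistically
predictive of an object category.  Experiment 1 uses three object categories
with contingency conditions 0.80-0.20 (three contexts) and uniform 0.33 (three
contexts); Experiment 2 uses two categories with conditions 0.90-0.10,
0.70-0.30 and 0.50-0.50 (two contexts each).  A learning phase (feedback,
repeatable objects) precedes an encoding phase in which trial-unique objects
are shown once each, padded with repeated "filler" objects so that the
category frequencies realize the nominal contingencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXP1 = "EXP1"
EXP2 = "EXP2"

#: Contrast codes used downstream for the between-subject experiment term.
EXPERIMENT_CODES = {EXP1: 0.5, EXP2: -0.5}


@dataclass(frozen=True)
class ContextSpec:
    """One scene context: its contingency condition and encoding composition.

    ``probs`` is ordered by *slot*: slot 0 is the dominant category slot; the
    counterbalancing assignment maps slots to concrete category indices per
    participant.  ``n_unique`` trial-unique (non-filler) encoding objects are
    split evenly across categories; ``n_fillers`` filler objects are each
    shown ``filler_reps`` times, in the dominant category except in uniform /
    0.50 conditions where they are split evenly.
    """

    context: int
    condition: str
    probs: tuple[float, ...]
    n_unique: int
    n_fillers: int
    filler_reps: int

    @property
    def n_encoding_trials(self) -> int:
        return self.n_unique + self.n_fillers * self.filler_reps


@dataclass(frozen=True)
class ExperimentDesign:
    """Full specification of one experiment's task structure."""

    experiment_id: str
    n_categories: int
    contexts: tuple[ContextSpec, ...]
    n_new_distractors: int
    immediate_fraction: float  # fraction of old items tested immediately

    @property
    def n_encoding_trials(self) -> int:
        return sum(c.n_encoding_trials for c in self.contexts)

    @property
    def n_unique_objects(self) -> int:
        return sum(c.n_unique for c in self.contexts)

    @property
    def n_old_tested(self) -> int:
        return int(round(self.n_unique_objects * self.immediate_fraction))


def build_design(experiment_id: str) -> ExperimentDesign:
    """Return the fully specified design for ``"EXP1"`` or ``"EXP2"``.

    Experiment 1: per 0.80-context, 24 unique objects (8 per category) plus
    8 dominant-category fillers repeated seven times -> 64/8/8 = 0.80/0.10/0.10
    over 80 trials; uniform contexts have 24 uniques and no fillers.  Total
    312 encoding trials, 144 uniques, 144 new distractors, immediate test on
    half the old items.

    Experiment 2: 0.90-contexts 20 uniques + 5 fillers x16 (100 trials),
    0.70-contexts 20 uniques + 5 fillers x3 (35 trials; realized 25/10),
    0.50-contexts 10 uniques + 10 fillers x2 (30 trials).  Total 330 trials,
    100 uniques, 80 new distractors, all old items tested immediately.
    """
    if experiment_id == EXP1:
        third = 1.0 / 3.0
        contexts = tuple(
            [
                ContextSpec(c, "0.80-0.20", (0.8, 0.1, 0.1), 24, 8, 7)
                for c in range(3)
            ]
            + [
                ContextSpec(c, "0.33", (third, third, third), 24, 0, 0)
                for c in range(3, 6)
            ]
        )
        return ExperimentDesign(EXP1, 3, contexts, 144, 0.5)
    if experiment_id == EXP2:
        contexts = (
            ContextSpec(0, "0.90-0.10", (0.9, 0.1), 20, 5, 16),
            ContextSpec(1, "0.90-0.10", (0.9, 0.1), 20, 5, 16),
            ContextSpec(2, "0.70-0.30", (0.7, 0.3), 20, 5, 3),
            ContextSpec(3, "0.70-0.30", (0.7, 0.3), 20, 5, 3),
            ContextSpec(4, "0.50-0.50", (0.5, 0.5), 10, 10, 2),
            ContextSpec(5, "0.50-0.50", (0.5, 0.5), 10, 10, 2),
        )
        return ExperimentDesign(EXP2, 2, contexts, 80, 1.0)
    raise ValueError(f"unknown experiment id: {experiment_id!r}")


def counterbalance_assignment(
    participant_index: int, design: ExperimentDesign
) -> dict[int, int]:
    """Map context id -> dominant category index for one participant.

    A Latin-square rotation: within each contingency condition, the k-th
    context's dominant category is ``(k + participant_index) mod J``, so a
    full cycle of ``J`` participants pairs every category with every
    context-condition equally often.  Uniform contexts get a nominal
    "dominant" slot assignment too (it only anchors the slot -> category
    mapping; their contingencies are flat).
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    J = design.n_categories
    assignment: dict[int, int] = {}
    by_condition: dict[str, int] = {}
    for ctx in design.contexts:
        k = by_condition.get(ctx.condition, 0)
        by_condition[ctx.condition] = k + 1
        assignment[ctx.context] = (k + participant_index) % J
    return assignment


def largest_remainder_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of ``n`` trials to categories by largest remainder."""
    probs = np.asarray(probs, dtype=float)
    exact = probs * n
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    short = n - counts.sum()
    # stable: larger remainder first, index breaks ties
    order = np.lexsort((np.arange(len(probs)), -rem))
    counts[order[:short]] += 1
    return counts


def _slot_to_category(slot: int, dominant: int, J: int) -> int:
    return (dominant + slot) % J


def generate_learning_schedule(
    design: ExperimentDesign,
    assignment: dict[int, int],
    n_trials_per_context: int = 40,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Seeded learning-phase schedule: categories realized to nearest counts.

    Raises ``ValueError`` naming the context if the trial count cannot give
    every category at least one presentation under its contingency.
    """
    if n_trials_per_context < 1:
        raise ValueError("n_trials_per_context must be >= 1")
    rng = np.random.default_rng(seed)
    J = design.n_categories
    rows = []
    for ctx in design.contexts:
        counts = largest_remainder_counts(np.array(ctx.probs), n_trials_per_context)
        if np.any(counts == 0):
            raise ValueError(
                f"context {ctx.context}: {n_trials_per_context} trials cannot "
                f"realize contingency {ctx.condition} (a category gets 0 trials)"
            )
        dom = assignment[ctx.context]
        k = 0
        for slot, cnt in enumerate(counts):
            cat = _slot_to_category(slot, dom, J)
            for _ in range(cnt):
                rows.append(
                    dict(
                        phase="LEARNING",
                        context=ctx.context,
                        condition=ctx.condition,
                        category_shown=cat,
                        is_filler=0,
                        object_id=f"L{ctx.context}_{k}",
                    )
                )
                k += 1
    df = pd.DataFrame(rows)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def generate_encoding_schedule(
    design: ExperimentDesign,
    assignment: dict[int, int],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Seeded encoding-phase schedule.

    Unique objects appear once each, split evenly over categories within a
    context; fillers repeat per the design.  In dominant-contingency contexts
    fillers all belong to the dominant category; in flat conditions (0.33,
    0.50-0.50) they are split evenly.  Trial order is a uniform random
    permutation.
    """
    rng = np.random.default_rng(seed)
    J = design.n_categories
    rows = []
    for ctx in design.contexts:
        dom = assignment[ctx.context]
        if ctx.n_unique % J != 0:
            raise ValueError(
                f"context {ctx.context}: {ctx.n_unique} unique objects do not "
                f"split evenly over {J} categories"
            )
        per_cat = ctx.n_unique // J
        u = 0
        for slot in range(J):
            cat = _slot_to_category(slot, dom, J)
            for _ in range(per_cat):
                rows.append(
                    dict(
                        phase="ENCODING",
                        context=ctx.context,
                        condition=ctx.condition,
                        category_shown=cat,
                        is_filler=0,
                        object_id=f"U{ctx.context}_{u}",
                    )
                )
                u += 1
        flat = ctx.condition in ("0.33", "0.50-0.50")
        for f in range(ctx.n_fillers):
            if flat:
                cat = _slot_to_category(f % J, dom, J)
            else:
                cat = dom
            for _ in range(ctx.filler_reps):
                rows.append(
                    dict(
                        phase="ENCODING",
                        context=ctx.context,
                        condition=ctx.condition,
                        category_shown=cat,
                        is_filler=1,
                        object_id=f"F{ctx.context}_{f}",
                    )
                )
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df


def realized_proportions(schedule: pd.DataFrame) -> pd.DataFrame:
    """Empirical category frequencies per context (schedule metadata)."""
    out = (
        schedule.groupby(["context", "category_shown"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    out["proportion"] = out["count"] / out.groupby("context")["count"].transform("sum")
    return out


def combine_phases(
    learning: pd.DataFrame, encoding: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate phases and add the pooled per-context trial counter ``t``.

    The counter increments within each context across both phases, matching
    the learning models' per-context trial index.
    """
    df = pd.concat([learning, encoding], ignore_index=True)
    df["trial"] = np.arange(1, len(df) + 1)
    df["context_trial"] = df.groupby("context").cumcount() + 1
    return df
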