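"""Trial-level cleaning and descriptive measures.

Cleaning follows the study protocol for two-alternative magnitude comparison:
items behaving as warm-up are dropped (by default the first symbolic test item
and the first three non-symbolic test items, plus any designed practice items,
which carry ``item_index <= 0``), responses faster than 250 ms or slower than
4 s are discarded, and a subject is excluded entirely when more than half of
either task's analysable items fell outside those limits.

Descriptive measures are the per-subject mean accuracy and the median RT of
correctly answered items.  Missing measures (e.g. no correct trial) propagate
as NaN so downstream analyses can drop subjects pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "DEFAULT_PRACTICE_RULES",
    "TRIAL_COLUMNS",
    "drop_practice_items",
    "apply_rt_cutoffs",
    "exclude_subjects",
    "median_rt_correct",
    "mean_accuracy",
    "preprocess",
    "subject_descriptives",
]

#: Standard trial-table schema (delimited text, UTF-8, header required).
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "task",
    "item_index",
    "left_value",
    "right_value",
    "n1",
    "n2",
    "ratio_bin",
    "size_control",
    "correct",
    "rt_s",
]

#: Item indices removed as (additional) practice.  Non-positive indices are
#: designed practice items; index 1 (symbolic) and 1-3 (non-symbolic) are the
#: slow first test items treated as extra practice, leaving 23 / 45 items.
DEFAULT_PRACTICE_RULES = {
    "symbolic": [-2, -1, 0, 1],
    "nonsymbolic": [-1, 0, 1, 2, 3],
}

KNOWN_TASKS = ("symbolic", "nonsymbolic")


@dataclass
class FilterReport:
    """Bookkeeping of what each cleaning stage removed."""

    n_input: int = 0
    n_removed_practice: int = 0
    n_removed_fast: int = 0
    n_removed_slow: int = 0
    n_removed_excluded_subjects: int = 0
    excluded_subjects: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_removed_practice
            - self.n_removed_fast
            - self.n_removed_slow
            - self.n_removed_excluded_subjects
        )

    def fractions(self) -> dict:
        """Removal fractions per category relative to the input trial count."""
        if self.n_input == 0:
            return {"practice": 0.0, "fast": 0.0, "slow": 0.0, "excluded_subjects": 0.0}
        return {
            "practice": self.n_removed_practice / self.n_input,
            "fast": self.n_removed_fast / self.n_input,
            "slow": self.n_removed_slow / self.n_input,
            "excluded_subjects": self.n_removed_excluded_subjects / self.n_input,
        }

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions()
        rows = [
            ("input", self.n_input, 1.0),
            ("removed_practice", self.n_removed_practice, frac["practice"]),
            ("removed_fast", self.n_removed_fast, frac["fast"]),
            ("removed_slow", self.n_removed_slow, frac["slow"]),
            (
                "removed_excluded_subjects",
                self.n_removed_excluded_subjects,
                frac["excluded_subjects"],
            ),
            ("kept", self.n_kept, self.n_kept / max(self.n_input, 1)),
        ]
        return pd.DataFrame(rows, columns=["category", "n_trials", "fraction"])


def drop_practice_items(trials: pd.DataFrame, task_rules: dict | None = None):
    """Remove practice / warm-up items per task.

    ``task_rules`` maps a task label to the item indices to drop; the default
    is :data:`DEFAULT_PRACTICE_RULES`.  An empty map is the identity.
    Returns ``(kept_trials, FilterReport)``.
    """
    if task_rules is None:
        task_rules = DEFAULT_PRACTICE_RULES
    unknown = set(task_rules) - set(KNOWN_TASKS)
    if unknown:
        raise ValueError(f"unknown task labels in practice rules: {sorted(unknown)}")
    report = FilterReport(n_input=len(trials))
    drop = pd.Series(False, index=trials.index)
    for task, items in task_rules.items():
        drop |= (trials["task"] == task) & trials["item_index"].isin(list(items))
    report.n_removed_practice = int(drop.sum())
    return trials.loc[~drop].copy(), report


def apply_rt_cutoffs(trials: pd.DataFrame, lo: float = 0.250, hi: float = 4.0):
    """Discard responses faster than ``lo`` or slower than ``hi`` seconds.

    Inequalities are strict: RTs exactly at a cutoff are kept.  Returns
    ``(kept, removed, FilterReport)``.
    """
    if not lo < hi:
        raise ValueError(f"lower cutoff must be below upper cutoff, got {lo} >= {hi}")
    fast = trials["rt_s"] < lo
    slow = trials["rt_s"] > hi
    report = FilterReport(
        n_input=len(trials),
        n_removed_fast=int(fast.sum()),
        n_removed_slow=int(slow.sum()),
    )
    removed = trials.loc[fast | slow].copy()
    kept = trials.loc[~(fast | slow)].copy()
    return kept, removed, report


def exclude_subjects(kept: pd.DataFrame, removed: pd.DataFrame, threshold: float = 0.5):
    """Drop subjects with out-of-range responses to more than half a task's items.

    For every subject and task the fraction of removed (out-of-range) trials
    among administered post-practice items is computed; a subject whose
    fraction strictly exceeds ``threshold`` in *either* task is dropped
    entirely.  Returns ``(kept_without_excluded, excluded_subject_ids)``.
    """
    n_kept = kept.groupby(["subject_id", "task"]).size()
    n_rem = removed.groupby(["subject_id", "task"]).size()
    frac = n_rem.div(n_rem.add(n_kept, fill_value=0), fill_value=0)
    excluded = sorted(frac[frac > threshold].index.get_level_values("subject_id").unique())
    out = kept.loc[~kept["subject_id"].isin(excluded)].copy()
    return out, excluded


def median_rt_correct(trials: pd.DataFrame) -> float:
    """Median RT over correct trials; NaN when there is no correct trial."""
    rts = trials.loc[trials["correct"] == 1, "rt_s"]
    if rts.empty:
        return float("nan")
    return float(rts.median())


def mean_accuracy(trials: pd.DataFrame) -> float:
    """Mean of the correctness indicator."""
    if len(trials) == 0:
        raise ValueError("mean_accuracy requires at least one trial")
    return float(np.mean(trials["correct"]))


def preprocess(
    trials: pd.DataFrame,
    rt_lo: float = 0.250,
    rt_hi: float = 4.0,
    practice_rules: dict | None = None,
    exclusion_threshold: float = 0.5,
):
    """Full cleaning pipeline: practice removal, RT cutoffs, subject exclusion.

    Returns ``(clean_trials, FilterReport)``.
    """
    post_practice, rep1 = drop_practice_items(trials, practice_rules)
    kept, removed, rep2 = apply_rt_cutoffs(post_practice, rt_lo, rt_hi)
    clean, excluded = exclude_subjects(kept, removed, exclusion_threshold)
    report = FilterReport(
        n_input=len(trials),
        n_removed_practice=rep1.n_removed_practice,
        n_removed_fast=rep2.n_removed_fast,
        n_removed_slow=rep2.n_removed_slow,
        n_removed_excluded_subjects=len(kept) - len(clean),
        excluded_subjects=excluded,
    )
    return clean, report


def subject_descriptives(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x task: median correct RT, mean accuracy, trial count."""
    rows = []
    for (sid, task), grp in trials.groupby(["subject_id", "task"], sort=True):
        rows.append(
            {
                "subject_id": sid,
                "task": task,
                "group": grp["group"].iloc[0],
                "n_trials": len(grp),
                "median_rt": median_rt_correct(grp),
                "accuracy": mean_accuracy(grp),
            }
        )
    return pd.DataFrame(rows)
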