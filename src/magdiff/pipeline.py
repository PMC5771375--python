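"""One-command orchestration of the full analysis.

``run_study`` executes, in order: data acquisition (an input trial CSV or
synthetic generation), validation, preprocessing, per-subject diffusion
fitting, Weber-fraction estimation, descriptive summaries, and the
inferential tables (split-half reliability, achievement correlations with
Holm adjustment and Williams tests, group comparison with Cohen's d / Welch
tests, and the 2 x 2 mixed ANOVAs on drift rate and boundary separation).
Every stage's output is a plain DataFrame persisted as CSV; a provenance
block (config hash, seed, version) makes the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import DiffusionKSModel
from .preprocessing import TRIAL_COLUMNS, preprocess, subject_descriptives
from .psychophysics import WeberModel
from .stats import (
    cohens_d,
    holm_adjust,
    mixed_anova,
    pearson_r,
    split_half_reliability,
    welch_t,
    williams_test,
)
from .synthetic import PopulationConfig, simulate_study

__all__ = ["StudyConfig", "StudyReport", "run_study", "validate_input", "fit_all"]

MEASURES = ["v", "a", "t0", "st0", "accuracy", "weber", "median_rt"]


@dataclass
class StudyConfig:
    """Configuration for one study run (YAML-serialisable)."""

    input_csv: str | None = None
    synthetic: dict = field(default_factory=dict)  # PopulationConfig overrides
    rt_lo: float = 0.250
    rt_hi: float = 4.0
    min_trials: int = 10
    n_restarts: int = 5
    maxfev: int = 400
    quartile_mode: str = "all"
    reliability: bool = True
    reliability_restarts: int = 3
    correlation_group: str = "con"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "synthetic": dict(self.synthetic),
            "rt_lo": self.rt_lo,
            "rt_hi": self.rt_hi,
            "min_trials": self.min_trials,
            "n_restarts": self.n_restarts,
            "maxfev": self.maxfev,
            "quartile_mode": self.quartile_mode,
            "reliability": self.reliability,
            "reliability_restarts": self.reliability_restarts,
            "correlation_group": self.correlation_group,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    """All tables of one study run plus provenance."""

    filter_report: pd.DataFrame
    subject_summary: pd.DataFrame
    reliability: pd.DataFrame
    correlations: pd.DataFrame
    group_comparison: pd.DataFrame
    anova: pd.DataFrame
    provenance: dict

    def tables(self) -> dict:
        return {
            "filter_report": self.filter_report,
            "subject_summary": self.subject_summary,
            "reliability": self.reliability,
            "correlations": self.correlations,
            "group_comparison": self.group_comparison,
            "anova": self.anova,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def validate_input(trials: pd.DataFrame | str | Path) -> list[str]:
    """Schema and range diagnostics for a trial table; empty list = clean."""
    if not isinstance(trials, pd.DataFrame):
        trials = pd.read_csv(trials)
    diags: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        diags.append(f"missing columns: {missing}")
        return diags
    bad_rt = trials.index[~(trials["rt_s"] > 0)].tolist()
    if bad_rt:
        diags.append(f"non-positive rt_s in rows: {bad_rt[:20]}")
    bad_corr = trials.index[~trials["correct"].isin([0, 1])].tolist()
    if bad_corr:
        diags.append(f"correct not in {{0,1}} in rows: {bad_corr[:20]}")
    bad_task = sorted(set(trials["task"]) - {"symbolic", "nonsymbolic"})
    if bad_task:
        diags.append(f"unknown task labels: {bad_task}")
    dup = trials.duplicated(subset=["subject_id", "task", "item_index"])
    if dup.any():
        diags.append(
            f"duplicate subject x task x item keys in rows: {trials.index[dup].tolist()[:20]}"
        )
    return diags


def fit_all(
    trials: pd.DataFrame,
    min_trials: int = 10,
    n_restarts: int = 5,
    maxfev: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the diffusion model for every subject x task; tidy fit table.

    Fit failures (too few trials) are reported as rows with NaN estimates and
    ``converged=False``; the pipeline continues pairwise.
    """
    rows = []
    for (sid, task), grp in trials.groupby(["subject_id", "task"], sort=True):
        row = {"subject_id": sid, "task": task, "group": grp["group"].iloc[0]}
        sub_seed = _stable_seed(seed, sid, task)
        try:
            res = DiffusionKSModel.from_dataframe(grp, min_trials=min_trials).fit(
                n_restarts=n_restarts, seed=sub_seed, maxfev=maxfev
            )
            row.update(res.to_dict())
        except ValueError:
            row.update(
                {
                    "a": np.nan,
                    "v": np.nan,
                    "t0": np.nan,
                    "st0": np.nan,
                    "ks_stat": np.nan,
                    "n_trials": len(grp),
                    "converged": False,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _stable_seed(seed: int, *keys) -> int:
    blob = json.dumps([seed, *map(str, keys)]).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31 - 1)


def _weber_fits(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    nonsym = trials[trials["task"] == "nonsymbolic"]
    for sid, grp in nonsym.groupby("subject_id", sort=True):
        try:
            fit = WeberModel.from_dataframe(grp).fit()
            rows.append({"subject_id": sid, "weber": fit.w, "weber_at_boundary": fit.at_boundary})
        except ValueError:
            rows.append({"subject_id": sid, "weber": np.nan, "weber_at_boundary": True})
    return pd.DataFrame(rows)


def build_subject_summary(trials: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Per subject x task: descriptives + fitted parameters (+ Weber fraction)."""
    desc = subject_descriptives(trials)
    summary = desc.merge(
        fits[["subject_id", "task", "a", "v", "t0", "st0", "ks_stat", "converged"]],
        on=["subject_id", "task"],
        how="left",
    )
    weber = _weber_fits(trials)
    if not weber.empty:
        summary = summary.merge(weber, on="subject_id", how="left")
    else:
        summary["weber"] = np.nan
        summary["weber_at_boundary"] = np.nan
    summary["weber_at_boundary"] = summary["weber_at_boundary"].astype(float)
    mask = summary["task"] == "symbolic"
    summary.loc[mask, "weber"] = np.nan
    summary.loc[mask, "weber_at_boundary"] = np.nan
    return summary


def _wide(summary: pd.DataFrame, measure: str) -> pd.DataFrame:
    col = {"accuracy": "accuracy", "median_rt": "median_rt", "weber": "weber"}.get(
        measure, measure
    )
    w = summary.pivot_table(index="subject_id", columns="task", values=col, aggfunc="first")
    return w


def _correlation_table(summary: pd.DataFrame, achievement: pd.Series) -> pd.DataFrame:
    """Achievement correlations per measure and task, Holm adjusted as one
    family (Weber fraction excluded from the family, as its near-collinearity
    with accuracy would double-count a test), plus Williams tests comparing
    the two tasks' correlations for each measure."""
    rows = []
    for measure in MEASURES:
        w = _wide(summary, measure)
        for task in ("symbolic", "nonsymbolic"):
            if task not in w.columns:
                continue
            x = w[task].reindex(achievement.index)
            if measure == "weber" and task == "symbolic":
                continue
            r, p = pearson_r(achievement.to_numpy(), x.to_numpy())
            rows.append({"measure": measure, "task": task, "r": r, "p": p})
    table = pd.DataFrame(rows)
    in_family = table["measure"] != "weber"
    adj = np.full(len(table), np.nan)
    ok = in_family & table["p"].notna()
    if ok.any():
        adj[ok.to_numpy()] = holm_adjust(table.loc[ok, "p"].to_numpy())
    table["p_holm"] = adj
    # Williams test per measure (needs both tasks and the cross-task r)
    t_col, p_col = [], []
    for _, row in table.iterrows():
        measure = row["measure"]
        w = _wide(summary, measure)
        if row["task"] != "symbolic" or "nonsymbolic" not in w.columns or measure == "weber":
            t_col.append(np.nan)
            p_col.append(np.nan)
            continue
        merged = pd.concat([achievement, w], axis=1).dropna()
        if len(merged) <= 3:
            t_col.append(np.nan)
            p_col.append(np.nan)
            continue
        r_jk, _ = pearson_r(merged.iloc[:, 0], merged["symbolic"])
        r_jh, _ = pearson_r(merged.iloc[:, 0], merged["nonsymbolic"])
        r_kh, _ = pearson_r(merged["symbolic"], merged["nonsymbolic"])
        try:
            res = williams_test(r_jk, r_jh, r_kh, len(merged))
            t_col.append(res.t)
            p_col.append(res.p)
        except ValueError:
            t_col.append(np.nan)
            p_col.append(np.nan)
    table["williams_t"] = t_col
    table["williams_p"] = p_col
    return table


def _comparison_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Group means/SDs, Cohen's d with CI and Holm-adjusted Welch tests."""
    rows = []
    for task in ("symbolic", "nonsymbolic"):
        for measure in MEASURES:
            if measure == "weber" and task == "symbolic":
                continue
            sub = summary[summary["task"] == task]
            col = measure
            con = sub.loc[sub["group"] == "con", col].dropna()
            dys = sub.loc[sub["group"] == "dys", col].dropna()
            if len(con) < 2 or len(dys) < 2:
                continue
            es = cohens_d(con.mean(), con.std(ddof=1), len(con), dys.mean(), dys.std(ddof=1), len(dys))
            wt = welch_t(con.mean(), con.std(ddof=1), len(con), dys.mean(), dys.std(ddof=1), len(dys))
            rows.append(
                {
                    "task": task,
                    "measure": measure,
                    "con_mean": con.mean(),
                    "con_sd": con.std(ddof=1),
                    "dys_mean": dys.mean(),
                    "dys_sd": dys.std(ddof=1),
                    "d": es.d,
                    "ci_low": es.ci_low,
                    "ci_up": es.ci_up,
                    "t": wt.t,
                    "df": wt.df,
                    "p": wt.p,
                }
            )
    table = pd.DataFrame(rows)
    in_family = table["measure"] != "weber"
    adj = np.full(len(table), np.nan)
    adj[in_family.to_numpy()] = holm_adjust(table.loc[in_family, "p"].to_numpy())
    table["p_holm"] = adj
    return table


def _anova_table(summary: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for measure in ("v", "a"):
        w = _wide(summary, measure)[["symbolic", "nonsymbolic"]]
        groups = (
            summary.drop_duplicates("subject_id")
            .set_index("subject_id")["group"]
            .reindex(w.index)
        )
        res = mixed_anova(w, groups.to_numpy())
        for _, r in res.table.iterrows():
            rows.append({"measure": measure, **r.to_dict()})
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig,
    seed: int = 0,
    out_dir=None,
) -> StudyReport:
    """Execute the full study pipeline; deterministic for a given seed."""
    subjects = None
    if config.input_csv:
        trials = pd.read_csv(config.input_csv)
    else:
        pop = PopulationConfig(**config.synthetic)
        trials, subjects, _ = simulate_study(pop, seed)
    diags = validate_input(trials)
    if diags:
        raise ValueError("input validation failed: " + "; ".join(diags))

    clean, report = preprocess(trials, rt_lo=config.rt_lo, rt_hi=config.rt_hi)
    fits = fit_all(
        clean,
        min_trials=config.min_trials,
        n_restarts=config.n_restarts,
        maxfev=config.maxfev,
        seed=seed,
    )
    summary = build_subject_summary(clean, fits)

    if config.reliability:
        reliability = split_half_reliability(
            clean, fit_kwargs={"n_restarts": config.reliability_restarts, "maxfev": config.maxfev}
        )
    else:
        reliability = pd.DataFrame(
            columns=["parameter", "task", "r_half", "reliability", "n_subjects", "n_dropped"]
        )

    # achievement per subject: from the synthetic population when generated,
    # otherwise not available in the trial schema -> correlations are empty
    if subjects is not None:
        corr_group = config.correlation_group
        ach = subjects.set_index("subject_id")["achievement"]
        if corr_group in ("con", "dys"):
            keep = subjects.loc[subjects["group"] == corr_group, "subject_id"]
            ach = ach.loc[ach.index.intersection(keep)]
        correlations = _correlation_table(summary, ach)
    else:
        correlations = pd.DataFrame(
            columns=["measure", "task", "r", "p", "p_holm", "williams_t", "williams_p"]
        )

    comparison = _comparison_table(summary)
    anova = _anova_table(summary)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": seed,
        "version": __version__,
        "n_subjects": int(summary["subject_id"].nunique()),
    }
    study = StudyReport(
        filter_report=report.to_frame(),
        subject_summary=summary,
        reliability=reliability,
        correlations=correlations,
        group_comparison=comparison,
        anova=anova,
        provenance=provenance,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
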