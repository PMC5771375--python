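"""Inferential layer: reliability, correlations, effect sizes, Welch tests,
dependent-correlation comparison, and the 2 x 2 mixed (split-plot) ANOVA.

All routines operate on summary vectors or tidy per-subject tables and mirror
the reporting conventions of group-comparison studies in numerical cognition:
Cohen's d from the pooled SD with a large-sample normal CI, Welch's t with
Satterthwaite degrees of freedom, Bonferroni-Holm multiplicity control,
Williams' t for two dependent correlations sharing a variable, Spearman-Brown
corrected split-half reliabilities obtained by refitting the diffusion model
on item-split halves, and a mixed ANOVA with one between-subject factor
(group) and one within-subject factor (task type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_r",
    "holm_adjust",
    "williams_test",
    "cohens_d",
    "welch_t",
    "mixed_anova",
    "spearman_brown",
    "split_half_reliability",
    "EffectSize",
    "WelchResult",
    "WilliamsResult",
    "AnovaResult",
]


# ---------------------------------------------------------------------------
# correlations and multiplicity


def pearson_r(x, y):
    """Product-moment correlation with two-sided p; pairwise NaN deletion.

    Returns ``(nan, nan)`` when fewer than 3 complete pairs remain or either
    variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def holm_adjust(pvals):
    """Step-down Bonferroni-Holm adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


@dataclass(frozen=True)
class WilliamsResult:
    t: float
    df: int
    p: float


def williams_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> WilliamsResult:
    """Williams' t for H0: rho_jk = rho_jh with shared variable j, df = n - 3."""
    for r in (r_jk, r_jh, r_kh):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    if det <= 0:
        raise ValueError("singular correlation matrix")
    rbar = (r_jk + r_jh) / 2
    t = (r_jk - r_jh) * np.sqrt(
        (n - 1) * (1 + r_kh)
        / (2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r_kh) ** 3)
    )
    df = n - 3
    p = 2 * sps.t.sf(abs(t), df)
    return WilliamsResult(t=float(t), df=df, p=float(p))


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class EffectSize:
    """Pooled-SD Cohen's d with a large-sample CI."""

    d: float
    ci_low: float
    ci_up: float
    n1: int
    n2: int


def cohens_d(m1, s1, n1, m2, s2, n2, conf: float = 0.95) -> EffectSize:
    """Cohen's d from summary statistics, pooled SD, normal-approximation CI.

    SE(d) = sqrt((n1 + n2)/(n1 * n2) + d**2 / (2 * (n1 + n2))).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    d = (m1 - m2) / s_pooled
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    zc = sps.norm.ppf(0.5 + conf / 2)
    return EffectSize(
        d=float(d), ci_low=float(d - zc * se), ci_up=float(d + zc * se), n1=n1, n2=n2
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(m1, s1, n1, m2, s2, n2) -> WelchResult:
    """Two-sample Welch t-test from summary statistics (two-sided p)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    se1, se2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


# ---------------------------------------------------------------------------
# reliability


def spearman_brown(r: float) -> float:
    """Step up a half-test correlation to full-test length: 2r / (1 + r)."""
    return 2 * r / (1 + r)


def split_half_reliability(
    trials: pd.DataFrame,
    parameters: tuple = ("a", "v", "t0"),
    split_rule: str = "odd_even",
    min_trials_half: int = 4,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Split-half reliability of diffusion parameters, Spearman-Brown corrected.

    Each subject's trials within a task are split into halves (default: by
    odd/even item order), the diffusion model is refitted on each half, and
    the half-estimates are correlated across subjects.  Subjects whose half
    fits fail (too few trials) are dropped pairwise and counted.

    Returns a tidy table: parameter, task, r_half, reliability, n_subjects,
    n_dropped.
    """
    from .fitting import DiffusionKSModel  # local import avoids cycle at import time

    if split_rule != "odd_even":
        raise ValueError(f"unknown split rule {split_rule!r}")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_restarts", 3)
    rows = []
    for task, task_trials in trials.groupby("task", sort=True):
        halves: dict[str, dict[str, dict]] = {"h1": {}, "h2": {}}
        n_dropped = 0
        for sid, grp in task_trials.groupby("subject_id", sort=True):
            grp = grp.sort_values("item_index")
            order = np.arange(len(grp))
            h1 = grp.iloc[order % 2 == 0]
            h2 = grp.iloc[order % 2 == 1]
            if len(h1) < min_trials_half or len(h2) < min_trials_half:
                n_dropped += 1
                continue
            try:
                for name, half in (("h1", h1), ("h2", h2)):
                    res = DiffusionKSModel.from_dataframe(
                        half, min_trials=min_trials_half
                    ).fit(**fit_kwargs)
                    halves[name][sid] = res.to_dict()
            except ValueError:
                halves["h1"].pop(sid, None)
                n_dropped += 1
        common = sorted(set(halves["h1"]) & set(halves["h2"]))
        for param in parameters:
            x = [halves["h1"][sid][param] for sid in common]
            y = [halves["h2"][sid][param] for sid in common]
            r, _ = pearson_r(x, y)
            rows.append(
                {
                    "parameter": param,
                    "task": task,
                    "r_half": r,
                    "reliability": spearman_brown(r) if np.isfinite(r) else float("nan"),
                    "n_subjects": len(common),
                    "n_dropped": n_dropped,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA


@dataclass
class AnovaResult:
    """2 x 2 mixed ANOVA table (group between, task within).

    ``table`` rows: group, task, group x task; columns: SS, df1, df2, F, p,
    eta2 (classical, SS_effect / SS_total) and eta2_partial.
    """

    table: pd.DataFrame
    ss_total: float

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def mixed_anova(values: pd.DataFrame, groups) -> AnovaResult:
    """Split-plot ANOVA of a two-column per-subject table against group labels.

    ``values`` holds one row per subject and exactly two columns (the two
    task conditions); ``groups`` the between-subject labels.  Subjects with a
    missing cell are dropped.  Sums of squares are the sequential (weighted
    means) decomposition, which is exact here because the within factor is
    balanced: every subject contributes both conditions.

    Effects: the group main effect is tested against subject-within-group
    error; the task main effect and the group x task interaction against the
    subject x task error.
    """
    values = pd.DataFrame(values)
    if values.shape[1] != 2:
        raise ValueError("values must have exactly two task columns")
    groups = np.asarray(groups)
    if len(groups) != len(values):
        raise ValueError("groups must align with the rows of values")
    ok = values.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    y1 = values.iloc[:, 0].to_numpy(dtype=float)[ok]
    y2 = values.iloc[:, 1].to_numpy(dtype=float)[ok]
    g = groups[ok]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    n = len(y1)
    if n < 3:
        raise ValueError("too few complete subjects for the ANOVA")

    y = np.concatenate([y1, y2])
    gm = y.mean()
    ss_total = float(np.sum((y - gm) ** 2))

    subj_mean = (y1 + y2) / 2
    ss_between = 2 * np.sum((subj_mean - gm) ** 2)
    ss_group = 2 * sum(
        np.sum(g == lev) * (subj_mean[g == lev].mean() - gm) ** 2 for lev in levels
    )
    ss_err_between = ss_between - ss_group

    d = y1 - y2
    dbar = d.mean()
    ss_task = n * dbar**2 / 2
    ss_inter = sum(
        np.sum(g == lev) * (d[g == lev].mean() - dbar) ** 2 for lev in levels
    ) / 2
    ss_err_within = sum(
        np.sum((d[g == lev] - d[g == lev].mean()) ** 2) for lev in levels
    ) / 2

    df_err = n - 2
    rows = []
    for effect, ss, ss_err in (
        ("group", ss_group, ss_err_between),
        ("task", ss_task, ss_err_within),
        ("group x task", ss_inter, ss_err_within),
    ):
        ms, ms_err = ss / 1, ss_err / df_err
        f = ms / ms_err if ms_err > 0 else float("inf")
        p = float(sps.f.sf(f, 1, df_err))
        rows.append(
            {
                "effect": effect,
                "SS": float(ss),
                "df1": 1,
                "df2": df_err,
                "F": float(f),
                "p": p,
                "eta2": float(ss / ss_total) if ss_total > 0 else float("nan"),
                "eta2_partial": float(ss / (ss + ss_err)) if ss + ss_err > 0 else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_subjects"] = n
    table.attrs["n_dropped"] = n_dropped
    return AnovaResult(table=table, ss_total=ss_total)
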