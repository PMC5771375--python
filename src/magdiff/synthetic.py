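"""Synthetic study cohorts for the magnitude-comparison diffusion analysis.

Generates everything the analysis pipeline consumes, with the statistical
structure the analysis assumes: a control group and a dyscalculia group whose
per-task diffusion parameters follow configurable group means/SDs (defaults
are the published group summaries of the study population this package
models: 272 control and 81 dyscalculic elementary-school children), a
24-item distance-balanced symbolic design, a 48-item ratio-binned dot
comparison design (dot counts 5-21), practice items, and optional contaminant
responses (fast guesses and slow outliers) exercising the cleaning rules.

A per-subject latent achievement factor loads on the diffusion parameters so
that correlations between fitted parameters and an achievement score of
roughly the published magnitudes (|r| ~ 0.2-0.3 for drift rate and symbolic
boundary separation) emerge; the loadings are package defaults, not estimates
from any real data.  Within a subject the same parameter correlates 0.5
across tasks (a placeholder; real cross-task covariance is unknown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import expit

from .preprocessing import TRIAL_COLUMNS
from .wiener import _invert_defective_cdf

__all__ = [
    "PopulationConfig",
    "DesignSpec",
    "make_symbolic_design",
    "make_nonsymbolic_design",
    "sample_population",
    "simulate_dataset",
    "inject_contaminants",
    "simulate_study",
]

RATIO_BINS = (1.2, 1.4, 1.6, 2.6)
DOT_MIN, DOT_MAX = 5, 21
RATIO_TOL = 0.05

#: Group summary statistics (mean, SD) per task for the diffusion parameters,
#: the published cohort values this generator emulates by default.
TABLE5_MEANS = {
    "con": {
        "symbolic": {"a": 1.5, "v": 2.44, "t0": 0.73, "st0": 0.23},
        "nonsymbolic": {"a": 1.49, "v": 1.68, "t0": 0.61, "st0": 0.26},
    },
    "dys": {
        "symbolic": {"a": 1.73, "v": 1.92, "t0": 0.78, "st0": 0.33},
        "nonsymbolic": {"a": 1.6, "v": 1.46, "t0": 0.8, "st0": 0.43},
    },
}
TABLE5_SDS = {
    "con": {
        "symbolic": {"a": 0.48, "v": 0.9, "t0": 0.17, "st0": 0.22},
        "nonsymbolic": {"a": 0.47, "v": 0.7, "t0": 0.33, "st0": 0.23},
    },
    "dys": {
        "symbolic": {"a": 0.41, "v": 0.62, "t0": 0.18, "st0": 0.3},
        "nonsymbolic": {"a": 0.43, "v": 0.69, "t0": 0.57, "st0": 0.43},
    },
}
WEBER = {"con": (0.77, 0.72), "dys": (0.85, 0.76)}
ACHIEVEMENT = {"con": (107.81, 12.31), "dys": (78.89, 4.18)}

#: Standardised loadings of the latent achievement factor on each parameter,
#: (symbolic, non-symbolic); signs follow the published correlation pattern
#: (ability up, caution and non-decision variability down with achievement).
DEFAULT_LOADINGS = {
    "v": (0.32, 0.30),
    "a": (-0.26, -0.04),
    "t0": (-0.16, -0.08),
    "st0": (-0.18, -0.20),
}

#: Validity clipping bounds for sampled parameters.
PARAM_BOUNDS = {"a": (0.2, 4.0), "v": (-6.0, 6.0), "t0": (0.1, 2.0), "st0": (0.01, 2.0)}


@dataclass
class PopulationConfig:
    """Study-population configuration; defaults are the emulated cohort."""

    n_con: int = 272
    n_dys: int = 81
    param_means: dict = field(default_factory=lambda: _deepcopy_nested(TABLE5_MEANS))
    param_sds: dict = field(default_factory=lambda: _deepcopy_nested(TABLE5_SDS))
    weber: dict = field(default_factory=lambda: dict(WEBER))
    achievement: dict = field(default_factory=lambda: dict(ACHIEVEMENT))
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    cross_task_corr: float = 0.5
    contaminant_fast_rate: float = 0.0
    contaminant_slow_rate: float = 0.0

    def __post_init__(self):
        if self.n_con < 2 or self.n_dys < 2:
            raise ValueError("group sizes must be at least 2")
        for group in ("con", "dys"):
            for task in ("symbolic", "nonsymbolic"):
                for p, sd in self.param_sds[group][task].items():
                    if sd <= 0:
                        raise ValueError(f"SD for {group}/{task}/{p} must be > 0")
        if not 0 <= self.cross_task_corr < 1:
            raise ValueError("cross_task_corr must be in [0, 1)")
        for rate in (self.contaminant_fast_rate, self.contaminant_slow_rate):
            if not 0 <= rate < 0.5:
                raise ValueError("contaminant rates must lie in [0, 0.5)")


def _deepcopy_nested(d: dict) -> dict:
    return {
        k: _deepcopy_nested(v) if isinstance(v, dict) else v for k, v in d.items()
    }


@dataclass
class DesignSpec:
    """Item design for one task: a table of stimuli plus practice flags."""

    task: str
    items: pd.DataFrame  # item_index (<=0 for practice), stimulus metadata

    @property
    def test_items(self) -> pd.DataFrame:
        return self.items.loc[self.items["item_index"] >= 1]


def make_symbolic_design(rng: np.random.Generator) -> DesignSpec:
    """24 test items of single-digit pairs, distances 1-6 four times each.

    The larger numeral appears left on half the items of every distance; 3
    practice items (item_index 0, -1, -2) are prepended.
    """
    rows = []
    for dist in range(1, 7):
        sides = [True, True, False, False]
        rng.shuffle(sides)
        for larger_left in sides:
            small = int(rng.integers(1, 10 - dist))
            large = small + dist
            left, right = (large, small) if larger_left else (small, large)
            rows.append({"left_value": left, "right_value": right, "distance": dist})
    rng.shuffle(rows)
    for i, row in enumerate(rows):
        row["item_index"] = i + 1
    practice = []
    for j in range(3):
        dist = int(rng.integers(1, 7))
        small = int(rng.integers(1, 10 - dist))
        left, right = (small + dist, small) if rng.random() < 0.5 else (small, small + dist)
        practice.append(
            {"left_value": left, "right_value": right, "distance": dist, "item_index": -j}
        )
    items = pd.DataFrame(practice[::-1] + rows)
    return DesignSpec(task="symbolic", items=items.reset_index(drop=True))


def _ratio_pairs(bin_target: float) -> list[tuple[int, int]]:
    """Integer dot pairs (larger, smaller) within +/-0.05 of the bin ratio."""
    pairs = []
    for small in range(DOT_MIN, DOT_MAX + 1):
        for large in range(small + 1, DOT_MAX + 1):
            if abs(large / small - bin_target) <= RATIO_TOL + 1e-12:
                pairs.append((large, small))
    return pairs


def make_nonsymbolic_design(rng: np.random.Generator) -> DesignSpec:
    """48 dot-comparison test items: 12 per ratio bin, half size-controlled.

    Dot counts lie in 5-21 and each pair's ratio is within 0.05 of its bin
    target; the larger set appears left on half the items of every bin; 2
    practice items (item_index 0, -1) are prepended.
    """
    rows = []
    for bin_target in RATIO_BINS:
        pairs = _ratio_pairs(bin_target)
        if not pairs:
            raise ValueError(f"no feasible dot pairs for ratio bin {bin_target}")
        chosen = [pairs[i] for i in rng.integers(0, len(pairs), size=12)]
        size_flags = [True] * 6 + [False] * 6
        side_flags = [True] * 6 + [False] * 6
        rng.shuffle(size_flags)
        rng.shuffle(side_flags)
        for (large, small), size_ctrl, larger_left in zip(chosen, size_flags, side_flags):
            n1, n2 = (large, small) if larger_left else (small, large)
            rows.append(
                {
                    "n1": n1,
                    "n2": n2,
                    "ratio_bin": bin_target,
                    "ratio": large / small,
                    "size_control": size_ctrl,
                }
            )
    rng.shuffle(rows)
    for i, row in enumerate(rows):
        row["item_index"] = i + 1
    practice = []
    for j in range(2):
        bin_target = RATIO_BINS[int(rng.integers(0, len(RATIO_BINS)))]
        pairs = _ratio_pairs(bin_target)
        large, small = pairs[int(rng.integers(0, len(pairs)))]
        practice.append(
            {
                "n1": large,
                "n2": small,
                "ratio_bin": bin_target,
                "ratio": large / small,
                "size_control": bool(rng.random() < 0.5),
                "item_index": -j,
            }
        )
    items = pd.DataFrame(practice[::-1] + rows)
    return DesignSpec(task="nonsymbolic", items=items.reset_index(drop=True))


def _correlated_z(lam_s, lam_n, cross_corr, ach_z, rng):
    """Per-task standard scores with achievement loadings and cross-task corr.

    z_task = lam * A + sqrt(1 - lam**2) * (sqrt(rho') * u + sqrt(1 - rho') * e)
    with rho' chosen so that corr(z_sym, z_non) equals ``cross_corr``.
    """
    n = len(ach_z)
    implied = lam_s * lam_n
    denom = math.sqrt((1 - lam_s**2) * (1 - lam_n**2))
    rho = max((cross_corr - implied) / denom, 0.0)
    u = rng.standard_normal(n)
    out = {}
    for task, lam in (("symbolic", lam_s), ("nonsymbolic", lam_n)):
        e = rng.standard_normal(n)
        resid = math.sqrt(rho) * u + math.sqrt(1 - rho) * e
        out[task] = lam * ach_z + math.sqrt(1 - lam**2) * resid
    return out


def sample_population(config: PopulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw subjects with true diffusion parameters, Weber fraction, achievement.

    Returns one row per subject: subject_id, group, achievement, per-task
    true parameters (``a_symbolic`` ... ``st0_nonsymbolic``) and ``w_true``.
    Parameter draws are normal around the group means, clipped to validity
    bounds (a > 0, t0 - st0/2 >= 0).
    """
    frames = []
    for group, n in (("con", config.n_con), ("dys", config.n_dys)):
        ach_z = rng.standard_normal(n)
        mu_ach, sd_ach = config.achievement[group]
        cols = {
            "group": np.repeat(group, n),
            "achievement": mu_ach + sd_ach * ach_z,
        }
        z_v_nonsym = None
        for param in ("a", "v", "t0", "st0"):
            lam_s, lam_n = config.loadings[param]
            z = _correlated_z(lam_s, lam_n, config.cross_task_corr, ach_z, rng)
            for task in ("symbolic", "nonsymbolic"):
                mu = config.param_means[group][task][param]
                sd = config.param_sds[group][task][param]
                lo, hi = PARAM_BOUNDS[param]
                cols[f"{param}_{task}"] = np.clip(mu + sd * z[task], lo, hi)
            if param == "v":
                z_v_nonsym = z["nonsymbolic"]
        # Weber fraction: tied (negatively) to non-symbolic ability
        mu_w, sd_w = config.weber[group]
        z_w = -0.8 * z_v_nonsym + math.sqrt(1 - 0.8**2) * rng.standard_normal(n)
        cols["w_true"] = np.clip(mu_w + sd_w * z_w, 0.02, 3.0)
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    # keep t0 - st0/2 >= 0 after independent clipping
    for task in ("symbolic", "nonsymbolic"):
        out[f"st0_{task}"] = np.minimum(
            out[f"st0_{task}"], 1.9 * out[f"t0_{task}"]
        )
    out.insert(0, "subject_id", [f"s{i + 1:04d}" for i in range(len(out))])
    return out


def _simulate_block(a, v_items, t0, st0, rng):
    """Simulate one subject x task block with per-item drift rates."""
    v_items = np.asarray(v_items, dtype=float)
    n = len(v_items)
    pc = expit(a * v_items)
    correct = rng.random(n) < pc
    u = rng.random(n)
    mass = np.where(correct, pc, 1 - pc)
    drift = np.where(correct, -v_items, v_items)
    td = _invert_defective_cdf(u * mass, a, drift)
    ter = t0 + st0 * (rng.random(n) - 0.5)
    return correct.astype(int), td + ter


def simulate_dataset(
    subjects: pd.DataFrame,
    designs: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the full trial table for every subject x design item.

    Symbolic items share the subject's drift rate; non-symbolic drift scales
    with the item's log numerosity ratio, normalised so the subject's
    configured drift is the design average (the estimation model still fits a
    single drift per subject and task, as the analysis assumes).  RTs are
    rounded to millisecond precision.
    """
    frames = []
    nonsym_items = designs["nonsymbolic"].items
    test = nonsym_items["item_index"] >= 1
    log_ratio = np.log(nonsym_items["ratio"].to_numpy(dtype=float))
    mean_log_ratio = log_ratio[test.to_numpy()].mean()
    for _, subj in subjects.iterrows():
        for task in ("symbolic", "nonsymbolic"):
            items = designs[task].items
            a = float(subj[f"a_{task}"])
            v = float(subj[f"v_{task}"])
            t0 = float(subj[f"t0_{task}"])
            st0 = float(subj[f"st0_{task}"])
            if task == "nonsymbolic":
                v_items = v * log_ratio / mean_log_ratio
            else:
                v_items = np.full(len(items), v)
            correct, rt = _simulate_block(a, v_items, t0, st0, rng)
            block = pd.DataFrame(
                {
                    "subject_id": subj["subject_id"],
                    "group": subj["group"],
                    "task": task,
                    "item_index": items["item_index"].to_numpy(),
                    "left_value": items.get("left_value", pd.Series([np.nan] * len(items))).to_numpy(),
                    "right_value": items.get("right_value", pd.Series([np.nan] * len(items))).to_numpy(),
                    "n1": items.get("n1", pd.Series([np.nan] * len(items))).to_numpy(),
                    "n2": items.get("n2", pd.Series([np.nan] * len(items))).to_numpy(),
                    "ratio_bin": items.get("ratio_bin", pd.Series([np.nan] * len(items))).to_numpy(),
                    "size_control": items.get("size_control", pd.Series([np.nan] * len(items))).to_numpy(),
                    "correct": correct,
                    "rt_s": np.round(rt, 3),
                }
            )
            frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def inject_contaminants(
    trials: pd.DataFrame,
    fast_rate: float,
    slow_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replace a random fraction of responses with contaminants.

    Fast guesses: RT ~ U(0.05, 0.25) s with random correctness.  Slow
    outliers: RT ~ U(4, 8) s, correctness untouched.
    """
    for rate in (fast_rate, slow_rate):
        if not 0 <= rate < 0.5:
            raise ValueError("contaminant rates must lie in [0, 0.5)")
    out = trials.copy()
    u = rng.random(len(out))
    fast = u < fast_rate
    slow = (u >= fast_rate) & (u < fast_rate + slow_rate)
    n_fast, n_slow = int(fast.sum()), int(slow.sum())
    if n_fast:
        out.loc[fast, "rt_s"] = np.round(rng.uniform(0.05, 0.25, n_fast), 3)
        out.loc[fast, "correct"] = (rng.random(n_fast) < 0.5).astype(int)
    if n_slow:
        out.loc[slow, "rt_s"] = np.round(rng.uniform(4.0, 8.0, n_slow), 3)
    return out


def simulate_study(config: PopulationConfig, seed: int):
    """Generate a complete study dataset from a master seed.

    Returns ``(trials, subjects, designs)``; the same config and seed always
    produce byte-identical trial tables.
    """
    rng = np.random.default_rng(seed)
    designs = {
        "symbolic": make_symbolic_design(rng),
        "nonsymbolic": make_nonsymbolic_design(rng),
    }
    subjects = sample_population(config, rng)
    trials = simulate_dataset(subjects, designs, rng)
    if config.contaminant_fast_rate or config.contaminant_slow_rate:
        trials = inject_contaminants(
            trials, config.contaminant_fast_rate, config.contaminant_slow_rate, rng
        )
    return trials, subjects, designs
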