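"""Per-subject diffusion-parameter estimation by Kolmogorov-Smirnov distance.

The estimator minimises the supremum distance between the model's signed-RT
CDF (errors negated, correct responses positive) and the empirical signed-RT
CDF over ``(a, v, t0, st0)``.  This objective is robust to contaminant
response times and, unlike maximum likelihood, its bias does not depend on
the number of trials — the reason it is the method of choice for designs with
only a few dozen items per condition.

The public surface is a statsmodels-style pair:

>>> model = DiffusionKSModel(correct, rt)          # doctest: +SKIP
>>> res = model.fit(seed=1)                        # doctest: +SKIP
>>> res.params.v, res.ks_stat                      # doctest: +SKIP

Optimisation is derivative-free Nelder-Mead with multiple restarts: one
closed-form EZ-diffusion start plus seeded random perturbations of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .wiener import DiffusionParams, predicted_quartiles, signed_rt_cdf

__all__ = [
    "EmpiricalSignedCDF",
    "empirical_signed_cdf",
    "ks_statistic",
    "ez_init",
    "DiffusionKSModel",
    "DiffusionKSResults",
    "FitAssessment",
    "fit_subject_task",
    "assess_fit",
]

#: Optimisation bounds: generous cover of parameter ranges seen in children's
#: magnitude-comparison data (a ~ 1.5, v ~ 1.4-2.4, t0 ~ 0.6-0.8 s).
BOUNDS_A = (0.2, 4.0)
BOUNDS_V = (-6.0, 6.0)
T0_MIN = 0.05
_PENALTY = 1.5  # objective value outside the feasible region (KS is <= 1)


def signed_times(correct, rt) -> np.ndarray:
    """Map responses to the signed axis: errors at -rt, corrects at +rt."""
    correct = np.asarray(correct)
    rt = np.asarray(rt, dtype=float)
    return np.where(correct == 1, rt, -rt)


class EmpiricalSignedCDF:
    """Right-continuous empirical CDF of signed response times."""

    def __init__(self, correct, rt):
        if len(np.atleast_1d(rt)) == 0:
            raise ValueError("empirical CDF requires at least one trial")
        self.x = np.sort(signed_times(correct, rt))
        self.n = len(self.x)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.x, t, side="right") / self.n


def empirical_signed_cdf(correct, rt) -> EmpiricalSignedCDF:
    """Empirical counterpart of :func:`magdiff.wiener.signed_rt_cdf`."""
    return EmpiricalSignedCDF(correct, rt)


def ks_statistic(params: DiffusionParams, correct, rt) -> float:
    """Supremum distance between model and empirical signed-RT CDFs.

    Evaluated at both one-sided limits of every empirical jump point, which
    attains the supremum for a continuous model CDF.
    """
    x = np.sort(signed_times(correct, rt))
    n = len(x)
    if n == 0:
        raise ValueError("ks_statistic requires at least one trial")
    g = signed_rt_cdf(x, params)
    steps_hi = np.arange(1, n + 1) / n
    steps_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(g - steps_hi)), np.max(np.abs(g - steps_lo))))


def ez_init(
    accuracy: float,
    rt_mean_correct: float,
    rt_var_correct: float,
    n: int,
    st0_frac: float = 0.5,
) -> DiffusionParams:
    """Closed-form EZ-diffusion starting values (unit diffusion coefficient).

    Accuracy exactly 0 or 1 is edge-corrected to ``0.5/n`` or ``(n-0.5)/n``;
    accuracy exactly 0.5 is nudged upward (ties break toward positive drift).
    Degenerate RT variance falls back to a generic start.  ``st0`` is
    initialised to ``st0_frac * t0``.
    """
    if accuracy >= 1.0:
        accuracy = (n - 0.5) / n
    elif accuracy <= 0.0:
        accuracy = 0.5 / n
    if abs(accuracy - 0.5) < 1e-12:
        accuracy += 1.0 / (2 * n)
    if not (rt_var_correct > 0) or not np.isfinite(rt_var_correct):
        t0 = max(T0_MIN, rt_mean_correct - 0.3 if np.isfinite(rt_mean_correct) else 0.3)
        return DiffusionParams(1.2, 1.0, t0, st0_frac * t0)
    L = math.log(accuracy / (1 - accuracy))
    x = L * (L * accuracy**2 - L * accuracy + accuracy - 0.5) / rt_var_correct
    v = math.copysign(abs(x) ** 0.25, accuracy - 0.5)
    v = float(np.clip(v, BOUNDS_V[0] + 1e-3, BOUNDS_V[1] - 1e-3))
    a = float(np.clip(L / v, BOUNDS_A[0] + 1e-3, BOUNDS_A[1] - 1e-3))
    mdt = (a / (2 * v)) * math.tanh(a * v / 2)
    t0 = max(T0_MIN, rt_mean_correct - mdt)
    return DiffusionParams(a, v, t0, st0_frac * t0)


@dataclass
class FitAssessment:
    """Predicted vs observed accuracy and RT quartiles for one fit."""

    predicted_accuracy: float
    observed_accuracy: float
    predicted_quartiles: tuple
    observed_quartiles: tuple
    mode: str

    @property
    def accuracy_residual(self) -> float:
        return self.observed_accuracy - self.predicted_accuracy

    @property
    def quartile_residuals(self) -> tuple:
        return tuple(
            o - p for o, p in zip(self.observed_quartiles, self.predicted_quartiles)
        )


@dataclass
class DiffusionKSResults:
    """Results of a KS diffusion fit for one subject x task."""

    params: DiffusionParams
    ks_stat: float
    n_trials: int
    n_restarts: int
    converged: bool
    n_fev: int
    trace: list = field(default_factory=list, repr=False)
    model: "DiffusionKSModel | None" = field(default=None, repr=False)

    def assess(self, mode: str = "all") -> FitAssessment:
        """Compare model-implied accuracy/quartiles with the observed ones."""
        if self.model is None:
            raise ValueError("results are detached from their model data")
        return assess_fit(self, self.model.correct, self.model.rt, mode=mode)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "a": p.a,
            "v": p.v,
            "t0": p.t0,
            "st0": p.st0,
            "ks_stat": self.ks_stat,
            "n_trials": self.n_trials,
            "converged": self.converged,
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "Diffusion model (unbiased, unit diffusion) - KS fit",
            "=" * 51,
            f"{'boundary separation a':<30}{p.a:>10.4f}",
            f"{'drift rate v':<30}{p.v:>10.4f}",
            f"{'non-decision time t0 (s)':<30}{p.t0:>10.4f}",
            f"{'non-decision range st0 (s)':<30}{p.st0:>10.4f}",
            "-" * 51,
            f"{'KS statistic':<30}{self.ks_stat:>10.4f}",
            f"{'n trials':<30}{self.n_trials:>10d}",
            f"{'restarts':<30}{self.n_restarts:>10d}",
            f"{'objective evaluations':<30}{self.n_fev:>10d}",
            f"{'converged':<30}{str(self.converged):>10}",
        ]
        return "\n".join(lines)


class DiffusionKSModel:
    """Kolmogorov-Smirnov estimator of the four-parameter diffusion model.

    Parameters
    ----------
    correct : array-like of {0, 1}
        Response correctness per trial.
    rt : array-like of float
        Response times in seconds (> 0).
    min_trials : int
        Refuse to fit fewer trials than this (default 10).
    """

    def __init__(self, correct, rt, min_trials: int = 10):
        self.correct = np.asarray(correct).astype(int)
        self.rt = np.asarray(rt, dtype=float)
        if self.correct.shape != self.rt.shape:
            raise ValueError("correct and rt must have the same length")
        if np.any(self.rt <= 0):
            raise ValueError("all response times must be positive")
        self.min_trials = min_trials
        self.n_trials = len(self.rt)
        self._x = np.sort(signed_times(self.correct, self.rt))
        self._x_abs_min = float(self.rt.min())
        self._steps_hi = np.arange(1, self.n_trials + 1) / self.n_trials
        self._steps_lo = np.arange(0, self.n_trials) / self.n_trials

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, correct_col: str = "correct", rt_col: str = "rt_s", **kw
    ) -> "DiffusionKSModel":
        return cls(df[correct_col].to_numpy(), df[rt_col].to_numpy(), **kw)

    # -- objective ---------------------------------------------------------

    def ks(self, params: DiffusionParams) -> float:
        if _kernels.HAVE_NUMBA:
            return _kernels.ks_from_sorted(
                self._x, params.a, params.v, params.t0, params.st0
            )
        g = signed_rt_cdf(self._x, params)
        return float(
            max(np.max(np.abs(g - self._steps_hi)), np.max(np.abs(g - self._steps_lo)))
        )

    def _objective(self, x: np.ndarray) -> float:
        a, v, t0, st0 = x
        lo_support = t0 - st0 / 2
        if a <= 0 or t0 < 0 or st0 < 0 or lo_support < 0:
            return _PENALTY + abs(min(a, t0, st0, lo_support, 0.0))
        # no observed RT can precede the non-decision support edge; steer the
        # simplex back instead of letting it wander in a flat KS region
        min_rt = self._x_abs_min
        if lo_support > min_rt:
            return _PENALTY + (lo_support - min_rt)
        return self.ks(DiffusionParams(a, v, t0, st0))

    # -- fitting -----------------------------------------------------------

    def _starts(self, n_restarts: int, rng: np.random.Generator):
        acc = float(np.mean(self.correct))
        crt = self.rt[self.correct == 1]
        mrt = float(crt.mean()) if crt.size else float(self.rt.mean())
        vrt = float(crt.var(ddof=1)) if crt.size > 1 else float("nan")
        ez = ez_init(acc, mrt, vrt, self.n_trials)
        min_rt = float(self.rt.min())
        starts = [ez]
        for _ in range(n_restarts - 1):
            a = float(np.clip(ez.a * math.exp(0.3 * rng.standard_normal()), *BOUNDS_A))
            v = float(np.clip(ez.v + 0.6 * rng.standard_normal(), *BOUNDS_V))
            t0 = float(
                np.clip(ez.t0 * (1 + 0.2 * rng.standard_normal()), T0_MIN, max(min_rt, T0_MIN))
            )
            st0 = float(np.clip(ez.st0 * math.exp(0.5 * rng.standard_normal()), 0.0, 1.8 * t0))
            starts.append(DiffusionParams(a, v, t0, st0))
        return starts, min_rt

    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        maxfev: int = 400,
        fatol: float = 1e-5,
        xatol: float = 1e-4,
    ) -> DiffusionKSResults:
        """Minimise the KS distance; deterministic for a given seed.

        Raises ``ValueError`` when fewer than ``min_trials`` trials are
        available.  Non-convergence of every restart is flagged on the result
        (``converged=False``), never silently ignored.
        """
        if self.n_trials < self.min_trials:
            raise ValueError(
                f"refusing to fit {self.n_trials} trials (min_trials={self.min_trials})"
            )
        rng = np.random.default_rng(seed)
        starts, min_rt = self._starts(n_restarts, rng)
        # t0 itself may exceed the fastest RT when st0 > 0; only the support
        # edge t0 - st0/2 must stay below it, which the objective enforces
        t0_hi = max(min_rt, T0_MIN + 1e-4) + 1.5
        bounds = [BOUNDS_A, BOUNDS_V, (T0_MIN, t0_hi), (0.0, 2.0 * t0_hi)]
        lower = np.array([b[0] for b in bounds])
        upper = np.array([b[1] for b in bounds])
        best_x, best_f = None, np.inf
        trace = []
        total_fev = 0
        any_success = False
        for start in starts:
            t0x = float(np.clip(start.t0, T0_MIN, max(min_rt, T0_MIN)))
            x0 = np.array(
                [
                    np.clip(start.a, *BOUNDS_A),
                    np.clip(start.v, *BOUNDS_V),
                    t0x,
                    np.clip(start.st0, 0.0, 1.8 * t0x),
                ]
            )
            if _kernels.HAVE_NUMBA:
                xb, fb, nfev, ok = _kernels.nelder_mead_ks(
                    x0,
                    lower,
                    upper,
                    self._x,
                    self._x_abs_min,
                    maxfev,
                    fatol,
                    xatol,
                    _kernels._GL_NODES,
                    _kernels._GL_WEIGHTS,
                )
                fb = float(fb)
            else:
                res = minimize(
                    self._objective,
                    x0,
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={"maxfev": maxfev, "fatol": fatol, "xatol": xatol},
                )
                xb, fb, nfev, ok = res.x, float(res.fun), res.nfev, bool(res.success)
            total_fev += nfev
            trace.append({"x0": x0.tolist(), "fun": fb, "nfev": nfev})
            any_success = any_success or ok
            if fb < best_f:
                best_x, best_f = np.asarray(xb, dtype=float), fb
        a, v, t0, st0 = best_x
        st0 = min(st0, 2 * t0)  # guard floating error at the constraint edge
        return DiffusionKSResults(
            params=DiffusionParams(float(a), float(v), float(t0), float(st0)),
            ks_stat=float(best_f),
            n_trials=self.n_trials,
            n_restarts=n_restarts,
            converged=any_success,
            n_fev=total_fev,
            trace=trace,
            model=self,
        )


def fit_subject_task(
    trials: pd.DataFrame, min_trials: int = 10, **fit_kwargs
) -> DiffusionKSResults:
    """Fit one subject x task trial table (columns ``correct`` and ``rt_s``)."""
    model = DiffusionKSModel.from_dataframe(trials, min_trials=min_trials)
    return model.fit(**fit_kwargs)


def assess_fit(
    fit: DiffusionKSResults, correct, rt, mode: str = "all"
) -> FitAssessment:
    """Pair model-implied accuracy/quartiles with their observed counterparts.

    ``mode`` selects whether quartiles are over all responses or correct
    responses only (both conventions are in use for this kind of scatter
    diagnostic).
    """
    correct = np.asarray(correct)
    rt = np.asarray(rt, dtype=float)
    pred_acc, pred_q = predicted_quartiles(fit.params, mode=mode)
    obs_acc = float(np.mean(correct))
    obs_rt = rt if mode == "all" else rt[correct == 1]
    obs_q = tuple(float(q) for q in np.quantile(obs_rt, [0.25, 0.5, 0.75]))
    return FitAssessment(
        predicted_accuracy=pred_acc,
        observed_accuracy=obs_acc,
        predicted_quartiles=pred_q,
        observed_quartiles=obs_q,
        mode=mode,
    )
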