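"""Weber-fraction estimation for non-symbolic (dot-set) comparison.

The approximate number system is modelled as representing a numerosity ``n``
by a Gaussian with mean ``n`` and standard deviation ``w * n`` (linear
scalar variability).  The probability of correctly judging which of two dot
sets ``n1 != n2`` is larger is then

    P(correct) = Phi( |n1 - n2| / (w * sqrt(n1**2 + n2**2)) )

which decreases from 1 (w -> 0, noiseless) to 1/2 (w -> infinity, guessing).
The Weber fraction ``w`` is estimated per subject by maximising the Bernoulli
log-likelihood of the observed correctness over ``w`` in [0, 3]; optima on
the interval boundary are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

__all__ = ["weber_p_correct", "WeberFit", "WeberModel", "fit_weber"]

W_MAX = 3.0
_GRID_STEP = 0.005
_P_FLOOR = 1e-12


def weber_p_correct(n1, n2, w):
    """Probability of a correct larger/smaller judgement of two numerosities."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 == n2):
        raise ValueError("equal numerosities have no correct response")
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("Weber fraction must be non-negative")
    with np.errstate(divide="ignore"):
        z = np.abs(n1 - n2) / (w * np.sqrt(n1**2 + n2**2))
    out = ndtr(z)  # w == 0 -> z = inf -> 1.0
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class WeberFit:
    """Maximum-likelihood Weber fraction for one subject."""

    w: float
    loglik: float
    at_boundary: bool
    n_trials: int

    def summary(self) -> str:
        return (
            "Weber fraction (linear ANS model) - ML fit\n"
            + "=" * 42
            + f"\n{'w':<20}{self.w:>10.4f}"
            + f"\n{'log-likelihood':<20}{self.loglik:>10.4f}"
            + f"\n{'n trials':<20}{self.n_trials:>10d}"
            + f"\n{'at boundary':<20}{str(self.at_boundary):>10}"
        )


class WeberModel:
    """Bernoulli likelihood of correctness under the linear ANS model."""

    def __init__(self, n1, n2, correct):
        self.n1 = np.asarray(n1, dtype=float)
        self.n2 = np.asarray(n2, dtype=float)
        self.correct = np.asarray(correct).astype(int)
        if not (len(self.n1) == len(self.n2) == len(self.correct)):
            raise ValueError("n1, n2 and correct must have equal length")
        if len(self.n1) == 0:
            raise ValueError("at least one trial is required")
        if np.any(self.n1 == self.n2):
            raise ValueError("equal numerosities are not presentable")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "WeberModel":
        return cls(df["n1"].to_numpy(), df["n2"].to_numpy(), df["correct"].to_numpy())

    def loglik(self, w: float) -> float:
        p = np.clip(weber_p_correct(self.n1, self.n2, w), _P_FLOOR, 1 - _P_FLOOR)
        return float(np.sum(np.where(self.correct == 1, np.log(p), np.log1p(-p))))

    def fit(self) -> WeberFit:
        """Dense grid search followed by bounded golden-section refinement."""
        grid = np.arange(_GRID_STEP, W_MAX + _GRID_STEP / 2, _GRID_STEP)
        z = np.abs(self.n1 - self.n2) / np.sqrt(self.n1**2 + self.n2**2)
        p = np.clip(ndtr(z[None, :] / grid[:, None]), _P_FLOOR, 1 - _P_FLOOR)
        ll = np.where(self.correct[None, :] == 1, np.log(p), np.log1p(-p)).sum(axis=1)
        i = int(np.argmax(ll))
        lo = grid[max(i - 1, 0)] if i > 0 else 0.0
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda w: -self.loglik(w), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        w = float(res.x)
        ll_w = -float(res.fun)
        # all-correct data push w to 0; compare against the w -> 0 limit
        ll0 = self.loglik(0.0)
        if ll0 >= ll_w:
            w, ll_w = 0.0, ll0
        at_boundary = w <= _GRID_STEP or w >= W_MAX - _GRID_STEP
        return WeberFit(w=w, loglik=ll_w, at_boundary=at_boundary, n_trials=len(self.n1))


def fit_weber(trials: pd.DataFrame) -> WeberFit:
    """Fit the Weber fraction from a non-symbolic trial table (n1, n2, correct)."""
    return WeberModel.from_dataframe(trials).fit()
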