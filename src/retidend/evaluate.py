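"""Decoder evaluation: accuracy as a smooth function of cricket distance.

Per-frame decoder correctness is regressed on the distance to the cricket
with a penalized-spline logistic generalized additive model (no random
effects); frames of cricket-removed clips inherit the distance of their
paired cricket-present counterpart.  The fitted curve with pointwise
confidence intervals makes the RGC population variants comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = ["EvalCurve", "accuracy_vs_distance", "bootstrap_accuracy_diff"]


@dataclass
class EvalCurve:
    distances: np.ndarray     # evaluation grid, cm
    accuracy: np.ndarray      # fitted P(correct) on the grid
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_accuracy: float      # raw fraction correct


def accuracy_vs_distance(correct: np.ndarray, distances: np.ndarray,
                         df: int = 6, alpha: float = 1.0,
                         n_grid: int = 100,
                         ci_level: float = 0.95) -> EvalCurve:
    """Fit a logistic penalized-spline GAM of correctness vs distance.

    ``correct`` is a 0/1 array per frame; ``distances`` the matched
    cricket distance in cm.  Sparse data (fewer distinct distances than
    spline degrees of freedom) widens the smoothing by reducing ``df``
    with a warning.  Returns the fitted accuracy curve with pointwise
    Wald confidence intervals on a uniform distance grid.
    """
    correct = np.asarray(correct, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if correct.shape != distances.shape:
        raise ValueError("correct and distances must align")
    n_unique = len(np.unique(distances))
    if n_unique < df + 2:
        df_new = max(4, n_unique - 2)
        warnings.warn(
            f"only {n_unique} distinct distances; widening smoothing "
            f"(df {df} -> {df_new})")
        df = df_new

    if np.all(correct == correct[0]):
        # degenerate: constant correctness, no model needed
        grid = np.linspace(distances.min(), distances.max(), n_grid)
        const = np.full(n_grid, correct[0])
        return EvalCurve(grid, const, const.copy(), const.copy(),
                         float(correct.mean()))

    bs = BSplines(distances[:, None], df=[df], degree=[3])
    exog = np.ones((len(correct), 1))
    gam = GLMGam(correct, exog=exog, smoother=bs,
                 family=sm.families.Binomial(), alpha=[alpha])
    res = gam.fit()

    grid = np.linspace(distances.min(), distances.max(), n_grid)
    basis = bs.transform(grid[:, None])
    design = np.column_stack([np.ones(n_grid), basis])
    eta = design @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.einsum("ij,jk,ik->i", design, cov, design))
    z = norm.ppf(0.5 + ci_level / 2)
    inv = lambda e: 1.0 / (1.0 + np.exp(-e))
    return EvalCurve(grid, inv(eta), inv(eta - z * se), inv(eta + z * se),
                     float(correct.mean()))


def bootstrap_accuracy_diff(correct_a: np.ndarray, correct_b: np.ndarray,
                            n_boot: int = 2000, seed: int = 0,
                            ci_level: float = 0.95) -> tuple[float, float, float]:
    """Bootstrap CI of the accuracy difference mean(a) - mean(b).

    Returns ``(diff, lo, hi)``; a positive ``lo`` establishes a > b at the
    requested confidence.
    """
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = (a[rng.integers(len(a), size=len(a))].mean()
                    - b[rng.integers(len(b), size=len(b))].mean())
    q = (1 - ci_level) / 2
    return float(a.mean() - b.mean()), float(np.quantile(diffs, q)), \
        float(np.quantile(diffs, 1 - q))
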