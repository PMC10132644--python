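"""In vitro cleavage kinetics: fraction cleaved, first-order fits, comparisons.

Plasmid cleavage time courses are quantified from gel densitometry of the
three topological states — supercoiled (uncut), nicked, and linear — with
fraction cleaved = (nicked + linear) / (nicked + linear + supercoiled).
The time course is fit to the first-order rate equation

    f(t) = A · (1 − exp(−k_obs · t))

by bounded least squares (k_obs ≥ 0, plateau A in [0, 1]) from a fixed
grid of initial rates, so the fit is deterministic.  Replicate rate
constants are averaged, and conditions are compared with the classical
unpaired two-tailed t test.

Default quench times are 7, 15, 30, 60, 300, 900 and 1,800 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats as sps

#: default quench times (seconds)
DEFAULT_TIMEPOINTS = (7.0, 15.0, 30.0, 60.0, 300.0, 900.0, 1800.0)

#: deterministic multi-start grid for the rate constant (per second)
K_START_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


class EmptyLaneError(ValueError):
    """All three band intensities are zero: nothing was loaded."""


@dataclass
class TimeCourse:
    """Fraction cleaved over time for one replicate."""

    timepoints: np.ndarray  # seconds, strictly increasing
    fraction_cleaved: np.ndarray  # in [0, 1]
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.fraction_cleaved = np.asarray(self.fraction_cleaved, dtype=float)
        if self.timepoints.shape != self.fraction_cleaved.shape:
            raise ValueError("timepoints and fractions must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any((self.fraction_cleaved < 0) | (self.fraction_cleaved > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class RateFit:
    """First-order fit result for one time course."""

    k_obs: float  # per second, >= 0
    plateau: float  # fitted amplitude A in [0, 1]
    rss: float
    converged: bool
    degenerate: bool = False  # no cleavage signal: k and A pinned at 0
    k_is_lower_bound: bool = False  # reaction saturated by the first timepoint

    def __post_init__(self) -> None:
        if self.k_obs < 0:
            raise ValueError("k_obs must be >= 0")


def fraction_cleaved(supercoiled: float, nicked: float, linear: float) -> float:
    """(nicked + linear) / (nicked + linear + supercoiled), band fractions >= 0."""
    if min(supercoiled, nicked, linear) < 0:
        raise ValueError("band intensities must be nonnegative")
    total = supercoiled + nicked + linear
    if total == 0:
        raise EmptyLaneError("all-zero densitometry")
    return (nicked + linear) / total


def first_order(t: np.ndarray, k: float, plateau: float) -> np.ndarray:
    return plateau * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def fit_first_order(tc: TimeCourse, fix_plateau: Optional[float] = None) -> RateFit:
    """Bounded least-squares fit of f(t) = A(1 − e^{−kt}) to one time course.

    The plateau A is fitted freely in [0, 1] unless ``fix_plateau`` pins it.
    Optimisation restarts from a fixed grid of initial rates and keeps the
    lowest residual sum of squares, making the result deterministic.  A
    time course with no signal at all is flagged degenerate (k = A = 0);
    a reaction already >= 99% complete at the first timepoint only bounds
    k from below, which is flagged rather than reported as precise.
    """
    t = tc.timepoints
    y = tc.fraction_cleaved
    if t.size < 3:
        raise ValueError("need at least 3 timepoints to fit")
    if fix_plateau is not None and not 0.0 <= fix_plateau <= 1.0:
        raise ValueError("fix_plateau must lie in [0, 1]")

    if np.all(y == 0.0):
        return RateFit(k_obs=0.0, plateau=0.0 if fix_plateau is None else fix_plateau,
                       rss=0.0, converged=True, degenerate=True)

    if fix_plateau is None:
        def residuals(p):
            return first_order(t, p[0], p[1]) - y
        bounds = ([0.0, 0.0], [np.inf, 1.0])
        a0 = min(1.0, max(float(y.max()), 1e-6))
        starts = [[k0, a0] for k0 in K_START_GRID]
    else:
        def residuals(p):
            return first_order(t, p[0], fix_plateau) - y
        bounds = ([0.0], [np.inf])
        starts = [[k0] for k0 in K_START_GRID]

    best = None
    any_success = False
    for p0 in starts:
        try:
            sol = optimize.least_squares(residuals, p0, bounds=bounds, method="trf",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        any_success = any_success or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("optimizer failed from every start")
    rss, sol = best
    k = float(sol.x[0])
    plateau = float(fix_plateau if fix_plateau is not None else sol.x[1])
    saturated = plateau > 0 and first_order(np.array([t[0]]), k, plateau)[0] >= 0.99 * plateau
    return RateFit(
        k_obs=k,
        plateau=plateau,
        rss=rss,
        converged=any_success,
        k_is_lower_bound=bool(saturated),
    )


def summarize_replicates(fits: Sequence[RateFit]) -> tuple[float, float, int]:
    """Mean and sample SD of k_obs over converged fits; SD is NaN for n = 1."""
    ks = [f.k_obs for f in fits if f.converged]
    if not ks:
        raise ValueError("no converged fits to summarize")
    mean = float(np.mean(ks))
    sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else float("nan")
    return mean, sd, len(ks)


def compare_conditions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Unpaired two-tailed t test between two sets of rate constants.

    Classical pooled-variance form by default (``welch=True`` for unequal
    variances).  With zero variance in both groups and equal means the test
    is vacuous: (t, p) = (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
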