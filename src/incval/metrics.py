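"""Accuracy measures and incremental values on score-distribution pairs.

The central identities, written for a risk score with conditional CDFs
F1 (events) and F0 (non-events), event rate pi and q_alpha = F1^{-1}(alpha):

    AUC = ∫₀¹ F0(q_alpha) d alpha
    AP  = ∫₀¹ {1 + (pi⁻¹ − 1) [1 − F0(q_alpha)] / (1 − alpha)}⁻¹ d alpha

and, for a change from an old to a new model,

    ΔΨ = ∫₀¹ w_Ψ(alpha) Δ(alpha) d alpha,   Ψ ∈ {AUC, AP},

with Δ(alpha) = F_new,0(q_new,alpha) − F_old,0(q_old,alpha), w_AUC ≡ 1 and
w_AP the event-rate-dependent weight of :func:`ap_weight` that grows as
alpha → 1.  The weight is why ΔAUC and ΔAP can disagree: ΔAP concentrates
on the upper (high-risk) quantiles, and increasingly so as pi shrinks.

Throughout, the incremental-value sign convention is new minus old.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (
    DegenerateDistributionError,
    EmpiricalPair,
    GridPair,
    ScoreDistributionPair,
)

#: Default quadrature grid in alpha: composite trapezoid over
#: [1e-6, 1 - 1e-6]; the excluded endpoint slivers contribute at most 2e-6
#: to either integral since both integrands are bounded in [0, 1].
DEFAULT_ALPHA_GRID = np.linspace(1e-6, 1.0 - 1e-6, 20_001)

_INTERNAL_IDENTITY_TOL = 1e-4


def _alpha_integral(values: np.ndarray, grid: np.ndarray) -> float:
    """Composite trapezoid over the alpha grid, extended to the full unit
    interval by end slabs carrying the boundary values (both integrands
    are bounded in [0, 1] and smooth at the endpoints, so the slab error
    is O(eps^2) for the 1e-6 end gaps of the default grid)."""
    return float(np.trapezoid(values, grid)
                 + grid[0] * values[0] + (1.0 - grid[-1]) * values[-1])


class InternalConsistencyError(AssertionError):
    """Two mathematically equivalent computation paths disagreed."""


def _check_pi(pi: float) -> float:
    pi = float(pi)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"event rate pi must lie in (0, 1), got {pi}")
    return pi


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(pair: ScoreDistributionPair, alpha_grid: np.ndarray | None = None) -> float:
    """Area under the ROC curve, ∫₀¹ F0(q_alpha) d alpha.

    Closed-form pairs integrate on the alpha grid with exact quantiles.
    Grid pairs integrate the equivalent threshold-space form ∫ F0 dF1,
    which avoids inverting the tabulated CDF.  Empirical pairs use the
    exact stepwise value, the mean of F0_hat over the observed event
    scores, which coincides with the strict Mann-Whitney estimator on
    tie-free data.
    """
    if isinstance(pair, EmpiricalPair):
        return float(np.mean(pair.cdf0(pair.event_scores)))
    if isinstance(pair, GridPair):
        f1, f0 = pair.f1_values, pair.f0_values
        if f1[-1] - f1[0] <= 1e-12:
            raise DegenerateDistributionError("event-score distribution is degenerate")
        return float(np.sum(0.5 * (f0[1:] + f0[:-1]) * np.diff(f1)))
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    q = pair.quantile1(grid)
    if not np.any(np.diff(q) > 0):
        raise DegenerateDistributionError("event-score distribution is degenerate")
    return _alpha_integral(pair.cdf0(q), grid)


# ---------------------------------------------------------------------------
# AP
# ---------------------------------------------------------------------------

def _ap_integrand_from_log_ratio(log_ratio: np.ndarray, pi: float) -> np.ndarray:
    """{1 + (pi⁻¹−1) exp(log_ratio)}⁻¹ evaluated stably."""
    k = 1.0 / pi - 1.0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + k * np.exp(log_ratio))


def ap(pair: ScoreDistributionPair, pi: float,
       alpha_grid: np.ndarray | None = None) -> float:
    """Average precision (area under the precision-recall curve).

    Computed as ∫₀¹ {1 + (pi⁻¹−1)[1−F0(q_alpha)]/(1−alpha)}⁻¹ d alpha.
    The tail ratio [1−F0(q_alpha)]/(1−alpha) is evaluated in log-survival
    form: both factors vanish as alpha → 1 and the naive quotient loses
    every significant digit there.

    Empirical pairs are integrated exactly: on each interval between
    consecutive event order statistics the survival ratio is constant and
    the alpha-integral has a closed-form antiderivative.
    """
    pi = _check_pi(pi)
    if isinstance(pair, EmpiricalPair):
        return _ap_empirical_exact(pair, pi)
    if isinstance(pair, GridPair):
        return _ap_grid(pair, pi)
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    q = pair.quantile1(grid)
    log_ratio = pair.log_sf0(q) - np.log1p(-grid)
    return _alpha_integral(_ap_integrand_from_log_ratio(log_ratio, pi), grid)


def _ap_grid(pair: GridPair, pi: float) -> float:
    """Threshold-space AP for tabulated pairs: ∫ {1 + k S0/S1}⁻¹ dF1."""
    f1 = pair.f1_values
    s1 = pair.sf1_values if pair.sf1_values is not None else 1.0 - f1
    s0 = pair.sf0_values if pair.sf0_values is not None else 1.0 - pair.f0_values
    k = 1.0 / pi - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s1 > 0, s0 / np.where(s1 > 0, s1, 1.0), np.inf)
    integrand = 1.0 / (1.0 + k * ratio)
    # where S1 has fully vanished the integrand limit is taken from the
    # last threshold that still carries event mass; dF1 there is 0 anyway
    if np.any(s1 <= 0):
        last = np.max(np.nonzero(s1 > 0))
        integrand[s1 <= 0] = integrand[last]
    mid = 0.5 * (integrand[1:] + integrand[:-1])
    return float(np.sum(mid * np.diff(f1)))


def _ap_empirical_exact(pair: EmpiricalPair, pi: float) -> float:
    """Exact alpha-integral of the AP integrand for step ECDFs.

    With q_alpha constant on (alpha_{i-1}, alpha_i] the integrand is
    t/(t + b) in t = 1 − alpha with b = k * S0_hat at the i-th event
    order statistic; ∫ t/(t+b) dt = t − b log(t+b).
    """
    n1 = pair.event_scores.size
    k = 1.0 / pi - 1.0
    s0 = 1.0 - pair.cdf0(pair.event_scores)  # aligned with sorted event scores
    b = k * s0
    edges = np.arange(n1 + 1) / n1  # alpha breakpoints
    t_hi = 1.0 - edges[:-1]  # upper t endpoint of each interval
    t_lo = 1.0 - edges[1:]

    def antider(t, b):
        b_safe = np.where(b > 0, b, 1.0)
        return np.where(b > 0, t - b_safe * np.log(t + b_safe), t)

    return float(np.sum(antider(t_hi, b) - antider(t_lo, b)))


def ap_from_pr_curve(pair: ScoreDistributionPair, pi: float,
                     thresholds: np.ndarray | None = None) -> float:
    """AP as the literal area under the PR curve, ∫ PPV dTPR on a
    threshold grid.  Serves as an independent quadrature route for
    cross-checking :func:`ap` (the two agree to ~1e-5 for smooth pairs)."""
    pi = _check_pi(pi)
    c = pair.threshold_grid if thresholds is None else np.asarray(thresholds)
    s1 = pair.sf1(c)
    s0 = pair.sf0(c)
    den = pi * s1 + (1.0 - pi) * s0
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(den > 0, pi * s1 / np.where(den > 0, den, 1.0), np.nan)
    if np.any(np.isnan(ppv)):
        last = np.max(np.nonzero(~np.isnan(ppv)))
        ppv[np.isnan(ppv)] = ppv[last]
    tpr = s1
    # TPR decreases with c; integrate PPV over the TPR axis
    mid = 0.5 * (ppv[1:] + ppv[:-1])
    return float(np.sum(mid * -np.diff(tpr)))


# ---------------------------------------------------------------------------
# Operating-point curves
# ---------------------------------------------------------------------------

def curve_points(pair: ScoreDistributionPair, pi: float,
                 thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """TPR/FPR/PPV/NPV at each threshold c.

    TPR = 1−F1(c), FPR = 1−F0(c),
    PPV = pi·TPR / [pi·TPR + (1−pi)·FPR],
    NPV = (1−pi)·F0 / [pi·F1 + (1−pi)·F0].

    Where a denominator vanishes (no subjects on that side of c) the
    limiting value from the interior of the support is carried over.
    """
    pi = _check_pi(pi)
    c = pair.threshold_grid if thresholds is None else np.asarray(thresholds, float)
    if np.any(np.diff(c) < 0):
        raise ValueError("thresholds must be sorted ascending")
    f1, f0 = pair.cdf1(c), pair.cdf0(c)
    s1, s0 = pair.sf1(c), pair.sf0(c)
    ppv_den = pi * s1 + (1.0 - pi) * s0
    npv_den = pi * f1 + (1.0 - pi) * f0
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = pi * s1 / ppv_den
        npv = (1.0 - pi) * f0 / npv_den
    ppv = _fill_limit(ppv, ppv_den, from_left=True)
    npv = _fill_limit(npv, npv_den, from_left=False)
    return pd.DataFrame({"c": c, "tpr": s1, "fpr": s0, "ppv": ppv, "npv": npv})


def _fill_limit(values: np.ndarray, den: np.ndarray, from_left: bool) -> np.ndarray:
    values = np.asarray(values, float).copy()
    bad = ~(den > 0)
    if np.any(bad) and np.any(~bad):
        edge = np.max(np.nonzero(~bad)) if from_left else np.min(np.nonzero(~bad))
        values[bad] = values[edge]
    return values


# ---------------------------------------------------------------------------
# Delta(alpha) decomposition
# ---------------------------------------------------------------------------

@dataclass
class DeltaCurve:
    """Δ(alpha) with the AP weight, for one old/new model comparison."""

    alpha_grid: np.ndarray
    delta_values: np.ndarray
    weight_values: np.ndarray | None = None
    event_rate: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"alpha": self.alpha_grid, "delta": self.delta_values})
        if self.weight_values is not None:
            df["w_ap"] = self.weight_values
            df["w_ap_times_delta"] = self.weight_values * self.delta_values
        return df


def delta_alpha(old: ScoreDistributionPair, new: ScoreDistributionPair,
                alpha_grid: np.ndarray | None = None,
                pi: float | None = None) -> DeltaCurve:
    """Δ(alpha) = F_new,0(q_new,alpha) − F_old,0(q_old,alpha).

    Positive values mean the new score separates events from non-events
    better at the events' alpha-quantile.  Δ is conditional on outcome
    status, hence free of the event rate; pass ``pi`` to also tabulate the
    AP weight on the same grid.
    """
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    delta = new.cdf0(new.quantile1(grid)) - old.cdf0(old.quantile1(grid))
    weights = None
    if pi is not None:
        weights = ap_weight(old, new, grid, pi)
    return DeltaCurve(grid, np.asarray(delta), weights, pi)


def ap_weight(old: ScoreDistributionPair, new: ScoreDistributionPair,
              alpha, pi: float):
    """The weight w_AP(alpha) that turns ∫ w·Δ d alpha into ΔAP.

    w_AP(alpha) = [(pi⁻¹−1)/(1−alpha)] /
                  ({1+(pi⁻¹−1) S_new,0(q_new,alpha)/(1−alpha)}
                   {1+(pi⁻¹−1) S_old,0(q_old,alpha)/(1−alpha)})

    It increases with alpha, and for rare outcomes (small pi) it inflates
    the upper quantiles further while shrinking the lower ones.
    """
    pi = _check_pi(pi)
    alpha_arr = np.atleast_1d(np.asarray(alpha, dtype=float))
    k = 1.0 / pi - 1.0
    log1m = np.log1p(-alpha_arr)
    r_new = np.exp(new.log_sf0(new.quantile1(alpha_arr)) - log1m)
    r_old = np.exp(old.log_sf0(old.quantile1(alpha_arr)) - log1m)
    w = (k / (1.0 - alpha_arr)) / ((1.0 + k * r_new) * (1.0 + k * r_old))
    return w if np.ndim(alpha) else float(w[0])


def incv(old: ScoreDistributionPair, new: ScoreDistributionPair,
         pi: float, metric: str,
         alpha_grid: np.ndarray | None = None) -> float:
    """Incremental value Ψ_new − Ψ_old for Ψ ∈ {"AUC", "AP"}.

    The direct difference is returned; as a guard, the weighted-integral
    route ∫ w_Ψ(alpha) Δ(alpha) d alpha (with w_AUC ≡ 1) is evaluated on
    the alpha grid and the two must agree within 1e-4 — the identity is
    exact in the mathematics, so a larger gap flags a numerical defect.
    """
    pi = _check_pi(pi)
    metric = metric.upper()
    if metric not in {"AUC", "AP"}:
        raise ValueError(f"metric must be 'AUC' or 'AP', got {metric!r}")
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    if metric == "AUC":
        direct = auc(new) - auc(old)
        weighted = _alpha_integral(delta_alpha(old, new, grid).delta_values, grid)
    else:
        direct = ap(new, pi) - ap(old, pi)
        curve = delta_alpha(old, new, grid, pi=pi)
        weighted = _alpha_integral(curve.weight_values * curve.delta_values, grid)
    if abs(direct - weighted) > _INTERNAL_IDENTITY_TOL:
        raise InternalConsistencyError(
            f"direct Δ{metric} {direct:.6g} and weighted integral {weighted:.6g} "
            f"disagree beyond {_INTERNAL_IDENTITY_TOL}"
        )
    return direct


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------

@dataclass
class BrierComponents:
    """Brier score split into event / non-event mean squared prediction errors.

    BrS = mspe1·pi + mspe0·(1−pi) with
    mspe1 = E{[1−p(X)]² | D=1} and mspe0 = E{p(X)² | D=0};
    sBrS = 1 − BrS/[pi(1−pi)] rescales so the non-informative model p ≡ pi
    scores 0 and the perfect model scores 1.
    """

    mspe1: float
    mspe0: float
    event_rate: float
    brier: float = field(init=False)
    sbrs: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mspe1 < 0 or self.mspe0 < 0:
            raise ValueError("MSPE components must be nonnegative")
        pi = _check_pi(self.event_rate)
        self.brier = self.mspe1 * pi + self.mspe0 * (1.0 - pi)
        self.sbrs = 1.0 - self.brier / (pi * (1.0 - pi))


def sbrs_from_mspe(components: BrierComponents) -> float:
    """Scaled Brier score of a component decomposition (1 = perfect,
    0 = no better than assigning everyone the event rate)."""
    return components.sbrs


# ---------------------------------------------------------------------------
# Average NPV and net benefit
# ---------------------------------------------------------------------------

def average_npv(pair: ScoreDistributionPair, pi: float,
                alpha_grid: np.ndarray | None = None) -> float:
    """E[NPV(r0)] — NPV averaged over the non-event score distribution.

    The mirror image of AP: the area under the NPV-versus-specificity
    curve, emphasising accuracy in the low-risk region.
    """
    pi = _check_pi(pi)
    if isinstance(pair, EmpiricalPair):
        c = pair.nonevent_scores
        f1, f0 = pair.cdf1(c), pair.cdf0(c)
        den = pi * f1 + (1.0 - pi) * f0
        return float(np.mean((1.0 - pi) * f0 / den))  # den >= (1-pi)/n0 > 0
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    c = pair.quantile0(grid)
    f1 = pair.cdf1(c)
    # along the grid F0(q0_u) = u, so NPV = (1-pi) u / [pi F1 + (1-pi) u]
    npv = (1.0 - pi) * grid / (pi * f1 + (1.0 - pi) * grid)
    return _alpha_integral(npv, grid)


def net_benefit(tpr: float, fpr: float, pi: float, p_t: float) -> float:
    """Net benefit of treating above a risk threshold p_t:
    NB = pi·TPR − (1−pi)·FPR·p_t/(1−p_t)."""
    pi = _check_pi(pi)
    if not 0.0 <= p_t < 1.0:
        raise ValueError(f"treatment threshold p_t must lie in [0, 1), got {p_t}")
    for name, v in (("tpr", tpr), ("fpr", fpr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return pi * tpr - (1.0 - pi) * fpr * p_t / (1.0 - p_t)


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def write_curve_csv(curve: pd.DataFrame, path) -> None:
    """Write a TPR/FPR/PPV/NPV table as CSV."""
    curve.to_csv(path, index=False)


def write_delta_csv(curve: DeltaCurve, path) -> None:
    """Write an alpha/delta/w_ap/w_ap·delta table as CSV."""
    curve.to_frame().to_csv(path, index=False)
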