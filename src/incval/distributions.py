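"""Conditional risk-score distributions for events and non-events.

Every rank-based accuracy measure of a risk score r(X) is a functional of
the pair of conditional CDFs ``F1(c) = Pr(r <= c | D=1)`` (events) and
``F0(c) = Pr(r <= c | D=0)`` (non-events).  This module provides that pair
in three representations:

* closed form — both conditionals are scipy frozen distributions (the
  binormal model, where events and non-events are each Gaussian);
* grid — tabulated CDF values on an ascending threshold grid with
  piecewise-linear interpolation (the output of the population engine);
* empirical — step ECDFs built from an observed sample.

A note on the binormal convention: ``BinormalSpec(mu1, sd1, mu0, sd0)``
reads the second parameter of each component as a **standard deviation**,
not a variance.  The two conventions give materially different (even
opposite-signed) AUC orderings for scores whose event distributions differ
in spread, so the choice is stated prominently here and in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


class InvalidSpecificationError(ValueError):
    """A distribution specification violates its constraints."""


class DegenerateDistributionError(ValueError):
    """The event-score distribution has no spread, so quantiles collapse."""


@dataclass(frozen=True)
class BinormalSpec:
    """Binormal risk score: r | D=1 ~ N(mu1, sd1^2), r | D=0 ~ N(mu0, sd0^2).

    ``sd1`` and ``sd0`` are standard deviations and must be positive.
    """

    mu1: float
    sd1: float
    mu0: float = 0.0
    sd0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sd1 > 0 and self.sd0 > 0):
            raise InvalidSpecificationError(
                f"standard deviations must be positive, got sd1={self.sd1}, sd0={self.sd0}"
            )


def _check_alpha(alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0.0) or np.any(alpha >= 1.0):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    return alpha


class ScoreDistributionPair:
    """Abstract pair (F1, F0) of conditional risk-score CDFs.

    Subclasses implement ``cdf1``, ``cdf0``, their survival counterparts,
    and the event-score quantile function ``quantile1``.  All methods are
    vectorised over their arguments.
    """

    representation: str = "abstract"

    # -- CDFs -----------------------------------------------------------
    def cdf1(self, c):
        raise NotImplementedError

    def cdf0(self, c):
        raise NotImplementedError

    def sf1(self, c):
        return 1.0 - self.cdf1(c)

    def sf0(self, c):
        return 1.0 - self.cdf0(c)

    def log_sf1(self, c):
        with np.errstate(divide="ignore"):
            return np.log(self.sf1(c))

    def log_sf0(self, c):
        with np.errstate(divide="ignore"):
            return np.log(self.sf0(c))

    # -- quantiles ------------------------------------------------------
    def quantile1(self, alpha):
        """q_alpha = F1^{-1}(alpha), the alpha-quantile of event scores."""
        raise NotImplementedError

    def quantile0(self, alpha):
        """F0^{-1}(alpha), the alpha-quantile of non-event scores."""
        raise NotImplementedError

    @property
    def threshold_grid(self) -> np.ndarray:
        """Ascending thresholds covering the effective support of both CDFs."""
        raise NotImplementedError


class ClosedFormPair(ScoreDistributionPair):
    """Pair backed by two scipy frozen continuous distributions."""

    representation = "closed-form"

    def __init__(self, dist1, dist0, n_grid: int = 10_001):
        self.dist1 = dist1
        self.dist0 = dist0
        self._n_grid = n_grid

    def cdf1(self, c):
        return self.dist1.cdf(c)

    def cdf0(self, c):
        return self.dist0.cdf(c)

    def sf1(self, c):
        return self.dist1.sf(c)

    def sf0(self, c):
        return self.dist0.sf(c)

    def log_sf1(self, c):
        return self.dist1.logsf(c)

    def log_sf0(self, c):
        return self.dist0.logsf(c)

    def quantile1(self, alpha):
        return self.dist1.ppf(_check_alpha(alpha))

    def quantile0(self, alpha):
        return self.dist0.ppf(_check_alpha(alpha))

    @property
    def threshold_grid(self) -> np.ndarray:
        # span mu +/- 8 sd of the wider component
        m1, s1 = self.dist1.mean(), self.dist1.std()
        m0, s0 = self.dist0.mean(), self.dist0.std()
        lo = min(m1 - 8 * s1, m0 - 8 * s0)
        hi = max(m1 + 8 * s1, m0 + 8 * s0)
        return np.linspace(lo, hi, self._n_grid)

    def to_grid(self, n_grid: int | None = None) -> "GridPair":
        """Tabulate this pair on its default threshold grid."""
        c = self.threshold_grid if n_grid is None else np.linspace(
            self.threshold_grid[0], self.threshold_grid[-1], n_grid
        )
        return GridPair(c, self.cdf1(c), self.cdf0(c),
                        sf1_values=self.sf1(c), sf0_values=self.sf0(c))


def _interp_monotone(x, xp, fp):
    """np.interp with clamping; xp must be nondecreasing."""
    return np.interp(x, xp, fp)


def _invert_cdf(alpha, values, thresholds, sf_values=None):
    """Piecewise-linear inverse of a tabulated CDF.

    For alpha in the upper tail the inversion runs through the survival
    table when available, which keeps precision where ``1 - cdf`` would
    cancel catastrophically.
    """
    alpha = np.atleast_1d(_check_alpha(alpha))
    out = np.interp(alpha, values, thresholds)
    if sf_values is not None:
        hi = alpha > 0.5
        if np.any(hi):
            # survival decreases with c: interpolate on the reversed axis
            out[hi] = np.interp(1.0 - alpha[hi], sf_values[::-1], thresholds[::-1])
    return out if out.shape else float(out)


class GridPair(ScoreDistributionPair):
    """Pair tabulated on an ascending threshold grid.

    CDF values are interpolated piecewise-linearly between thresholds and
    clamped to {0, 1} outside the grid.  Optional survival tables carry the
    upper tail at full relative precision (the plain ``1 - cdf`` difference
    loses all digits once the CDF is within 1e-16 of one); when given they
    are used for tail evaluation and for upper-tail quantile inversion.
    """

    representation = "grid"

    def __init__(self, thresholds, f1_values, f0_values,
                 sf1_values=None, sf0_values=None):
        thresholds = np.asarray(thresholds, dtype=float)
        f1_values = np.asarray(f1_values, dtype=float)
        f0_values = np.asarray(f0_values, dtype=float)
        if thresholds.ndim != 1 or np.any(np.diff(thresholds) <= 0):
            raise InvalidSpecificationError("thresholds must be strictly ascending")
        for name, v in (("f1_values", f1_values), ("f0_values", f0_values)):
            if v.shape != thresholds.shape:
                raise InvalidSpecificationError(f"{name} must match the threshold grid")
            if np.any(np.diff(v) < -1e-12) or v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise InvalidSpecificationError(f"{name} is not a valid CDF table")
        self.thresholds = thresholds
        self.f1_values = np.clip(f1_values, 0.0, 1.0)
        self.f0_values = np.clip(f0_values, 0.0, 1.0)
        self.sf1_values = None if sf1_values is None else np.asarray(sf1_values, float)
        self.sf0_values = None if sf0_values is None else np.asarray(sf0_values, float)
        if self.f1_values[-1] - self.f1_values[0] <= 0:
            raise DegenerateDistributionError("F1 carries no mass on the grid")

    def cdf1(self, c):
        return _interp_monotone(c, self.thresholds, self.f1_values)

    def cdf0(self, c):
        return _interp_monotone(c, self.thresholds, self.f0_values)

    def _sf(self, c, cdf_values, sf_values):
        if sf_values is None:
            return 1.0 - _interp_monotone(c, self.thresholds, cdf_values)
        # survival tables decrease; interpolate on log scale where positive
        s = np.interp(c, self.thresholds, sf_values)
        return np.clip(s, 0.0, 1.0)

    def sf1(self, c):
        return self._sf(c, self.f1_values, self.sf1_values)

    def sf0(self, c):
        return self._sf(c, self.f0_values, self.sf0_values)

    def quantile1(self, alpha):
        return _invert_cdf(alpha, self.f1_values, self.thresholds, self.sf1_values)

    def quantile0(self, alpha):
        return _invert_cdf(alpha, self.f0_values, self.thresholds, self.sf0_values)

    @property
    def threshold_grid(self) -> np.ndarray:
        return self.thresholds

    def transform_thresholds(self, func) -> "GridPair":
        """Apply a strictly increasing map to the threshold axis.

        Rank-based functionals (AUC, AP, F0 at F1-quantiles) are invariant
        under such maps; this helper exists so tests can assert it.
        """
        new_t = np.asarray(func(self.thresholds), dtype=float)
        if np.any(np.diff(new_t) <= 0):
            raise InvalidSpecificationError("transform must be strictly increasing")
        return GridPair(new_t, self.f1_values, self.f0_values,
                        self.sf1_values, self.sf0_values)


class EmpiricalPair(ScoreDistributionPair):
    """Step ECDF pair built from observed event and non-event scores."""

    representation = "empirical"

    def __init__(self, event_scores, nonevent_scores):
        e = np.sort(np.asarray(event_scores, dtype=float))
        ne = np.sort(np.asarray(nonevent_scores, dtype=float))
        if e.size < 1 or ne.size < 1:
            raise InvalidSpecificationError("need at least one event and one non-event")
        self.event_scores = e
        self.nonevent_scores = ne

    def cdf1(self, c):
        return np.searchsorted(self.event_scores, c, side="right") / self.event_scores.size

    def cdf0(self, c):
        return np.searchsorted(self.nonevent_scores, c, side="right") / self.nonevent_scores.size

    def quantile1(self, alpha):
        """Left-continuous ECDF inverse: inf{c : F1_hat(c) >= alpha}."""
        alpha = np.atleast_1d(_check_alpha(alpha))
        n = self.event_scores.size
        idx = np.ceil(alpha * n).astype(int) - 1
        out = self.event_scores[np.clip(idx, 0, n - 1)]
        return out if out.shape else float(out)

    def quantile0(self, alpha):
        alpha = np.atleast_1d(_check_alpha(alpha))
        n = self.nonevent_scores.size
        idx = np.ceil(alpha * n).astype(int) - 1
        out = self.nonevent_scores[np.clip(idx, 0, n - 1)]
        return out if out.shape else float(out)

    @property
    def threshold_grid(self) -> np.ndarray:
        return np.unique(np.concatenate([self.event_scores, self.nonevent_scores]))


def make_binormal_pair(spec: BinormalSpec, n_grid: int = 10_001) -> ClosedFormPair:
    """Closed-form pair with normal conditionals from a :class:`BinormalSpec`."""
    return ClosedFormPair(norm(spec.mu1, spec.sd1), norm(spec.mu0, spec.sd0), n_grid)


def binormal_auc(spec: BinormalSpec) -> float:
    """Closed-form binormal AUC, Phi((mu1-mu0)/sqrt(sd1^2+sd0^2))."""
    return float(norm.cdf((spec.mu1 - spec.mu0) / np.hypot(spec.sd1, spec.sd0)))


def f0_at_f1_quantile(pair: ScoreDistributionPair, alpha) -> float | np.ndarray:
    """F0(q_alpha): the share of non-events scoring below the events'
    alpha-quantile.  Larger values mean better separation at that quantile."""
    out = np.asarray(pair.cdf0(pair.quantile1(alpha)))
    return float(out.reshape(())) if np.ndim(alpha) == 0 else out


# Hypothetical risk scores used throughout the docs and tests: all share
# standard-normal non-events; the event distributions differ in location
# and spread so that r3 dominates while r1 and r2 trade places between
# AUC and AP.
R1 = BinormalSpec(1.8, 2.0)
R2 = BinormalSpec(1.5, 1.5)
R3 = BinormalSpec(3.0, 1.5)
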