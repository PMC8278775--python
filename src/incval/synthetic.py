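"""Seeded generators matching the statistical structure of the models.

Two mechanisms are provided: binormal risk scores (Gaussian score
conditional on outcome, outcome Bernoulli at the event rate) and the
probit true model with interaction, where markers are drawn first and the
outcome follows Bernoulli(pi(X, Y)).  The samples exercise every
estimator in :mod:`incval.empirical` and serve as a Monte-Carlo oracle
for the deterministic population engine.

Randomness flows from a single master seed through
``numpy.random.default_rng``; identical seeds give identical samples.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from ._probit import ProbitFitError, weighted_probit_mle
from .distributions import BinormalSpec
from .empirical import Sample
from .population import TrueModelSpec, WorkingModelSpec


def sample_true_model(spec: TrueModelSpec, n: int, seed: int) -> Sample:
    """Draw n records from the probit true model.

    X, Y iid standard normal, D ~ Bernoulli(Phi(b0 + b1 X + b2 Y + b3 XY)).
    The ``risk`` column carries the true conditional risk pi(X, Y) and the
    ``score`` column its probit linear predictor (a monotone transform).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    eta = spec.beta0 + spec.beta1 * x + spec.beta2 * y + spec.beta3 * x * y
    risk = norm.cdf(eta)
    d = (rng.random(n) < risk).astype(np.int8)
    return Sample(d=d, score=eta, risk=risk, x=x, y=y)


def sample_binormal(spec: BinormalSpec, pi: float, n: int, seed: int) -> Sample:
    """Draw n records with D ~ Bernoulli(pi) and a Gaussian score within
    each outcome class per the binormal spec."""
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must lie in (0, 1), got {pi}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    d = (rng.random(n) < pi).astype(np.int8)
    z = rng.standard_normal(n)
    score = np.where(d == 1, spec.mu1 + spec.sd1 * z, spec.mu0 + spec.sd0 * z)
    return Sample(d=d, score=score)


def fit_probit(sample: Sample, markers) -> WorkingModelSpec:
    """Maximum-likelihood probit fit of the outcome on the given markers.

    Newton (Fisher-scoring) iterations to gradient norm <= 1e-8; the
    large-n fits are the sampling oracle for
    :func:`incval.population.population_coefficients`.
    """
    markers = tuple(m.lower() for m in markers)
    cols = []
    for m in markers:
        v = getattr(sample, m, None)
        if v is None:
            raise ValueError(f"sample has no marker column {m!r}")
        cols.append(v)
    if sample.n_events == 0 or sample.n_events == sample.n:
        raise ProbitFitError("probit fit needs both outcome classes present")
    Z = np.column_stack([np.ones(sample.n)] + cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ProbitFitError("design matrix is rank deficient")
    w = np.full(sample.n, 1.0 / sample.n)
    gamma, _, _ = weighted_probit_mle(Z, sample.d.astype(float), w)
    return WorkingModelSpec(markers=markers, gamma=tuple(gamma),
                            provenance="sample-estimate")
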