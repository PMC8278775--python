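"""Nonparametric estimators of AUC, AP and the (scaled) Brier score.

Estimators operate on a :class:`Sample` of individual records with a
binary outcome ``d``, a real-valued risk ``score`` used for the
rank-based measures, and (optionally) a predicted ``risk`` probability
used for the Brier score.

AUC is the Mann-Whitney proportion of event/non-event pairs where the
event outranks the non-event.  AP is the average, over events, of the
empirical precision at each event's own score.  Two comparison
conventions are supported for AP:

* ``"geq"`` (default): numerator and denominator count scores >= the
  event's score, so each event counts its own record, every term is
  well defined (denominator >= 1), and ties are handled gracefully;
* ``"strict"``: the literal strictly-greater counts; the top-ranked
  event then produces a 0/0 term, which is dropped.

Both conventions converge to the population AP for continuous scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import EmpiricalPair
from .metrics import BrierComponents


class UndefinedMetricError(ValueError):
    """The sample cannot support the requested estimator."""


@dataclass
class Sample:
    """Individual-level records for the empirical estimators."""

    d: np.ndarray
    score: np.ndarray
    risk: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        if not np.isin(self.d, (0, 1)).all():
            raise ValueError("outcome d must contain only 0/1 values")
        self.d = self.d.astype(np.int8)
        self.score = np.asarray(self.score, dtype=float)
        n = self.d.size
        if n < 2:
            raise ValueError("a sample needs at least two records")
        for name in ("score", "risk", "x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} must have the same length as d")
                setattr(self, name, v)
        if self.risk is not None and (np.any(self.risk < 0) or np.any(self.risk > 1)):
            raise ValueError("risk values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.d.size

    @property
    def n_events(self) -> int:
        return int(self.d.sum())

    @property
    def event_rate(self) -> float:
        return float(self.d.mean())

    def to_frame(self) -> pd.DataFrame:
        out = {"id": self.id if self.id is not None else np.arange(self.n),
               "d": self.d, "score": self.score}
        for name in ("risk", "x", "y"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return pd.DataFrame(out)


def read_sample_csv(path) -> Sample:
    """Read a sample from CSV with required columns {id, d, score} and
    optional {risk, x, y}; d must be coded strictly as 0/1."""
    df = pd.read_csv(path)
    missing = {"id", "d", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV is missing columns: {sorted(missing)}")
    d_raw = df["d"].to_numpy()
    if not np.isin(d_raw, (0, 1)).all():
        raise ValueError("column d must contain only 0/1")
    kwargs = {}
    for name in ("risk", "x", "y"):
        if name in df.columns:
            kwargs[name] = df[name].to_numpy(dtype=float)
    return Sample(d=d_raw, score=df["score"].to_numpy(dtype=float),
                  id=df["id"].to_numpy(), **kwargs)


def write_sample_csv(sample: Sample, path) -> None:
    sample.to_frame().to_csv(path, index=False)


def _split_scores(sample: Sample) -> tuple[np.ndarray, np.ndarray]:
    ev = sample.score[sample.d == 1]
    ne = sample.score[sample.d == 0]
    if ev.size == 0 or ne.size == 0:
        raise UndefinedMetricError(
            "rank metrics need at least one event and one non-event")
    return ev, ne


def estimate_auc(sample: Sample, ties: str = "strict") -> float:
    """Mann-Whitney AUC estimate in O(n log n).

    ``ties="strict"`` counts tied pairs as 0 (the plain indicator
    I(r_i > r_j)); ``ties="midrank"`` counts them as 1/2.  Equality with
    the O(n^2) brute force is exact in either mode.
    """
    if ties not in {"strict", "midrank"}:
        raise ValueError("ties must be 'strict' or 'midrank'")
    ev, ne = _split_scores(sample)
    ne_sorted = np.sort(ne)
    below = np.searchsorted(ne_sorted, ev, side="left")  # non-events < r_i
    if ties == "strict":
        wins = below.sum()
    else:
        upto = np.searchsorted(ne_sorted, ev, side="right")
        wins = below.sum() + 0.5 * (upto - below).sum()
    return float(wins / (ev.size * ne.size))


def estimate_ap(sample: Sample, convention: str = "geq") -> float:
    """Average precision: mean over events of the precision at the
    event's own score (see the module docstring for the two comparison
    conventions)."""
    if convention not in {"geq", "strict"}:
        raise ValueError("convention must be 'geq' or 'strict'")
    ev = sample.score[sample.d == 1]
    if ev.size == 0:
        raise UndefinedMetricError("AP needs at least one event")
    all_sorted = np.sort(sample.score)
    ev_sorted = np.sort(ev)
    n = sample.n
    if convention == "geq":
        num = ev.size - np.searchsorted(ev_sorted, ev, side="left")
        den = n - np.searchsorted(all_sorted, ev, side="left")
        return float(np.mean(num / den))
    num = ev.size - np.searchsorted(ev_sorted, ev, side="right")
    den = n - np.searchsorted(all_sorted, ev, side="right")
    keep = den > 0
    if not np.any(keep):
        raise UndefinedMetricError(
            "strict AP is undefined: every event term is 0/0")
    return float(np.mean(num[keep] / den[keep]))


def estimate_brier_sbrs(sample: Sample) -> BrierComponents:
    """Brier score BrS = n⁻¹ Σ (D_i − p_i)², its event/non-event MSPE
    split, and the scaled Brier score 1 − BrS/[pi_hat(1−pi_hat)]."""
    if sample.risk is None:
        raise UndefinedMetricError("Brier estimators need the risk column")
    pi_hat = sample.event_rate
    if pi_hat in (0.0, 1.0):
        raise UndefinedMetricError(
            "scaled Brier score is undefined when the sample has a single class")
    sq = (sample.d - sample.risk) ** 2
    mspe1 = float(sq[sample.d == 1].mean())
    mspe0 = float(sq[sample.d == 0].mean())
    return BrierComponents(mspe1=mspe1, mspe0=mspe0, event_rate=pi_hat)


def empirical_pair(sample: Sample) -> EmpiricalPair:
    """Step-ECDF score-distribution pair from a sample.

    Feeding the result to :func:`incval.metrics.auc` reproduces
    :func:`estimate_auc` exactly on tie-free data, and the empirical
    Δ(alpha)/w_AP(alpha) display is obtained by passing two such pairs to
    :func:`incval.metrics.delta_alpha`.
    """
    ev, ne = _split_scores(sample)
    if ev.size < 2 or ne.size < 2:
        raise UndefinedMetricError(
            "an empirical pair needs at least two events and two non-events")
    return EmpiricalPair(ev, ne)
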