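"""Censored-survival machinery: Cox loss, concordance, Kaplan–Meier,
log-rank, and tercile risk stratification.

Conventions used throughout the package: observed time ``T = min(Ts, Tc)`` in
days with ``T > 0``, and event indicator ``delta = 1`` iff the event (death)
was observed, ``delta = 0`` for right censoring. Hazard scores are oriented so
that larger score = larger hazard = shorter expected survival.

The training loss is the negative Cox partial log-likelihood with Breslow tie
handling, averaged over events — it needs no baseline-hazard model and is
invariant to adding a constant to all scores. A batch with no events has no
admissible comparisons and raises (the failure mode seen in practice on
heavily censored cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.special import logsumexp
from scipy.stats import norm

from .matrix import InvalidInputError, OmisurvError

__all__ = [
    "SurvivalData",
    "KMCurve",
    "RiskStrata",
    "NonAdmissibleError",
    "cox_loss",
    "cox_loss_grad",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "tercile_stratify",
]


class NonAdmissibleError(OmisurvError, ValueError):
    """No admissible comparisons exist (e.g. a batch with all delta = 0)."""


@dataclass
class SurvivalData:
    """Per-sample survival records: observed times and event indicators."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise InvalidInputError("time and event must be 1-d and aligned")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise InvalidInputError("times must be finite and positive")
        if not np.isin(self.event, [0, 1]).all():
            raise InvalidInputError("event indicator must be 0 or 1")
        self.event = self.event.astype(np.int64)
        if self.sample_ids is not None and len(self.sample_ids) != len(self.time):
            raise InvalidInputError("sample_ids must align with records")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray | Sequence[int]) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(
            self.time[idx],
            self.event[idx],
            None
            if self.sample_ids is None
            else [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


def _as_scores(scores: np.ndarray, n: int) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if scores.shape != (n,):
        raise InvalidInputError(f"expected {n} scores, got shape {scores.shape}")
    return scores


def cox_loss(scores: np.ndarray, data: SurvivalData) -> float:
    """Negative Cox partial log-likelihood (Breslow ties), averaged over events.

    For each event i, the contribution is ``-(s_i - log sum_{j: t_j >= t_i}
    exp(s_j))``; tied event times share the same risk set. Raises
    :class:`NonAdmissibleError` when no event is present.
    """
    return _cox(scores, data, want_grad=False)[0]


def cox_loss_grad(
    scores: np.ndarray, data: SurvivalData
) -> tuple[float, np.ndarray]:
    """Cox loss and its gradient with respect to the scores."""
    return _cox(scores, data, want_grad=True)


def _cox(scores, data: SurvivalData, want_grad: bool):
    s = _as_scores(scores, len(data))
    events = np.flatnonzero(data.event == 1)
    if events.size == 0:
        raise NonAdmissibleError(
            "non-admissible batch: all records are censored (delta = 0)"
        )
    # at_risk[i, j] = 1 iff j is in the risk set of event i (t_j >= t_i)
    t_event = data.time[events]
    at_risk = data.time[None, :] >= t_event[:, None]
    lse = np.array(
        [logsumexp(s[row]) for row in at_risk]
    )  # per-event log partition
    d = events.size
    loss = float(np.sum(lse - s[events]) / d)
    if not want_grad:
        return loss, None
    grad = np.zeros_like(s)
    np.add.at(grad, events, -1.0)
    for i, row in enumerate(at_risk):
        p = np.exp(s[row] - lse[i])
        grad[row] += p
    return loss, grad / d


def concordance_index(scores: np.ndarray, data: SurvivalData) -> float:
    """Harrell's concordance index.

    A pair (i, j) is admissible iff the strictly earlier time belongs to an
    observed event; pairs tied on time are excluded. Among admissible pairs
    the shorter-surviving member should carry the strictly higher hazard
    score; score ties count 1/2. Raises :class:`NonAdmissibleError` if no
    admissible pair exists.
    """
    s = _as_scores(scores, len(data))
    t, e = data.time, data.event
    # admissible[i, j]: t_i < t_j and event at i
    adm = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_adm = int(adm.sum())
    if n_adm == 0:
        raise NonAdmissibleError("no admissible pairs (check event indicators)")
    diff = s[:, None] - s[None, :]
    concordant = float(((diff > 0) & adm).sum())
    tied = float(((diff == 0) & adm).sum())
    return (concordant + 0.5 * tied) / n_adm


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood 95% intervals."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "at_risk": self.at_risk,
            }
        )


def km_estimate(data: SurvivalData, confidence: float = 0.95) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    The curve is tabulated at the distinct observed event times. Confidence
    bounds use the Greenwood variance on the log-survival scale,
    ``log S +/- z * sqrt(sum d / (n (n - d)))``, exponentiated and clipped to
    [0, 1]; once S reaches 0 the bounds collapse to 0.
    """
    if len(data) == 0:
        raise InvalidInputError("km_estimate requires non-empty records")
    order = np.argsort(data.time, kind="stable")
    t, e = data.time[order], data.event[order]
    n = len(t)
    event_times = np.unique(t[e == 1])
    surv, lo, hi, at_risk = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    z = norm.ppf(0.5 + confidence / 2.0)
    for tau in event_times:
        n_at = int((t >= tau).sum())
        d = int(((t == tau) & (e == 1)).sum())
        s *= (n_at - d) / n_at
        at_risk.append(n_at)
        surv.append(s)
        if s > 0:
            gw += d / (n_at * (n_at - d))
            se = np.sqrt(gw)
            lo.append(min(1.0, max(0.0, s * np.exp(-z * se))))
            hi.append(min(1.0, s * np.exp(z * se)))
        else:
            lo.append(0.0)
            hi.append(0.0)
    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        ci_low=np.asarray(lo),
        ci_high=np.asarray(hi),
        at_risk=np.asarray(at_risk, dtype=np.int64),
    )


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square statistic, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise InvalidInputError("both groups must be non-empty")
    if group_a.n_events + group_b.n_events == 0:
        raise NonAdmissibleError("log-rank statistic undefined: no events")
    res = _ll_logrank(
        group_a.time, group_b.time, group_a.event, group_b.event
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        raise NonAdmissibleError("log-rank statistic undefined for these groups")
    return stat, p


def plot_km(curves: dict[str, KMCurve], path: str, title: str = "") -> None:
    """Write stepped Kaplan–Meier curves with shaded 95% bands to an image
    file. Requires matplotlib (the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, km in curves.items():
        t = np.concatenate([[0.0], km.event_times])
        s = np.concatenate([[1.0], km.survival])
        ax.step(t, s, where="post", label=label)
        ax.fill_between(
            km.event_times, km.ci_low, km.ci_high, step="post", alpha=0.2
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class RiskStrata:
    """Tercile risk labels with the hazard-score cut points."""

    labels: np.ndarray  # 'low' / 'intermediate' / 'high' per sample
    cut_low: float
    cut_high: float

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


def tercile_stratify(scores: np.ndarray) -> RiskStrata:
    """Stratify hazard scores at the 33rd and 66th percentiles.

    Percentiles use linear interpolation between order statistics. A sample is
    'low' iff its score <= the 33rd percentile, 'intermediate' iff it lies in
    (33rd, 66th], and 'high' otherwise, so ties at a cut resolve downward
    deterministically.
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if scores.size < 3:
        raise InvalidInputError("tercile stratification needs at least 3 samples")
    cut_low, cut_high = np.percentile(scores, [33.0, 66.0])
    labels = np.where(
        scores <= cut_low,
        "low",
        np.where(scores <= cut_high, "intermediate", "high"),
    ).astype(object)
    return RiskStrata(labels=labels, cut_low=float(cut_low), cut_high=float(cut_high))
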