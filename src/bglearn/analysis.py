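"""Outcome statistics: ex-Gaussian reaction times and learning-history metrics.

Reaction-time distributions are summarized with the exponentially modified
Gaussian (ex-Gaussian): the convolution of a normal component (mu, sigma)
with an exponential component of mean tau.  The tau parameter captures the
slow-response tail, the signature that separates the dopamine-imbalance
phenotype from controls.

The learning history of a subject is the per-epoch vector of outcome codes
(+1 large reward, +0.1 small reward, -1 punishment, 0 no response), each
attributed to the epoch's target action channel.  Its per-channel cumulative
sums quantify how evenly the four associations were reinforced; the
weighted-std statistic condenses them into a single number: the epoch-wise
across-channel standard deviation, weighted by the preponderance of negative
over positive cumulative outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExGaussParams",
    "HistoryMetrics",
    "fit_exgaussian",
    "cumulative_history",
    "weighted_std_history",
    "group_regression",
    "classify_subgroups",
]


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian parameters, all in the unit of the fitted sample (ms)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


@dataclass
class HistoryMetrics:
    """Per-channel cumulative history and the derived imbalance statistic."""

    cumsum: np.ndarray        # (4, n_epochs)
    ratio: float
    std_history: float
    weighted_std: float


def fit_exgaussian(rts: Sequence[float], min_n: int = 20) -> ExGaussParams:
    """Maximum-likelihood ex-Gaussian fit to reaction times (ms).

    Uses moment-based initialization (skewness splits the variance between
    the Gaussian and exponential parts) and scipy's exponnorm MLE.  Censored
    (non-finite) values must be removed by the caller.
    """
    x = np.asarray(rts, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} finite RTs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (zero-variance) sample")

    m, s = x.mean(), x.std(ddof=1)
    g1 = float(stats.skew(x))
    # moment estimator: tau^3 = skew * s^3 / 2, floored away from zero
    tau0 = max(s * (max(g1, 0.05) / 2.0) ** (1.0 / 3.0), 1e-3 * s)
    sigma0 = np.sqrt(max(s ** 2 - tau0 ** 2, (0.1 * s) ** 2))
    K0 = tau0 / sigma0
    K, loc, scale = stats.exponnorm.fit(x, K0, loc=m - tau0, scale=sigma0)
    if K <= 0 or scale <= 0:  # pragma: no cover - scipy guards
        raise RuntimeError("ex-Gaussian fit failed to converge")
    return ExGaussParams(mu=float(loc), sigma=float(scale),
                         tau=float(K * scale))


def cumulative_history(history: Sequence[float],
                       channels: Sequence[int]) -> np.ndarray:
    """Per-channel running sums of the outcome codes.

    ``channels[i]`` is the action channel to which epoch ``i``'s outcome is
    attributed (the target channel of the stimulus presented).  Returns a
    (4, n_epochs) matrix: each column is the cumulative sum per channel
    after that epoch.
    """
    h = np.asarray(history, dtype=float)
    ch = np.asarray(channels, dtype=int)
    if h.shape != ch.shape:
        raise ValueError("history and channels must have the same length")
    if not np.isin(np.round(np.abs(h), 4), [0.0, 0.1, 1.0]).all():
        raise ValueError("history codes must be in {+1, +0.1, -1, 0}")
    inc = np.zeros((4, h.size))
    inc[ch, np.arange(h.size)] = h
    return np.cumsum(inc, axis=1)


def weighted_std_history(cumsum: np.ndarray,
                         ratio_mode: Literal["count", "sum"] = "count",
                         scale: float = 1000.0) -> HistoryMetrics:
    """History-variability statistic from the per-channel cumulative sums.

    ``std_history`` is the mean (scaled by 1/``scale``) over epochs of the
    across-channel root-sum-of-squares deviation from the epoch mean.  The
    weighting ``ratio`` compares negative to positive cumulative outcomes;
    with ``ratio_mode='count'`` it is the count of (epoch, channel) cells
    with negative cumulative sum over the count of positive cells (the
    1/``scale`` factor on the numerator as in the displayed definition);
    with ``'sum'`` it is |sum of negative cells| / sum of positive cells.
    Both variants grow when failures dominate; the count form is the
    default.

    Raises ``ValueError`` when no cell is positive (ratio undefined: the
    subject never accumulated net reward on any channel — inspect the raw
    history instead).
    """
    cs = np.asarray(cumsum, dtype=float)
    if cs.ndim != 2 or cs.shape[0] != 4:
        raise ValueError("cumsum must be (4, n_epochs)")
    n = cs.shape[1]

    pos = cs > 0
    neg = cs < 0
    if not pos.any():
        raise ValueError("no positive cumulative-history cells; "
                         "ratio undefined for this subject")
    if ratio_mode == "count":
        ratio = (neg.sum() / scale) / pos.sum()
    elif ratio_mode == "sum":
        ratio = float(-cs[neg].sum()) / float(cs[pos].sum())
    else:
        raise ValueError("ratio_mode must be 'count' or 'sum'")

    mean_i = cs.mean(axis=0)
    std_hist = float(np.sqrt(((cs - mean_i) ** 2).sum(axis=0)).sum() / scale)
    return HistoryMetrics(cumsum=cs, ratio=float(ratio),
                          std_history=std_hist,
                          weighted_std=float(ratio) * std_hist)


def group_regression(x: Sequence[float], y: Sequence[float],
                     model: Literal["linear", "quadratic"] = "linear",
                     ) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit; returns (coefficients, R²).

    Coefficients are in numpy ``polyfit`` order (highest degree first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    deg = {"linear": 1, "quadratic": 2}[model]
    if x.size < deg + 2:
        raise ValueError(f"need at least {deg + 2} points for {model} fit")
    coef = np.polyfit(x, y, deg)
    yhat = np.polyval(coef, x)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return coef, 1.0
    return coef, 1.0 - ss_res / ss_tot


def classify_subgroups(pct_success: Sequence[float],
                       exg: Sequence[Optional[ExGaussParams]],
                       perfect_threshold: float = 99.0,
                       tail_dominance: float = 2.0) -> list[str]:
    """Assign dopamine-imbalance subjects to severity subgroups a/b/c.

    * ``a`` — (near-)perfect accuracy, control-like.
    * ``b`` — impaired accuracy with an exponential-tail-dominated RT
      distribution (tau > ``tail_dominance``·sigma): a mixture of fast and
      very slow responses.
    * ``c`` — impaired accuracy without tail dominance (slow, broadly
      Gaussian responses); the most severe, learning-deficit profile.

    Thresholds are configuration, not ground truth; they are recorded in
    the returned labels' docstring contract rather than inferred from data.
    """
    labels = []
    for p, e in zip(pct_success, exg):
        if p >= perfect_threshold:
            labels.append("a")
        elif e is not None and e.tau > tail_dominance * e.sigma:
            labels.append("b")
        else:
            labels.append("c")
    return labels
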