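"""Dopamine-gated Hebbian plasticity on the cortico-striatal weight matrices.

Four matrices are plastic: ``wGS`` and ``wNS`` (stimulus → Go / NoGo, full
4×4) and ``wGC`` and ``wNC`` (cortex → Go / NoGo, diagonal).  All start in a
naive state with every trainable entry at 0.5.  After each trial in which an
action was selected, the Hebb rule

    dw_ij = phi * [y_pre_j - theta_pre]^+ * (y_post_i - theta_post)

is applied once, using activities averaged over the prediction-error
signalling window (0.1 s latency, 0.05 s duration after the response).  The
presynaptic positive-part gate means silent inputs never drive learning; the
postsynaptic factor is signed, so weakly active striatal units lose weight.
The gain ``phi = 0.0013 * |RPE| * DA_ratio`` couples learning speed to the
subject's phasic/tonic dopamine ratio: the imbalance group learns with a
~2.8× larger gain, which amplifies early random asymmetries in experience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PlasticWeights",
    "LearningParams",
    "assign_outcome",
    "gain_phi",
    "hebb_update",
    "apply_learning_event",
]

PHI_COEFF = 0.0013  # base Hebbian gain coefficient


@dataclass
class PlasticWeights:
    """The four trainable cortico-striatal weight matrices.

    ``wGS``/``wNS`` are full 4×4 (rows: striatal channel, columns: stimulus
    channel); ``wGC``/``wNC`` are diagonal and stay diagonal under training.
    Entries are clipped to [0, 1].
    """

    wGS: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.5))
    wNS: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.5))
    wGC: np.ndarray = field(default_factory=lambda: np.diag(np.full(4, 0.5)))
    wNC: np.ndarray = field(default_factory=lambda: np.diag(np.full(4, 0.5)))

    def __post_init__(self) -> None:
        for name in ("wGS", "wNS", "wGC", "wNC"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4, got {m.shape}")
            setattr(self, name, m)
        for name in ("wGC", "wNC"):
            m = getattr(self, name)
            if np.any(m[~np.eye(4, dtype=bool)] != 0):
                raise ValueError(f"{name} must be diagonal")

    @classmethod
    def naive(cls) -> "PlasticWeights":
        """Naive state: all trainable entries at 0.5."""
        return cls()

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(self.wGS.copy(), self.wNS.copy(),
                              self.wGC.copy(), self.wNC.copy())

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"wGS": self.wGS, "wNS": self.wNS,
                "wGC": self.wGC, "wNC": self.wNC}


@dataclass(frozen=True)
class LearningParams:
    """Hebbian learning constants.

    ``theta_pre``/``theta_post`` are the pre/postsynaptic activity
    thresholds (midpoint of the normalized activity range by default);
    ``latency`` and ``window`` time the plasticity/prediction-error episode
    relative to the response; ``rpe_large``/``rpe_small`` are the two reward
    prediction-error magnitudes of the task.
    """

    phi_base: float = PHI_COEFF
    theta_pre: float = 0.5
    theta_post: float = 0.55
    latency: float = 0.1
    window: float = 0.05
    rpe_large: float = 1.0
    rpe_small: float = 0.1

    def __post_init__(self) -> None:
        if self.phi_base <= 0:
            raise ValueError("phi_base must be positive")
        if not (0 <= self.theta_pre <= 1 and 0 <= self.theta_post <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.window <= 0 or self.latency <= 0:
            raise ValueError("latency and window must be positive")


def assign_outcome(S: np.ndarray,
                   chosen: Optional[int]) -> tuple[str, float, float]:
    """Map a choice to ``(rpe_kind, magnitude, history_code)``.

    ``S`` is the canonical stimulus vector (one 1, one 0.2, two 0.1, before
    noise).  Choosing the strongest stimulus earns a large reward (RPE 1,
    code +1); the second strongest a small reward (RPE 0.1, code +0.1); a
    weak channel a punishment (code -1); no response yields no event
    (code 0).
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (4,):
        raise ValueError("S must have 4 entries")
    order = np.sort(S)[::-1]
    if not (np.isclose(order, [1.0, 0.2, 0.1, 0.1]).all()):
        raise ValueError("S is not one of the canonical stimulus vectors")
    if chosen is None:
        return "none", 0.0, 0.0
    if not 0 <= chosen < 4:
        raise ValueError("chosen channel must be in 0..3")
    if S[chosen] == 1.0:
        return "reward", 1.0, 1.0
    if S[chosen] == 0.2:
        return "reward", 0.1, 0.1
    return "punishment", 1.0, -1.0


def gain_phi(rpe: float, ratio: float,
             phi_base: float = PHI_COEFF) -> float:
    """Learning gain ``phi = phi_base * |RPE| * DA_ratio``."""
    if ratio < 0:
        raise ValueError("da ratio must be >= 0")
    return phi_base * abs(rpe) * ratio


def hebb_update(W: PlasticWeights, y_pre_S: np.ndarray, y_pre_C: np.ndarray,
                y_post_G: np.ndarray, y_post_N: np.ndarray, phi: float,
                lp: LearningParams = LearningParams()) -> PlasticWeights:
    """Apply one Hebbian step to all four matrices (returns a new object).

    Presynaptic activities are the stimulus vector (for ``wGS``/``wNS``) and
    the cortical outputs (for the diagonal ``wGC``/``wNC``); postsynaptic
    activities are the Go/NoGo outputs.  Entries are clipped to [0, 1] and
    the diagonal matrices only train their diagonal.
    """
    pre_S = np.clip(np.asarray(y_pre_S, float) - lp.theta_pre, 0.0, None)
    pre_C = np.clip(np.asarray(y_pre_C, float) - lp.theta_pre, 0.0, None)
    post_G = np.asarray(y_post_G, float) - lp.theta_post
    post_N = np.asarray(y_post_N, float) - lp.theta_post

    out = W.copy()
    out.wGS = np.clip(W.wGS + phi * np.outer(post_G, pre_S), 0.0, 1.0)
    out.wNS = np.clip(W.wNS + phi * np.outer(post_N, pre_S), 0.0, 1.0)
    dgc = phi * pre_C * post_G
    dnc = phi * pre_C * post_N
    out.wGC = np.diag(np.clip(np.diag(W.wGC) + dgc, 0.0, 1.0))
    out.wNC = np.diag(np.clip(np.diag(W.wNC) + dnc, 0.0, 1.0))
    return out


def apply_learning_event(W: PlasticWeights, S: np.ndarray,
                         window_yC: np.ndarray, window_yG: np.ndarray,
                         window_yN: np.ndarray, rpe: float, ratio: float,
                         lp: LearningParams = LearningParams()) -> PlasticWeights:
    """Weight update for one trial outcome.

    ``window_*`` are activities time-averaged over the prediction-error
    window; ``rpe`` the signed/unsigned RPE magnitude for the event and
    ``ratio`` the subject's cached DA ratio.  With ``rpe == 0`` (no
    response) the weights are returned unchanged.
    """
    if rpe == 0:
        return W
    phi = gain_phi(rpe, ratio, lp.phi_base)
    return hebb_update(W, S, window_yC, window_yG, window_yN, phi, lp)
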