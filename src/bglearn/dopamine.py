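"""Dopamine terminal dynamics: tonic/phasic release, reuptake, autoreceptors.

The model tracks extracellular dopamine concentration ``C_DA`` (μM/L) in the
synaptic cleft and presynaptic autoreceptor occupancy ``AR`` (fraction).
Dopamine is released tonically at a rate set by background firing and
phasically during reward-prediction-error (RPE) bursts; it is cleared by
saturable DAT reuptake (Michaelis–Menten) and first-order removal::

    dC/dt  = I_tonic + I_phasic(t) - Vmax*C/(km + C) - krem*C
    dAR/dt = kon*C*(1 - AR) - koff*AR

Phasic release is scaled by ``(AR_norm/AR)**2``: autoreceptor activation
suppresses both the burst firing rate and the vesicular release probability,
each assumed inversely proportional to occupancy and normalized so that the
scaling is unity at the reference occupancy ``AR_norm``.  A punishment
prediction error is modelled as a transient pause of the dopamine neuron:
``C_DA`` is clamped to zero over the signalling window.

Two named parameter presets differ only in the maximal DAT reuptake rate
``Vmax``: ``control`` (1.2 μM/L/s) and ``imbalance`` (1.8 μM/L/s).  The higher
reuptake lowers tonic dopamine, lowers autoreceptor occupancy and thereby
disinhibits phasic release — the phasic/tonic imbalance mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DAParams",
    "DAState",
    "RPEEvent",
    "ReceptorOccupancy",
    "tonic_release_rate",
    "phasic_release_rate",
    "step",
    "steady_state",
    "phasic_transient",
    "da_ratio",
    "receptor_occupancy",
    "punishment_decay_time",
]


@dataclass(frozen=True)
class DAParams:
    """Parameters of the dopamine dynamics model.

    Units: concentrations in μM/L, times in s, rates in 1/s unless noted.
    ``rho`` is in terminals/L and ``n0`` in molecules per vesicle fusion;
    release rates are converted to μM/L/s internally (×1e6 from mol/L/s).
    """

    Vmax: float = 1.2          # maximal DAT reuptake rate (μM/L/s)
    km: float = 0.15           # Michaelis constant (μM/L)
    krem: float = 0.04         # first-order removal rate (1/s)
    kon: float = 10.0          # autoreceptor on-rate (1/(μM s))
    koff: float = 0.4          # autoreceptor off-rate (1/s)
    rho: float = 0.025e15      # dopamine terminal density (terminals/L)
    alpha_vf: float = 0.21     # extracellular volume fraction
    n0: float = 3000.0         # molecules released per vesicle fusion
    NA: float = 6.02214076e23  # Avogadro constant (1/mol)
    Pr_tonic: float = 0.06     # tonic vesicle release probability
    Pr_phasic: float = 0.06    # phasic vesicle release probability
    nu_tonic: float = 4.0      # tonic firing rate (1/s)
    nu_phasic: float = 40.0    # burst firing rate (1/s)
    Bmax_D1: float = 1.6       # D1 receptor maximal density (μM/L)
    kD_D1: float = 1.0         # D1 dissociation constant (μM/L)
    Bmax_D2: float = 0.08      # D2 receptor maximal density (μM/L)
    kD_D2: float = 0.01        # D2 dissociation constant (μM/L)
    AR_norm: float = 0.334     # reference autoreceptor occupancy

    def __post_init__(self) -> None:
        positive = {
            "km": self.km, "koff": self.koff, "kon": self.kon,
            "rho": self.rho, "n0": self.n0, "NA": self.NA,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        nonneg = {
            "Vmax": self.Vmax, "krem": self.krem,
            "Pr_tonic": self.Pr_tonic, "Pr_phasic": self.Pr_phasic,
            "nu_tonic": self.nu_tonic, "nu_phasic": self.nu_phasic,
            "Bmax_D1": self.Bmax_D1, "Bmax_D2": self.Bmax_D2,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0 < self.alpha_vf < 1:
            raise ValueError("alpha_vf must lie in (0, 1)")
        if not 0 < self.AR_norm < 1:
            raise ValueError("AR_norm must lie in (0, 1)")

    @classmethod
    def control(cls, **overrides) -> "DAParams":
        """Control parameter preset (Vmax = 1.2 μM/L/s)."""
        return cls(**{"Vmax": 1.2, **overrides})

    @classmethod
    def imbalance(cls, **overrides) -> "DAParams":
        """Dopamine-imbalance preset (Vmax = 1.8 μM/L/s)."""
        return cls(**{"Vmax": 1.8, **overrides})

    def with_(self, **overrides) -> "DAParams":
        return replace(self, **overrides)


@dataclass
class DAState:
    """Instantaneous state of the dopamine compartment."""

    C_DA: float   # dopamine concentration (μM/L)
    AR: float     # autoreceptor occupancy (fraction)
    t: float = 0.0  # time (s)

    def __post_init__(self) -> None:
        if self.C_DA < 0:
            raise ValueError("C_DA must be >= 0")
        if not 0 <= self.AR <= 1:
            raise ValueError("AR must lie in [0, 1]")


@dataclass(frozen=True)
class RPEEvent:
    """A reward or punishment prediction-error signal.

    The dopamine consequence starts ``latency`` seconds after ``onset`` and
    lasts ``duration`` seconds: a phasic release burst for rewards, a hard
    ``C_DA = 0`` clamp for punishments.
    """

    kind: Literal["reward", "punishment"]
    magnitude: float = 1.0
    onset: float = 0.0
    latency: float = 0.1
    duration: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("reward", "punishment"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "reward" and self.magnitude < 0:
            raise ValueError("reward magnitude must be >= 0")
        if self.latency <= 0 or self.duration <= 0:
            raise ValueError("latency and duration must be positive")

    @property
    def window(self) -> tuple[float, float]:
        start = self.onset + self.latency
        return start, start + self.duration

    def active(self, t: float) -> bool:
        lo, hi = self.window
        return lo <= t <= hi


@dataclass(frozen=True)
class ReceptorOccupancy:
    """Bound D1/D2 receptor concentration (μM/L) at a given dopamine level."""

    D1: float
    D2: float


def tonic_release_rate(p: DAParams) -> float:
    """Tonic dopamine release rate in μM/L/s.

    ``rho * Pr_tonic * n0 / (alpha_vf * NA) * nu_tonic``, converted from
    mol/L/s to μM/L/s.  Independent of autoreceptor occupancy.
    """
    return p.rho * p.Pr_tonic * p.n0 / (p.alpha_vf * p.NA) * p.nu_tonic * 1e6


def phasic_release_rate(p: DAParams, AR: float, rpe: float) -> float:
    """Phasic (burst) dopamine release rate in μM/L/s.

    Both the vesicular release probability and the burst firing rate are
    inversely proportional to autoreceptor occupancy, normalized at
    ``AR_norm``; the rate therefore carries a factor ``(AR_norm/AR)**2`` and
    is proportional to the RPE magnitude.

    Raises ``ValueError`` for ``AR <= 0`` (an uncalibrated state).
    """
    if AR <= 0:
        raise ValueError("phasic release undefined at AR <= 0")
    scale = p.AR_norm / AR
    return (
        p.rho * (p.Pr_phasic * scale) * p.n0 * abs(rpe)
        / (p.alpha_vf * p.NA) * (p.nu_phasic * scale) * 1e6
    )


def receptor_occupancy(C: float, p: DAParams) -> ReceptorOccupancy:
    """Saturating D1/D2 occupancy ``Bmax_i * C / (kD_i + C)``."""
    if C < 0:
        raise ValueError("C must be >= 0")
    return ReceptorOccupancy(
        D1=p.Bmax_D1 * C / (p.kD_D1 + C),
        D2=p.Bmax_D2 * C / (p.kD_D2 + C),
    )


def _release(t: float, AR: float, p: DAParams,
             events: Sequence[RPEEvent]) -> tuple[float, bool]:
    """Total release rate at time ``t`` and whether a punishment clamp holds."""
    rate = tonic_release_rate(p)
    clamped = False
    for ev in events:
        if not ev.active(t):
            continue
        if ev.kind == "reward":
            if ev.magnitude != 0:
                rate += phasic_release_rate(p, AR, ev.magnitude)
        else:
            clamped = True
    return rate, clamped


def step(state: DAState, p: DAParams,
         events: Sequence[RPEEvent] = (), dt: float = 1e-3) -> DAState:
    """Advance the dopamine state by one fixed step (RK4, dt ≤ 1 ms).

    Inside a punishment window the concentration is clamped to zero while
    the autoreceptor continues to unbind (``dAR/dt = -koff*AR``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms for the fixed-step integrator")

    def rhs(t: float, C: float, AR: float) -> tuple[float, float]:
        rate, clamped = _release(t, AR, p, events)
        if clamped:
            dC = 0.0
            C = 0.0
        else:
            dC = rate - p.Vmax * C / (p.km + C) - p.krem * C
        dAR = C * p.kon * (1.0 - AR) - p.koff * AR
        return dC, dAR

    _, clamped_now = _release(state.t + dt, state.AR, p, events)
    t, C, AR = state.t, state.C_DA, state.AR
    k1 = rhs(t, C, AR)
    k2 = rhs(t + dt / 2, C + dt / 2 * k1[0], AR + dt / 2 * k1[1])
    k3 = rhs(t + dt / 2, C + dt / 2 * k2[0], AR + dt / 2 * k2[1])
    k4 = rhs(t + dt, C + dt * k3[0], AR + dt * k3[1])
    C_new = C + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    AR_new = AR + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    if clamped_now:
        C_new = 0.0
    return DAState(C_DA=max(C_new, 0.0), AR=min(max(AR_new, 0.0), 1.0),
                   t=t + dt)


def steady_state(p: DAParams) -> tuple[float, float]:
    """Tonic equilibrium ``(C_tonic, AR_star)`` under tonic release only.

    ``C_tonic`` is the unique positive root of
    ``I_tonic = Vmax*C/(km+C) + krem*C`` and
    ``AR_star = kon*C/(kon*C + koff)``.
    """
    it = tonic_release_rate(p)
    if it == 0.0:
        return 0.0, 0.0

    def f(C: float) -> float:
        return it - p.Vmax * C / (p.km + C) - p.krem * C

    hi = 1.0
    while f(hi) > 0:
        hi *= 10.0
    C = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
    AR = p.kon * C / (p.kon * C + p.koff)
    return C, AR


def phasic_transient(p: DAParams, rpe: float = 1.0, dt: float = 1e-4,
                     t_end: float = 0.4) -> tuple[np.ndarray, float]:
    """Trajectory of one reward burst from tonic steady state.

    Returns ``(trace, C_peak)`` where ``trace`` has columns ``(t, C_DA, AR)``
    sampled every ``dt`` and ``C_peak`` is the maximum concentration reached.
    The burst follows the standard event timing (latency 0.1 s, duration
    0.05 s); autoreceptor occupancy is tracked continuously through it, so
    the build-up of occupancy during the burst feeds back on release.
    """
    C, AR = steady_state(p)
    ev = RPEEvent(kind="reward", magnitude=rpe, onset=0.0)
    n = int(round(t_end / dt))
    out = np.empty((n + 1, 3))
    out[0] = (0.0, C, AR)
    lo, hi = ev.window
    it = tonic_release_rate(p)
    t = 0.0
    C_peak = C
    for i in range(1, n + 1):
        # RK4 on the two-state system with the burst term active in-window
        def rhs(tt: float, Cc: float, ARr: float) -> tuple[float, float]:
            rate = it
            if lo <= tt <= hi and rpe != 0:
                rate += phasic_release_rate(p, ARr, rpe)
            dC = rate - p.Vmax * Cc / (p.km + Cc) - p.krem * Cc
            dAR = Cc * p.kon * (1.0 - ARr) - p.koff * ARr
            return dC, dAR

        k1 = rhs(t, C, AR)
        k2 = rhs(t + dt / 2, C + dt / 2 * k1[0], AR + dt / 2 * k1[1])
        k3 = rhs(t + dt / 2, C + dt / 2 * k2[0], AR + dt / 2 * k2[1])
        k4 = rhs(t + dt, C + dt * k3[0], AR + dt * k3[1])
        C += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        AR += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        t += dt
        C_peak = max(C_peak, C)
        out[i] = (t, C, AR)
    return out, C_peak


def da_ratio(p: DAParams, rpe: float = 1.0) -> float:
    """Phasic/tonic dopamine ratio ``(C_peak - C_tonic) / C_tonic``.

    Computed from a single unit-RPE burst starting at the tonic steady
    state.  This ratio is a fixed per-subject constant that scales the
    Hebbian learning gain.
    """
    C_tonic, _ = steady_state(p)
    if C_tonic <= 0:
        raise ValueError("da_ratio undefined: tonic concentration is zero")
    _, C_peak = phasic_transient(p, rpe=rpe)
    return (C_peak - C_tonic) / C_tonic


def punishment_decay_time(p: DAParams, threshold_frac: float = 0.01,
                          dt: float = 1e-4) -> float:
    """Time for ``C_DA`` to fall below ``threshold_frac * C_tonic``.

    Integrates the firing-suppressed dynamics
    ``dC/dt = -Vmax*C/(km+C) - krem*C`` from the tonic steady state.  In the
    small-C limit the decay is exponential with rate ``Vmax/km + krem``.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    C0, _ = steady_state(p)
    C, t = C0, 0.0
    target = threshold_frac * C0
    while C > target:
        def rhs(Cc: float) -> float:
            return -p.Vmax * Cc / (p.km + Cc) - p.krem * Cc

        k1 = rhs(C)
        k2 = rhs(C + dt / 2 * k1)
        k3 = rhs(C + dt / 2 * k2)
        k4 = rhs(C + dt * k3)
        C += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        if t > 1e3:  # pragma: no cover - defensive
            raise RuntimeError("decay did not reach threshold")
    return t


def trajectory_frame(states: Iterable[DAState], p: DAParams):
    """Tabulate a dopamine trajectory as a DataFrame (t, C_DA, AR, D1, D2)."""
    import pandas as pd

    rows = []
    for s in states:
        occ = receptor_occupancy(s.C_DA, p)
        rows.append((s.t, s.C_DA, s.AR, occ.D1, occ.D2))
    return pd.DataFrame(rows, columns=["t", "C_DA", "AR", "D1", "D2"])
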