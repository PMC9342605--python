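"""Four-channel cortico–basal-ganglia–thalamic action-selection network.

Each modelled region — cortex (C), striatal Go (G) and NoGo (N) populations,
globus pallidus externa (GPe) and interna (GPi), thalamus (T) — is split into
four parallel action channels; the subthalamic nucleus (STN) and the
cholinergic interneuron pool (ChI) are shared across channels.  Every unit is
a first-order leaky integrator with a sigmoidal output normalized to [0, 1]::

    tau * du/dt = -u + I(t),      y = 1 / (1 + exp(-a * (u - c)))

Wiring (per channel unless noted):

* direct pathway: stimulus and cortex excite Go (through the plastic weights
  ``wGS``/``wGC``, gain increased by D1 occupancy and by the cholinergic
  tone); Go inhibits GPi.
* indirect pathway: stimulus and cortex excite NoGo (``wNS``/``wNC``, gain
  decreased by D2 occupancy, increased by cholinergic tone); NoGo inhibits
  GPe, which tonically inhibits GPi and the STN.
* hyperdirect pathway: cortex (summed over channels) excites the STN, which
  diffusely excites every GPi channel.
* output: GPi inhibits thalamus; thalamus excites its cortical channel.
* cortex: self-excitation plus cross-channel lateral inhibition implement a
  winner-takes-all race; each channel additionally receives its own noise
  sample, held constant over ``noise_hold`` integration steps (one draw per
  trial by default).

The stimulus vector S reaches the circuit only through the plastic striatal
afferents, so a naive network (all weights equal) cannot tell stimuli apart:
selection is then decided by cortical noise, which is what makes early
training performance random and learning necessary.

A numba-compiled kernel integrates a full trial (decision period, optional
reward/punishment dopamine episode, and the activity averages used by the
Hebb rule) at a fixed 1 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
from numba import njit

from .dopamine import DAParams, receptor_occupancy, steady_state, tonic_release_rate
from .plasticity import PlasticWeights

__all__ = [
    "NetworkParams",
    "NetworkState",
    "TrialOutcome",
    "canonical_stimuli",
    "step_network",
    "resting_state",
    "run_trial",
]

# state vector layout: 4 channels per region, then the two shared units
_C, _G, _N, _E, _I, _T = 0, 4, 8, 12, 16, 20
_STN, _CHI = 24, 25
NSTATE = 26


@dataclass(frozen=True)
class NetworkParams:
    """Time constants, sigmoid shapes, wiring gains and noise amplitude.

    The defaults are calibrated so that a trained control subject selects
    the correct channel in roughly 150 ms and a naive subject responds at
    chance: the behavioural operating point, not any single gain, is the
    meaningful quantity.
    """

    # time constants (s)
    tau_C: float = 0.045
    tau_str: float = 0.007
    tau_E: float = 0.020
    tau_STN: float = 0.020
    tau_I: float = 0.020
    tau_T: float = 0.020
    tau_chi: float = 0.020
    # sigmoid slope / centre per region
    a_C: float = 6.0
    c_C: float = 0.45
    a_G: float = 4.0
    c_G: float = 2.12
    a_N: float = 8.0
    c_N: float = 2.05
    a_E: float = 4.0
    c_E: float = 0.5
    a_STN: float = 4.0
    c_STN: float = 0.5
    a_I: float = 4.0
    c_I: float = 0.5
    a_T: float = 6.0
    c_T: float = 0.5
    a_chi: float = 4.0
    c_chi: float = 0.5
    # cortical winner-takes-all dynamics
    L_self: float = 0.5     # self-excitation (>= 0)
    L_inh: float = 0.9      # magnitude of lateral inhibition
    w_CT: float = 0.85      # thalamus -> cortex
    # pallidal / subthalamic wiring
    I_E0: float = 1.0       # GPe tonic drive
    w_EN: float = 1.1       # NoGo -| GPe
    I_S0: float = 0.3       # STN tonic drive
    w_SC: float = 0.2       # cortex (sum) -> STN
    w_SE: float = 0.4       # GPe (mean) -| STN
    I_I0: float = 1.2       # GPi tonic drive
    w_IG: float = 1.3       # Go -| GPi (channel-wise)
    w_IE: float = 0.35      # GPe -| GPi
    w_IS: float = 0.3       # STN -> GPi (diffuse)
    I_T0: float = 1.0       # thalamic tonic drive
    w_TI: float = 1.0       # GPi -| thalamus
    # neuromodulation
    I_chi0: float = 0.5     # cholinergic drive
    k_chi: float = 0.2      # cholinergic potentiation of both striatal paths
    k_D1: float = 1.3       # Go gain per unit D1 occupancy (μM/L)^-1
    k_D2: float = 3.5       # NoGo gain loss per unit D2 occupancy
    g_S: float = 2.6        # striatal gain on the stimulus afferents
    g_C: float = 1.0        # striatal gain on the cortical afferents
    # striatal collateral (Go/NoGo opponency) inhibition, channel-wise
    w_GN: float = 0.8       # NoGo -| Go
    w_NG: float = 0.15      # Go -| NoGo
    # cortical noise: uniform on [0, noise_high], held for noise_hold steps
    noise_high: float = 0.2
    noise_hold: float = 800.0

    def __post_init__(self) -> None:
        for f in ("tau_C", "tau_str", "tau_E", "tau_STN", "tau_I", "tau_T",
                  "tau_chi"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("a_C", "a_G", "a_N", "a_E", "a_STN", "a_I", "a_T", "a_chi"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.L_self < 0 or self.L_inh < 0:
            raise ValueError("L_self and L_inh must be >= 0")
        if self.noise_high < 0:
            raise ValueError("noise_high must be >= 0")

    def with_(self, **overrides) -> "NetworkParams":
        return replace(self, **overrides)

    def pack(self) -> np.ndarray:
        """Flatten to the float array consumed by the compiled kernel."""
        return np.array([getattr(self, f.name) for f in fields(self)],
                        dtype=np.float64)


_PARAM_NAMES = [f.name for f in fields(NetworkParams)]
_P = {name: i for i, name in enumerate(_PARAM_NAMES)}
# index constants used inside the numba kernel (compile-time globals)
P_TAU_C = _P["tau_C"]; P_TAU_STR = _P["tau_str"]; P_TAU_E = _P["tau_E"]
P_TAU_STN = _P["tau_STN"]; P_TAU_I = _P["tau_I"]; P_TAU_T = _P["tau_T"]
P_TAU_CHI = _P["tau_chi"]
P_A_C = _P["a_C"]; P_C_C = _P["c_C"]; P_A_G = _P["a_G"]
P_C_G = _P["c_G"]; P_A_N = _P["a_N"]; P_C_N = _P["c_N"]
P_A_E = _P["a_E"]; P_C_E = _P["c_E"]
P_A_STN = _P["a_STN"]; P_C_STN = _P["c_STN"]; P_A_I = _P["a_I"]
P_C_I = _P["c_I"]; P_A_T = _P["a_T"]; P_C_T = _P["c_T"]
P_A_CHI = _P["a_chi"]; P_C_CHI = _P["c_chi"]
P_L_SELF = _P["L_self"]; P_L_INH = _P["L_inh"]; P_W_CT = _P["w_CT"]
P_I_E0 = _P["I_E0"]; P_W_EN = _P["w_EN"]; P_I_S0 = _P["I_S0"]
P_W_SC = _P["w_SC"]; P_W_SE = _P["w_SE"]; P_I_I0 = _P["I_I0"]
P_W_IG = _P["w_IG"]; P_W_IE = _P["w_IE"]; P_W_IS = _P["w_IS"]
P_I_T0 = _P["I_T0"]; P_W_TI = _P["w_TI"]; P_I_CHI0 = _P["I_chi0"]
P_K_CHI = _P["k_chi"]; P_K_D1 = _P["k_D1"]; P_K_D2 = _P["k_D2"]
P_G_S = _P["g_S"]; P_G_C = _P["g_C"]
P_W_GN = _P["w_GN"]; P_W_NG = _P["w_NG"]
P_NOISE_HIGH = _P["noise_high"]


def canonical_stimuli() -> np.ndarray:
    """The four canonical training stimulus vectors, one per target channel."""
    return np.array([
        [1.0, 0.2, 0.1, 0.1],
        [0.2, 1.0, 0.1, 0.1],
        [0.1, 0.1, 0.2, 1.0],
        [0.1, 0.1, 1.0, 0.2],
    ])


@njit(cache=True)
def _step_core(u, y, S, wGS, wNS, wgc, wnc, D1, D2, noise4, npar, dt):
    """One synchronous Euler step of all 26 units (in place)."""
    chi = 1.0 + npar[P_K_CHI] * y[_CHI]
    fD1 = 1.0 + npar[P_K_D1] * D1
    fD2 = 1.0 - npar[P_K_D2] * D2
    if fD2 < 0.0:
        fD2 = 0.0
    sumC = y[_C] + y[_C + 1] + y[_C + 2] + y[_C + 3]
    meanE = 0.25 * (y[_E] + y[_E + 1] + y[_E + 2] + y[_E + 3])

    inp = np.empty(NSTATE)
    for j in range(4):
        gs = 0.0
        ns = 0.0
        for k in range(4):
            gs += wGS[j, k] * S[k]
            ns += wNS[j, k] * S[k]
        inp[_G + j] = (fD1 * chi * (npar[P_G_S] * gs
                                    + npar[P_G_C] * wgc[j] * y[_C + j])
                       - npar[P_W_GN] * y[_N + j])
        inp[_N + j] = (fD2 * chi * (npar[P_G_S] * ns
                                    + npar[P_G_C] * wnc[j] * y[_C + j])
                       - npar[P_W_NG] * y[_G + j])
        inp[_E + j] = npar[P_I_E0] - npar[P_W_EN] * y[_N + j]
        inp[_I + j] = (npar[P_I_I0] - npar[P_W_IG] * y[_G + j]
                       - npar[P_W_IE] * y[_E + j] + npar[P_W_IS] * y[_STN])
        inp[_T + j] = npar[P_I_T0] - npar[P_W_TI] * y[_I + j]
        inp[_C + j] = (npar[P_W_CT] * y[_T + j] + npar[P_L_SELF] * y[_C + j]
                       - npar[P_L_INH] * (sumC - y[_C + j]) + noise4[j])
    inp[_STN] = npar[P_I_S0] + npar[P_W_SC] * sumC - npar[P_W_SE] * meanE
    inp[_CHI] = npar[P_I_CHI0]

    for j in range(4):
        u[_C + j] += dt / npar[P_TAU_C] * (inp[_C + j] - u[_C + j])
        u[_G + j] += dt / npar[P_TAU_STR] * (inp[_G + j] - u[_G + j])
        u[_N + j] += dt / npar[P_TAU_STR] * (inp[_N + j] - u[_N + j])
        u[_E + j] += dt / npar[P_TAU_E] * (inp[_E + j] - u[_E + j])
        u[_I + j] += dt / npar[P_TAU_I] * (inp[_I + j] - u[_I + j])
        u[_T + j] += dt / npar[P_TAU_T] * (inp[_T + j] - u[_T + j])
    u[_STN] += dt / npar[P_TAU_STN] * (inp[_STN] - u[_STN])
    u[_CHI] += dt / npar[P_TAU_CHI] * (inp[_CHI] - u[_CHI])

    for j in range(4):
        y[_C + j] = 1.0 / (1.0 + np.exp(-npar[P_A_C] * (u[_C + j] - npar[P_C_C])))
        y[_G + j] = 1.0 / (1.0 + np.exp(-npar[P_A_G] * (u[_G + j] - npar[P_C_G])))
        y[_N + j] = 1.0 / (1.0 + np.exp(-npar[P_A_N] * (u[_N + j] - npar[P_C_N])))
        y[_E + j] = 1.0 / (1.0 + np.exp(-npar[P_A_E] * (u[_E + j] - npar[P_C_E])))
        y[_I + j] = 1.0 / (1.0 + np.exp(-npar[P_A_I] * (u[_I + j] - npar[P_C_I])))
        y[_T + j] = 1.0 / (1.0 + np.exp(-npar[P_A_T] * (u[_T + j] - npar[P_C_T])))
    y[_STN] = 1.0 / (1.0 + np.exp(-npar[P_A_STN] * (u[_STN] - npar[P_C_STN])))
    y[_CHI] = 1.0 / (1.0 + np.exp(-npar[P_A_CHI] * (u[_CHI] - npar[P_C_CHI])))


@njit(cache=True)
def _relax_kernel(u, y, S, wGS, wNS, wgc, wnc, D1, D2, npar, dt, n_steps):
    noise4 = np.zeros(4)
    for _ in range(n_steps):
        _step_core(u, y, S, wGS, wNS, wgc, wnc, D1, D2, noise4, npar, dt)


@njit(cache=True)
def _trial_kernel(u, y, S, wGS, wNS, wgc, wnc, noise, npar,
                  Vmax, km, krem, kon, koff, I_tonic, phasic_base, AR_norm,
                  Bmax1, kd1, Bmax2, kd2,
                  C0, AR0, dt, n_decision, threshold,
                  rpe_by_channel, learning_on, stop_on_response,
                  latency, duration, yC_trace):
    """Integrate one trial; returns selection, RT and window-averaged activity.

    ``noise`` is (n_steps, 4) pre-drawn cortical noise; the trial ends at
    the response (test mode) or at the end of the plasticity window
    (learning mode).  Dopamine is integrated alongside the network once an
    event is scheduled; D1/D2 occupancy always follows the instantaneous
    concentration.
    """
    C = C0
    AR = AR0
    D1 = Bmax1 * C / (kd1 + C)
    D2 = Bmax2 * C / (kd2 + C)

    chosen = -1
    rt = np.nan
    rpe = 0.0
    win_lo = -1.0
    win_hi = -1.0
    n_max = n_decision
    n_total = noise.shape[0]

    avg_yC = np.zeros(4)
    avg_yG = np.zeros(4)
    avg_yN = np.zeros(4)
    n_win = 0

    i = 0
    while i < n_max and i < n_total:
        t = i * dt
        in_window = chosen >= 0 and win_lo <= t <= win_hi
        if chosen >= 0:
            # dopamine episode dynamics (Euler; 1 ms resolves all rates)
            if in_window and rpe < 0.0:
                C = 0.0
                AR += dt * (-koff * AR)
            else:
                rate = I_tonic
                if in_window and rpe > 0.0:
                    s = AR_norm / AR
                    rate += phasic_base * s * s * rpe
                C += dt * (rate - Vmax * C / (km + C) - krem * C)
                if C < 0.0:
                    C = 0.0
                AR += dt * (C * kon * (1.0 - AR) - koff * AR)
            D1 = Bmax1 * C / (kd1 + C)
            D2 = Bmax2 * C / (kd2 + C)

        _step_core(u, y, S, wGS, wNS, wgc, wnc, D1, D2, noise[i], npar, dt)
        for j in range(4):
            yC_trace[i, j] = y[_C + j]

        if in_window:
            for j in range(4):
                avg_yC[j] += y[_C + j]
                avg_yG[j] += y[_G + j]
                avg_yN[j] += y[_N + j]
            n_win += 1

        if chosen < 0:
            best = -1
            best_y = threshold
            for j in range(4):
                if y[_C + j] > best_y:
                    best_y = y[_C + j]
                    best = j
            if best >= 0:
                chosen = best
                rt = (i + 1) * dt
                if not learning_on:
                    if stop_on_response:
                        i += 1
                        break
                    i += 1
                    continue
                rpe = rpe_by_channel[best]
                win_lo = rt + latency
                win_hi = win_lo + duration
                n_max = int(win_hi / dt) + 2
                if n_max > n_total:
                    n_max = n_total
        i += 1

    if n_win > 0:
        for j in range(4):
            avg_yC[j] /= n_win
            avg_yG[j] /= n_win
            avg_yN[j] /= n_win
    return chosen, rt, avg_yC, avg_yG, avg_yN, i


@dataclass
class NetworkState:
    """Internal states ``u`` and normalized outputs ``y`` of all 26 units."""

    u: np.ndarray = field(default_factory=lambda: np.zeros(NSTATE))
    y: np.ndarray = field(default_factory=lambda: np.zeros(NSTATE))
    t: float = 0.0

    _slices = {"cortex": slice(_C, _C + 4), "go": slice(_G, _G + 4),
               "nogo": slice(_N, _N + 4), "gpe": slice(_E, _E + 4),
               "gpi": slice(_I, _I + 4), "thalamus": slice(_T, _T + 4)}

    def output(self, region: str) -> np.ndarray:
        """Outputs of one region ('cortex', 'go', ..., 'stn', 'chi')."""
        if region == "stn":
            return self.y[_STN:_STN + 1]
        if region == "chi":
            return self.y[_CHI:_CHI + 1]
        return self.y[self._slices[region]]

    def copy(self) -> "NetworkState":
        return NetworkState(self.u.copy(), self.y.copy(), self.t)


@dataclass
class TrialOutcome:
    """Result of a single simulated trial."""

    chosen: Optional[int]          # selected channel, None if no response
    rt: float                      # reaction time (s), nan if no response
    S: np.ndarray                  # stimulus vector as presented
    window_yC: np.ndarray          # activities averaged over the RPE window
    window_yG: np.ndarray
    window_yN: np.ndarray
    yC_trace: Optional[np.ndarray] = None  # (n_steps, 4) cortical outputs

    @property
    def responded(self) -> bool:
        return self.chosen is not None


def step_network(state: NetworkState, S: np.ndarray, W: PlasticWeights,
                 D1: float, D2: float, noise: np.ndarray,
                 params: NetworkParams, dt: float = 1e-3) -> NetworkState:
    """Advance the network by one integration step (pure-python surface).

    Returns a new :class:`NetworkState`; ``noise`` is the 4-vector of
    cortical noise for this step.
    """
    S = np.asarray(S, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if S.shape != (4,) or noise.shape != (4,):
        raise ValueError("S and noise must have 4 entries")
    new = state.copy()
    _step_core(new.u, new.y, S, W.wGS, W.wNS,
               np.ascontiguousarray(np.diag(W.wGC)),
               np.ascontiguousarray(np.diag(W.wNC)),
               D1, D2, noise, params.pack(), dt)
    new.t = state.t + dt
    return new


def resting_state(params: NetworkParams, W: PlasticWeights,
                  da: DAParams, dt: float = 1e-3,
                  settle: float = 1.0) -> NetworkState:
    """Noise-free resting state with no stimulus, at tonic dopamine.

    Used as the initial condition of every trial; the 500 ms inter-trial
    pauses justify a full reset of the circuit between trials.
    """
    C0, _ = steady_state(da)
    occ = receptor_occupancy(C0, da)
    st = NetworkState()
    _relax_kernel(st.u, st.y, np.zeros(4), W.wGS, W.wNS,
                  np.ascontiguousarray(np.diag(W.wGC)),
                  np.ascontiguousarray(np.diag(W.wNC)),
                  occ.D1, occ.D2, params.pack(), dt,
                  int(round(settle / dt)))
    return st


def run_trial(S: np.ndarray, W: PlasticWeights, da: DAParams,
              params: NetworkParams, rng: np.random.Generator,
              duration: float = 0.8, response_threshold: float = 0.9,
              learning: bool = True,
              rpe_by_channel: Optional[np.ndarray] = None,
              init: Optional[NetworkState] = None,
              dt: float = 1e-3,
              keep_trace: bool = False,
              stop_at_response: bool = True) -> TrialOutcome:
    """Simulate one trial of the coupled dopamine + network system.

    The stimulus is applied from t = 0; the response is the first cortical
    channel to cross ``response_threshold`` and the reaction time is the
    crossing time.  In learning mode the corresponding dopamine event
    (``rpe_by_channel[chosen]``: positive magnitude for rewards, negative
    for punishment) is delivered and activities are averaged over the
    plasticity window; in test mode the trial stops at the response.
    "No response" within ``duration`` is a valid outcome.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (4,):
        raise ValueError("S must have 4 entries")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 < response_threshold < 1:
        raise ValueError("response_threshold must lie in (0, 1)")
    if learning and rpe_by_channel is None:
        raise ValueError("learning trials need rpe_by_channel")
    if rpe_by_channel is None:
        rpe_by_channel = np.zeros(4)

    n_decision = int(round(duration / dt))
    n_total = n_decision + int(round(0.2 / dt)) + 4 if learning else n_decision
    hold = max(int(params.noise_hold), 1)
    n_draw = -(-n_total // hold)
    noise = np.repeat(
        rng.uniform(0.0, params.noise_high, size=(n_draw, 4)), hold, axis=0
    )[:n_total]

    C0, AR0 = steady_state(da)
    st = init.copy() if init is not None else NetworkState()
    yC_trace = np.empty((n_total, 4))
    chosen, rt, avg_yC, avg_yG, avg_yN, n_used = _trial_kernel(
        st.u, st.y, S, W.wGS, W.wNS,
        np.ascontiguousarray(np.diag(W.wGC)),
        np.ascontiguousarray(np.diag(W.wNC)),
        noise, params.pack(),
        da.Vmax, da.km, da.krem, da.kon, da.koff,
        tonic_release_rate(da),
        da.rho * da.Pr_phasic * da.n0 / (da.alpha_vf * da.NA)
        * da.nu_phasic * 1e6,
        da.AR_norm, da.Bmax_D1, da.kD_D1, da.Bmax_D2, da.kD_D2,
        C0, AR0, dt, n_decision, response_threshold,
        np.asarray(rpe_by_channel, dtype=float), learning,
        stop_at_response, 0.1, 0.05, yC_trace)
    return TrialOutcome(
        chosen=None if chosen < 0 else int(chosen),
        rt=rt, S=S,
        window_yC=avg_yC, window_yG=avg_yG, window_yN=avg_yN,
        yC_trace=yC_trace[:n_used] if keep_trace else None,
    )
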