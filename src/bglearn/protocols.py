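"""Virtual-cohort experiments: training, test phase, noise sweep, gain curves.

Two groups of virtual subjects are built that differ only in the maximal DAT
reuptake rate ``Vmax`` (control 1.2, dopamine imbalance 1.8 μM/L/s); paired
subjects across groups share their noise seed, so each control subject and
its imbalance twin experience the same stimulus order and the same cortical
noise stream.

The training protocol presents the four canonical stimulus vectors in random
order within each of 250 blocks (1,000 epochs), each for up to 800 ms, with
the reward/punishment prediction-error dopamine event and one Hebbian update
per responded trial.  The learning criterion is 5 large-reward successes
within any 10 consecutive trials.  The test phase freezes the weights and
presents 100 stimuli (1,800 ms each): the target channel carries a stimulus
of 1 plus Gaussian noise, the other channels receive only cortical noise; a
response in the target channel counts as a success.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dopamine import DAParams, da_ratio
from .network import (NetworkParams, canonical_stimuli, resting_state,
                      run_trial)
from .plasticity import (LearningParams, PlasticWeights, apply_learning_event,
                         assign_outcome)

__all__ = [
    "SubjectSpec",
    "SubjectRecord",
    "TestResult",
    "build_cohort",
    "train_subject",
    "trials_to_criterion",
    "test_subject",
    "noise_sweep",
    "io_gain_curve",
]

N_EPOCHS_DEFAULT = 1000
TEST_STIMULI_DEFAULT = 100
TEST_NOISE_SD_DEFAULT = 0.1


@dataclass
class SubjectSpec:
    """One virtual subject: group, seed and model parameters."""

    group: str                       # "control" or "imbalance"
    subject_id: int
    noise_seed: int
    da_params: DAParams
    network_params: NetworkParams = field(default_factory=NetworkParams)
    learning_params: LearningParams = field(default_factory=LearningParams)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Per-subject, per-stream generator (streams keep phases independent)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.noise_seed,
                                   spawn_key=(stream,)))


@dataclass
class SubjectRecord:
    """Everything recorded about one subject's training."""

    spec: SubjectSpec
    history: np.ndarray              # per-epoch codes {+1, +0.1, -1, 0}
    target_channel: np.ndarray       # per-epoch target channel (0..3)
    chosen_channel: np.ndarray       # per-epoch chosen channel (-1 = none)
    train_rts: np.ndarray            # per-epoch RT (s), nan if no response
    weights: PlasticWeights          # final trained weights
    da_ratio: float
    trials_to_criterion: Optional[int] = None
    weight_snapshots: Optional[dict] = None   # epoch -> PlasticWeights


@dataclass
class TestResult:
    """Summary of a frozen-weights test run."""

    successes: np.ndarray            # per-trial bool
    rts: np.ndarray                  # per-trial RT (s), nan if none
    targets: np.ndarray
    chosen: np.ndarray               # -1 = no response

    @property
    def pct_success(self) -> float:
        return 100.0 * float(np.mean(self.successes))

    @property
    def responded_rts(self) -> np.ndarray:
        return self.rts[np.isfinite(self.rts)]


def build_cohort(n_per_group: int = 10, base_seed: int = 0,
                 network_params: Optional[NetworkParams] = None,
                 learning_params: Optional[LearningParams] = None,
                 ) -> list[SubjectSpec]:
    """Create the paired control/imbalance cohort.

    Subject ``k`` of each group shares ``noise_seed``; the groups differ
    only in ``Vmax``.  Seeds are derived with a counter scheme so enlarging
    the cohort never reshuffles existing subjects.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    npar = network_params or NetworkParams()
    lpar = learning_params or LearningParams()
    ss = np.random.SeedSequence(base_seed)
    specs = []
    for k in range(n_per_group):
        seed = int(ss.entropy) % (2 ** 31 - 1) + 7919 * k
        for group, da in (("control", DAParams.control()),
                          ("imbalance", DAParams.imbalance())):
            specs.append(SubjectSpec(group=group, subject_id=k,
                                     noise_seed=seed, da_params=da,
                                     network_params=npar,
                                     learning_params=lpar))
    return specs


def _rpe_by_channel(S: np.ndarray) -> np.ndarray:
    """Signed RPE for each possible choice under canonical stimulus S."""
    out = np.empty(4)
    for c in range(4):
        kind, mag, _ = assign_outcome(S, c)
        out[c] = mag if kind == "reward" else -1.0
    return out


def train_subject(spec: SubjectSpec, n_epochs: int = N_EPOCHS_DEFAULT,
                  trial_duration: float = 0.8,
                  response_threshold: float = 0.9,
                  snapshot_every: Optional[int] = None) -> SubjectRecord:
    """Run the full training phase for one subject.

    Weights start naive; each epoch runs one trial, assigns the outcome from
    the canonical stimulus ranks, delivers the dopamine event and applies
    the Hebb rule with the subject's cached DA ratio.
    """
    if n_epochs % 4:
        raise ValueError("n_epochs must be a multiple of 4 (blocks of 4)")
    stim = canonical_stimuli()
    ratio = da_ratio(spec.da_params)
    W = PlasticWeights.naive()
    rest = resting_state(spec.network_params, W, spec.da_params)
    rng = spec.rng(stream=0)

    n = n_epochs
    history = np.zeros(n)
    targets = np.zeros(n, dtype=int)
    chosen = np.full(n, -1, dtype=int)
    rts = np.full(n, np.nan)
    snapshots: dict[int, PlasticWeights] = {}

    epoch = 0
    for _block in range(n // 4):
        for si in rng.permutation(4):
            S = stim[si]
            out = run_trial(S, W, spec.da_params, spec.network_params, rng,
                            duration=trial_duration,
                            response_threshold=response_threshold,
                            learning=True, rpe_by_channel=_rpe_by_channel(S),
                            init=rest)
            kind, mag, code = assign_outcome(S, out.chosen)
            history[epoch] = code
            targets[epoch] = int(np.argmax(S))
            chosen[epoch] = -1 if out.chosen is None else out.chosen
            rts[epoch] = out.rt
            if out.chosen is not None:
                rpe = mag if kind == "reward" else -1.0
                W = apply_learning_event(W, S, out.window_yC, out.window_yG,
                                         out.window_yN, rpe, ratio,
                                         spec.learning_params)
            epoch += 1
            if snapshot_every and epoch % snapshot_every == 0:
                snapshots[epoch] = W.copy()

    return SubjectRecord(
        spec=spec, history=history, target_channel=targets,
        chosen_channel=chosen, train_rts=rts, weights=W, da_ratio=ratio,
        trials_to_criterion=trials_to_criterion(history),
        weight_snapshots=snapshots or None,
    )


def trials_to_criterion(history: Sequence[float], needed: int = 5,
                        window: int = 10) -> Optional[int]:
    """First trial index (1-based) at which the last ``window`` trials
    contain ``needed`` large-reward successes; ``None`` if never reached."""
    succ = (np.asarray(history, dtype=float) == 1.0).astype(int)
    cs = np.concatenate([[0], np.cumsum(succ)])
    for t in range(1, len(succ) + 1):
        if cs[t] - cs[max(0, t - window)] >= needed:
            return t
    return None


def test_subject(spec: SubjectSpec, weights: PlasticWeights,
                 n_stimuli: int = TEST_STIMULI_DEFAULT,
                 stimulus_noise_sd: float = TEST_NOISE_SD_DEFAULT,
                 trial_duration: float = 1.8,
                 response_threshold: float = 0.9,
                 rng: Optional[np.random.Generator] = None) -> TestResult:
    """Frozen-weights four-choice reaction-time test.

    Each trial presents one of the four canonical stimulus vectors with the
    target channel's value replaced by 1 plus Gaussian noise (sd
    ``stimulus_noise_sd``); cortical background noise is applied as during
    training.  Success is a response in the target channel; trials without
    a threshold crossing count as failures with censored RT.
    """
    rng = rng if rng is not None else spec.rng(stream=1)
    rest = resting_state(spec.network_params, weights, spec.da_params)
    stim = canonical_stimuli()
    successes = np.zeros(n_stimuli, dtype=bool)
    rts = np.full(n_stimuli, np.nan)
    targets = np.zeros(n_stimuli, dtype=int)
    chosen = np.full(n_stimuli, -1, dtype=int)
    for k in range(n_stimuli):
        si = int(rng.integers(4))
        S = stim[si].copy()
        tgt = int(np.argmax(S))
        S[tgt] = max(1.0 + rng.normal(0.0, stimulus_noise_sd), 0.0)
        out = run_trial(S, weights, spec.da_params, spec.network_params, rng,
                        duration=trial_duration,
                        response_threshold=response_threshold,
                        learning=False, init=rest)
        targets[k] = tgt
        chosen[k] = -1 if out.chosen is None else out.chosen
        successes[k] = out.chosen == tgt
        rts[k] = out.rt
    return TestResult(successes=successes, rts=rts, targets=targets,
                      chosen=chosen)


def noise_sweep(spec: SubjectSpec, weights: PlasticWeights,
                sd_grid: Sequence[float],
                n_stimuli: int = TEST_STIMULI_DEFAULT) -> np.ndarray:
    """Percent success at each stimulus-noise level in ``sd_grid``.

    Reuses the test-phase protocol with the target stimulus drawn with mean
    1 and the given standard deviation; one seeded stream per noise level.
    """
    out = np.empty(len(sd_grid))
    for i, sd in enumerate(sd_grid):
        if sd < 0:
            raise ValueError("noise sd must be >= 0")
        res = test_subject(spec, weights, n_stimuli=n_stimuli,
                           stimulus_noise_sd=sd,
                           rng=spec.rng(stream=100 + i))
        out[i] = res.pct_success
    return out


def io_gain_curve(spec: SubjectSpec, weights: PlasticWeights,
                  amplitude_grid: Sequence[float],
                  n_repeats: int = 10, background: float = 0.05,
                  trial_duration: float = 1.8) -> np.ndarray:
    """Cortical output in channel 1 versus input stimulus amplitude.

    A stimulus of the given amplitude feeds action channel 1 while the other
    channels receive a small background value; the response measure is the
    mean channel-1 cortical activity over the last 100 ms of the trial.
    Returns an array (len(grid), n_repeats).
    """
    rest = resting_state(spec.network_params, weights, spec.da_params)
    out = np.empty((len(amplitude_grid), n_repeats))
    for i, amp in enumerate(amplitude_grid):
        if not 0 <= amp <= 1.5:
            raise ValueError("amplitude out of range")
        rng = spec.rng(stream=200 + i)
        for r in range(n_repeats):
            S = np.array([amp, background, background, background])
            res = run_trial(S, weights, spec.da_params, spec.network_params,
                            rng, duration=trial_duration, learning=False,
                            init=rest, keep_trace=True,
                            stop_at_response=False)
            out[i, r] = float(res.yC_trace[-100:, 0].mean())
    return out
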