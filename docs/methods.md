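# Methods

`bglearn` simulates reinforcement learning in cortico–basal-ganglia loops
under two regimes of presynaptic dopamine regulation, and measures the
behavioural consequences in a four-choice reaction-time task.  This note
describes the model, its parameters, the numerical choices, and what the
simulator does and does not capture.

## Dopamine compartment

Extracellular dopamine `C_DA` (μM/L) in the striatal cleft follows

    dC/dt  = I_tonic + I_phasic(t) − Vmax·C/(km + C) − krem·C
    dAR/dt = kon·C·(1 − AR) − koff·AR

with saturable DAT reuptake (`Vmax`, `km`), first-order removal (`krem`),
and presynaptic D2-like autoreceptor occupancy `AR` with mass-action
binding (`kon`, `koff`).  Tonic release is

    I_tonic = ρ·Pr_tonic·n0/(α_vf·N_A)·ν_tonic

(terminal density ρ = 0.025·10¹⁵ /L, vesicle release probability 0.06,
3,000 molecules per fusion, extracellular volume fraction 0.21, tonic rate
4 Hz), converted to μM/L/s.  The terminal density is chosen so the control
tonic concentration is 0.02 μM/L, at which the autoreceptor equilibrium is
AR\* = kon·C/(kon·C + koff) = 0.334.

Phasic (burst) release during a reward-prediction-error signal multiplies
both the burst firing rate (40 Hz) and the vesicular release probability by
`0.334/AR`: autoreceptor activation suppresses phasic release, normalized
to unity at the control operating point.  The release rate is proportional
to |RPE|.  Burst timing is fixed: 0.1 s latency after the response, 0.05 s
duration.  A punishment prediction error is a transient pause of the
dopamine neuron, implemented as a hard `C_DA = 0` clamp over the same
window; the autoreceptor keeps unbinding (`dAR/dt = −koff·AR`) during the
clamp.  The gradual firing-suppressed decay (no release, reuptake and
removal only) is also implemented; from the control steady state it reaches
1% of baseline in ≈ 0.59 s, close to the ≈ 0.5 s linearized estimate
ln(100)/(Vmax/km + krem).

Two presets differ only in `Vmax`: control 1.2, dopamine imbalance
1.8 μM/L/s.  Raising reuptake lowers tonic dopamine (0.020 → 0.013 μM/L),
lowers autoreceptor occupancy (0.334 → 0.243), and thereby *raises* the
phasic burst amplitude — the phasic/tonic imbalance.  The single-burst
phasic/tonic ratio (C_peak − C_tonic)/C_tonic, computed with the
autoreceptor tracked continuously through the burst, is ≈ 3.07 for control
and ≈ 8.30 for imbalance.  This ratio is cached per subject and scales the
learning gain.

Postsynaptic D1/D2 occupancy is instantaneous saturable binding
`Bmax_i·C/(kD_i + C)` (Bmax 1.6/0.08 μM/L, kD 1.0/0.01 μM/L): D2 is nearly
saturated at tonic levels while D1 has large headroom, so bursts move D1
much more than D2, and pauses collapse D2 completely.

Integration is fixed-step: RK4 for the standalone dopamine routines
(1·10⁻⁴ s), explicit Euler at 1 ms inside the behavioural trial kernel.
The fastest time constants (burst 50 ms, reuptake ≈ 0.12 s) are well
resolved at 1 ms; the steady state agrees with long-time integration to
better than 10⁻⁴ relative error.

## Action-selection network

Each of cortex, striatal Go and NoGo populations, GPe, GPi and thalamus is
split into four action channels; the STN and a cholinergic pool are shared.
Units are first-order leaky integrators with sigmoidal outputs in [0, 1].
Wiring follows the standard direct / indirect / hyperdirect architecture
(see the module docstring of `bglearn.network` for the full list of
connections and `NetworkParams` for all values).  Design choices that go
beyond the standard textbook wiring, made because the behaviour of the
whole loop — not any single gain — is the constrained quantity:

* **Stimulus routing.** The stimulus vector S enters only through the
  plastic striatal afferents (`wGS`, `wNS`), scaled by `g_S`.  A naive
  network therefore cannot tell stimuli apart and selects at chance
  (verified: 24.8% correct over 600 naive trials), which is what makes the
  training phase meaningful.
* **Striatal opponency collaterals.** NoGo inhibits Go (`w_GN`) and Go
  weakly inhibits NoGo (`w_NG`) within a channel.  During a punishment the
  D2 gain loss disappears (C_DA = 0), the cortex-supported NoGo unit flips
  on and shuts the chosen Go unit down; this is what gives punishment a
  depressive effect on the wrong association under a purely Hebbian rule
  with no explicit anti-Hebbian term.
* **Noise-competitive selection.** Cortical noise (uniform on [0, 0.2],
  one draw per channel held for the whole trial) competes with the
  thalamo-cortical drive in a winner-takes-all race.  The thalamo-cortical
  weight is deliberately moderate so that small learned drive differences
  remain exploratory while fully learned differences saturate the race.
  Held-per-trial noise was chosen over per-step redrawing because 1 ms
  redraws average out over the cortical time constant and make naive
  selection quasi-deterministic instead of random.
* **Dopamine gains.** D1 occupancy multiplies the Go afferent gain
  (`k_D1`), D2 occupancy divides the NoGo gain (`k_D2`); the cholinergic
  pool applies a constant multiplicative potentiation to both pathways
  (its dynamics are not modelled).  During the decision period the
  occupancies sit at their tonic values; they follow the instantaneous
  concentration through reward bursts and punishment pauses.
* **STN→GPi is diffuse** (all channels), the conventional "global NoGo"
  of the hyperdirect pathway.

Every trial starts from the noise-free resting state (computed once per
weight configuration); the 500 ms inter-trial pauses justify a full reset,
and nothing except the weights carries over between trials.  Ties at the
response threshold are broken toward the larger activity, then the lower
channel index (deterministic).

## Plasticity

Four matrices are plastic, all 4×4: `wGS`, `wNS` full, `wGC`, `wNC`
diagonal (only diagonal entries train).  All trainable entries start at
0.5.  After each responded trial one Hebbian update is applied with the
activities time-averaged over the 50 ms prediction-error window:

    Δw_ij = φ·[y_pre_j − θ_pre]^+·(y_post_i − θ_post),
    φ = 0.0013·|RPE|·DA_ratio

Presynaptic activities are the stimulus entries (for `wGS`/`wNS`) and the
cortical outputs (for `wGC`/`wNC`); postsynaptic activities are Go/NoGo.
Weights are clipped to [0, 1] (unbounded growth is meaningless with
normalized activities).  Outcomes: choosing the strongest stimulus (value
1) gives RPE = 1; the second strongest (0.2) gives RPE = 0.1; a weak
channel (0.1) gives a punishment; no response gives no event.

`θ_pre = 0.5`; `θ_post = 0.55`.  The postsynaptic threshold sits slightly
above the midpoint because the reward burst raises D1 and with it the
activity of *all* Go units, chosen or not.  With θ_post at 0.5 this
indiscriminately potentiates wrong associations in both groups; at 0.55
the control group's burst (D1 swing ≈ 0.09 μM/L) stays inside the
deadzone while the imbalance group's larger swing (≈ 0.15 μM/L) crosses
it.  This is the mechanistic seat of the group difference in learning
stability: the imbalance group's oversized bursts reinforce associations
beyond the chosen one, and its ≈ 2.8× larger gain amplifies early random
asymmetries of experience into lasting biases.

## Protocols

* **Training**: 250 blocks × the 4 canonical stimulus vectors in random
  order (1,000 epochs), 800 ms per trial; outcome codes {+1, +0.1, −1, 0}
  recorded per epoch and attributed to the target channel of the epoch's
  stimulus.  Learning criterion: first trial at which the trailing 10
  trials contain 5 large-reward successes (small rewards do not count).
* **Test**: weights frozen; 100 stimuli of 1,800 ms with 500 ms pauses.
  Each trial presents a canonical vector with the target value replaced by
  1 + N(0, 0.1²); the non-target entries keep their canonical 0.2/0.1
  values (the task is the same as in training) and cortical noise is
  unchanged.  Success = response in the target channel; no-response trials
  count as failures with censored RT and are excluded from RT statistics.
* **Noise sweep**: the test repeated with the target value drawn with
  mean 1 and standard deviations from 0 to 1.
* **Gain curves**: stimulus amplitudes 0.1–1 in channel 1 with small
  background elsewhere; the response measure is channel-1 cortical
  activity over the last 100 ms of the trial.

Paired subjects (control #k, imbalance #k) share their noise seed; the
groups differ only in `Vmax`.  Per-subject seeds derive from the base seed
by a counter scheme, and separate streams feed training, test, and sweeps,
so runs are bitwise reproducible and enlarging the cohort does not
reshuffle existing subjects.

## Analysis

Reaction-time distributions are fitted with an exponentially modified
Gaussian (maximum likelihood via `scipy.stats.exponnorm`, moment-based
initialization); τ measures the slow tail.  Parameter recovery on
synthetic samples is within 10% at n = 5,000.  The learning-history
statistic first accumulates the outcome codes per channel, then computes
the epoch-wise across-channel root-sum-square deviation (scaled by 1/1000)
and weights it by the ratio of negative to positive cumulative cells.  The
ratio has two implemented readings — cell counts (default) or summed
magnitudes — both growing when failures dominate.  Severity subgroups:
`a` = near-perfect accuracy; among impaired subjects, `b` if the RT tail
dominates (τ > 2σ), else `c`.  The thresholds are configuration, not
estimates.

## Calibration and reference behaviour

The dopamine compartment is fully determined by published parameter
values.  The network has no authoritative parameter source, so its gains
were calibrated against the behavioural endpoints: trained controls
respond correctly in ≈ 140 ms with small variability; naive subjects
respond at chance; the trained control ignition threshold lies around
stimulus amplitude 0.5–0.7.  With the default configuration and ten
subjects per group the simulator produces (base seeds 1–3): control test
success 94–96% with tight RTs near 140 ms; imbalance success 67–81% with
2–5× larger between-subject spread; pooled imbalance ex-Gaussian τ of
47–49 ms versus 32–38 ms for controls, with a smaller imbalance μ (fast
guesses plus a slow tail); mean trials-to-criterion around 40–50 with an
SD of the same order, consistent with a chance-driven first passage of the
5-of-10 rule at ≈ 25% success.

## Known limitations

* The network is a reconstruction constrained at the behavioural level;
  per-unit activity traces are not comparable to any reference
  implementation, and several microcircuit elements (collateral weights,
  afferent gains, noise correlation time) are modelling choices rather
  than measurements.
* In this reconstruction the larger Hebbian gain makes the imbalance group
  reach the learning criterion *faster* on average than controls, and no
  imbalance subject fails the criterion within 1,000 epochs; impaired
  imbalance subjects err quickly (over-consolidated wrong associations)
  rather than slowly.  Correspondingly, the weighted-std history statistic
  is larger in the control group (whose slower learning accumulates more
  punishments), and the within-group regression of RT variability on
  history variability is weak.  Operating points that reversed these
  orderings (weaker punishment opponency, tonic NoGo pressure, stronger
  phasic inflation) degraded control accuracy below its ceiling, and were
  rejected; the discrepancy is documented rather than hidden.
* Autoreceptor desensitization, spatial dopamine gradients, long-term DAT
  regulation, inhibition tasks and medication effects are out of scope.
* Cohorts use identical parameters within a group; all between-subject
  variability is experiential (noise seed), which understates real
  inter-individual physiological variability.
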