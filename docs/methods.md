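# Methods

## Model

The network represents a patch of cortex receiving afferents from a
seizure focus.  Three populations:

| population | size (default) | model | role |
|---|---|---|---|
| RS | 8,000 (80% of N) | AdEx / CAdEx / HH, regular-spiking preset | excitatory |
| FS | 2,000 (20% of N) | AdEx / CAdEx / HH, fast-spiking preset | inhibitory |
| EXT | 8,000 (= RS) | inhomogeneous Poisson | afferent drive |

Every ordered pair of neurons is connected independently with
probability 0.05 (Erdős–Rényi; autapses excluded), giving binomial
in-degrees with means ≈100 (from FS) and ≈400 (from RS and from EXT).
The six directed blocks RS/FS/EXT → RS/FS are drawn from independent
substreams of the connectivity seed, so the inhibitory out-probabilities
p_ie (FS→RS) and p_ii (FS→FS) can be varied without reshuffling the rest
— required for connectivity screens that isolate inhibition.

Synapses are conductance-based: a presynaptic spike increments each
target's g_E by Q_E = 1.5 nS (excitatory source) or g_I by Q_I = 5 nS
(FS source); conductances decay exponentially with τ_syn = 5 ms and
enter the membrane as I_syn = g_E(E_E − V) + g_I(E_I − V), E_E = 0 mV,
E_I = −80 mV.

Neuron parameters follow the RS/FS presets in
`neuron_models.py` (AdEx: C = 200 pF, g_L = 10 nS, E_L = −65 mV,
V_T = −50/−48 mV, Δ_T = 2/0.5 mV, b = 100/0 pA, τ_w = 1 s, t_ref = 5 ms,
reset −65 mV).  Four quantities the presets need but that have no
single established value are set as follows and are configurable:

- **V_D = −40 mV**, the numerical spike-detection ceiling for AdEx and
  CAdEx, also the upper edge of the Kuramoto phase mapping.  Any value a
  few Δ_T above V_T behaves identically because the spike-initiation
  term is explosive past threshold.
- **τ_w(FS) = 500 ms**: with a = b = 0 the FS adaptation current is
  identically zero, so the value is inert; it is kept positive only so
  the equations remain well-posed.
- **CAdEx RS ḡ_A = 0 nS**: RS adaptation is then purely spike-triggered
  through δg_A = 1 nS with τ_A = 1 s.  The CAdEx FS preset has both
  ḡ_A = 0 and δg_A = 0 (a non-adapting cell); its τ_A = 0.01 ms is kept
  as specified and is handled by the integrator (below).
- **HH conductances g_Na = 20 µS, g_K = 6 µS** (with C_m = 200 pF).
  The parameter carries an explicit unit field; nano-siemens values are
  loadable but do not support action potentials at this capacitance.
  HH has no reset: spikes are counted at upward crossings of 0 mV with
  a 1 ms lockout.

## Drive and stimulation

The commanded external rate is the plateau perturbation (β = 6 Hz basal;
α, τ_on/off, T₁, T₂ configurable; defaults T₁ = 2 s, T₂ = 3 s, τ = 100 ms)
plus any Gaussian stimulus pulses, clipped below at 0 Hz.  Each EXT
neuron is an independent Poisson process realized by Bernoulli thinning
per integration step (rate·dt ≤ 0.01 at default settings).  Thinning
draws one uniform per EXT neuron per step *unconditionally*, so two runs
sharing a drive seed but differing in the stimulus share all underlying
randomness — the stimulation protocol compares each realization with
its own counterfactual, as a closed-loop intervention would.

## Integration

Forward Euler on the membrane equations at dt = 0.1 ms, with three
refinements:

- synaptic conductances decay by the exact factor e^{−dt/τ_syn};
- the CAdEx adaptation conductance and the HH gating variables use the
  exponential-Euler update (exact for the ODE linearized at the current
  V).  This is unconditionally stable — necessary because the FS CAdEx
  τ_A = 0.01 ms is far below dt — and confines gating variables to
  [0, 1] by construction;
- the AdEx/CAdEx spike-initiation exponent is capped at 16; past that
  point the trajectory is committed to a spike and the cap only
  prevents floating-point overflow before detection at V_D.

Spikes detected in step k increment their targets' conductances in step
k+1 (one-step latency; no explicit axonal delay).  During the 5 ms
refractory period V is clamped at V_R while w (or g_A) and the synaptic
conductances continue to evolve; recorded V is V_R throughout, which is
what makes high-firing groups appear as low-μ_V bands in the
coarse-grained maps.  Membrane potentials are sampled every 1 ms by
default.  Non-finite states abort the run with the first offending
neuron and time; experiment drivers log and exclude such runs.

Convergence: halving dt to 0.05 ms changes total spike counts of a
desk-scale basal run with a matched (replayed) drive realization by
<1%, and the single-neuron inter-spike interval at dt = 0.01 ms matches
a 10× finer reference to <1%.  Outcome-level quantities near the
bistable boundary are intrinsically realization-sensitive (see
Limitations).

## Observables

Population rates are spike-count histograms normalized by N_pop and the
bin width (5 ms default — equal to t_ref, so the AdEx/CAdEx rate cannot
exceed 200 Hz).  A run is **propagative** iff the RS rate averaged over
[T₁, T₂] strictly exceeds β + α; the commanded plateau rate is used for
the input (it equals the realized EXT rate in expectation).  Per-neuron
rates discard a 500 ms transient.  Coarse-graining partitions a
population by exact inhibitory in-degree; group summaries are μ_V
(arithmetic mean of recorded V) and the Kuramoto order parameter of
potentials clipped to [V_R, V_D] and mapped linearly to phases in
[0, π] — a half-circle, so V = V_R and V = V_D remain distinguishable.
Cross-connectivity averages keep only group keys realized in every
network (extreme in-degrees are too rare to average).

## Scaled-down study conditions

`NetworkConfig.desk_scaled(k)` divides N_total by k and multiplies all
connection probabilities by k, preserving every mean in-degree and
hence the synaptic working point; finite-size fluctuations grow by
~√k.  The test suite uses k = 5 (N = 2,000): this preserves the basal
rates (FS 15.8 Hz, RS 2.2 Hz vs 16.6/2.3 at full scale), the 200 Hz
ceiling and the >800 Hz 1-ms peaks, and widens the bistable band.  The
stimulation screen is run at the scaled network's own tipping point
(α = 70 Hz, where 13/20 drive realizations propagate), since a
counter-stimulation study is only informative where the outcome is
undecided.  Problem sizes used by the default test run: one 2 s
full-scale basal run, one 2 s full-scale seizure run, 15 full-scale
runs for the bistability check, and 100 desk-scale runs (one baseline
plus four pulse conditions at 20 realizations) for the stimulation
screen.

## What the generator does and does not emulate

All data are produced by the simulator itself; the external drive is
stationary-rate-modulated Poisson.  Real afferent activity is bursty
and correlated, real cortex has distance-dependent connectivity,
synaptic delays, weight heterogeneity and plasticity — none are
modeled.  Passing tests therefore demonstrate the network-level
mechanism (inhibitory control, its structural determinants, and the
onset-window sensitivity to small rate perturbations), not a
quantitative match to tissue.

## Known limitations

- The propagative/non-propagative boundary is numerically delicate: its
  position in α shifts by tens of Hz under unprintable implementation
  details (integration scheme, delivery timing, detection ceiling).
  In this implementation the bistable band at τ = 100 ms sits near
  α ≈ 60–70 Hz; at α = 80 Hz essentially all realizations propagate.
  Within-implementation structure — existence of a band, monotone
  fraction in α, insensitivity to connectivity realization — is robust.
- At desk scale the prevention side of the stimulation window weakens:
  −5 Hz at plateau onset cancels ~a quarter of borderline seizures
  rather than the majority, because finite-size fluctuations at
  N = 2,000 are ~√5 larger than at full scale while the pulse
  amplitude is fixed.
- HH networks need dt ≤ 0.02 ms for accurate spike shapes; the engine
  accepts any dt but the default 0.1 ms is tuned for AdEx/CAdEx.
- Forward Euler plus a one-step delivery delay means exact spike times
  carry O(dt) jitter; analyses here use rates, potentials and binned
  statistics, none of which resolve below 1 ms.
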