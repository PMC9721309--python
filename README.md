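# seizprop

Spiking-network models of how seizure activity invades *normal* brain
tissue.  A small cortical area is modeled as a sparse random network of
10,000 conductance-based point neurons — 80% excitatory regular-spiking
(RS) and 20% inhibitory fast-spiking (FS) cells, each pair connected
independently with probability 0.05 — driven by an external population of
8,000 Poisson units wired by the same rule.  An incoming seizure is a
paroxysmal elevation of the external rate: a plateau of height α above
the 6 Hz basal rate with Gaussian rise and decay,

    ν(t) = β + α·[exp(−(t−T₁)²/2τ_on²)  (t<T₁);  1  (T₁≤t≤T₂);
                  exp(−(t−T₂)²/2τ_off²) (t>T₂)].

Each realization is classified **propagative** when the excitatory
population's mean plateau rate exceeds the commanded input β+α (the
area would relay the seizure downstream) or **non-propagative** when the
inhibitory population keeps it below (the seizure is contained).

The package is aimed at computational neuroscientists studying network
mechanisms of seizure propagation and closed-loop control.  It provides:

- three interchangeable neuron models with RS/FS parameter presets:
  **AdEx** (`C V̇ = g_L(E_L−V) + g_L Δ_T e^{(V−V_T)/Δ_T} − w + I_syn`,
  adaptation current `τ_w ẇ = a(V−E_L) − w`, reset V→V_R, w→w+b),
  **CAdEx** (adaptation as a conductance g_A with sigmoidal voltage
  activation), and **Hodgkin–Huxley** (Traub–Miles kinetics);
- conductance-based synapses: quantal jumps Q_E = 1.5 nS / Q_I = 5 nS
  per presynaptic spike, exponential decay τ_syn = 5 ms,
  `I_syn = g_E(E_E−V) + g_I(E_I−V)` with E_E = 0, E_I = −80 mV;
- a vectorized forward-Euler engine (dt = 0.1 ms) with exact conductance
  decay, one-step spike delivery, 5 ms refractory clamp, and full seed
  reproducibility for both connectivity and drive;
- observables: binned population rates, the propagation classifier,
  per-neuron rate vs in-degree correlations, raster sortings, and
  structural coarse-graining by exact inhibitory in-degree with
  per-group mean potential μ_V and a modified Kuramoto order parameter
  `R e^{iΨ} = (1/N) Σ_j e^{iθ_j}`, θ_j mapping V_j ∈ [V_R, V_D] → [0, π];
- experiment drivers: (α, τ) and (p_ie, p_ii) propagation grids, static
  vs dynamic coarse-grained profiles, and a Gaussian counter-stimulation
  protocol (σ = 10 ms, ±1 / ±5 Hz) that replays identical drive
  realizations with and without the pulse.

## Worked example

```python
from seizprop import (NetworkConfig, PerturbationParams, build_network,
                      run_simulation, single_neuron_rates)

net = build_network(NetworkConfig(connectivity_seed=1))
result = run_simulation(net, PerturbationParams(alpha=0.0),
                        duration=2000.0, drive_seed=2)
print(f"FS rate {single_neuron_rates(result, 'FS', 500.0).mean():.1f} Hz, "
      f"RS rate {single_neuron_rates(result, 'RS', 500.0).mean():.2f} Hz")
```

prints

```
FS rate 16.6 Hz, RS rate 2.30 Hz
```

— the basal asynchronous-irregular operating point: inhibitory cells near
15 Hz, excitatory cells near 2 Hz, i.e. a balanced network in which the
FS population holds the RS population far below the 6 Hz input it
receives.  Driving the same network with an `alpha=100` plateau produces
a propagative seizure whose 5 ms-binned global rate saturates at the
200 Hz ceiling set by the 5 ms refractory period (1 ms bins reveal
transient peaks above 800 Hz).

The `examples/` directory holds one short script per capability
(`basal_activity.py`, `seizure_response.py`, `coarse_graining.py`,
`stimulation_control.py`); each prints the numbers it computes and a
line on what they mean.  A thin CLI mirrors the drivers:
`seizprop simulate|classify|grid-perturb|grid-inhibition|stimulate|profiles`,
each taking `--config`, `--seed`, `--out`.

## Layout

- `src/seizprop/neuron_models.py` — AdEx/CAdEx/HH dynamics, resets, presets
- `src/seizprop/network.py` — random connectivity blocks, in-degrees
- `src/seizprop/drive.py` — perturbation waveform, pulses, Poisson trains
- `src/seizprop/engine.py` — network integrator and recording
- `src/seizprop/observables.py` — rates, classifier, coarse-graining, Kuramoto
- `src/seizprop/experiments.py` — grids, stimulation protocol, profiles
- `src/seizprop/io.py` — HDF5 containers, plain-text and Matrix Market export
- `docs/methods.md` — model assumptions, numerical choices, limitations
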