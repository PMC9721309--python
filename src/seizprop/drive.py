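"""External drive: paroxysmal rate waveform and Poisson spike generation.

The afferent seizure-like perturbation is a plateau of height ``alpha``
above the basal rate ``beta``, with Gaussian-shaped rise and decay:

    nu(t) = beta + alpha * [ exp(-(t-T1)^2 / (2 tau_on^2))   t < T1
                             1                               T1 <= t <= T2
                             exp(-(t-T2)^2 / (2 tau_off^2))  t > T2 ]

Counter-stimulation pulses are additive Gaussian rate offsets (possibly
negative); the total commanded rate is clipped at zero.  The external
population emits independent inhomogeneous Poisson trains at the
commanded rate, realized by per-step Bernoulli thinning so that runs
differing only in the stimulus share the underlying randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PerturbationParams",
    "StimulusPulse",
    "perturbation_rate",
    "total_rate",
    "make_rate_fn",
    "generate_poisson_spikes",
]


@dataclass(frozen=True)
class PerturbationParams:
    """Plateau perturbation riding on the basal Poisson rate.

    Defaults: basal rate 6 Hz, plateau from 2 s to 3 s with 100 ms
    Gaussian rise/decay; ``alpha = 0`` gives a constant basal drive.
    """

    beta: float = 6.0       # basal rate (Hz)
    alpha: float = 0.0      # plateau amplitude above basal (Hz)
    T1: float = 2000.0      # plateau start (ms)
    T2: float = 3000.0      # plateau end (ms)
    tau_on: float = 100.0   # rise time constant (ms)
    tau_off: float = 100.0  # decay time constant (ms)

    def __post_init__(self) -> None:
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("beta and alpha must be non-negative")
        if not self.T1 < self.T2:
            raise ValueError("plateau requires T1 < T2")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("tau_on and tau_off must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusPulse:
    """Gaussian rate offset used for counter- (or pro-) stimulation."""

    amplitude: float        # Hz; negative to suppress drive
    t_peak: float           # ms
    sigma: float = 10.0     # Gaussian width (ms)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def perturbation_rate(t, p: PerturbationParams):
    """Commanded perturbation rate (Hz) at time(s) t (ms).

    Continuous everywhere; equals beta far from the plateau and
    beta + alpha on it.
    """
    t = np.asarray(t, dtype=float)
    rise = np.exp(-((t - p.T1) ** 2) / (2.0 * p.tau_on**2))
    fall = np.exp(-((t - p.T2) ** 2) / (2.0 * p.tau_off**2))
    envelope = np.where(t < p.T1, rise, np.where(t <= p.T2, 1.0, fall))
    out = p.beta + p.alpha * envelope
    return float(out) if out.ndim == 0 else out


def total_rate(t, p: PerturbationParams, pulses: Sequence[StimulusPulse] = ()):
    """Perturbation rate plus stimulus pulses, clipped below at 0 Hz."""
    t_arr = np.asarray(t, dtype=float)
    rate = np.asarray(perturbation_rate(t_arr, p), dtype=float)
    for pulse in pulses:
        rate = rate + pulse.amplitude * np.exp(
            -((t_arr - pulse.t_peak) ** 2) / (2.0 * pulse.sigma**2)
        )
    rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def make_rate_fn(p: PerturbationParams,
                 pulses: Sequence[StimulusPulse] = ()) -> Callable:
    """Bind perturbation + pulses into a rate(t) callable."""
    def rate_fn(t):
        return total_rate(t, p, pulses)
    return rate_fn


def generate_poisson_spikes(
    rate_fn: Callable,
    n_neurons: int,
    t0: float,
    t1: float,
    dt: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent inhomogeneous Poisson trains for ``n_neurons`` units.

    Bernoulli-per-bin thinning: in each step of width dt (ms) every neuron
    spikes independently with probability rate_fn(t)·dt/1000.  Requires
    rate·dt << 1 (checked at 0.1).  Returns (neuron_ids, times_ms) sorted
    by time; bit-reproducible given the seed.
    """
    if dt <= 0 or t1 <= t0:
        raise ValueError("need dt > 0 and t1 > t0")
    rng = np.random.default_rng(seed)
    n_steps = int(round((t1 - t0) / dt))
    ids: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for k in range(n_steps):
        t = t0 + k * dt
        rate = float(rate_fn(t))
        if rate < 0:
            raise ValueError(f"rate function returned {rate} < 0 at t={t}")
        prob = rate * dt * 1e-3
        if prob > 0.1:
            raise ValueError(
                f"rate*dt = {prob:.3f} too coarse at t={t}; reduce dt"
            )
        # One uniform per neuron per step, drawn even at rate 0, keeps
        # realizations coupled across runs that differ only in the rate.
        hits = np.nonzero(rng.random(n_neurons) < prob)[0]
        if hits.size:
            ids.append(hits.astype(np.int32))
            times.append(np.full(hits.size, t + dt, dtype=np.float64))
    if not ids:
        return np.empty(0, np.int32), np.empty(0, np.float64)
    return np.concatenate(ids), np.concatenate(times)
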