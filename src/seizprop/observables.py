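"""Quantitative read-outs of a simulation.

Covers population firing-rate series, the propagation verdict (does the
excitatory population out-fire the commanded input plateau?), per-neuron
rate statistics against in-degrees, raster sortings, and the
inhibitory-in-degree coarse-graining with its two per-group summaries:
the mean membrane potential mu_V and a modified Kuramoto order parameter
computed on membrane potentials mapped linearly from [VR, VD] to phases
in [0, pi] (a half circle, so that V = VR and V = VD remain distinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drive import PerturbationParams
from .engine import SimulationResult
from .network import Network

__all__ = [
    "RateSeries",
    "PropagationVerdict",
    "GroupProfile",
    "population_rate",
    "classify_propagation",
    "single_neuron_rates",
    "degree_rate_correlation",
    "group_by_inhibitory_indegree",
    "group_mean_potential",
    "kuramoto_order",
    "compute_group_profiles",
    "group_profiles_frame",
    "sort_raster",
]


@dataclass
class RateSeries:
    """Binned population firing rate: spike count / (N_pop * bin_width)."""

    bin_width: float           # ms
    t: np.ndarray              # bin centers (ms)
    rate: np.ndarray           # Hz

    def mean_over(self, t_start: float, t_end: float) -> float:
        """Mean rate across bins whose centers fall in [t_start, t_end]."""
        sel = (self.t >= t_start) & (self.t <= t_end)
        if not sel.any():
            raise ValueError("window contains no rate bins")
        return float(self.rate[sel].mean())


@dataclass
class PropagationVerdict:
    """Outcome of the propagative / non-propagative classification."""

    label: str                 # "propagative" | "non_propagative"
    delta_rate: float          # mean plateau nu_e minus beta+alpha (Hz)
    window: tuple[float, float]

    @property
    def propagative(self) -> bool:
        return self.label == "propagative"


@dataclass
class GroupProfile:
    """Per-inhibitory-in-degree group summary time series."""

    group_key: int             # exact inhibitory in-degree
    members: np.ndarray        # neuron ids within the population
    t: np.ndarray | None = None
    mu_V: np.ndarray | None = None   # mean membrane potential (mV)
    R: np.ndarray | None = None      # Kuramoto order parameter in [0, 1]
    Psi: np.ndarray | None = None    # mean phase in [0, pi]


def population_rate(result: SimulationResult, population: str,
                    bin_width: float = 5.0) -> RateSeries:
    """Population firing rate from binned spike counts.

    ``population`` may be a recorded population name or "ALL" for the
    simulated network (RS + FS together).
    """
    if population == "ALL":
        times = result.all_network_spike_times()
        n_pop = (result.config_echo["populations"]["RS"]
                 + result.config_echo["populations"]["FS"])
    else:
        times = result.spikes[population][1]
        n_pop = result.config_echo["populations"][population]
    edges = np.arange(0.0, result.duration + bin_width, bin_width)
    counts, _ = np.histogram(times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rate = counts / (n_pop * bin_width * 1e-3)
    return RateSeries(bin_width=bin_width, t=centers, rate=rate)


def classify_propagation(result: SimulationResult,
                         perturbation: PerturbationParams,
                         bin_width: float = 5.0) -> PropagationVerdict:
    """Label a run propagative when the excitatory rate exceeds the input.

    The excitatory (RS) rate is averaged over the plateau [T1, T2] and
    compared with the commanded plateau rate beta + alpha; the verdict is
    propagative iff the difference is strictly positive.
    """
    if perturbation.T2 > result.duration or perturbation.T1 < 0:
        raise ValueError("classification window lies outside the simulation")
    nu_e = population_rate(result, "RS", bin_width)
    mean_rate = nu_e.mean_over(perturbation.T1, perturbation.T2)
    delta = mean_rate - (perturbation.beta + perturbation.alpha)
    label = "propagative" if delta > 0 else "non_propagative"
    return PropagationVerdict(label=label, delta_rate=delta,
                              window=(perturbation.T1, perturbation.T2))


def single_neuron_rates(result: SimulationResult, population: str,
                        transient: float = 500.0) -> np.ndarray:
    """Per-neuron firing rate (Hz): post-transient spikes / remaining time."""
    if transient >= result.duration:
        raise ValueError("transient must be shorter than the simulation")
    ids, times = result.spikes[population]
    n_pop = result.config_echo["populations"][population]
    keep = times > transient
    counts = np.bincount(ids[keep], minlength=n_pop)
    return counts / ((result.duration - transient) * 1e-3)


def degree_rate_correlation(rates: np.ndarray, in_degrees: np.ndarray) -> float:
    """Standard Pearson correlation between per-neuron rates and in-degrees."""
    rho, _ = stats.pearsonr(np.asarray(rates, float),
                            np.asarray(in_degrees, float))
    return float(rho)


def group_by_inhibitory_indegree(net: Network, population: str) -> list[GroupProfile]:
    """Partition a population into groups of identical inhibitory in-degree.

    One group per realized in-degree value with at least one member,
    sorted by key.  With the default network (binomial in-degrees, mean
    ~100) this yields on the order of 60 nonempty groups.
    """
    deg = net.inhibitory_in_degrees(population)
    keys = np.unique(deg)
    return [GroupProfile(group_key=int(k), members=np.nonzero(deg == k)[0])
            for k in keys]


def group_mean_potential(result: SimulationResult,
                         groups: list[GroupProfile],
                         population: str) -> np.ndarray:
    """mu_V(t) per group: mean recorded V over members at each sample time."""
    vm = result.vm[population]
    return np.stack([vm[:, g.members].mean(axis=1) for g in groups])


def kuramoto_order(V_values: np.ndarray, VR: float, VD: float):
    """Modified Kuramoto order parameter of a set of membrane potentials.

    Potentials are clipped to [VR, VD] and mapped linearly onto phases
    theta in [0, pi]; R e^{i Psi} is the mean unit phasor.  R = 1 means
    full alignment, R = 0 none.  Accepts a 1-D set (returns scalars) or a
    (time, neuron) array (returns time series).
    """
    if not VR < VD:
        raise ValueError("need VR < VD")
    V = np.asarray(V_values, dtype=float)
    if V.size == 0:
        raise ValueError("empty group: Kuramoto order undefined")
    theta = np.pi * (np.clip(V, VR, VD) - VR) / (VD - VR)
    z = np.exp(1j * theta).mean(axis=-1)
    R = np.minimum(np.abs(z), 1.0)       # guard rounding at full alignment
    Psi = np.clip(np.angle(z), 0.0, np.pi)
    return (float(R), float(Psi)) if np.ndim(z) == 0 else (R, Psi)


def compute_group_profiles(result: SimulationResult,
                           groups: list[GroupProfile],
                           population: str,
                           VR: float = -65.0,
                           VD: float = -40.0) -> list[GroupProfile]:
    """Fill mu_V, R and Psi time series into in-degree group profiles."""
    vm = result.vm[population]
    t = result.vm_times
    out = []
    for g in groups:
        sub = vm[:, g.members].astype(np.float64)
        R, Psi = kuramoto_order(sub, VR, VD)
        out.append(GroupProfile(
            group_key=g.group_key, members=g.members, t=t,
            mu_V=sub.mean(axis=1), R=np.atleast_1d(R), Psi=np.atleast_1d(Psi),
        ))
    return out


def group_profiles_frame(profiles: list[GroupProfile],
                         realization: int = 0) -> pd.DataFrame:
    """Tidy table (realization, group_key, t, mu_V, R, Psi) of profiles."""
    frames = []
    for g in profiles:
        frames.append(pd.DataFrame({
            "realization": realization,
            "group_key": g.group_key,
            "t": g.t,
            "mu_V": g.mu_V,
            "R": g.R,
            "Psi": g.Psi,
        }))
    return pd.concat(frames, ignore_index=True)


def sort_raster(result: SimulationResult, population: str, key: str,
                net: Network | None = None) -> np.ndarray:
    """Permutation of neuron ids for raster display.

    ``key`` is "spike_count" (total spikes in the run) or
    "inhibitory_indegree" (requires ``net``).  Stable ascending sort,
    ties broken by original id.
    """
    n_pop = result.config_echo["populations"][population]
    if key == "spike_count":
        values = result.spike_counts(population, n_pop)
    elif key == "inhibitory_indegree":
        if net is None:
            raise ValueError("inhibitory_indegree sorting requires the network")
        values = net.inhibitory_in_degrees(population)
    else:
        raise ValueError(f"unknown sort key {key!r}")
    return np.argsort(values, kind="stable")
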