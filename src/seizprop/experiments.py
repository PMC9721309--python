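"""Experiment drivers: parameter grids, stimulation protocol, profiles.

Each driver wraps many seeded simulations and reduces them to the study's
summary quantities: the fraction of propagative realizations over a
(amplitude, time-constant) or (p_ie, p_ii) grid, the prevented/triggered
fractions of the Gaussian counter-stimulation protocol, and the static
versus dynamic coarse-grained profiles of mu_V and Kuramoto R.

All drivers derive their per-run seeds from a single master seed through
``numpy.random.SeedSequence`` spawning, so any experiment rerun from its
emitted configuration reproduces its outputs exactly.  Runs that diverge
numerically are recorded and excluded, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .drive import PerturbationParams, StimulusPulse
from .engine import (RecordSpec, SimulationDivergedError, SimulationResult,
                     run_simulation)
from .network import Network, NetworkConfig, build_network
from .observables import (classify_propagation, compute_group_profiles,
                          group_by_inhibitory_indegree)

logger = logging.getLogger(__name__)

__all__ = [
    "GridResult",
    "StimulationOutcome",
    "grid_perturbation",
    "grid_inhibitory_connectivity",
    "stimulation_protocol",
    "static_profile",
    "dynamic_profile",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class GridResult:
    """Propagation statistics over a 2-D parameter grid.

    ``fraction_propagative[i, j]`` is the fraction of non-diverged
    realizations classified propagative in cell (axis0[i], axis1[j]);
    ``delta_mean``/``delta_sd`` summarize the continuous excess rate
    Delta = nu_e - nu_Pois (used for the HH networks, where the response
    is graded rather than bistable).
    """

    axes: dict[str, np.ndarray]
    n_seeds: int
    fraction_propagative: np.ndarray
    delta_mean: np.ndarray
    delta_sd: np.ndarray
    n_diverged: np.ndarray
    config: dict = field(default_factory=dict)


@dataclass
class StimulationOutcome:
    """Effect of one Gaussian pulse condition on the propagation outcome."""

    t_peak: float
    amplitude: float
    n_initially_propagative: int
    n_initially_nonpropagative: int
    n_prevented: int
    n_triggered: int

    @property
    def frac_prevented(self) -> float:
        if self.n_initially_propagative == 0:
            return 0.0
        return self.n_prevented / self.n_initially_propagative

    @property
    def frac_triggered(self) -> float:
        if self.n_initially_nonpropagative == 0:
            return 0.0
        return self.n_triggered / self.n_initially_nonpropagative


def _run_and_classify(net, pert, duration, dt, drive_seed, pulses=()):
    result = run_simulation(net, pert, duration=duration, dt=dt,
                            pulses=pulses, drive_seed=drive_seed)
    return classify_propagation(result, pert)


def grid_perturbation(
    cfg: NetworkConfig,
    alphas=np.arange(50.0, 121.0, 10.0),
    taus=np.arange(20.0, 141.0, 20.0),
    n_seeds: int = 100,
    T1: float = 2000.0,
    T2: float = 3000.0,
    duration: float | None = None,
    dt: float = 0.1,
    master_seed: int = 0,
) -> GridResult:
    """Screen plateau amplitude against rise/decay time constant.

    For each (alpha, tau) cell, ``n_seeds`` realizations are run with
    fresh connectivity and drive seeds and classified; the propagative
    fraction and the mean/SD of the plateau rate excess are recorded.
    """
    alphas = np.asarray(alphas, float)
    taus = np.asarray(taus, float)
    if duration is None:
        duration = T2
    frac = np.zeros((alphas.size, taus.size))
    dmean = np.zeros_like(frac)
    dsd = np.zeros_like(frac)
    ndiv = np.zeros_like(frac, dtype=int)
    seeds = _child_seeds(master_seed, 2 * n_seeds * frac.size)
    it = iter(seeds)
    for i, alpha in enumerate(alphas):
        for j, tau in enumerate(taus):
            pert = PerturbationParams(alpha=float(alpha), T1=T1, T2=T2,
                                      tau_on=float(tau), tau_off=float(tau))
            deltas, labels = [], []
            for _ in range(n_seeds):
                conn_seed, drv_seed = next(it), next(it)
                net = build_network(
                    NetworkConfig(**{**cfg.to_dict(),
                                     "connectivity_seed": conn_seed}))
                try:
                    verdict = _run_and_classify(net, pert, duration, dt, drv_seed)
                except SimulationDivergedError as err:
                    logger.warning("diverged at alpha=%s tau=%s: %s",
                                   alpha, tau, err)
                    ndiv[i, j] += 1
                    continue
                deltas.append(verdict.delta_rate)
                labels.append(verdict.propagative)
            if labels:
                frac[i, j] = np.mean(labels)
                dmean[i, j] = np.mean(deltas)
                dsd[i, j] = np.std(deltas)
    return GridResult(
        axes={"alpha": alphas, "tau": taus},
        n_seeds=n_seeds, fraction_propagative=frac,
        delta_mean=dmean, delta_sd=dsd, n_diverged=ndiv,
        config={"network": cfg.to_dict(), "T1": T1, "T2": T2,
                "duration": duration, "dt": dt, "master_seed": master_seed},
    )


def grid_inhibitory_connectivity(
    cfg: NetworkConfig,
    p_ie_values=np.arange(0.04, 0.0601, 0.005),
    p_ii_values=np.arange(0.04, 0.0601, 0.005),
    alpha: float = 70.0,
    tau: float = 70.0,
    n_seeds: int = 100,
    T1: float = 2000.0,
    T2: float = 3000.0,
    duration: float | None = None,
    dt: float = 0.1,
    master_seed: int = 0,
) -> GridResult:
    """Screen the inhibitory out-probabilities p_ie (FS→RS) and p_ii (FS→FS).

    Only the two inhibitory blocks differ between cells with the same
    connectivity seed (the excitatory and external blocks come from
    independent substreams), isolating the effect of inhibition.
    """
    p_ie_values = np.asarray(p_ie_values, float)
    p_ii_values = np.asarray(p_ii_values, float)
    if duration is None:
        duration = T2
    pert = PerturbationParams(alpha=alpha, T1=T1, T2=T2,
                              tau_on=tau, tau_off=tau)
    frac = np.zeros((p_ie_values.size, p_ii_values.size))
    dmean = np.zeros_like(frac)
    dsd = np.zeros_like(frac)
    ndiv = np.zeros_like(frac, dtype=int)
    seeds = _child_seeds(master_seed, 2 * n_seeds)
    for i, p_ie in enumerate(p_ie_values):
        for j, p_ii in enumerate(p_ii_values):
            deltas, labels = [], []
            for r in range(n_seeds):
                conn_seed, drv_seed = seeds[2 * r], seeds[2 * r + 1]
                net = build_network(NetworkConfig(
                    **{**cfg.to_dict(), "p_ie": float(p_ie),
                       "p_ii": float(p_ii), "connectivity_seed": conn_seed}))
                try:
                    verdict = _run_and_classify(net, pert, duration, dt, drv_seed)
                except SimulationDivergedError as err:
                    logger.warning("diverged at p_ie=%s p_ii=%s: %s",
                                   p_ie, p_ii, err)
                    ndiv[i, j] += 1
                    continue
                deltas.append(verdict.delta_rate)
                labels.append(verdict.propagative)
            if labels:
                frac[i, j] = np.mean(labels)
                dmean[i, j] = np.mean(deltas)
                dsd[i, j] = np.std(deltas)
    return GridResult(
        axes={"p_ie": p_ie_values, "p_ii": p_ii_values},
        n_seeds=n_seeds, fraction_propagative=frac,
        delta_mean=dmean, delta_sd=dsd, n_diverged=ndiv,
        config={"network": cfg.to_dict(), "alpha": alpha, "tau": tau,
                "T1": T1, "T2": T2, "duration": duration, "dt": dt,
                "master_seed": master_seed},
    )


def stimulation_protocol(
    cfg: NetworkConfig,
    t_peaks=(1500.0, 1850.0, 1950.0, 1975.0, 2000.0, 2500.0),
    amplitudes=(1.0, 5.0, -1.0, -5.0),
    n_realizations: int = 100,
    alpha: float = 80.0,
    tau: float = 100.0,
    sigma: float = 10.0,
    T1: float = 2000.0,
    T2: float = 3000.0,
    duration: float | None = None,
    dt: float = 0.1,
    master_seed: int = 0,
    conditions: list[tuple[float, float]] | None = None,
) -> list[StimulationOutcome]:
    """Closed-loop-style control screen with Gaussian rate pulses.

    Connectivity is held fixed; for each drive seed the unstimulated
    baseline labels the realization propagative or not, then the same
    drive realization is rerun with each (t_peak, amplitude) pulse.
    Prevented events are baseline-propagative runs turned non-propagative
    by the pulse; triggered events are the converse.

    ``conditions`` — an explicit list of (t_peak, amplitude) pairs —
    replaces the full t_peaks x amplitudes cross product when given.
    """
    if duration is None:
        duration = T2
    if conditions is None:
        conditions = [(tp, a) for tp in t_peaks for a in amplitudes]
    pert = PerturbationParams(alpha=alpha, T1=T1, T2=T2,
                              tau_on=tau, tau_off=tau)
    net = build_network(cfg)
    drive_seeds = _child_seeds(master_seed, n_realizations)

    baseline: dict[int, bool] = {}
    for s in drive_seeds:
        baseline[s] = _run_and_classify(net, pert, duration, dt, s).propagative

    outcomes = []
    for t_peak, amp in conditions:
        pulse = StimulusPulse(amplitude=float(amp),
                              t_peak=float(t_peak), sigma=sigma)
        n_prev = n_trig = 0
        for s in drive_seeds:
            after = _run_and_classify(net, pert, duration, dt, s,
                                      pulses=(pulse,)).propagative
            if baseline[s] and not after:
                n_prev += 1
            elif not baseline[s] and after:
                n_trig += 1
        n_prop = sum(baseline.values())
        outcomes.append(StimulationOutcome(
            t_peak=float(t_peak), amplitude=float(amp),
            n_initially_propagative=n_prop,
            n_initially_nonpropagative=n_realizations - n_prop,
            n_prevented=n_prev, n_triggered=n_trig,
        ))
    return outcomes


def _profile_arrays(profiles, t_sel):
    keys = np.array([g.group_key for g in profiles])
    mu = np.array([g.mu_V[t_sel].mean() for g in profiles])
    R = np.array([g.R[t_sel].mean() for g in profiles])
    return keys, mu, R


def static_profile(
    cfg: NetworkConfig,
    fixed_rate: float,
    n_seeds: int = 10,
    population: str = "RS",
    duration: float = 2000.0,
    transient: float = 500.0,
    dt: float = 0.1,
    master_seed: int = 0,
):
    """Steady-state per-group mu_V and R under a constant external rate.

    Groups whose key is not realized in every seed's network are dropped
    before averaging (extreme in-degrees are too poorly represented to
    average meaningfully).  Returns (keys, mu_V, R) arrays averaged over
    post-transient time and seeds.
    """
    pert = PerturbationParams(beta=fixed_rate, alpha=0.0,
                              T1=duration + 1.0, T2=duration + 2.0)
    seeds = _child_seeds(master_seed, 2 * n_seeds)
    per_seed = []
    for r in range(n_seeds):
        net = build_network(NetworkConfig(
            **{**cfg.to_dict(), "connectivity_seed": seeds[2 * r]}))
        result = run_simulation(
            net, pert, duration=duration, dt=dt, drive_seed=seeds[2 * r + 1],
            record=RecordSpec(vm_populations=(population,)))
        groups = group_by_inhibitory_indegree(net, population)
        profiles = compute_group_profiles(result, groups, population)
        t_sel = result.vm_times >= transient
        per_seed.append(_profile_arrays(profiles, t_sel))
    common = set(per_seed[0][0].tolist())
    for keys, _, _ in per_seed[1:]:
        common &= set(keys.tolist())
    keys_out = np.array(sorted(common))
    mu_out = np.zeros(keys_out.size)
    R_out = np.zeros(keys_out.size)
    for keys, mu, R in per_seed:
        idx = np.searchsorted(keys, keys_out)
        mu_out += mu[idx]
        R_out += R[idx]
    return keys_out, mu_out / n_seeds, R_out / n_seeds


def dynamic_profile(
    cfg: NetworkConfig,
    alpha: float,
    capture_time: float = 1950.0,
    tau: float = 100.0,
    n_seeds: int = 10,
    population: str = "RS",
    T1: float = 2000.0,
    T2: float = 3000.0,
    dt: float = 0.1,
    master_seed: int = 0,
):
    """Per-group mu_V and R snapshot just before seizure onset.

    The network (fixed connectivity) is driven by the ramping
    perturbation and the group statistics are captured at
    ``capture_time`` (e.g. 1950 ms for an onset at T1 = 2000 ms),
    averaged over drive seeds.  Returns (keys, mu_V, R, mu_V standard
    error, R standard error).
    """
    pert = PerturbationParams(alpha=alpha, T1=T1, T2=T2,
                              tau_on=tau, tau_off=tau)
    net = build_network(cfg)
    groups = group_by_inhibitory_indegree(net, population)
    keys = np.array([g.group_key for g in groups])
    seeds = _child_seeds(master_seed, n_seeds)
    mus, Rs = [], []
    for s in seeds:
        result = run_simulation(
            net, pert, duration=capture_time + dt, dt=dt, drive_seed=s,
            record=RecordSpec(vm_populations=(population,)))
        profiles = compute_group_profiles(result, groups, population)
        idx = int(np.argmin(np.abs(result.vm_times - capture_time)))
        mus.append([g.mu_V[idx] for g in profiles])
        Rs.append([g.R[idx] for g in profiles])
    mus = np.asarray(mus)
    Rs = np.asarray(Rs)
    se = lambda x: x.std(axis=0, ddof=1) / np.sqrt(n_seeds) if n_seeds > 1 \
        else np.zeros(x.shape[1])
    return keys, mus.mean(axis=0), Rs.mean(axis=0), se(mus), se(Rs)
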