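"""Network time-stepping: synaptic conductances, integration, recording.

The integrator is forward Euler on the membrane equations at dt = 0.1 ms
by default, with two standard refinements for the linear subsystems:
synaptic conductances decay by the exact factor exp(-dt/tau_syn) between
spikes, and the CAdEx adaptation conductance and HH gating variables use
the exponential-Euler update (exact for the ODE linearized at the current
voltage), which is unconditionally stable and keeps gating in [0, 1].

Spikes detected in one step increment the conductances of their targets
at the next step (one-step delivery latency, no explicit axonal delay):
each presynaptic spike adds the quantal Q_E = 1.5 nS (excitatory source)
or Q_I = 5 nS (inhibitory source) to its targets.

During the absolute refractory period (integrate-and-fire models) the
membrane potential is clamped at the reset value VR while the adaptation
variable and the synaptic conductances continue to evolve; recorded V is
VR throughout the clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .drive import PerturbationParams, StimulusPulse, total_rate
from .network import Network
from .neuron_models import (AdExParams, CAdExParams, HHParams, get_preset,
                            hh_rates, hh_steady_gates)

__all__ = [
    "RecordSpec",
    "SimulationResult",
    "SimulationDivergedError",
    "run_simulation",
    "simulate_single_neuron",
]


class SimulationDivergedError(RuntimeError):
    """Raised when a membrane state becomes non-finite during a run."""

    def __init__(self, neuron: int, t: float):
        self.neuron = int(neuron)
        self.t = float(t)
        super().__init__(
            f"simulation diverged: non-finite state at neuron {neuron}, t = {t:.3f} ms"
        )


@dataclass(frozen=True)
class RecordSpec:
    """What to record besides spikes.

    ``vm_populations`` selects populations whose membrane potentials are
    sampled every ``record_dt`` ms (1 ms default, the cadence used by the
    coarse-grained membrane-potential analyses).
    """

    vm_populations: tuple[str, ...] = ()
    conductance_populations: tuple[str, ...] = ()
    record_dt: float = 1.0


@dataclass
class SimulationResult:
    """Spike trains, sampled membrane potentials and the drive trace."""

    spikes: dict[str, tuple[np.ndarray, np.ndarray]]  # pop -> (ids, times ms)
    vm: dict[str, np.ndarray]          # pop -> (n_samples, n_neurons) float32
    vm_times: np.ndarray               # sample times (ms)
    drive_times: np.ndarray            # ms
    drive_rate: np.ndarray             # commanded rate (Hz)
    duration: float                    # ms
    dt: float
    config_echo: dict
    gE_rec: dict[str, np.ndarray] = field(default_factory=dict)  # nS samples
    gI_rec: dict[str, np.ndarray] = field(default_factory=dict)

    def spike_counts(self, population: str, n_neurons: int | None = None) -> np.ndarray:
        ids, _ = self.spikes[population]
        if n_neurons is None:
            n_neurons = self.config_echo["populations"][population]
        return np.bincount(ids, minlength=n_neurons)

    def all_network_spike_times(self) -> np.ndarray:
        """Spike times of the simulated populations (RS and FS), sorted."""
        return np.sort(np.concatenate(
            [self.spikes["RS"][1], self.spikes["FS"][1]]
        ))


def _pop_param_arrays(model_kind: str, n_rs: int, n_fs: int,
                      rs_params, fs_params) -> dict[str, np.ndarray]:
    """Per-neuron parameter arrays for the concatenated [RS | FS] state."""
    def cat(field_name: str) -> np.ndarray:
        return np.concatenate([
            np.full(n_rs, getattr(rs_params, field_name), dtype=np.float64),
            np.full(n_fs, getattr(fs_params, field_name), dtype=np.float64),
        ])

    if model_kind == "adex":
        names = ["C", "gL", "EL", "VT", "DeltaT", "a", "b", "tau_w",
                 "VD", "VR", "t_ref"]
    elif model_kind == "cadex":
        names = ["C", "gL", "EL", "VT", "DeltaT", "VD", "VR", "t_ref",
                 "gA_bar", "EA", "VA", "DeltaA", "tau_A", "delta_gA"]
    elif model_kind == "hh":
        arrs = {n: cat(n) for n in ["Cm", "gL", "EL", "ENa", "EK",
                                    "VT_shift", "V_spike_detect", "lockout"]}
        arrs["gNa"] = np.concatenate([
            np.full(n_rs, rs_params.gNa_nS), np.full(n_fs, fs_params.gNa_nS)])
        arrs["gK"] = np.concatenate([
            np.full(n_rs, rs_params.gK_nS), np.full(n_fs, fs_params.gK_nS)])
        return arrs
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return {n: cat(n) for n in names}


def _hh_rates_arrays(V: np.ndarray, VT_shift: np.ndarray):
    U = V - VT_shift

    def vtrap(x, scale):
        small = np.abs(x) < 1e-9 * scale
        safe = np.where(small, 1.0, x)
        return np.where(small, scale - x / 2.0, safe / np.expm1(safe / scale))

    a_n = 0.032 * vtrap(15.0 - U, 5.0)
    b_n = 0.5 * np.exp((10.0 - U) / 40.0)
    a_m = 0.32 * vtrap(13.0 - U, 4.0)
    b_m = 0.28 * vtrap(U - 40.0, 5.0)
    a_h = 0.128 * np.exp((17.0 - U) / 18.0)
    b_h = 4.0 / (1.0 + np.exp((40.0 - U) / 5.0))
    return (a_n, b_n), (a_m, b_m), (a_h, b_h)


def run_simulation(
    net: Network,
    perturbation: PerturbationParams | None = None,
    duration: float = 4000.0,
    dt: float = 0.1,
    pulses: tuple[StimulusPulse, ...] = (),
    record: RecordSpec = RecordSpec(),
    drive_seed: int | None = None,
    rs_params=None,
    fs_params=None,
    ext_spikes: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimulationResult:
    """Advance the whole network for ``duration`` ms.

    The external population fires Poisson trains at the commanded rate
    (perturbation plus pulses, clipped at 0), thinned against one uniform
    draw per external neuron per step so that runs sharing ``drive_seed``
    but differing in the stimulus share the underlying randomness.
    Bit-reproducible given (connectivity_seed, drive_seed, dt).

    Alternatively a pre-generated external train ``ext_spikes = (ids,
    times)`` (e.g. from :func:`seizprop.drive.generate_poisson_spikes`)
    can be replayed, which keeps the drive realization fixed across
    integration step sizes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = net.config
    model_kind = cfg.model_kind
    if perturbation is None:
        perturbation = PerturbationParams()
    if drive_seed is None:
        drive_seed = cfg.drive_seed
    if rs_params is None:
        rs_params = get_preset(model_kind, "RS")
    if fs_params is None:
        fs_params = get_preset(model_kind, "FS")

    n_rs, n_fs, n_ext = net.n_rs, net.n_fs, net.n_ext
    n_net = n_rs + n_fs
    prm = _pop_param_arrays(model_kind, n_rs, n_fs, rs_params, fs_params)

    # Delivery structure: CSR over [net sources | ext sources] -> net targets.
    W_net = net.afferent_matrix("RS")
    W_fs = net.afferent_matrix("FS")
    W_ext = net.afferent_matrix("EXT")
    net_indptr = np.concatenate([W_net.indptr, W_net.nnz + W_fs.indptr[1:]])
    net_indices = np.concatenate([W_net.indices, W_fs.indices])
    ext_indptr, ext_indices = W_ext.indptr, W_ext.indices

    decay = math.exp(-dt / cfg.tau_syn)
    rng = np.random.default_rng(np.random.SeedSequence(drive_seed))

    def gather_targets(indptr, indices, src):
        """Concatenated target lists of the spiking sources (vectorized)."""
        L = indptr[src + 1] - indptr[src]
        total = int(L.sum())
        if total == 0:
            return np.empty(0, indices.dtype)
        offs = np.cumsum(L) - L
        pos = np.arange(total) - np.repeat(offs, L) + np.repeat(indptr[src], L)
        return indices[pos]

    # State (membrane starts at rest, adaptation at zero, gates at their
    # voltage-clamp steady state)
    V = prm["EL"].copy()
    gE = np.zeros(n_net)
    gI = np.zeros(n_net)
    if model_kind == "adex":
        w = np.zeros(n_net)
    elif model_kind == "cadex":
        gA = np.zeros(n_net)
    else:
        n_g = np.empty(n_net)
        m_g = np.empty(n_net)
        h_g = np.empty(n_net)
        (a_n, b_n), (a_m, b_m), (a_h, b_h) = _hh_rates_arrays(V, prm["VT_shift"])
        n_g[:] = a_n / (a_n + b_n)
        m_g[:] = a_m / (a_m + b_m)
        h_g[:] = a_h / (a_h + b_h)
        last_spike = np.full(n_net, -np.inf)
    if model_kind in ("adex", "cadex"):
        refrac = np.zeros(n_net)

    n_steps = int(round(duration / dt))
    record_every = max(1, int(round(record.record_dt / dt)))
    n_samples = n_steps // record_every + 1
    vm_store: dict[str, np.ndarray] = {}
    pop_slices = {"RS": slice(0, n_rs), "FS": slice(n_rs, n_net)}
    for pop in record.vm_populations:
        size = n_rs if pop == "RS" else n_fs
        vm_store[pop] = np.empty((n_samples, size), dtype=np.float32)
    g_store: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop in record.conductance_populations:
        size = n_rs if pop == "RS" else n_fs
        g_store[pop] = (np.empty((n_samples, size)), np.empty((n_samples, size)))
    vm_times = np.empty(n_samples)
    drive_rate_trace = np.empty(n_samples)

    spike_ids: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []
    ext_ids: list[np.ndarray] = []
    ext_times: list[np.ndarray] = []

    pend_E = np.zeros(n_net)   # conductance increments scheduled for next step
    pend_I = np.zeros(n_net)

    # commanded rate, precomputed on the step grid
    step_t = np.arange(n_steps, dtype=np.float64) * dt
    step_prob = np.asarray(
        total_rate(step_t, perturbation, pulses), dtype=np.float64) * dt * 1e-3

    if ext_spikes is not None:
        ids_in, t_in = ext_spikes
        order = np.argsort(t_in, kind="stable")
        ext_sorted_id = np.asarray(ids_in)[order]
        ext_sorted_t = np.asarray(t_in)[order]
        # partition spike times onto the step grid once: window k is
        # (k*dt, (k+1)*dt], so every spike is delivered exactly once
        grid = np.arange(n_steps + 1, dtype=np.float64) * dt
        ext_ptr = np.searchsorted(ext_sorted_t, grid, side="right")

    sample_idx = 0

    def take_sample(t: float, rate: float) -> None:
        nonlocal sample_idx
        for pop, arr in vm_store.items():
            arr[sample_idx] = V[pop_slices[pop]]
        for pop, (ge_arr, gi_arr) in g_store.items():
            ge_arr[sample_idx] = gE[pop_slices[pop]]
            gi_arr[sample_idx] = gI[pop_slices[pop]]
        vm_times[sample_idx] = t
        drive_rate_trace[sample_idx] = rate
        sample_idx += 1

    take_sample(0.0, float(total_rate(0.0, perturbation, pulses)))

    for k in range(n_steps):
        t = k * dt
        t_next = t + dt

        # (i) exact conductance decay, then deliver last step's spikes
        gE *= decay
        gI *= decay
        if pend_E.any():
            gE += pend_E
            pend_E[:] = 0.0
        if pend_I.any():
            gI += pend_I
            pend_I[:] = 0.0

        # (ii) synaptic current
        I_syn = gE * (cfg.E_E - V) + gI * (cfg.E_I - V)

        # (iii) advance membrane and auxiliary variables one step
        if model_kind == "adex":
            active = refrac <= 0.0
            arg = np.minimum((V - prm["VT"]) / prm["DeltaT"], 16.0)
            dV = (prm["gL"] * (prm["EL"] - V)
                  + prm["gL"] * prm["DeltaT"] * np.exp(arg)
                  - w + I_syn) / prm["C"]
            w += dt * (prm["a"] * (V - prm["EL"]) - w) / prm["tau_w"]
            V = np.where(active, V + dt * dV, prm["VR"])
            np.maximum(refrac - dt, 0.0, out=refrac)
            spiking = active & (V >= prm["VD"])
            if spiking.any():
                V[spiking] = prm["VR"][spiking]
                w[spiking] += prm["b"][spiking]
                refrac[spiking] = prm["t_ref"][spiking]
        elif model_kind == "cadex":
            active = refrac <= 0.0
            arg = np.minimum((V - prm["VT"]) / prm["DeltaT"], 16.0)
            dV = (prm["gL"] * (prm["EL"] - V)
                  + prm["gL"] * prm["DeltaT"] * np.exp(arg)
                  + gA * (prm["EA"] - V) + I_syn) / prm["C"]
            act = prm["gA_bar"] / (1.0 + np.exp((prm["VA"] - V) / prm["DeltaA"]))
            gA = act + (gA - act) * np.exp(-dt / prm["tau_A"])
            V = np.where(active, V + dt * dV, prm["VR"])
            np.maximum(refrac - dt, 0.0, out=refrac)
            spiking = active & (V >= prm["VD"])
            if spiking.any():
                V[spiking] = prm["VR"][spiking]
                gA[spiking] += prm["delta_gA"][spiking]
                refrac[spiking] = prm["t_ref"][spiking]
        else:  # hh
            V_prev = V
            dV = (-prm["gL"] * (V - prm["EL"])
                  - prm["gK"] * n_g**4 * (V - prm["EK"])
                  - prm["gNa"] * m_g**3 * h_g * (V - prm["ENa"])
                  + I_syn) / prm["Cm"]
            (a_n, b_n), (a_m, b_m), (a_h, b_h) = _hh_rates_arrays(V, prm["VT_shift"])
            for x, a, b in ((n_g, a_n, b_n), (m_g, a_m, b_m), (h_g, a_h, b_h)):
                tau_inv = a + b
                xinf = a / tau_inv
                x += (xinf - x) * -np.expm1(-dt * tau_inv)
            V = V + dt * dV
            spiking = ((V_prev < prm["V_spike_detect"])
                       & (V >= prm["V_spike_detect"])
                       & (t_next - last_spike > prm["lockout"]))
            if spiking.any():
                last_spike[spiking] = t_next

        if spiking.any():
            src = np.nonzero(spiking)[0]
            spike_ids.append(src.astype(np.int32))
            spike_times.append(np.full(src.size, t_next))
            exc_src = src[src < n_rs]
            inh_src = src[src >= n_rs]
            if exc_src.size:
                tgt = gather_targets(net_indptr, net_indices, exc_src)
                pend_E += cfg.Q_E * np.bincount(tgt, minlength=n_net)
            if inh_src.size:
                tgt = gather_targets(net_indptr, net_indices, inh_src)
                pend_I += cfg.Q_I * np.bincount(tgt, minlength=n_net)

        # external Poisson population (always draw, to couple realizations)
        if ext_spikes is not None:
            hits = ext_sorted_id[ext_ptr[k]:ext_ptr[k + 1]]
        else:
            hits = np.nonzero(rng.random(n_ext) < step_prob[k])[0]
        if hits.size:
            ext_ids.append(hits.astype(np.int32))
            ext_times.append(np.full(hits.size, t_next))
            tgt = gather_targets(ext_indptr, ext_indices, hits)
            if tgt.size:
                pend_E += cfg.Q_E * np.bincount(tgt, minlength=n_net)

        if (k + 1) % record_every == 0:
            if not np.isfinite(V).all():
                bad = int(np.nonzero(~np.isfinite(V))[0][0])
                raise SimulationDivergedError(bad, t_next)
            take_sample(t_next, float(total_rate(t_next, perturbation, pulses)))

    def collect(parts_ids, parts_times, offset=0, upper=None):
        if not parts_ids:
            return np.empty(0, np.int32), np.empty(0, np.float64)
        ids = np.concatenate(parts_ids)
        ts = np.concatenate(parts_times)
        if upper is not None:
            keep = (ids >= offset) & (ids < upper)
            return (ids[keep] - offset).astype(np.int32), ts[keep]
        return ids, ts

    spikes = {
        "RS": collect(spike_ids, spike_times, 0, n_rs),
        "FS": collect(spike_ids, spike_times, n_rs, n_net),
        "EXT": collect(ext_ids, ext_times),
    }
    config_echo = {
        "network": cfg.to_dict(),
        "perturbation": perturbation.to_dict(),
        "pulses": [p.to_dict() for p in pulses],
        "duration": duration,
        "dt": dt,
        "drive_seed": int(drive_seed),
        "record_dt": record.record_dt,
        "populations": {"RS": n_rs, "FS": n_fs, "EXT": n_ext},
    }
    return SimulationResult(
        spikes=spikes,
        vm={p: a[:sample_idx] for p, a in vm_store.items()},
        vm_times=vm_times[:sample_idx],
        drive_times=vm_times[:sample_idx].copy(),
        drive_rate=drive_rate_trace[:sample_idx],
        duration=duration,
        dt=dt,
        config_echo=config_echo,
        gE_rec={p: a[0][:sample_idx] for p, a in g_store.items()},
        gI_rec={p: a[1][:sample_idx] for p, a in g_store.items()},
    )


def simulate_single_neuron(
    model_kind: str,
    params,
    I_syn,
    duration: float,
    dt: float = 0.01,
    V0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one isolated neuron under an injected current.

    ``I_syn`` is either a constant (pA) or a callable of time (ms).
    Returns (times, V trace, spike times).  Used for oracle comparisons
    (inter-spike intervals against a finer-step reference) and for
    locating subthreshold fixed points empirically.
    """
    const_I = not callable(I_syn)
    n_steps = int(round(duration / dt))
    t_arr = np.arange(n_steps + 1) * dt
    V_tr = np.empty(n_steps + 1)
    spike_times = []

    if model_kind == "adex":
        p: AdExParams = params
        V, w, refrac = (V0 if V0 is not None else p.EL), 0.0, 0.0
        V_tr[0] = V
        for k in range(n_steps):
            t = k * dt
            I = I_syn if const_I else float(I_syn(t))
            if refrac > 0:
                V = p.VR
                refrac -= dt
            else:
                arg = min((V - p.VT) / p.DeltaT, 16.0)
                V += dt * (p.gL * (p.EL - V) + p.gL * p.DeltaT * math.exp(arg)
                           - w + I) / p.C
            w += dt * (p.a * (V - p.EL) - w) / p.tau_w
            if refrac <= 0 and V >= p.VD:
                V = p.VR
                w += p.b
                refrac = p.t_ref
                spike_times.append(t + dt)
            V_tr[k + 1] = V
    elif model_kind == "cadex":
        p = params
        V, gA, refrac = (V0 if V0 is not None else p.EL), 0.0, 0.0
        V_tr[0] = V
        for k in range(n_steps):
            t = k * dt
            I = I_syn if const_I else float(I_syn(t))
            act = p.gA_bar / (1.0 + math.exp((p.VA - V) / p.DeltaA))
            if refrac > 0:
                V = p.VR
                refrac -= dt
            else:
                arg = min((V - p.VT) / p.DeltaT, 16.0)
                V += dt * (p.gL * (p.EL - V) + p.gL * p.DeltaT * math.exp(arg)
                           + gA * (p.EA - V) + I) / p.C
            gA = act + (gA - act) * math.exp(-dt / p.tau_A)
            if refrac <= 0 and V >= p.VD:
                V = p.VR
                gA += p.delta_gA
                refrac = p.t_ref
                spike_times.append(t + dt)
            V_tr[k + 1] = V
    elif model_kind == "hh":
        p = params
        V = V0 if V0 is not None else p.EL
        from .neuron_models import NeuronState, hh_derivative
        n0, m0, h0 = hh_steady_gates(V, p)
        st = NeuronState(V=V, n=n0, m=m0, h=h0)
        last = -np.inf
        V_tr[0] = V
        for k in range(n_steps):
            t = k * dt
            I = I_syn if const_I else float(I_syn(t))
            dV, dn, dm, dh = hh_derivative(st, p, I)
            V_new = st.V + dt * dV
            (a_n, b_n), (a_m, b_m), (a_h, b_h) = hh_rates(st.V, p)
            def exp_euler(x, a, b):
                tot = float(a) + float(b)
                return float(a) / tot + (x - float(a) / tot) * math.exp(-dt * tot)
            st = NeuronState(
                V=V_new,
                n=min(1.0, max(0.0, exp_euler(st.n, a_n, b_n))),
                m=min(1.0, max(0.0, exp_euler(st.m, a_m, b_m))),
                h=min(1.0, max(0.0, exp_euler(st.h, a_h, b_h))),
            )
            if (V_tr[k] < p.V_spike_detect <= V_new
                    and t + dt - last > p.lockout):
                last = t + dt
                spike_times.append(t + dt)
            V_tr[k + 1] = V_new
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    return t_arr, V_tr, np.asarray(spike_times)
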