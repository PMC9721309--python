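"""Single-neuron dynamics: AdEx, CAdEx and Hodgkin–Huxley point models.

Each model is described by a parameter dataclass, a right-hand-side
function, and (for the integrate-and-fire variants) a reset rule.  The
module also carries the regular-spiking (RS, excitatory) and fast-spiking
(FS, inhibitory) presets used throughout the network simulations.

Units follow the usual conductance-based convention: mV, ms, pF, nS, pA.
With these units ``nS * mV = pA`` and ``pA / pF = mV/ms``, so no unit
conversion factors appear in the right-hand sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np

__all__ = [
    "AdExParams",
    "CAdExParams",
    "HHParams",
    "NeuronState",
    "ADEX_RS",
    "ADEX_FS",
    "CADEX_RS",
    "CADEX_FS",
    "HH_RS",
    "HH_FS",
    "PRESETS",
    "get_preset",
    "adex_derivative",
    "adex_reset",
    "cadex_derivative",
    "cadex_reset",
    "hh_derivative",
    "hh_rates",
    "detect_spike",
]

# Exponent clip for the spike-initiation term: once (V-VT)/DeltaT exceeds
# this the trajectory is committed to a spike, so capping only avoids
# floating-point overflow between threshold and the detection ceiling VD.
_EXP_CLIP = 16.0


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite value in state or parameters: {v!r}")


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire parameters.

    The membrane follows a leak plus an exponential spike-initiation term
    and is coupled to an adaptation current w:

        C dV/dt  = gL(EL - V) + gL*DeltaT*exp((V - VT)/DeltaT) - w + I_syn
        tau_w dw/dt = a (V - EL) - w

    A spike is registered when V reaches the numerical detection ceiling
    ``VD``; the membrane is then reset to ``VR``, w is incremented by ``b``
    and the neuron is refractory for ``t_ref`` ms.
    """

    C: float = 200.0        # membrane capacitance (pF)
    gL: float = 10.0        # leak conductance (nS)
    EL: float = -65.0       # leak reversal (mV)
    VT: float = -50.0       # spike-initiation threshold point (mV)
    DeltaT: float = 2.0     # spike-initiation slope factor (mV)
    a: float = 0.0          # subthreshold adaptation conductance (nS)
    b: float = 100.0        # spike-triggered adaptation increment (pA)
    tau_w: float = 1000.0   # adaptation time constant (ms)
    VD: float = -40.0       # numerical spike-detection ceiling (mV)
    VR: float = -65.0       # reset potential (mV)
    t_ref: float = 5.0      # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.gL > 0 and self.DeltaT > 0 and self.tau_w > 0):
            raise ValueError("C, gL, DeltaT and tau_w must be positive")
        if not self.VR < self.VD:
            raise ValueError("reset VR must lie below the detection ceiling VD")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class CAdExParams:
    """Conductance-based adaptive exponential integrate-and-fire parameters.

    Adaptation is a conductance gA with a sigmoidal voltage activation
    instead of the AdEx current w:

        C dV/dt   = gL(EL-V) + gL*DeltaT*exp((V-VT)/DeltaT) + gA(EA-V) + I_syn
        tau_A dgA/dt = gA_bar / (1 + exp((VA - V)/DeltaA)) - gA

    On a spike gA is incremented by ``delta_gA``.
    """

    C: float = 200.0
    gL: float = 10.0
    EL: float = -65.0
    VT: float = -50.0
    DeltaT: float = 2.0
    VD: float = -40.0
    VR: float = -65.0
    t_ref: float = 5.0
    gA_bar: float = 0.0     # maximal subthreshold adaptation conductance (nS)
    EA: float = -65.0       # adaptation reversal (mV)
    VA: float = -30.0       # adaptation half-activation voltage (mV)
    DeltaA: float = 1.0     # adaptation activation slope (mV)
    tau_A: float = 1000.0   # adaptation time constant (ms)
    delta_gA: float = 1.0   # spike-triggered conductance increment (nS)

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.gL > 0 and self.DeltaT > 0):
            raise ValueError("C, gL and DeltaT must be positive")
        if not (self.tau_A > 0 and self.DeltaA > 0):
            raise ValueError("tau_A and DeltaA must be positive")
        if self.gA_bar < 0 or self.delta_gA < 0:
            raise ValueError("gA_bar and delta_gA must be non-negative")
        if not self.VR < self.VD:
            raise ValueError("reset VR must lie below the detection ceiling VD")


@dataclass(frozen=True)
class HHParams:
    """Hodgkin–Huxley (Traub–Miles kinetics) parameters.

        Cm dV/dt = -gL(V-EL) - gK n^4 (V-EK) - gNa m^3 h (V-ENa) + I_syn

    ``conductance_unit`` records the unit of gL/gNa/gK explicitly.  The
    working defaults use micro-siemens for the active conductances (a
    point-neuron total for ~20,000 µm² of membrane); nano-siemens values
    are loadable for audit but do not produce action potentials at
    Cm = 200 pF.  Internally everything is converted to nS.

    There is no reset: spikes are counted as upward crossings of
    ``V_spike_detect`` with a ``lockout`` to avoid double counting.
    """

    Cm: float = 200.0             # pF
    gL: float = 10.0              # always nS
    gNa: float = 20.0             # in `conductance_unit`
    gK: float = 6.0               # in `conductance_unit`
    conductance_unit: Literal["uS", "nS"] = "uS"
    EL: float = -65.0
    ENa: float = 60.0
    EK: float = -90.0
    VT_shift: float = -50.0       # kinetics threshold shift (mV); -52 for FS
    V_spike_detect: float = 0.0   # upward-crossing level for spike counting (mV)
    lockout: float = 1.0          # minimum spacing between counted spikes (ms)

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        if min(self.gL, self.gNa, self.gK) < 0:
            raise ValueError("conductances must be non-negative")
        if not self.ENa > self.EK:
            raise ValueError("ENa must exceed EK")
        if self.conductance_unit not in ("uS", "nS"):
            raise ValueError("conductance_unit must be 'uS' or 'nS'")

    @property
    def gNa_nS(self) -> float:
        return self.gNa * (1000.0 if self.conductance_unit == "uS" else 1.0)

    @property
    def gK_nS(self) -> float:
        return self.gK * (1000.0 if self.conductance_unit == "uS" else 1.0)


@dataclass
class NeuronState:
    """Instantaneous state of a single neuron (model-dependent fields)."""

    V: float = -65.0              # membrane potential (mV)
    w: float = 0.0                # adaptation current (pA, AdEx)
    gA: float = 0.0               # adaptation conductance (nS, CAdEx)
    n: float = 0.0                # K activation gate (HH)
    m: float = 0.0                # Na activation gate (HH)
    h: float = 1.0                # Na inactivation gate (HH)
    refrac_remaining: float = 0.0  # ms

    def __post_init__(self) -> None:
        for x in (self.n, self.m, self.h):
            if not -1e-9 <= x <= 1 + 1e-9:
                raise ValueError("gating variables must lie in [0, 1]")
        if self.refrac_remaining < 0:
            raise ValueError("refrac_remaining must be non-negative")


# ---------------------------------------------------------------------------
# Presets (RS = regular-spiking excitatory, FS = fast-spiking inhibitory)
# ---------------------------------------------------------------------------

ADEX_RS = AdExParams()
# FS cells are non-adapting (a = b = 0), so tau_w is inert; kept positive.
ADEX_FS = AdExParams(VT=-48.0, DeltaT=0.5, b=0.0, tau_w=500.0)

CADEX_RS = CAdExParams()
CADEX_FS = CAdExParams(
    DeltaT=0.5, gA_bar=0.0, EA=-70.0, VA=-45.0, DeltaA=0.5,
    tau_A=0.01, delta_gA=0.0,
)

HH_RS = HHParams(VT_shift=-50.0)
HH_FS = HHParams(VT_shift=-52.0)

PRESETS: dict[tuple[str, str], object] = {
    ("adex", "RS"): ADEX_RS,
    ("adex", "FS"): ADEX_FS,
    ("cadex", "RS"): CADEX_RS,
    ("cadex", "FS"): CADEX_FS,
    ("hh", "RS"): HH_RS,
    ("hh", "FS"): HH_FS,
}

_PARAM_CLASSES = {"adex": AdExParams, "cadex": CAdExParams, "hh": HHParams}


def get_preset(model_kind: str, cell_class: str, **overrides):
    """Return the named parameter preset, optionally with field overrides."""
    try:
        base = PRESETS[(model_kind, cell_class)]
    except KeyError:
        raise KeyError(
            f"no preset for model {model_kind!r}, class {cell_class!r}"
        ) from None
    return replace(base, **overrides) if overrides else base


def params_to_dict(p) -> dict:
    """Flat key/value form of a parameter set (for YAML/JSON serialization)."""
    return asdict(p)


def params_from_dict(model_kind: str, d: dict):
    return _PARAM_CLASSES[model_kind](**d)


# ---------------------------------------------------------------------------
# Right-hand sides and resets
# ---------------------------------------------------------------------------

def adex_derivative(state: NeuronState, p: AdExParams, I_syn: float) -> tuple[float, float]:
    """Time derivatives (dV/dt in mV/ms, dw/dt in pA/ms) of the AdEx model."""
    _require_finite(state.V, state.w, I_syn)
    arg = min((state.V - p.VT) / p.DeltaT, _EXP_CLIP)
    dV = (p.gL * (p.EL - state.V)
          + p.gL * p.DeltaT * math.exp(arg)
          - state.w + I_syn) / p.C
    dw = (p.a * (state.V - p.EL) - state.w) / p.tau_w
    return dV, dw


def adex_reset(state: NeuronState, p: AdExParams) -> NeuronState:
    """Post-spike reset: V -> VR, w -> w + b, refractoriness armed."""
    if state.V < p.VD:
        raise ValueError("adex_reset called with V below the detection ceiling")
    return replace(state, V=p.VR, w=state.w + p.b, refrac_remaining=p.t_ref)


def cadex_derivative(state: NeuronState, p: CAdExParams, I_syn: float) -> tuple[float, float]:
    """Time derivatives (dV/dt, dgA/dt) of the CAdEx model."""
    _require_finite(state.V, state.gA, I_syn)
    arg = min((state.V - p.VT) / p.DeltaT, _EXP_CLIP)
    dV = (p.gL * (p.EL - state.V)
          + p.gL * p.DeltaT * math.exp(arg)
          + state.gA * (p.EA - state.V) + I_syn) / p.C
    act = p.gA_bar / (1.0 + math.exp((p.VA - state.V) / p.DeltaA))
    dgA = (act - state.gA) / p.tau_A
    return dV, dgA


def cadex_reset(state: NeuronState, p: CAdExParams) -> NeuronState:
    """Post-spike reset: V -> VR, gA -> gA + delta_gA, refractoriness armed."""
    if state.V < p.VD:
        raise ValueError("cadex_reset called with V below the detection ceiling")
    return replace(state, V=p.VR, gA=state.gA + p.delta_gA, refrac_remaining=p.t_ref)


# HH gating kinetics (Traub–Miles).  U = V - VT_shift.  The alpha_n and
# alpha_m rate functions have removable singularities where their
# denominators vanish; they are evaluated by the analytic limit there.

def _vtrap(x: np.ndarray | float, scale: float):
    """x / (exp(x/scale) - 1) with the removable singularity filled in.

    The limit at x -> 0 is `scale`; near zero the second-order expansion
    scale - x/2 + x^2/(12 scale) is used to keep the evaluation smooth.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9 * abs(scale)
    safe = np.where(small, 1.0, x)
    out = np.where(small, scale - x / 2.0, safe / np.expm1(safe / scale))
    return out if out.ndim else float(out)


def hh_rates(V, p: HHParams):
    """Gating rate functions alpha/beta for n, m, h at potential V (1/ms)."""
    U = np.asarray(V, dtype=float) - p.VT_shift
    a_n = 0.032 * _vtrap(15.0 - U, 5.0)
    b_n = 0.5 * np.exp((10.0 - U) / 40.0)
    a_m = 0.32 * _vtrap(13.0 - U, 4.0)
    b_m = 0.28 * _vtrap(U - 40.0, 5.0)
    a_h = 0.128 * np.exp((17.0 - U) / 18.0)
    b_h = 4.0 / (1.0 + np.exp((40.0 - U) / 5.0))
    return (a_n, b_n), (a_m, b_m), (a_h, b_h)


def hh_derivative(state: NeuronState, p: HHParams, I_syn: float) -> tuple[float, float, float, float]:
    """Time derivatives (dV/dt, dn/dt, dm/dt, dh/dt) of the HH model."""
    _require_finite(state.V, I_syn)
    tol = 1e-9
    for x in (state.n, state.m, state.h):
        if not -tol <= x <= 1 + tol:
            raise ValueError("gating variable outside [0, 1]")
    V, n, m, h = state.V, state.n, state.m, state.h
    dV = (-p.gL * (V - p.EL)
          - p.gK_nS * n**4 * (V - p.EK)
          - p.gNa_nS * m**3 * h * (V - p.ENa)
          + I_syn) / p.Cm
    (a_n, b_n), (a_m, b_m), (a_h, b_h) = hh_rates(V, p)
    return (dV,
            float(a_n) * (1 - n) - float(b_n) * n,
            float(a_m) * (1 - m) - float(b_m) * m,
            float(a_h) * (1 - h) - float(b_h) * h)


def hh_steady_gates(V: float, p: HHParams) -> tuple[float, float, float]:
    """Voltage-clamp steady-state gating values x_inf = alpha/(alpha+beta)."""
    (a_n, b_n), (a_m, b_m), (a_h, b_h) = hh_rates(V, p)
    return (float(a_n / (a_n + b_n)),
            float(a_m / (a_m + b_m)),
            float(a_h / (a_h + b_h)))


def detect_spike(model_kind: str, V_prev: float, V_now: float, p) -> bool:
    """Spike test for one integration step.

    Integrate-and-fire models spike when V reaches the detection ceiling
    VD; the HH model spikes on an upward crossing of ``V_spike_detect``
    (the lockout against double counting is enforced by the caller that
    tracks time).
    """
    if model_kind in ("adex", "cadex"):
        return V_now >= p.VD
    if model_kind == "hh":
        return V_prev < p.V_spike_detect <= V_now
    raise ValueError(f"unknown model kind {model_kind!r}")
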