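"""Seeded simulator of membranes, synaptic responses, cohorts and anatomy.

The membrane model is a two-variable linear subthreshold system with an
adaptation/resonance current and a pasted stereotyped spike::

    C  dV/dt = -g_L (V - E_L) - a w + I(t)
    tau_w dw/dt = (V - E_L) - w

with C in pF, conductances in nS, voltages in mV, currents in pA and time in
ms.  For ``a > 0`` the second variable produces sag on hyperpolarizing steps
and subthreshold resonance; the effective (steady-state) input resistance is
``1 / (g_L + a)``.  When V crosses the spike threshold a stereotyped
template waveform is pasted and the voltage is reset, so action-potential
threshold, amplitude and duration have exact ground truth.

The subthreshold system is integrated exactly for zero-order-hold input via
the matrix exponential of the 2x2 system (implemented as two first-order
recursions with :func:`scipy.signal.lfilter`); smooth stimuli are sampled at
step midpoints so the discretisation error is second order.  Recording
noise is modelled as an additive Ornstein-Uhlenbeck process on the recorded
voltage.

Synaptic responses are injected as calibrated difference-of-exponential
current kernels: each component (fast/slow EPSP, GABA_A-like fast IPSP,
GABA_B-like slow IPSP) is scaled so that, alone on the noise-free membrane,
its somatic peak equals the requested amplitude.

Closed-form companions (`analytic_impedance`, `analytic_step_response`,
`analytic_psp_response`) provide independent oracles for the simulated
traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .recordings import (
    DEFAULT_TIME_STEP_MS,
    CellClass,
    CellRecord,
    Cohort,
    Layer,
    ProtocolKind,
    StimulusProtocol,
    Sweep,
)

__all__ = [
    "MembraneParams",
    "PSPComponent",
    "SynapseParams",
    "ClassSpec",
    "CohortConfig",
    "CellGroundTruth",
    "CohortGroundTruth",
    "LayerGeometry",
    "simulate_membrane",
    "simulate_membrane_events",
    "analytic_impedance",
    "analytic_step_response",
    "analytic_psp_response",
    "psp_calibration_scale",
    "simulate_evoked",
    "generate_cohort",
    "default_cohort_config",
    "generate_puncta",
    "default_layer_geometry",
    "generate_intensity_profile",
    "build_current",
    "RESPONSE_CLASSES",
]

RESPONSE_CLASSES = ("none", "suprathreshold", "excitatory", "inhibitory", "biphasic")

COMPONENT_NAMES = ("epsp_fast", "epsp_slow", "ipsp_fast", "ipsp_slow")


@dataclass(frozen=True)
class MembraneParams:
    """Parameters of the two-variable subthreshold membrane + spike template."""

    C_pF: float = 150.0
    g_L_nS: float = 7.5
    E_L_mV: float = -65.0
    a_nS: float = 0.0  # resonance-current gain
    tau_w_ms: float = 25.0  # resonance-current time constant
    V_T_mV: float = -42.0  # spike threshold
    V_r_mV: float = -55.0  # post-spike reset
    ap_peak_mV: float = 30.0
    ap_rise_ms: float = 0.5
    ap_fall_ms: float = 1.0
    noise_sd_mV: float = 0.0
    noise_tau_ms: float = 5.0

    def __post_init__(self) -> None:
        if min(self.C_pF, self.g_L_nS, self.tau_w_ms) <= 0:
            raise ValueError("C, g_L and tau_w must be > 0")
        if self.a_nS < 0:
            raise ValueError("a must be >= 0")
        if self.V_T_mV <= self.E_L_mV:
            raise ValueError("spike threshold must exceed the leak reversal")
        if self.noise_sd_mV < 0 or self.noise_tau_ms <= 0:
            raise ValueError("noise_sd >= 0 and noise_tau > 0 required")

    @property
    def tau_m_ms(self) -> float:
        """Passive membrane time constant C / g_L."""
        return self.C_pF / self.g_L_nS

    @property
    def input_resistance_MOhm(self) -> float:
        """Steady-state input resistance 1/(g_L + a), in MOhm."""
        return 1000.0 / (self.g_L_nS + self.a_nS)


@dataclass(frozen=True)
class PSPComponent:
    """One synaptic response component as a difference-of-exponentials kernel.

    ``amplitude_mV`` is the somatic peak the component should reach alone on
    the noise-free membrane: positive for excitatory, negative for
    inhibitory components.
    """

    amplitude_mV: float
    rise_ms: float
    decay_ms: float
    latency_ms: float
    train_scaling: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("decay must exceed rise")
        if self.latency_ms < 0:
            raise ValueError("latency must be >= 0")


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic input: a mapping of component name -> PSPComponent.

    Component names come from :data:`COMPONENT_NAMES`.  Excitatory
    components must have amplitude >= 0, inhibitory <= 0, and the fast IPSP
    latency must exceed the fast EPSP latency (disynaptic feedforward path).
    """

    components: Mapping[str, PSPComponent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, comp in self.components.items():
            if name not in COMPONENT_NAMES:
                raise ValueError(f"unknown synaptic component {name!r}")
            if name.startswith("epsp") and comp.amplitude_mV < 0:
                raise ValueError(f"{name}: excitatory amplitude must be >= 0")
            if name.startswith("ipsp") and comp.amplitude_mV > 0:
                raise ValueError(f"{name}: inhibitory amplitude must be <= 0")
        e = self.components.get("epsp_fast")
        i = self.components.get("ipsp_fast")
        if e is not None and i is not None and not (i.latency_ms > e.latency_ms):
            raise ValueError("fast IPSP latency must exceed fast EPSP latency")

    def active(self) -> Dict[str, PSPComponent]:
        return {k: c for k, c in self.components.items() if c.amplitude_mV != 0.0}


# ---------------------------------------------------------------------------
# Linear-system machinery
# ---------------------------------------------------------------------------


def _system_matrices(p: MembraneParams) -> Tuple[np.ndarray, np.ndarray]:
    A = np.array(
        [
            [-p.g_L_nS / p.C_pF, -p.a_nS / p.C_pF],
            [1.0 / p.tau_w_ms, -1.0 / p.tau_w_ms],
        ]
    )
    B = np.array([1.0 / p.C_pF, 0.0])
    return A, B


def _eig(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam, Vm = np.linalg.eig(A)
    # Guard against a defective pair (e.g. a=0 with tau_m == tau_w): nudge.
    if np.linalg.cond(Vm) > 1e8:
        lam, Vm = np.linalg.eig(A * (1.0 + 1e-9) + np.diag([0.0, 1e-12]))
    return lam, Vm, np.linalg.inv(Vm)


class _Discretized:
    """Exact zero-order-hold discretisation of dx/dt = A x + B u."""

    def __init__(self, p: MembraneParams, dt: float):
        A, B = _system_matrices(p)
        lam, Vm, Vinv = _eig(A)
        self.lam_d = np.exp(lam * dt)  # discrete eigenvalues
        self.Vm = Vm
        self.Vinv = Vinv
        # modal input weights: Vinv @ (A^-1 (Ad - I) B) done per mode:
        # for mode i, contribution c_i = (Vinv B)_i * (e^{lam dt} - 1) / lam
        vb = Vinv @ B
        self.c = vb * (self.lam_d - 1.0) / lam

    def run(self, u: np.ndarray, x0: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Propagate x_{k+1} = Ad x_k + Bd u_k; returns (x_path[2, n], x_end).

        ``x_path[:, k]`` is the state at sample k, with ``x_path[:, 0] = x0``.
        """
        n = len(u)
        y0 = self.Vinv @ x0.astype(complex)
        y = np.empty((2, n), dtype=complex)
        powers = None
        for i in range(2):
            lam = self.lam_d[i]
            w = lfilter([self.c[i]], [1.0, -lam], u.astype(complex))
            if powers is None:
                k = np.arange(n)
            yi = np.empty(n, dtype=complex)
            yi[0] = y0[i]
            if n > 1:
                hom = y0[i] * np.exp(np.log(lam) * np.arange(1, n)) if lam != 0 else 0.0
                yi[1:] = w[:-1] + hom
            y[i] = yi
        x_path = self.Vm @ y
        return x_path.real, x_path[:, -1].real


def build_current(
    protocol: StimulusProtocol, n_samples: int, time_step: float
) -> np.ndarray:
    """Command-current trace (pA) for a protocol, sampled at step midpoints."""
    t = (np.arange(n_samples) + 0.5) * time_step
    I = np.zeros(n_samples)
    kind = protocol.kind
    on = protocol.onset_ms
    if kind is ProtocolKind.CURRENT_STEP:
        amp = protocol.param("amplitude_pA")
        dur = protocol.param("duration_ms")
        I[(t >= on) & (t < on + dur)] = amp
    elif kind is ProtocolKind.CURRENT_RAMP:
        slope = protocol.param("slope_pA_per_s") / 1000.0  # pA per ms
        dur = protocol.param("duration_ms")
        mask = (t >= on) & (t < on + dur)
        I[mask] = slope * (t[mask] - on)
    elif kind is ProtocolKind.ZAP:
        f0 = protocol.param("f0_hz")
        f1 = protocol.param("f1_hz")
        dur = protocol.param("duration_ms")
        amp = protocol.param("amplitude_pA")
        mask = (t >= on) & (t < on + dur)
        ts = (t[mask] - on) / 1000.0  # seconds
        T = dur / 1000.0
        phase = 2.0 * np.pi * (f0 * ts + (f1 - f0) * ts**2 / (2.0 * T))
        I[mask] = amp * np.sin(phase)
    elif kind is ProtocolKind.PAIRED_AP:
        amp = protocol.param("amplitude_pA")
        width = protocol.param("pulse_width_ms")
        I[(t >= on) & (t < on + width)] = amp
    # opto_pulse / opto_train / none inject no somatic current
    return I


def _spike_template(p: MembraneParams, dt: float) -> np.ndarray:
    n_rise = max(1, int(round(p.ap_rise_ms / dt)))
    n_fall = max(1, int(round(p.ap_fall_ms / dt)))
    rise = np.linspace(p.V_T_mV, p.ap_peak_mV, n_rise + 1)[1:]
    fall = np.linspace(p.ap_peak_mV, p.V_r_mV, n_fall + 1)[1:]
    return np.concatenate([rise, fall])


def _ou_noise(
    n: int, dt: float, sd: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    alpha = math.exp(-dt / tau)
    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - alpha**2)
    innov[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -alpha], innov)


def _simulate_core(
    params: MembraneParams,
    current: np.ndarray,
    time_step: float,
    rng: Optional[np.random.Generator],
    allow_spikes: bool = True,
) -> Tuple[np.ndarray, List[float]]:
    """Integrate the membrane; returns (voltage trace mV, spike times ms)."""
    n = len(current)
    disc = _Discretized(params, time_step)
    template = _spike_template(params, time_step)
    V = np.empty(n)
    spikes: List[float] = []
    x = np.zeros(2)  # (V - E_L, w), start at rest
    # integrate in bounded chunks so that a spike only discards the tail of
    # its own chunk (keeps many-spike sweeps linear in sweep length)
    chunk = 20000
    i = 0
    while i < n:
        stop_chunk = n if not allow_spikes else min(i + chunk, n)
        x_path, x_end = disc.run(current[i:stop_chunk], x)
        v_seg = x_path[0] + params.E_L_mV
        if allow_spikes:
            above = np.nonzero(v_seg >= params.V_T_mV)[0]
        else:
            above = np.array([], dtype=int)
        if len(above) == 0:
            V[i:stop_chunk] = v_seg
            x = x_end
            i = stop_chunk
            continue
        k = int(above[0])
        V[i : i + k + 1] = v_seg[: k + 1]
        V[i + k] = params.V_T_mV  # clamp crossing sample to threshold
        spikes.append((i + k) * time_step)
        stop = min(i + k + 1 + len(template), n)
        V[i + k + 1 : stop] = template[: stop - (i + k + 1)]
        x = np.array([params.V_r_mV - params.E_L_mV, x_path[1, k]])
        i = stop
    if rng is not None and params.noise_sd_mV > 0:
        V = V + _ou_noise(n, time_step, params.noise_sd_mV, params.noise_tau_ms, rng)
    return V, spikes


def _check_protocol_fits(protocol: StimulusProtocol, duration_ms: float) -> None:
    end = protocol.onset_ms
    p = protocol.parameters
    if "duration_ms" in p:
        end += float(p["duration_ms"])
    if protocol.kind is ProtocolKind.OPTO_TRAIN:
        end += float(p.get("n_pulses", 10)) * 1000.0 / float(p["frequency_hz"])
    if end > duration_ms:
        raise ValueError(
            f"protocol extends to {end} ms but sweep duration is {duration_ms} ms"
        )


def simulate_membrane_events(
    params: MembraneParams,
    protocol: StimulusProtocol,
    duration_ms: float,
    seed: int,
    time_step: float = DEFAULT_TIME_STEP_MS,
    cell_id: str = "",
    condition: str = "baseline",
    sweep_index: int = 0,
) -> Tuple[Sweep, List[float]]:
    """Simulate one sweep; also return the true spike (threshold) times in ms."""
    _check_protocol_fits(protocol, duration_ms)
    n = int(round(duration_ms / time_step)) + 1
    current = build_current(protocol, n, time_step)
    rng = np.random.default_rng(seed)
    V, spikes = _simulate_core(params, current, time_step, rng)
    sweep = Sweep(
        time_step=time_step,
        voltage=V,
        current=current,
        protocol=protocol,
        sweep_index=sweep_index,
        cell_id=cell_id,
        condition=condition,
    )
    return sweep, spikes


def simulate_membrane(
    params: MembraneParams,
    protocol: StimulusProtocol,
    duration_ms: float,
    seed: int,
    **kwargs,
) -> Sweep:
    """Simulate the membrane response to a stimulus protocol.

    Deterministic given ``seed``; with zero noise and no stimulus the trace
    sits at ``E_L``.
    """
    sweep, _ = simulate_membrane_events(params, protocol, duration_ms, seed, **kwargs)
    return sweep


# ---------------------------------------------------------------------------
# Closed-form oracles
# ---------------------------------------------------------------------------


def analytic_impedance(params: MembraneParams, freq_hz) -> np.ndarray | float:
    """Subthreshold impedance magnitude |Z(f)| in MOhm.

    Z(w) = (1 + i w tau_w) / ((g_L + i w C)(1 + i w tau_w) + a), with the
    angular frequency in rad/ms so that C (pF) / ms carries units of nS.
    At f = 0 this reduces to 1/(g_L + a); for a = 0 it is a one-pole
    low-pass, monotonically decreasing in frequency.
    """
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    w = 2.0 * np.pi * f / 1000.0  # rad per ms
    num = 1.0 + 1j * w * params.tau_w_ms
    den = (params.g_L_nS + 1j * w * params.C_pF) * num + params.a_nS
    z = np.abs(num / den) * 1000.0  # 1/nS = GOhm -> MOhm
    return float(z) if np.isscalar(freq_hz) else z


def _expm_apply(lam, Vm, Vinv, v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """e^{A t} v for a vector of times; returns array (2, len(t))."""
    y0 = Vinv @ v.astype(complex)
    modes = np.exp(np.outer(lam, t)) * y0[:, None]
    return (Vm @ modes).real


def analytic_step_response(
    params: MembraneParams, amplitude_pA: float, t_ms: np.ndarray
) -> np.ndarray:
    """Closed-form voltage deflection (mV) after a current step at t = 0."""
    A, B = _system_matrices(params)
    t = np.asarray(t_ms, dtype=float)
    x_ss = -np.linalg.solve(A, B * amplitude_pA)  # steady state
    dev = _expm_apply(*_eig(A), -x_ss, t)  # e^{At}(x0 - x_ss), x0 = 0
    return dev[0] + x_ss[0]


def analytic_psp_response(
    params: MembraneParams,
    component: PSPComponent,
    t_ms: np.ndarray,
    scale_pA: float = 1.0,
) -> np.ndarray:
    """Closed-form deflection (mV) to a difference-of-exponentials current.

    The injected current is ``scale_pA * (exp(-s/decay) - exp(-s/rise))``
    for ``s = t - latency >= 0``.  Solved by superposing the particular
    solutions of the two exponential drives (partial fractions), entirely
    independent of the discrete-time simulation path.
    """
    A, B = _system_matrices(params)
    lam, Vm, Vinv = _eig(A)
    t = np.asarray(t_ms, dtype=float)
    s = t - component.latency_ms
    out = np.zeros((2, len(s)))
    active = s >= 0
    sa = s[active]
    x0_part = np.zeros(2)
    parts = []
    for tau, sign in ((component.decay_ms, 1.0), (component.rise_ms, -1.0)):
        M = A + np.eye(2) / tau
        xp0 = -np.linalg.solve(M, B * scale_pA * sign)
        parts.append((tau, xp0))
        x0_part += xp0
    hom = _expm_apply(lam, Vm, Vinv, -x0_part, sa)
    total = hom
    for tau, xp0 in parts:
        total = total + xp0[:, None] * np.exp(-sa / tau)[None, :]
    out[:, active] = total
    return out[0]


# ---------------------------------------------------------------------------
# Evoked-response simulation
# ---------------------------------------------------------------------------


def _unit_kernel(
    comp: PSPComponent, onsets_ms: Sequence[float], scalings: Sequence[float],
    n: int, dt: float,
) -> np.ndarray:
    t = (np.arange(n) + 0.5) * dt
    out = np.zeros(n)
    for onset, scaling in zip(onsets_ms, scalings):
        s = t - (onset + comp.latency_ms)
        mask = s >= 0
        out[mask] += scaling * (
            np.exp(-s[mask] / comp.decay_ms) - np.exp(-s[mask] / comp.rise_ms)
        )
    return out


def psp_calibration_scale(params: MembraneParams, comp: PSPComponent,
                          time_step: float = DEFAULT_TIME_STEP_MS) -> float:
    """Current scale (pA) at which the component's somatic peak equals its
    requested amplitude on the noise-free membrane."""
    if comp.amplitude_mV == 0:
        return 0.0
    horizon = comp.latency_ms + 10.0 * comp.decay_ms
    n = int(round(horizon / time_step)) + 1
    kernel = _unit_kernel(comp, [0.0], [1.0], n, time_step)
    V, _ = _simulate_core(
        replace(params, noise_sd_mV=0.0), kernel, time_step, None, allow_spikes=False
    )
    peak = np.max(np.abs(V - params.E_L_mV))
    return comp.amplitude_mV / peak


def _pulse_onsets(protocol: StimulusProtocol) -> List[float]:
    if protocol.kind is ProtocolKind.OPTO_PULSE:
        return [protocol.onset_ms]
    if protocol.kind is ProtocolKind.OPTO_TRAIN:
        freq = protocol.param("frequency_hz")
        n_pulses = int(protocol.param("n_pulses"))
        period = 1000.0 / freq
        return [protocol.onset_ms + k * period for k in range(n_pulses)]
    raise ValueError(f"not an optogenetic protocol: {protocol.kind.value}")


def simulate_evoked(
    membrane: MembraneParams,
    synapse: SynapseParams,
    protocol: StimulusProtocol,
    n_sweeps: int,
    seed: int,
    duration_ms: Optional[float] = None,
    time_step: float = DEFAULT_TIME_STEP_MS,
    cell_id: str = "",
    condition: str = "baseline",
) -> Tuple[List[Sweep], Dict[str, float]]:
    """Simulate optogenetically evoked sweeps for one cell x condition.

    Returns the sweeps plus a ground-truth record of the calibrated current
    scale per component.  Deterministic per seed; each sweep gets an
    independent noise realisation.
    """
    onsets = _pulse_onsets(protocol)
    if duration_ms is None:
        duration_ms = onsets[-1] + 500.0
    n = int(round(duration_ms / time_step)) + 1
    current = np.zeros(n)
    truth: Dict[str, float] = {}
    n_pulses = len(onsets)
    for name, comp in synapse.active().items():
        if protocol.kind is ProtocolKind.OPTO_TRAIN:
            scalings = comp.train_scaling or tuple([1.0] * n_pulses)
            if len(scalings) != n_pulses:
                raise ValueError(
                    f"{name}: train_scaling length {len(scalings)} != "
                    f"pulse count {n_pulses}"
                )
        else:
            scalings = (1.0,)
        scale = psp_calibration_scale(membrane, comp, time_step)
        current += scale * _unit_kernel(comp, onsets, scalings, n, time_step)
        truth[f"scale_{name}_pA"] = scale
    sweeps = []
    seeds = np.random.SeedSequence(seed).spawn(n_sweeps)
    for idx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        V, _ = _simulate_core(membrane, current, time_step, rng)
        sweeps.append(
            Sweep(
                time_step=time_step,
                voltage=V,
                current=np.zeros(n),  # light stimulus, no injected current
                protocol=protocol,
                sweep_index=idx,
                cell_id=cell_id,
                condition=condition,
            )
        )
    return sweeps, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """Study-design parameters for one cell class."""

    n: int
    response_mix: Mapping[str, float]
    epsp_amp_median_mV: float = 4.0
    epsp_amp_log_sd: float = 0.5
    ipsp_amp_median_mV: float = 2.0
    ipsp_amp_log_sd: float = 0.5
    ei_alpha: float = 3.2
    ei_beta: float = 2.6
    epsp_latency_mean_ms: float = 2.0
    epsp_latency_sd_ms: float = 0.3
    ipsp_fast_extra_latency_ms: float = 1.5
    ipsp_slow_extra_latency_ms: float = 5.0
    ipsp_train_growth: float = 1.0  # IPSP scaling at the last train pulse
    has_slow_ipsp: bool = True
    #: range of the fast (GABA_A-like) share of the total IPSP amplitude
    ipsp_fast_fraction: Tuple[float, float] = (0.6, 0.85)
    membrane_kind: str = "pyramidal"  # 'stellate' (resonant) or 'pyramidal'

    def __post_init__(self) -> None:
        total = float(sum(self.response_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"response mixture weights sum to {total}, not 1")
        for cls in self.response_mix:
            if cls not in RESPONSE_CLASSES:
                raise ValueError(f"unknown response class {cls!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    classes: Mapping[CellClass, ClassSpec]
    noise_sd_mV: float = 0.2
    noise_tau_ms: float = 5.0
    n_opto_sweeps: int = 10
    train_frequencies_hz: Tuple[float, ...] = (10.0,)
    n_train_pulses: int = 10
    include_intrinsic: bool = False
    #: set False to draw cells and ground truth without simulating sweeps
    simulate_sweeps: bool = True
    zap_duration_ms: float = 20000.0
    ml_range_um: Tuple[float, float] = (0.0, 900.0)
    dv_range_mm: Tuple[float, float] = (2.9, 4.3)
    time_step_ms: float = DEFAULT_TIME_STEP_MS
    opto_onset_ms: float = 520.0
    train_onset_ms: float = 1010.0


@dataclass
class CellGroundTruth:
    cell_class: CellClass
    response_class: str
    membrane: MembraneParams
    synapse: SynapseParams
    ei_ratio: Optional[float]
    epsp_amp_mV: float
    ipsp_amp_mV: float  # magnitude
    ml_distance_um: float
    dv_depth_mm: float
    kernel_scales: Dict[str, float] = field(default_factory=dict)


@dataclass
class CohortGroundTruth:
    cells: Dict[str, CellGroundTruth] = field(default_factory=dict)


def default_cohort_config(
    scale: float = 1.0,
    noise_sd_mV: float = 0.2,
    include_intrinsic: bool = False,
    train_frequencies_hz: Tuple[float, ...] = (10.0,),
) -> CohortConfig:
    """Study-design defaults emulating the recorded cohort.

    Response-class mixtures follow the reported per-class counts (e.g. for
    layer-2 stellate cells: 21 unresponsive, 2 suprathreshold, and
    biphasic/excitatory/inhibitory subthreshold responses in roughly
    56/27/5 proportion out of 111 cells).  ``scale`` multiplies every class
    count (rounded, minimum 1 for nonzero classes) so the same design can be
    run at reduced size.
    """

    def mix(**kw):
        total = sum(kw.values())
        return {k: v / total for k, v in kw.items()}

    def n_of(count: int) -> int:
        if count == 0:
            return 0
        return max(1, int(round(count * scale)))

    classes = {
        CellClass.L2_SC: ClassSpec(
            n=n_of(111),
            response_mix=mix(none=21, suprathreshold=2, biphasic=56,
                             excitatory=27, inhibitory=5),
            epsp_amp_median_mV=3.5,
            ei_alpha=1.6,
            ei_beta=1.3,  # mean ~0.55, broad (heterogeneous, spans 0-1)
            ipsp_train_growth=1.5,
            ipsp_fast_fraction=(0.5, 0.75),  # prominent slow GABA_B component
            membrane_kind="stellate",
        ),
        CellClass.L2_PC: ClassSpec(
            n=n_of(47),
            response_mix=mix(none=10, suprathreshold=2, biphasic=19, excitatory=16),
            epsp_amp_median_mV=6.0,
            ei_alpha=14.0,
            ei_beta=4.4,  # mean ~0.76, narrow (excitation-biased)
            epsp_latency_mean_ms=2.6,
            ipsp_fast_fraction=(0.85, 0.98),  # little slow inhibition
            membrane_kind="pyramidal",
        ),
        CellClass.L3_PC: ClassSpec(
            n=n_of(23),
            response_mix=mix(none=11, biphasic=5, excitatory=7),
            epsp_amp_median_mV=2.5,
            epsp_latency_mean_ms=4.0,
            ei_alpha=6.0,
            ei_beta=3.0,
            membrane_kind="pyramidal",
        ),
        CellClass.L5A_PC: ClassSpec(
            n=n_of(11),
            response_mix=mix(none=9, biphasic=1, excitatory=1),
            epsp_amp_median_mV=2.0,
            epsp_latency_mean_ms=4.5,
            membrane_kind="pyramidal",
        ),
        CellClass.L5B_PC: ClassSpec(
            n=n_of(5),
            response_mix=mix(none=4, excitatory=1),
            epsp_amp_median_mV=2.0,
            epsp_latency_mean_ms=4.5,
            membrane_kind="pyramidal",
        ),
        CellClass.L1_IN: ClassSpec(
            n=n_of(17),
            response_mix=mix(suprathreshold=4, excitatory=13),
            epsp_amp_median_mV=5.0,
            has_slow_ipsp=False,
            membrane_kind="pyramidal",
        ),
        CellClass.L2_IN_FS: ClassSpec(
            n=n_of(30),
            response_mix=mix(none=5, suprathreshold=5, excitatory=20),
            epsp_amp_median_mV=5.0,
            has_slow_ipsp=False,
            membrane_kind="pyramidal",
        ),
        CellClass.L2_IN_LTS: ClassSpec(
            n=n_of(12),
            response_mix=mix(none=5, suprathreshold=2, excitatory=4, biphasic=1),
            epsp_amp_median_mV=4.0,
            has_slow_ipsp=False,
            membrane_kind="pyramidal",
        ),
    }
    return CohortConfig(
        classes=classes,
        noise_sd_mV=noise_sd_mV,
        include_intrinsic=include_intrinsic,
        train_frequencies_hz=train_frequencies_hz,
    )


def _draw_membrane(kind: str, rng: np.random.Generator,
                   noise_sd: float, noise_tau: float) -> MembraneParams:
    jitter = lambda v: v * rng.uniform(0.85, 1.15)
    E_L = float(np.clip(rng.normal(-65.0, 2.5), -75.0, -53.0))
    if kind == "stellate":
        return MembraneParams(
            C_pF=jitter(200.0), g_L_nS=jitter(8.0), E_L_mV=E_L,
            a_nS=jitter(4.0), tau_w_ms=jitter(25.0),
            V_T_mV=E_L + 23.0, V_r_mV=E_L - 5.0,
            noise_sd_mV=noise_sd, noise_tau_ms=noise_tau,
        )
    return MembraneParams(
        C_pF=jitter(150.0), g_L_nS=jitter(6.5), E_L_mV=E_L,
        a_nS=0.0, tau_w_ms=25.0,
        V_T_mV=E_L + 23.0, V_r_mV=E_L - 5.0,
        noise_sd_mV=noise_sd, noise_tau_ms=noise_tau,
    )


def _draw_synapse(
    spec: ClassSpec, response_class: str, rng: np.random.Generator,
    n_train_pulses: int, membrane: MembraneParams,
) -> Tuple[SynapseParams, Optional[float], float, float]:
    """Draw synaptic parameters for one cell; returns (synapse, true E-I
    ratio, EPSP amplitude, IPSP magnitude)."""
    lat_e = float(np.clip(
        rng.normal(spec.epsp_latency_mean_ms, spec.epsp_latency_sd_ms), 0.5, 10.0))
    epsp = ipsp = 0.0
    ei: Optional[float] = None
    # Amplitudes are clipped into [1.2, 9] mV: comfortably above the 0.5 mV
    # detection floor and below the range where the stellate rebound current
    # or component cancellation would change the apparent response class.
    amp_clip = (1.2, 8.0)
    if response_class == "suprathreshold":
        epsp = (membrane.V_T_mV - membrane.E_L_mV) * rng.uniform(1.2, 1.6)
    elif response_class == "excitatory":
        epsp = float(np.clip(rng.lognormal(math.log(spec.epsp_amp_median_mV),
                                           spec.epsp_amp_log_sd), *amp_clip))
        ei = 1.0
    elif response_class == "inhibitory":
        ipsp = float(np.clip(rng.lognormal(math.log(spec.ipsp_amp_median_mV),
                                           spec.ipsp_amp_log_sd), *amp_clip))
        ei = 0.0
    elif response_class == "biphasic":
        epsp = float(np.clip(rng.lognormal(math.log(spec.epsp_amp_median_mV),
                                           spec.epsp_amp_log_sd), *amp_clip))
        # E-I ratio drawn per cell, kept away from degenerate endpoints
        ei = float(np.clip(rng.beta(spec.ei_alpha, spec.ei_beta), 0.2, 0.8))
        # the IPSP must stay detectable under the overlapping EPSP: keep it
        # above both 2 mV and ~30% of the EPSP amplitude
        ipsp = float(np.clip(epsp * (1.0 - ei) / ei,
                             max(2.0, 0.3 * epsp), amp_clip[1]))
        ei = epsp / (epsp + ipsp)
    components: Dict[str, PSPComponent] = {}
    growth_end = (
        rng.uniform(max(1.0, spec.ipsp_train_growth - 0.2),
                    spec.ipsp_train_growth + 0.2)
        if spec.ipsp_train_growth > 1.0
        else 1.0
    )
    growth = np.linspace(1.0, growth_end, n_train_pulses)
    if epsp > 0:
        components["epsp_fast"] = PSPComponent(
            amplitude_mV=epsp, rise_ms=0.6, decay_ms=8.0, latency_ms=lat_e,
            train_scaling=tuple([1.0] * n_train_pulses),
        )
    if ipsp > 0:
        # fast GABA_A-like and (optionally) slow GABA_B-like components
        frac_fast = (
            float(rng.uniform(*spec.ipsp_fast_fraction))
            if spec.has_slow_ipsp
            else 1.0
        )
        # the fast IPSP kernel outlasts the EPSP kernel, as the GABA_A
        # conductance outlasts the AMPA current; with current kernels both
        # tails otherwise decay at the membrane time constant and a larger
        # EPSP would mask the inhibitory dip entirely
        components["ipsp_fast"] = PSPComponent(
            amplitude_mV=-ipsp * frac_fast, rise_ms=2.5, decay_ms=45.0,
            latency_ms=lat_e + spec.ipsp_fast_extra_latency_ms,
            train_scaling=tuple(growth),
        )
        if spec.has_slow_ipsp and frac_fast < 1.0:
            components["ipsp_slow"] = PSPComponent(
                amplitude_mV=-ipsp * (1.0 - frac_fast), rise_ms=50.0,
                decay_ms=180.0,
                latency_ms=lat_e + spec.ipsp_slow_extra_latency_ms,
                train_scaling=tuple(growth),
            )
    return SynapseParams(components=components), ei, epsp, ipsp


def generate_cohort(
    config: CohortConfig, seed: int
) -> Tuple[Cohort, CohortGroundTruth]:
    """Generate a synthetic cohort with per-cell ground truth.

    Class counts are exact (sampling happens only within class); the
    response class of each cell is drawn from the configured mixture.
    Deterministic per (config, seed).
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    cells: List[CellRecord] = []
    sweeps: Dict[str, List[Sweep]] = {}
    truth = CohortGroundTruth()
    class_names = list(RESPONSE_CLASSES)
    counter = 0
    for cell_class, spec in config.classes.items():
        probs = np.array([spec.response_mix.get(c, 0.0) for c in class_names])
        for _ in range(spec.n):
            counter += 1
            cell_id = f"c{counter:04d}"
            cell_seed = np.random.SeedSequence([seed, counter])
            crng = np.random.default_rng(cell_seed)
            response_class = class_names[int(crng.choice(len(class_names), p=probs))]
            membrane = _draw_membrane(
                spec.membrane_kind, crng, config.noise_sd_mV, config.noise_tau_ms
            )
            synapse, ei, epsp, ipsp = _draw_synapse(
                spec, response_class, crng, config.n_train_pulses, membrane
            )
            ml = float(crng.uniform(*config.ml_range_um))
            dv = float(crng.uniform(*config.dv_range_mm))
            record = CellRecord(
                cell_id=cell_id,
                cell_class=cell_class,
                ml_distance_um=ml,
                dv_depth_mm=dv,
                resting_vm_mV=membrane.E_L_mV,
                series_resistance_MOhm=float(crng.uniform(8.0, 30.0)),
            )
            cells.append(record)
            if not config.simulate_sweeps:
                truth.cells[cell_id] = CellGroundTruth(
                    cell_class=cell_class,
                    response_class=response_class,
                    membrane=membrane,
                    synapse=synapse,
                    ei_ratio=ei,
                    epsp_amp_mV=epsp,
                    ipsp_amp_mV=ipsp,
                    ml_distance_um=ml,
                    dv_depth_mm=dv,
                )
                continue
            cell_sweeps: List[Sweep] = []
            # single-pulse opto sweeps
            pulse_protocol = StimulusProtocol(
                kind=ProtocolKind.OPTO_PULSE,
                onset_ms=config.opto_onset_ms,
                parameters={"pulse_width_ms": 3.0},
            )
            swps, scales = simulate_evoked(
                membrane, synapse, pulse_protocol, config.n_opto_sweeps,
                seed=int(crng.integers(2**31)),
                duration_ms=config.opto_onset_ms + 600.0,
                time_step=config.time_step_ms, cell_id=cell_id,
            )
            cell_sweeps.extend(swps)
            # train sweeps
            for freq in config.train_frequencies_hz:
                train_protocol = StimulusProtocol(
                    kind=ProtocolKind.OPTO_TRAIN,
                    onset_ms=config.train_onset_ms,
                    parameters={
                        "pulse_width_ms": 3.0,
                        "frequency_hz": freq,
                        "n_pulses": config.n_train_pulses,
                    },
                )
                period = 1000.0 / freq
                tr, _ = simulate_evoked(
                    membrane, synapse, train_protocol, 1,
                    seed=int(crng.integers(2**31)),
                    duration_ms=config.train_onset_ms
                    + config.n_train_pulses * period + 250.0,
                    time_step=config.time_step_ms, cell_id=cell_id,
                )
                cell_sweeps.extend(tr)
            if config.include_intrinsic:
                cell_sweeps.extend(
                    _intrinsic_sweeps(membrane, config, crng, cell_id)
                )
            sweeps[cell_id] = cell_sweeps
            truth.cells[cell_id] = CellGroundTruth(
                cell_class=cell_class,
                response_class=response_class,
                membrane=membrane,
                synapse=synapse,
                ei_ratio=ei,
                epsp_amp_mV=epsp,
                ipsp_amp_mV=ipsp,
                ml_distance_um=ml,
                dv_depth_mm=dv,
                kernel_scales=scales,
            )
    return Cohort(cells=cells, sweeps=sweeps), truth


def _intrinsic_sweeps(
    membrane: MembraneParams, config: CohortConfig,
    rng: np.random.Generator, cell_id: str,
) -> List[Sweep]:
    out = []
    step = StimulusProtocol(
        kind=ProtocolKind.CURRENT_STEP, onset_ms=500.0,
        parameters={"amplitude_pA": -80.0, "duration_ms": 3000.0},
    )
    s, _ = simulate_membrane_events(
        membrane, step, 4000.0, int(rng.integers(2**31)),
        time_step=config.time_step_ms, cell_id=cell_id,
    )
    out.append(s)
    ramp = StimulusProtocol(
        kind=ProtocolKind.CURRENT_RAMP, onset_ms=200.0,
        parameters={"slope_pA_per_s": 50.0, "duration_ms": 3000.0},
    )
    s, _ = simulate_membrane_events(
        membrane, ramp, 3400.0, int(rng.integers(2**31)),
        time_step=config.time_step_ms, cell_id=cell_id,
    )
    out.append(s)
    # chirp amplitude set for a small (~<= 5 mV) subthreshold excursion
    amp = min(5.0 / (analytic_impedance(membrane, 0.5) / 1000.0), 200.0)
    zap = StimulusProtocol(
        kind=ProtocolKind.ZAP, onset_ms=500.0,
        parameters={
            "f0_hz": 0.5, "f1_hz": 20.0,
            "duration_ms": config.zap_duration_ms, "amplitude_pA": amp,
        },
    )
    s, _ = simulate_membrane_events(
        membrane, zap, config.zap_duration_ms + 1000.0,
        int(rng.integers(2**31)),
        time_step=config.time_step_ms, cell_id=cell_id,
    )
    out.append(s)
    return out


# ---------------------------------------------------------------------------
# Anatomy generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerGeometry:
    """Stack of layer slabs along the depth axis, with mediolateral and
    z (slice-depth) extents in micrometres.

    ``x`` is mediolateral distance from the parasubiculum border, ``y`` is
    laminar depth from the pia (layer 1 first), ``z`` is depth within the
    slice/stack.
    """

    layers: Tuple[Tuple[Layer, float], ...]
    ml_extent_um: float = 900.0
    z_extent_um: float = 1000.0

    def __post_init__(self) -> None:
        if any(width <= 0 for _, width in self.layers):
            raise ValueError("layer widths must be > 0")
        if self.ml_extent_um <= 0 or self.z_extent_um <= 0:
            raise ValueError("extents must be > 0")

    def layer_bounds(self) -> Dict[Layer, Tuple[float, float]]:
        bounds = {}
        y = 0.0
        for layer, width in self.layers:
            bounds[Layer(layer)] = (y, y + width)
            y += width
        return bounds


def default_layer_geometry() -> LayerGeometry:
    return LayerGeometry(
        layers=(
            (Layer.L1, 100.0),
            (Layer.L2, 150.0),
            (Layer.L3, 250.0),
            (Layer.L5A, 150.0),
            (Layer.L5B, 250.0),
        )
    )


def generate_puncta(
    geometry: LayerGeometry,
    rates_per_mm3: Mapping[Layer, float],
    ml_gradient: Optional[Sequence[float]] = None,
    seed: int = 0,
    bin_width_um: float = 150.0,
) -> Tuple[pd.DataFrame, Dict]:
    """Sample a layered 3-D Poisson puncta field.

    Within each layer-slab x mediolateral-bin cell the process is
    homogeneous Poisson with intensity ``rate * gradient[bin]`` (per mm^3).
    Returns a table with columns x_um, y_um, z_um, intensity.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(math.ceil(geometry.ml_extent_um / bin_width_um))
    if ml_gradient is None:
        ml_gradient = [1.0] * n_bins
    ml_gradient = list(ml_gradient)
    if len(ml_gradient) < n_bins:
        raise ValueError("ml_gradient shorter than the number of bins")
    rows = []
    for layer, (y0, y1) in geometry.layer_bounds().items():
        rate = float(rates_per_mm3.get(layer, 0.0))
        if rate < 0:
            raise ValueError(f"negative rate for layer {layer.value}")
        for b in range(n_bins):
            x0 = b * bin_width_um
            x1 = min((b + 1) * bin_width_um, geometry.ml_extent_um)
            vol_mm3 = (x1 - x0) * (y1 - y0) * geometry.z_extent_um * 1e-9
            lam = rate * ml_gradient[b] * vol_mm3
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            xs = rng.uniform(x0, x1, count)
            ys = rng.uniform(y0, y1, count)
            zs = rng.uniform(0.0, geometry.z_extent_um, count)
            inten = rng.uniform(80.0, 255.0, count)
            rows.append(
                np.column_stack([xs, ys, zs, inten])
            )
    if rows:
        data = np.concatenate(rows)
    else:
        data = np.empty((0, 4))
    table = pd.DataFrame(data, columns=["x_um", "y_um", "z_um", "intensity"])
    truth = {
        "rates_per_mm3": {Layer(k).value: float(v) for k, v in rates_per_mm3.items()},
        "ml_gradient": [float(g) for g in ml_gradient],
        "geometry": geometry,
    }
    return table, truth


def generate_intensity_profile(
    peak_pos_um: float,
    width_um: float,
    baseline: float,
    amplitude: float,
    noise_sd: float,
    n_points: int,
    seed: int = 0,
    extent_um: float = 600.0,
) -> Tuple[pd.DataFrame, Dict]:
    """Noisy Gaussian-bump laminar fluorescence profile, gray values in
    [0, 255]."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, extent_um, n_points)
    clean = baseline + amplitude * np.exp(-0.5 * ((x - peak_pos_um) / width_um) ** 2)
    raw = np.clip(clean + rng.normal(0.0, noise_sd, n_points), 0.0, 255.0)
    table = pd.DataFrame({"position_um": x, "intensity": raw})
    truth = {
        "peak_pos_um": float(peak_pos_um),
        "width_um": float(width_um),
        "baseline": float(baseline),
        "amplitude": float(amplitude),
    }
    return table, truth
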