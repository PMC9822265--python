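"""Sub- and suprathreshold intrinsic membrane properties from current-clamp
sweeps.

Measurements follow the standard current-clamp definitions: input
resistance from the steady-state deflection of a hyperpolarizing step,
membrane time constant as the time to reach 1 - 1/e (~63%) of the
steady-state change, sag as the peak-to-steady deflection ratio, rheobase
from the first spike on a depolarizing ramp, spike threshold from the
1 mV/ms derivative criterion, and subthreshold resonance from the FFT
impedance spectrum of a ZAP (swept-sine) response.

Windows: the baseline is the mean of the 200 ms before stimulus onset and
the steady state is the mean of the last 500 ms of the step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .recordings import ProtocolKind, Sweep

__all__ = [
    "APEvent",
    "ImpedanceSpectrum",
    "ResonanceResult",
    "IntrinsicProfile",
    "ContaminationError",
    "IndeterminateError",
    "input_resistance",
    "membrane_tau",
    "sag_ratio",
    "rheobase",
    "detect_aps",
    "ap_features",
    "impedance_spectrum",
    "resonance_frequency",
    "extract_intrinsic_profile",
    "BASELINE_WINDOW_MS",
    "STEADY_WINDOW_MS",
    "AP_DERIVATIVE_CRITERION_MV_PER_MS",
]

BASELINE_WINDOW_MS = 200.0
STEADY_WINDOW_MS = 500.0
#: Spike threshold: first point where dV/dt exceeds 1 mV/ms.
AP_DERIVATIVE_CRITERION_MV_PER_MS = 1.0
#: A derivative-criterion crossing only counts as a spike if the voltage
#: reaches at least this peak within AP_PEAK_WINDOW_MS (rejects fast PSPs).
AP_PEAK_FLOOR_MV = -20.0
AP_PEAK_WINDOW_MS = 2.0
AP_REFRACTORY_MS = 2.0
TAU_FRACTION = 1.0 - 1.0 / np.e  # 0.6321...


class ContaminationError(ValueError):
    """Spikes contaminate a subthreshold measurement window."""


class IndeterminateError(ValueError):
    """The measurement is undefined for this trace (e.g. no deflection)."""


@dataclass(frozen=True)
class APEvent:
    threshold_time_ms: float
    threshold_vm_mV: float
    peak_time_ms: float
    peak_vm_mV: float


@dataclass(frozen=True)
class ImpedanceSpectrum:
    frequency_hz: np.ndarray
    magnitude_MOhm: np.ndarray  # boxcar-smoothed (0.5 Hz)
    raw_magnitude_MOhm: np.ndarray


@dataclass(frozen=True)
class ResonanceResult:
    frequency_hz: float
    resonant: bool  # False when the peak sits at the low edge of the band


@dataclass
class IntrinsicProfile:
    """Intrinsic properties of one cell."""

    resting_vm_mV: Optional[float] = None
    input_resistance_MOhm: Optional[float] = None
    tau_m_ms: Optional[float] = None
    sag_ratio: Optional[float] = None
    rheobase_pA: Optional[float] = None
    ap_threshold_mV: Optional[float] = None
    ap_amplitude_mV: Optional[float] = None
    ap_duration_ms: Optional[float] = None
    resonance_freq_hz: Optional[float] = None
    resonant: Optional[bool] = None


# ---------------------------------------------------------------------------
# Step-response measurements
# ---------------------------------------------------------------------------


def _step_params(sweep: Sweep) -> Tuple[float, float, float]:
    if sweep.protocol.kind is not ProtocolKind.CURRENT_STEP:
        raise ValueError(f"expected a current_step sweep, got {sweep.protocol.kind.value}")
    amp = sweep.protocol.param("amplitude_pA")
    dur = sweep.protocol.param("duration_ms")
    if amp == 0:
        raise ValueError("step amplitude must be nonzero")
    return sweep.protocol.onset_ms, amp, dur


def _window_mean(sweep: Sweep, t0: float, t1: float) -> float:
    i0 = max(0, sweep.index_at(t0))
    i1 = min(sweep.n_samples, sweep.index_at(t1))
    if i1 <= i0:
        raise ValueError(f"empty window [{t0}, {t1}) ms")
    return float(np.mean(sweep.voltage[i0:i1]))


def _baseline(sweep: Sweep, onset: float) -> float:
    return _window_mean(sweep, max(0.0, onset - BASELINE_WINDOW_MS), onset)


def _steady(sweep: Sweep, onset: float, duration: float) -> float:
    return _window_mean(sweep, onset + duration - STEADY_WINDOW_MS, onset + duration)


def _check_no_spikes(sweep: Sweep, t0: float, t1: float) -> None:
    for ev in detect_aps(sweep):
        if t0 <= ev.threshold_time_ms < t1:
            raise ContaminationError(
                f"spike at {ev.threshold_time_ms:.2f} ms contaminates the window"
            )


def input_resistance(sweep: Sweep) -> float:
    """Input resistance (MOhm) from a hyperpolarizing current step.

    Rin = (steady-state voltage - baseline voltage) / step amplitude,
    reported as a positive value; 1 mV/pA = 1 GOhm.
    """
    onset, amp, dur = _step_params(sweep)
    if amp < 0:
        _check_no_spikes(sweep, onset - BASELINE_WINDOW_MS, onset + dur)
    dv = _steady(sweep, onset, dur) - _baseline(sweep, onset)
    return abs(dv / amp) * 1000.0


def membrane_tau(sweep: Sweep) -> float:
    """Membrane time constant (ms): time for the step response to reach
    63.21% (1 - 1/e) of its steady-state change, linearly interpolated."""
    onset, amp, dur = _step_params(sweep)
    if amp < 0:
        _check_no_spikes(sweep, onset - BASELINE_WINDOW_MS, onset + dur)
    base = _baseline(sweep, onset)
    steady = _steady(sweep, onset, dur)
    dv_ss = steady - base
    if abs(dv_ss) < 0.5:
        raise IndeterminateError("steady-state change < 0.5 mV")
    i0 = sweep.index_at(onset)
    i1 = min(sweep.n_samples, sweep.index_at(onset + dur))
    frac = (sweep.voltage[i0:i1] - base) / dv_ss
    target = TAU_FRACTION
    above = np.nonzero(frac >= target)[0]
    if len(above) == 0:
        raise IndeterminateError("response never reaches 63% of steady state")
    k = int(above[0])
    if k < 2:
        warnings.warn("63% reached within 2 samples of onset; tau is at the "
                      "resolution limit")
    if k == 0:
        t_cross = 0.0
    else:
        f0, f1 = frac[k - 1], frac[k]
        t_cross = (k - 1 + (target - f0) / (f1 - f0)) * sweep.time_step
    return float(t_cross + (i0 * sweep.time_step - onset))


def sag_ratio(sweep: Sweep) -> float:
    """Sag ratio: peak hyperpolarization / steady-state hyperpolarization
    (both relative to baseline) on a hyperpolarizing step; >= 1 when sag is
    present, ~1 for a passive membrane."""
    onset, amp, dur = _step_params(sweep)
    if amp >= 0:
        raise ValueError("sag is measured on hyperpolarizing steps")
    _check_no_spikes(sweep, onset - BASELINE_WINDOW_MS, onset + dur)
    base = _baseline(sweep, onset)
    steady = _steady(sweep, onset, dur)
    if base - steady < 0.5:
        raise IndeterminateError("steady-state change < 0.5 mV")
    i0 = sweep.index_at(onset)
    i1 = min(sweep.n_samples, sweep.index_at(onset + dur))
    v_min = float(np.min(sweep.voltage[i0:i1]))
    return (base - v_min) / (base - steady)


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------


def detect_aps(sweep: Sweep) -> List[APEvent]:
    """Detect action potentials.

    Threshold is the first sample in each suprathreshold excursion where the
    centred-difference dV/dt exceeds 1 mV/ms; the candidate is accepted only
    if the voltage reaches at least -20 mV within 2 ms (this rejects large,
    fast PSPs which can also satisfy the derivative criterion).  Events are
    separated by a 2 ms refractory period and one event is returned per
    excursion above that event's own threshold voltage.
    """
    v = sweep.voltage
    dt = sweep.time_step
    dv = np.empty_like(v)
    dv[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    dv[0] = (v[1] - v[0]) / dt
    dv[-1] = (v[-1] - v[-2]) / dt
    candidates = np.nonzero(dv > AP_DERIVATIVE_CRITERION_MV_PER_MS)[0]
    peak_win = max(1, int(round(AP_PEAK_WINDOW_MS / dt)))
    refractory = int(round(AP_REFRACTORY_MS / dt))
    events: List[APEvent] = []
    blocked_until = -1
    for i in candidates:
        if i <= blocked_until:
            continue
        seg = v[i : i + peak_win + 1]
        k_peak = int(np.argmax(seg))
        if seg[k_peak] < AP_PEAK_FLOOR_MV:
            continue
        peak_idx = i + k_peak
        thr_vm = float(v[i])
        events.append(
            APEvent(
                threshold_time_ms=i * dt,
                threshold_vm_mV=thr_vm,
                peak_time_ms=peak_idx * dt,
                peak_vm_mV=float(v[peak_idx]),
            )
        )
        # skip the rest of this excursion (until V falls back below
        # threshold) plus a refractory gap
        j = peak_idx
        while j < len(v) and v[j] >= thr_vm:
            j += 1
        blocked_until = max(j, peak_idx + refractory)
    return events


def ap_features(event: APEvent, sweep: Sweep) -> Tuple[float, float]:
    """(amplitude mV, duration ms) of one action potential.

    Amplitude is peak minus threshold voltage; duration is the width at the
    threshold voltage (time between the upward and downward crossings, with
    linear interpolation).
    """
    amplitude = event.peak_vm_mV - event.threshold_vm_mV
    v = sweep.voltage
    dt = sweep.time_step
    i_peak = int(round(event.peak_time_ms / dt))
    thr = event.threshold_vm_mV
    below = np.nonzero(v[i_peak:] < thr)[0]
    if len(below) == 0:
        raise ValueError("trace ends before the spike repolarises to threshold")
    k = i_peak + int(below[0])
    # interpolate the downward crossing between samples k-1 and k
    t_down = (k - 1 + (v[k - 1] - thr) / (v[k - 1] - v[k])) * dt
    duration = t_down - event.threshold_time_ms
    return float(amplitude), float(duration)


def rheobase(sweep: Sweep) -> Optional[float]:
    """Rheobase (pA) from a depolarizing current ramp: the injected current
    at the time of the first action potential.  Returns None when the ramp
    stays subthreshold."""
    if sweep.protocol.kind is not ProtocolKind.CURRENT_RAMP:
        raise ValueError("rheobase requires a current_ramp sweep")
    slope = sweep.protocol.param("slope_pA_per_s")
    onset = sweep.protocol.onset_ms
    events = detect_aps(sweep)
    events = [e for e in events if e.threshold_time_ms >= onset]
    if not events:
        return None
    return slope * (events[0].threshold_time_ms - onset) / 1000.0


# ---------------------------------------------------------------------------
# Impedance / resonance
# ---------------------------------------------------------------------------

IMPEDANCE_SMOOTHING_HZ = 0.5


def impedance_spectrum(sweep: Sweep) -> ImpedanceSpectrum:
    """Impedance magnitude spectrum |Z|(f) from a ZAP sweep.

    |Z| = |FFT(V - mean V)| / |FFT(I - mean I)| restricted to the chirp
    band, smoothed with a 0.5 Hz boxcar.  Raises ContaminationError when
    spikes are present.
    """
    if sweep.protocol.kind is not ProtocolKind.ZAP:
        raise ValueError("impedance requires a zap sweep")
    if detect_aps(sweep):
        raise ContaminationError("spikes present in ZAP sweep")
    f0 = sweep.protocol.param("f0_hz")
    f1 = sweep.protocol.param("f1_hz")
    v = sweep.voltage - np.mean(sweep.voltage)
    i = sweep.current - np.mean(sweep.current)
    fv = np.fft.rfft(v)
    fi = np.fft.rfft(i)
    freqs = np.fft.rfftfreq(len(v), d=sweep.time_step / 1000.0)
    band = (freqs >= f0) & (freqs <= f1)
    if not np.any(band):
        raise ValueError("chirp band contains no FFT bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.abs(fv[band]) / np.abs(fi[band]) * 1000.0  # GOhm -> MOhm
    df = freqs[1] - freqs[0]
    width = max(1, int(round(IMPEDANCE_SMOOTHING_HZ / df)))
    kernel = np.ones(width)
    # edge-aware boxcar: divide by the number of in-band bins under the window
    smooth = np.convolve(raw, kernel, mode="same") / np.convolve(
        np.ones_like(raw), kernel, mode="same"
    )
    return ImpedanceSpectrum(
        frequency_hz=freqs[band], magnitude_MOhm=smooth, raw_magnitude_MOhm=raw
    )


def resonance_frequency(spectrum: ImpedanceSpectrum) -> ResonanceResult:
    """Frequency of the peak of the smoothed impedance magnitude.

    Ties break toward the lower frequency; a peak at the low edge of the
    band is flagged non-resonant (low-pass membrane).
    """
    if len(spectrum.frequency_hz) == 0:
        raise ValueError("empty spectrum")
    k = int(np.argmax(spectrum.magnitude_MOhm))
    return ResonanceResult(
        frequency_hz=float(spectrum.frequency_hz[k]), resonant=k > 0
    )


# ---------------------------------------------------------------------------
# Convenience per-cell extraction
# ---------------------------------------------------------------------------


def extract_intrinsic_profile(
    step_sweep: Optional[Sweep] = None,
    ramp_sweep: Optional[Sweep] = None,
    zap_sweep: Optional[Sweep] = None,
) -> IntrinsicProfile:
    """Assemble an IntrinsicProfile from whichever protocol sweeps exist."""
    profile = IntrinsicProfile()
    if step_sweep is not None:
        onset = step_sweep.protocol.onset_ms
        profile.resting_vm_mV = _baseline(step_sweep, onset)
        profile.input_resistance_MOhm = input_resistance(step_sweep)
        profile.tau_m_ms = membrane_tau(step_sweep)
        try:
            profile.sag_ratio = sag_ratio(step_sweep)
        except (ValueError, IndeterminateError):
            pass
    if ramp_sweep is not None:
        profile.rheobase_pA = rheobase(ramp_sweep)
        events = detect_aps(ramp_sweep)
        if events:
            amp, dur = ap_features(events[0], ramp_sweep)
            profile.ap_threshold_mV = events[0].threshold_vm_mV
            profile.ap_amplitude_mV = amp
            profile.ap_duration_ms = dur
    if zap_sweep is not None:
        spec = impedance_spectrum(zap_sweep)
        res = resonance_frequency(spec)
        profile.resonance_freq_hz = res.frequency_hz
        profile.resonant = res.resonant
    return profile
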