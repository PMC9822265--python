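"""Measurement and classification of optogenetically evoked responses.

The averaged trace of repeated sweeps is reduced to an EPSP amplitude (peak
depolarisation, a centred 1 ms mean around the extremum), an IPSP amplitude
(magnitude of the peak hyperpolarisation, sought after the EPSP peak when
both components exist), a 10%-rise latency, a half-width, a response
classification (none / suprathreshold / excitatory / inhibitory /
biphasic), and an excitation-inhibition ratio

    E-I ratio = EPSP / (EPSP + |IPSP|)  in [0, 1],

where 1 is pure excitation, 0 pure inhibition, 0.5 balance.  Baseline is
the mean of the 490 ms before stimulus onset excluding the final 10 ms
(990 ms for trains).  Latency and half-width are reported only for
responses of at least 1 mV, and are measured on the averaged trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intrinsic import detect_aps
from .recordings import ProtocolKind, StimulusProtocol, Sweep

__all__ = [
    "EvokedResponse",
    "TrainResponse",
    "PairedResult",
    "baseline_vm",
    "average_sweeps",
    "measure_evoked",
    "ei_ratio",
    "classify_response",
    "measure_train",
    "paired_connectivity",
    "condition_contrast",
    "MIN_REPORTABLE_AMPLITUDE_MV",
    "DETECTION_FLOOR_MV",
]

#: Latency / half-width are reported only when the governing component
#: reaches this amplitude.
MIN_REPORTABLE_AMPLITUDE_MV = 1.0
#: A component "exists" for classification when its amplitude exceeds
#: max(DETECTION_FLOOR_MV, 3 x the noise SD of the averaged baseline).
DETECTION_FLOOR_MV = 0.5
#: Single-pulse response search window after stimulus onset.
RESPONSE_WINDOW_MS = 500.0
#: A response is suprathreshold if any individual sweep spikes within this
#: window after stimulus onset.
SUPRATHRESHOLD_WINDOW_MS = 50.0
PEAK_MEAN_WINDOW_MS = 1.0


@dataclass
class EvokedResponse:
    cell_id: str
    condition: str
    baseline_vm_mV: float
    epsp_amp_mV: float  # >= 0, peak depolarisation
    ipsp_amp_mV: float  # >= 0, magnitude of peak hyperpolarisation
    classification: str
    ei_ratio: Optional[float]
    latency_ms: Optional[float]
    half_width_ms: Optional[float]
    n_sweeps_averaged: int


@dataclass
class TrainResponse:
    cell_id: str
    frequency_hz: float
    baseline_vm_mV: float
    epsp_amp_mV: np.ndarray  # per pulse
    ipsp_amp_mV: np.ndarray
    ei_ratio: np.ndarray  # NaN where undefined

    @property
    def n_pulses(self) -> int:
        return len(self.epsp_amp_mV)


@dataclass
class PairedResult:
    pre_cell: str
    post_cell: str
    connected: bool
    ipsp_amp_mV: float
    half_width_ms: Optional[float]


def baseline_vm(sweep: Sweep, protocol: Optional[StimulusProtocol] = None) -> float:
    """Pre-stimulus baseline membrane potential.

    Mean over [onset-500, onset-10) ms for single-pulse protocols and
    [onset-1000, onset-10) ms for trains; the 10 ms immediately before the
    stimulus are always excluded.
    """
    protocol = protocol or sweep.protocol
    span = 1000.0 if protocol.kind is ProtocolKind.OPTO_TRAIN else 500.0
    onset = protocol.onset_ms
    if onset < span:
        raise ValueError(
            f"baseline needs {span} ms before onset; onset is at {onset} ms"
        )
    i0 = sweep.index_at(onset - span)
    i1 = sweep.index_at(onset - 10.0)
    return float(np.mean(sweep.voltage[i0:i1]))


def average_sweeps(sweeps: Sequence[Sweep]) -> Sweep:
    """Pointwise mean trace of repeated sweeps of the same protocol."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.n_samples != first.n_samples or s.time_step != first.time_step:
            raise ValueError("sweeps differ in length or sampling")
        if s.protocol.kind is not first.protocol.kind:
            raise ValueError("sweeps differ in protocol")
    return Sweep(
        time_step=first.time_step,
        voltage=np.mean([s.voltage for s in sweeps], axis=0),
        current=np.mean([s.current for s in sweeps], axis=0),
        protocol=first.protocol,
        sweep_index=0,
        cell_id=first.cell_id,
        condition=first.condition,
    )


def _smooth_1ms(v: np.ndarray, dt: float) -> np.ndarray:
    """Centred 1 ms boxcar mean (the '1 ms window at peak' of the averaged
    trace)."""
    width = max(1, int(round(PEAK_MEAN_WINDOW_MS / dt)))
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width) / width
    return np.convolve(v, kernel, mode="same")


def ei_ratio(epsp_amp: float, ipsp_amp: float) -> float:
    """Excitation-inhibition ratio E/(E+|I|), in [0, 1]."""
    if epsp_amp < 0 or ipsp_amp < 0:
        raise ValueError("amplitudes must be non-negative magnitudes")
    total = epsp_amp + ipsp_amp
    if total <= 0:
        raise ValueError("E-I ratio undefined when both amplitudes are zero")
    return epsp_amp / total


def classify_response(
    epsp_amp: float,
    ipsp_amp: float,
    suprathreshold: bool,
    baseline_noise_sd: float = 0.0,
) -> str:
    """Classify a response from its component amplitudes.

    A component exists when its amplitude >= max(0.5 mV, 3 x the noise SD
    of the averaged baseline).  A spike in any individual sweep dominates.
    """
    if epsp_amp < 0 or ipsp_amp < 0:
        raise ValueError("amplitudes must be non-negative magnitudes")
    if suprathreshold:
        return "suprathreshold"
    floor = max(DETECTION_FLOOR_MV, 3.0 * baseline_noise_sd)
    has_e = epsp_amp >= floor
    has_i = ipsp_amp >= floor
    if has_e and has_i:
        return "biphasic"
    if has_e:
        return "excitatory"
    if has_i:
        return "inhibitory"
    return "none"


def _component_extrema(
    smoothed: np.ndarray, baseline: float, i0: int, i1: int,
    floor: float = DETECTION_FLOOR_MV,
) -> Tuple[float, int, float, int]:
    """(epsp_amp, epsp_idx, ipsp_amp, ipsp_idx) within [i0, i1).

    The depolarising peak is sought first; when it is large enough to count
    as a component the hyperpolarising trough is sought after it (the EPSP
    precedes the disynaptic IPSP); otherwise the trough is sought over the
    whole window so that a noise maximum cannot hide a pure IPSP.
    """
    window = smoothed[i0:i1]
    k_max = int(np.argmax(window))
    epsp = max(0.0, float(window[k_max] - baseline))
    trough_from = k_max if epsp >= floor else 0
    k_min = trough_from + int(np.argmin(window[trough_from:]))
    ipsp = max(0.0, float(baseline - window[k_min]))
    return epsp, i0 + k_max, ipsp, i0 + k_min


def _latency(
    smoothed: np.ndarray,
    dt: float,
    onset_idx: int,
    search_end: int,
    baseline: float,
    peak_amp: float,
    positive: bool,
) -> Optional[float]:
    """Time from onset to a 10%-of-peak deviation from baseline."""
    target = 0.1 * peak_amp
    seg = smoothed[onset_idx:search_end] - baseline
    dev = seg if positive else -seg
    above = np.nonzero(dev >= target)[0]
    if len(above) == 0:
        return None
    k = int(above[0])
    if k == 0:
        return 0.0
    frac = (target - dev[k - 1]) / (dev[k] - dev[k - 1])
    return (k - 1 + frac) * dt


def _half_width(
    smoothed: np.ndarray,
    dt: float,
    peak_idx: int,
    baseline: float,
    positive: bool,
) -> Optional[float]:
    """Width at half the peak deflection, linear interpolation at the
    crossings."""
    dev = (smoothed - baseline) if positive else (baseline - smoothed)
    half = dev[peak_idx] / 2.0
    if half <= 0:
        return None
    left = None
    for k in range(peak_idx, 0, -1):
        if dev[k - 1] < half <= dev[k]:
            left = (k - 1 + (half - dev[k - 1]) / (dev[k] - dev[k - 1])) * dt
            break
    right = None
    for k in range(peak_idx, len(dev) - 1):
        if dev[k] >= half > dev[k + 1]:
            right = (k + (dev[k] - half) / (dev[k] - dev[k + 1])) * dt
            break
    if left is None or right is None:
        return None
    return right - left


def _baseline_noise_sd(sweep: Sweep, onset: float, span: float) -> float:
    i0 = sweep.index_at(max(0.0, onset - span))
    i1 = sweep.index_at(onset - 10.0)
    return float(np.std(sweep.voltage[i0:i1]))


def measure_evoked(
    sweeps: Sequence[Sweep],
    protocol: Optional[StimulusProtocol] = None,
) -> EvokedResponse:
    """Measure a single-pulse evoked response from repeated sweeps.

    Amplitudes, latency and half-width are read from the averaged trace;
    spikes are detected on the individual sweeps (a response is
    suprathreshold if any sweep spikes within 50 ms of the stimulus).
    """
    avg = average_sweeps(sweeps)
    protocol = protocol or avg.protocol
    if protocol.kind is not ProtocolKind.OPTO_PULSE:
        raise ValueError("measure_evoked expects an opto_pulse protocol")
    onset = protocol.onset_ms
    base = baseline_vm(avg, protocol)
    smoothed = _smooth_1ms(avg.voltage, avg.time_step)
    i0 = avg.index_at(onset) + 1
    i1 = min(avg.n_samples, avg.index_at(onset + RESPONSE_WINDOW_MS) + 1)
    if i1 <= i0:
        raise ValueError("empty response window")
    noise_sd = _baseline_noise_sd(avg, onset, 490.0)
    floor = max(DETECTION_FLOOR_MV, 3.0 * noise_sd)
    epsp, epsp_idx, ipsp, ipsp_idx = _component_extrema(
        smoothed, base, i0, i1, floor)

    supra = False
    for s in sweeps:
        for ev in detect_aps(s):
            if onset <= ev.threshold_time_ms <= onset + SUPRATHRESHOLD_WINDOW_MS:
                supra = True
                break
        if supra:
            break

    classification = classify_response(epsp, ipsp, supra, noise_sd)

    ei: Optional[float] = None
    if classification in ("excitatory", "inhibitory", "biphasic"):
        ei = ei_ratio(epsp, ipsp)

    # the governing component is the leading one: the EPSP when present,
    # otherwise the IPSP
    latency = half_width = None
    if classification in ("excitatory", "biphasic") and epsp >= MIN_REPORTABLE_AMPLITUDE_MV:
        latency = _latency(smoothed, avg.time_step, avg.index_at(onset), i1,
                           base, epsp, positive=True)
        half_width = _half_width(smoothed, avg.time_step, epsp_idx, base, True)
    elif classification == "inhibitory" and ipsp >= MIN_REPORTABLE_AMPLITUDE_MV:
        latency = _latency(smoothed, avg.time_step, avg.index_at(onset), i1,
                           base, ipsp, positive=False)
        half_width = _half_width(smoothed, avg.time_step, ipsp_idx, base, False)

    return EvokedResponse(
        cell_id=avg.cell_id,
        condition=avg.condition,
        baseline_vm_mV=base,
        epsp_amp_mV=epsp,
        ipsp_amp_mV=ipsp,
        classification=classification,
        ei_ratio=ei,
        latency_ms=latency,
        half_width_ms=half_width,
        n_sweeps_averaged=len(sweeps),
    )


def measure_train(
    sweeps: Sequence[Sweep],
    protocol: Optional[StimulusProtocol] = None,
) -> TrainResponse:
    """Per-pulse extrema of a 10/20 Hz train response.

    Each pulse k is measured within [onset_k, onset_k + period) (100 ms at
    10 Hz, 50 ms at 20 Hz) against the single train-level baseline (990 ms
    pre-train window).
    """
    avg = average_sweeps(sweeps)
    protocol = protocol or avg.protocol
    if protocol.kind is not ProtocolKind.OPTO_TRAIN:
        raise ValueError("measure_train expects an opto_train protocol")
    freq = protocol.param("frequency_hz")
    n_pulses = int(protocol.param("n_pulses"))
    period = 1000.0 / freq
    base = baseline_vm(avg, protocol)
    smoothed = _smooth_1ms(avg.voltage, avg.time_step)
    noise_sd = _baseline_noise_sd(avg, protocol.onset_ms, 990.0)
    floor = max(DETECTION_FLOOR_MV, 3.0 * noise_sd)
    epsp = np.zeros(n_pulses)
    ipsp = np.zeros(n_pulses)
    ei = np.full(n_pulses, np.nan)
    for k in range(n_pulses):
        t0 = protocol.onset_ms + k * period
        i0 = avg.index_at(t0) + 1
        i1 = avg.index_at(t0 + period) + 1
        if i1 > avg.n_samples:
            raise ValueError(
                f"pulse window {k} extends past the end of the sweep"
            )
        e, _, i_amp, _ = _component_extrema(smoothed, base, i0, i1, floor)
        epsp[k] = e
        ipsp[k] = i_amp
        if e + i_amp > 0:
            ei[k] = ei_ratio(e, i_amp)
    return TrainResponse(
        cell_id=avg.cell_id,
        frequency_hz=freq,
        baseline_vm_mV=base,
        epsp_amp_mV=epsp,
        ipsp_amp_mV=ipsp,
        ei_ratio=ei,
    )


def paired_connectivity(
    pre_sweep: Sweep,
    post_sweeps: Sequence[Sweep],
    min_amp_mV: float = 0.1,
) -> PairedResult:
    """Test for a pre -> post inhibitory connection in a paired recording.

    The post-cell average trace is searched for a hyperpolarisation within
    50 ms of the pre-cell action potential; the pair is connected when the
    trough exceeds both 0.1 mV and 3 x the SD of the post-cell baseline.
    Half-width is computed on the average of all pulses.
    """
    events = detect_aps(pre_sweep)
    if not events:
        raise ValueError("no action potential found in the pre-cell sweep")
    t_spike = events[0].peak_time_ms
    avg = average_sweeps(post_sweeps)
    smoothed = _smooth_1ms(avg.voltage, avg.time_step)
    span = min(490.0, t_spike - avg.time_step)
    i0 = avg.index_at(max(0.0, t_spike - span))
    i1 = max(i0 + 1, avg.index_at(t_spike - 10.0))
    base = float(np.mean(avg.voltage[i0:i1]))
    noise_sd = float(np.std(avg.voltage[i0:i1]))
    j0 = avg.index_at(t_spike)
    j1 = min(avg.n_samples, avg.index_at(t_spike + SUPRATHRESHOLD_WINDOW_MS) + 1)
    seg = smoothed[j0:j1]
    k_min = int(np.argmin(seg))
    amp = max(0.0, base - float(seg[k_min]))
    connected = amp >= max(min_amp_mV, 3.0 * noise_sd)
    half_width = None
    if connected:
        half_width = _half_width(smoothed, avg.time_step, j0 + k_min, base, False)
    return PairedResult(
        pre_cell=pre_sweep.cell_id,
        post_cell=avg.cell_id,
        connected=connected,
        ipsp_amp_mV=amp if connected else amp,
        half_width_ms=half_width,
    )


def condition_contrast(
    responses_by_condition: Mapping[str, Mapping[str, EvokedResponse]],
) -> pd.DataFrame:
    """Long-format paired feature table across pharmacological conditions.

    Rows: one per cell x condition x feature for the cells present in every
    condition; features are epsp_amp_mV, ipsp_amp_mV and half_width_ms.
    Ready for a Friedman test (>= 3 conditions) or paired Wilcoxon (2).
    """
    conditions = list(responses_by_condition)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    shared = set(responses_by_condition[conditions[0]])
    for cond in conditions[1:]:
        shared &= set(responses_by_condition[cond])
    if not shared:
        raise ValueError("no cells shared across conditions")
    rows = []
    for cell_id in sorted(shared):
        for cond in conditions:
            r = responses_by_condition[cond][cell_id]
            for feature, value in (
                ("epsp_amp_mV", r.epsp_amp_mV),
                ("ipsp_amp_mV", r.ipsp_amp_mV),
                ("half_width_ms", r.half_width_ms),
            ):
                rows.append(
                    {"cell_id": cell_id, "condition": cond,
                     "feature": feature, "value": value}
                )
    return pd.DataFrame(rows)
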