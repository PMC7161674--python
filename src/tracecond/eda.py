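"""Phasic electrodermal analysis: tonic/phasic decomposition, per-trial
wave features, and the conditioned-response decision rule.

The decomposition estimates the slowly drifting tonic level as a smoothed
running low percentile, subtracts it, and deconvolves the remaining phasic
signal by a unit-area Bateman kernel (Tikhonov-regularised in the Fourier
domain) to obtain a nonnegative sudomotor driver.  Wave features are read
off the phasic conductance itself: peak magnitude above the value at tone
onset, time to reach that peak within the search window, and the time for
the wave to decay back near its onset level.

The conditioned response (CR) is called present when the unreinforced
noxious tone (NOC*) evokes a larger wave than the last musical trial
(MUS4) while remaining below the last delivered noxious stimulus (NOC3):
M(NOC*) > M(MUS4) and M(NOC3) > M(NOC*), strict, with an optional
magnitude floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .protocol import (
    DEFAULT_SEARCH_WINDOW_S,
    ProtocolTimeline,
    StimulusEvent,
    TimeWindow,
    epoch_window,
)
from .synthgen import DEFAULT_KERNEL, GsrRecording, KernelParams, bateman_kernel

__all__ = [
    "PhasicSignal",
    "WaveFeatures",
    "CrDecision",
    "decompose_phasic",
    "extract_wave_features",
    "detect_cr",
    "features_table",
    "cr_from_features_table",
    "LEARNED_MAGNITUDE_FLOOR_US",
]

#: Empirically learned NOC* magnitude threshold, available as a config
#: preset for the CR floor; the default floor stays 0 because the decision
#: rule itself is ordinal.
LEARNED_MAGNITUDE_FLOOR_US = 0.05


@dataclass
class PhasicSignal:
    fs: float
    samples: np.ndarray  # µS, phasic component (>= 0)
    driver: np.ndarray  # deconvolved sudomotor activity (>= 0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.driver = np.asarray(self.driver, dtype=float)
        if len(self.samples) != len(self.driver):
            raise ValueError("phasic and driver must have equal length")


@dataclass(frozen=True)
class WaveFeatures:
    """Per-trial skin-conductance wave characterisation."""

    event_label: str
    peak_magnitude: float  # µS, peak minus value at tone onset
    time_to_peak: float  # s from tone onset
    decay_time: float  # s from the peak to near-onset level
    onset_value: float  # µS, phasic value at tone onset
    peak_time_abs: float  # s from recording start


@dataclass(frozen=True)
class CrDecision:
    present: bool
    magnitudes: dict


def decompose_phasic(
    recording: GsrRecording,
    kernel: KernelParams = DEFAULT_KERNEL,
    tonic_window: float = 30.0,
    smooth_window: float = 4.0,
    reg: float = 1e-3,
) -> PhasicSignal:
    """Split a conductance recording into tonic and phasic parts and
    deconvolve the sudomotor driver.

    tonic = running 10th percentile over ``tonic_window`` seconds, smoothed
    by a ``smooth_window`` moving average; phasic = recording - tonic,
    floored at 0; driver = Tikhonov-regularised Fourier deconvolution of
    the phasic signal by the unit-area response kernel, clipped at 0.
    """
    x = recording.samples
    fs = recording.fs
    win = int(round(tonic_window * fs))
    if len(x) <= win:
        raise ValueError(
            f"recording ({len(x)} samples) shorter than tonic window ({win} samples)"
        )
    tonic = ndimage.percentile_filter(x, percentile=10, size=win, mode="nearest")
    sm = max(int(round(smooth_window * fs)), 1)
    tonic = ndimage.uniform_filter1d(tonic, size=sm, mode="nearest")
    phasic = np.clip(x - tonic, 0.0, None)

    k = bateman_kernel(kernel)
    k_unit = k / k.sum()  # unit discrete area
    n = len(phasic)
    nfft = int(2 ** np.ceil(np.log2(n + len(k_unit))))
    kf = np.fft.rfft(k_unit, nfft)
    pf = np.fft.rfft(phasic, nfft)
    denom = np.abs(kf) ** 2 + reg * np.max(np.abs(kf)) ** 2
    driver = np.fft.irfft(pf * np.conj(kf) / denom, nfft)[:n]
    driver = np.clip(driver, 0.0, None)
    return PhasicSignal(fs=fs, samples=phasic, driver=driver)


def extract_wave_features(
    phasic: PhasicSignal,
    event: StimulusEvent,
    window: TimeWindow | None = None,
    decay_fraction: float = 0.10,
    decay_cap: float | None = None,
) -> WaveFeatures:
    """Wave features for one trial.

    The peak is searched inside ``window`` (default: 10 s from the tone);
    decay tracking continues past the window but stops at ``decay_cap``
    (the next trial's onset, or the end of the recording).  ``decay_time``
    is the time from the peak until the phasic signal first returns to
    onset_value + ``decay_fraction`` * magnitude; if it never does before
    the cap, the capped duration is reported.
    """
    if window is None:
        window = epoch_window(event)
    if not 0 < decay_fraction < 1:
        raise ValueError("decay_fraction must lie in (0, 1)")
    fs = phasic.fs
    x = phasic.samples
    i0 = int(round(window.start * fs))
    i1 = int(round(window.end * fs))
    if i0 < 0 or i1 >= len(x):
        raise ValueError(
            f"window [{window.start}, {window.end}] s outside recording "
            f"({len(x) / fs:.1f} s)"
        )
    seg = x[i0 : i1 + 1]
    onset_value = float(seg[0])
    i_peak = int(np.argmax(seg))  # first maximum
    peak = float(seg[i_peak])
    magnitude = max(peak - onset_value, 0.0)
    time_to_peak = i_peak / fs
    peak_abs = i0 + i_peak

    cap_time = decay_cap if decay_cap is not None else (len(x) - 1) / fs
    i_cap = min(int(round(cap_time * fs)), len(x) - 1)
    threshold = onset_value + decay_fraction * magnitude
    decay_time = (i_cap - peak_abs) / fs
    below = np.nonzero(x[peak_abs : i_cap + 1] <= threshold)[0]
    if len(below) > 0:
        decay_time = below[0] / fs
    return WaveFeatures(
        event_label=event.label,
        peak_magnitude=magnitude,
        time_to_peak=time_to_peak,
        decay_time=max(decay_time, 0.0),
        onset_value=onset_value,
        peak_time_abs=peak_abs / fs,
    )


def detect_cr(
    f_mus4: WaveFeatures,
    f_noc3: WaveFeatures,
    f_nocstar: WaveFeatures,
    floor: float = 0.0,
) -> CrDecision:
    """Ordinal CR rule on the three probe trials (strict inequalities)."""
    m = {
        "MUS4": f_mus4.peak_magnitude,
        "NOC3": f_noc3.peak_magnitude,
        "NOC_STAR": f_nocstar.peak_magnitude,
    }
    present = (
        m["NOC_STAR"] > m["MUS4"]
        and m["NOC3"] > m["NOC_STAR"]
        and m["NOC_STAR"] > floor
    )
    return CrDecision(present=present, magnitudes=m)


def features_table(
    recording: GsrRecording,
    timeline: ProtocolTimeline,
    kernel: KernelParams = DEFAULT_KERNEL,
    search_window: float = DEFAULT_SEARCH_WINDOW_S,
    decay_fraction: float = 0.10,
    tonic_window: float = 30.0,
    subject_id: str | None = None,
    phasic: PhasicSignal | None = None,
) -> pd.DataFrame:
    """Wave features for all 16 trials, ordered by position."""
    if phasic is None:
        phasic = decompose_phasic(recording, kernel, tonic_window=tonic_window)
    rows = []
    for e in timeline.events:
        window = epoch_window(e, search_window)
        cap = min(timeline.next_onset_after(e), (len(phasic.samples) - 1) / phasic.fs)
        f = extract_wave_features(
            phasic, e, window, decay_fraction=decay_fraction, decay_cap=cap
        )
        rows.append(
            {
                "subject_id": subject_id,
                "event_label": e.label,
                "sequence": e.sequence.value,
                "position": e.position,
                "peak_magnitude_uS": f.peak_magnitude,
                "time_to_peak_s": f.time_to_peak,
                "decay_time_s": f.decay_time,
                "onset_value_uS": f.onset_value,
                "peak_time_abs_s": f.peak_time_abs,
            }
        )
    return pd.DataFrame(rows)


def cr_from_features_table(table: pd.DataFrame, floor: float = 0.0) -> CrDecision:
    """Apply the CR rule to a 16-row features table."""
    mags = table.set_index("event_label")["peak_magnitude_uS"]
    m = {k: float(mags[k]) for k in ("MUS4", "NOC3", "NOC_STAR")}
    present = (
        m["NOC_STAR"] > m["MUS4"] and m["NOC3"] > m["NOC_STAR"] and m["NOC_STAR"] > floor
    )
    return CrDecision(present=present, magnitudes=m)
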