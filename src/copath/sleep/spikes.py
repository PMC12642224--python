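"""Epileptiform spike detection.

Subclinical epileptiform discharges are brief, high-amplitude EEG
transients. Because ongoing delta/theta oscillations dominate the raw
trace and vary strongly between vigilance states, detection operates on
a high-frequency band (15-70 Hz by default) where spikes — sharp
transients tens of milliseconds wide — retain most of their energy and
the background is small and stationary. Samples whose absolute filtered
amplitude exceeds ``threshold_sd`` times the robust SD (median absolute
deviation scaled to the Gaussian SD) of the filtered trace seed events;
an event's width is the full width of its supra-threshold excursion;
events closer than 200 ms are merged; events outside the width bounds
are discarded. The reported amplitude is the signed raw-EEG peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .core import Recording
from .spindles import _runs, bandpass


@dataclass
class SpikeEvent:
    time: float  # s, at the peak
    amplitude: float  # uV, signed raw-EEG value at the peak
    width: float  # ms, full width of the supra-threshold excursion


def detect_spikes(
    rec: Recording,
    threshold_sd: float = 6.0,
    width_bounds: tuple[float, float] = (1.0, 100.0),
    merge_window: float = 0.2,
    detection_band: tuple[float, float] = (15.0, 70.0),
) -> list[SpikeEvent]:
    """Detect high-amplitude transients in the EEG channel."""
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    fs = rec.sampling_rate
    if rec.eeg.std() == 0:
        return []
    lo, hi = detection_band
    hi = min(hi, 0.45 * fs)
    filt = bandpass(rec.eeg, fs, (lo, hi))
    robust_sd = median_abs_deviation(filt, scale="normal")
    if robust_sd == 0:
        return []
    thr = threshold_sd * robust_sd

    above = np.abs(filt) > thr
    if not above.any():
        return []
    runs = _runs(above)
    # merge excursions closer than merge_window seconds
    gap = int(round(merge_window * fs))
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    lo_w, hi_w = width_bounds
    events = []
    for start, stop in merged:
        width_ms = (stop - start) / fs * 1000.0
        if not (lo_w <= width_ms <= hi_w):
            continue
        seg = rec.eeg[start:stop]
        peak = start + int(np.argmax(np.abs(seg)))
        events.append(SpikeEvent(time=peak / fs, amplitude=float(rec.eeg[peak]),
                                 width=width_ms))
    return events


def spikes_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    return pd.DataFrame([(e.time, e.amplitude, e.width) for e in events],
                        columns=["time", "amplitude", "width"])
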