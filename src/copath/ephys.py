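"""fEPSP sweep metrics, input-output curves, and theta-burst LTP.

A field EPSP sweep is a negative-going deflection after a stimulus
artifact; its initial slope (fitted on the rising phase between 10% and
40% of the peak amplitude) indexes synaptic strength. LTP is expressed as
the percentage of the pre-induction baseline mean slope, summarized over
an early (0-30 min) and a late (30-60 min) window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Sweep:
    """One evoked-potential sweep: time (ms) and voltage (mV)."""

    time: np.ndarray = field(repr=False)
    voltage: np.ndarray = field(repr=False)
    stimulus_time: float = 0.0
    intensity: float | None = None  # stimulation intensity, uV

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must align")
        if self.time.size < 2 or (np.diff(self.time) <= 0).any():
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.stimulus_time <= self.time[-1]):
            raise ValueError("stimulus_time outside the record")


#: samples within this window after the stimulus are excluded from all
#: metrics (stimulus artifact / fiber volley)
ARTIFACT_WINDOW_MS = 1.0
#: pre-stimulus baseline window
BASELINE_WINDOW_MS = 5.0


def _baseline(s: Sweep) -> float:
    pre = (s.time < s.stimulus_time) & (s.time >= s.stimulus_time - BASELINE_WINDOW_MS)
    if not pre.any():
        return 0.0
    return float(s.voltage[pre].mean())


def _response_window(s: Sweep) -> np.ndarray:
    return s.time > s.stimulus_time + ARTIFACT_WINDOW_MS


def fepsp_amplitude(s: Sweep) -> tuple[float, bool]:
    """Baseline-to-negative-peak amplitude (mV) and a saturation flag.

    Baseline is the pre-stimulus mean over 5 ms. The flag marks clipped
    traces (>= 5 consecutive samples pinned at the extreme value).
    """
    post = _response_window(s)
    if not post.any():
        raise ValueError("post-stimulus window is empty")
    v = s.voltage[post]
    base = _baseline(s)
    peak = float(v.min())
    at_peak = np.isclose(v, peak)
    # clipped if the minimum is held for a run of >= 5 samples
    run, longest = 0, 0
    for flag in at_peak:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    amplitude = abs(peak - base)
    return amplitude, bool(amplitude > 0 and longest >= 5)


def fepsp_slope(s: Sweep, lo_frac: float = 0.10, hi_frac: float = 0.40) -> float:
    """Least-squares slope (mV/ms) of the rising phase at 10-40% of peak.

    The 10%/40% crossings are located on a 3-point-median smoothed trace
    to stabilize them against single-sample noise; the fit itself uses the
    raw samples. Raises if fewer than 3 samples fall in the window.
    """
    post = _response_window(s)
    if not post.any():
        raise ValueError("post-stimulus window is empty")
    t, v = s.time[post], s.voltage[post]
    base = _baseline(s)
    smooth = np.copy(v)
    if v.size >= 3:
        smooth[1:-1] = np.median(np.column_stack([v[:-2], v[1:-1], v[2:]]), axis=1)
    depth_s = base - smooth  # positive as the trace descends
    peak_idx = int(np.argmin(smooth))
    amp = depth_s[peak_idx]
    if amp <= 0:
        raise ValueError("no negative-going response")
    rising = depth_s[: peak_idx + 1]
    # fit all raw samples between the 10% and 40% *crossing points* of the
    # smoothed trace (a contiguous range, not per-sample membership, which
    # would select on noise and bias the slope toward zero)
    above_lo = np.flatnonzero(rising >= lo_frac * amp)
    above_hi = np.flatnonzero(rising >= hi_frac * amp)
    if above_lo.size == 0 or above_hi.size == 0:
        raise ValueError("fewer than 3 samples in the 10-40% rising window")
    i10, i40 = above_lo[0], above_hi[0]
    if i40 - i10 + 1 < 3:
        raise ValueError("fewer than 3 samples in the 10-40% rising window")
    sel = slice(i10, i40 + 1)
    slope, _ = np.polyfit(t[sel], v[sel], 1)
    return float(slope)


@dataclass
class IOCurve:
    """Input-output curve summary over increasing stimulation intensities."""

    intensities: np.ndarray
    amplitudes: np.ndarray
    slopes: np.ndarray
    max_amplitude: float
    max_slope: float

    def intensity_at_fraction(self, fraction: float, metric: str = "amplitude") -> float:
        """Lowest intensity whose response reaches ``fraction`` of the plateau,
        linearly interpolated between neighboring intensities."""
        y = self.amplitudes if metric == "amplitude" else np.abs(self.slopes)
        target = fraction * y.max()
        above = np.flatnonzero(y >= target)
        if above.size == 0:
            return float(self.intensities[-1])
        j = above[0]
        if j == 0 or y[j] == target:
            return float(self.intensities[j])
        x0, x1 = self.intensities[j - 1], self.intensities[j]
        y0, y1 = y[j - 1], y[j]
        return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))


def io_curve(sweeps: list[Sweep]) -> IOCurve:
    """Build the I/O curve from sweeps recorded at increasing intensities.

    The plateau (maximal response) is the maximum observed amplitude/slope;
    a non-monotone curve is accepted with a warning. Sweeps whose rising
    phase cannot be fitted contribute NaN slope.
    """
    if len(sweeps) < 3:
        raise ValueError("need sweeps at >= 3 intensities")
    if any(s.intensity is None for s in sweeps):
        raise ValueError("every sweep needs an intensity")
    order = np.argsort([s.intensity for s in sweeps])
    sweeps = [sweeps[i] for i in order]
    intensities = np.array([s.intensity for s in sweeps], dtype=float)
    amps = np.array([fepsp_amplitude(s)[0] for s in sweeps])
    slopes = np.full(len(sweeps), np.nan)
    for i, s in enumerate(sweeps):
        try:
            slopes[i] = fepsp_slope(s)
        except ValueError:
            pass
    if amps.max() == 0:
        raise ValueError("all responses are zero")
    if (np.diff(amps) < 0).any():
        warnings.warn("non-monotone I/O curve; plateau taken as the maximum")
    return IOCurve(
        intensities=intensities,
        amplitudes=amps,
        slopes=slopes,
        max_amplitude=float(amps.max()),
        max_slope=float(np.nanmax(np.abs(slopes))) if np.isfinite(slopes).any() else np.nan,
    )


@dataclass
class LTPSeries:
    """Baseline and post-induction sweeps on a fixed inter-sweep interval."""

    baseline_sweeps: list[Sweep]
    post_sweeps: list[Sweep]
    interval_s: float = 20.0  # one sweep every 20 s

    def post_times_min(self) -> np.ndarray:
        return np.arange(len(self.post_sweeps)) * self.interval_s / 60.0


def ltp_normalize(
    series: LTPSeries,
    early_window: tuple[float, float] = (0.0, 30.0),
    late_window: tuple[float, float] = (30.0, 60.0),
) -> tuple[float, float, pd.DataFrame]:
    """Normalize post-induction slopes to the baseline mean (=100%).

    Returns (early-window mean %, late-window mean %, per-sweep time
    course). Windows are minutes after induction, half-open [lo, hi), and
    must overlap the recorded post period.
    """
    base_slopes = np.array([fepsp_slope(s) for s in series.baseline_sweeps])
    base_mean = base_slopes.mean()
    if base_mean == 0:
        raise ValueError("zero baseline mean slope")
    post_slopes = np.array([fepsp_slope(s) for s in series.post_sweeps])
    times = series.post_times_min()
    norm = post_slopes / base_mean * 100.0
    course = pd.DataFrame({"time_min": times, "normalized_slope_pct": norm})

    def window_mean(win: tuple[float, float]) -> float:
        lo, hi = win
        sel = (times >= lo) & (times < hi)
        if not sel.any():
            raise ValueError(f"window {win} outside the post period")
        return float(norm[sel].mean())

    return window_mean(early_window), window_mean(late_window), course


@dataclass
class TBSSchedule:
    """Theta-burst induction schedule: trains of bursts of pulses.

    The canonical protocol is 5 trains at 20 s intervals, each of 10
    bursts at 10 Hz, each burst 4 pulses at 100 Hz — 200 pulses total.
    """

    n_trains: int = 5
    train_interval_s: float = 20.0
    bursts_per_train: int = 10
    burst_rate_hz: float = 10.0
    pulses_per_burst: int = 4
    pulse_rate_hz: float = 100.0

    @property
    def total_pulses(self) -> int:
        return self.n_trains * self.bursts_per_train * self.pulses_per_burst

    def validate(self) -> None:
        if min(self.n_trains, self.bursts_per_train, self.pulses_per_burst) < 1:
            raise ValueError("schedule counts must be positive")
        if self.pulse_rate_hz <= self.burst_rate_hz:
            raise ValueError("pulse rate must exceed burst rate")
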