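"""Synthetic EEG/EMG/movement recordings with planted ground truth.

The generator emulates the statistical structure that staging and event
detection assume, not biophysics: additive band-limited oscillators over
pink noise. NREM segments carry strong 1-4 Hz power, REM strong 6-9 Hz
power with near-silent EMG, Wake strong EMG and locomotor activity, and
QW none of the above. Spindles are planted as Tukey-windowed 10-14 Hz
sinusoids inside NREM (flat envelope, so onset/offset/duration ground
truth is unambiguous); spikes as
brief high-amplitude transients during sleep. The planted hypnogram and
event lists are returned exactly as emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

from ..sleep.core import STATES, Hypnogram, Recording
from ..sleep.spindles import SPINDLE_BAND, SpindleEvent, bandpass

#: per-state (delta, theta, emg) oscillator scales, in uV of component RMS
DEFAULT_BAND_AMPLITUDES = {
    "Wake": (10.0, 15.0, 30.0),
    "QW": (8.0, 8.0, 5.0),
    "NREM": (40.0, 8.0, 3.0),
    "REM": (6.0, 35.0, 1.0),
}


def default_state_sequence(n_cycles: int = 2) -> list[tuple[str, float]]:
    """Default planted hypnogram: repeated wake/sleep cycles.

    Per 1000 s cycle the composition is 40% Wake, 26% QW, 25% NREM and
    9% REM (REM always entered from NREM), a realistic light-phase mouse
    architecture whose state clusters are balanced for the percentile
    auto-thresholds used by the stager.
    """
    cycle = [
        ("Wake", 250.0), ("QW", 130.0), ("NREM", 130.0), ("REM", 40.0),
        ("Wake", 150.0), ("QW", 130.0), ("NREM", 120.0), ("REM", 50.0),
    ]
    return cycle * n_cycles


@dataclass
class PlantedEEGSpec:
    """Ground-truth description of a synthetic EEG/EMG recording.

    Rates are deterministic: the planted event count is
    round(rate x eligible time), which keeps recall/precision measurements
    exact. ``spindle_snr`` fixes the planted spindle peak relative to the
    SD of the 10-14 Hz-filtered NREM background.
    """

    sampling_rate: float = 500.0
    state_sequence: list = field(default_factory=default_state_sequence)
    epoch_len: float = 10.0
    spindle_rate: float = 2.0  # events per NREM minute
    spindle_freq: float = 12.0  # Hz, within the 10-14 Hz spindle band
    spindle_duration_range: tuple[float, float] = (0.8, 2.0)  # s
    spindle_snr: float = 3.0
    spike_rate: float = 12.0  # events per hour of sleep (non-Wake)
    spike_amplitude_sd: float = 8.0  # x robust SD of the background EEG
    spike_width_ms: float = 30.0
    band_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    noise_sd: float = 10.0  # pink-noise background, uV

    def __post_init__(self) -> None:
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")
        if not (SPINDLE_BAND[0] <= self.spindle_freq <= SPINDLE_BAND[1]):
            raise ValueError("spindle_freq must lie within 10-14 Hz")
        if min(self.spindle_rate, self.spike_rate) < 0:
            raise ValueError("rates must be >= 0")
        bad = {s for s, _ in self.state_sequence} - set(STATES)
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}; allowed: {STATES}")
        total = sum(d for _, d in self.state_sequence)
        if total < 10 * self.epoch_len:
            raise ValueError("total duration must be >= 10 epochs")


@dataclass
class SimulatedEEG:
    recording: Recording
    hypnogram: Hypnogram
    spindles: list[SpindleEvent]
    spike_times: np.ndarray
    state_per_sample: np.ndarray = field(repr=False)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise (the oscillator building block)."""
    x = bandpass(rng.standard_normal(n), fs, band)
    return x / x.std()


def _place_events(
    runs: list[tuple[int, int]],
    durations_samples: np.ndarray,
    rng: np.random.Generator,
    margin: int,
    min_gap: int,
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Place non-overlapping [start, stop) windows inside the given runs."""
    placed: list[tuple[int, int]] = []
    lengths = np.array([stop - start for start, stop in runs], dtype=float)
    weights = lengths / lengths.sum()
    for dur in durations_samples:
        for _ in range(max_tries):
            ri = rng.choice(len(runs), p=weights)
            start0, stop0 = runs[ri]
            lo, hi = start0 + margin, stop0 - margin - dur
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            if all(s >= e + min_gap or s + dur + min_gap <= b
                   for b, e in placed):
                placed.append((s, s + int(dur)))
                break
        else:
            raise RuntimeError("could not place all events; lower the rate")
    return sorted(placed)


def simulate_eeg(spec: PlantedEEGSpec, seed: int | None = None) -> SimulatedEEG:
    """Synthesize EEG, EMG and movement traces with exact ground truth."""
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    durations = np.array([d for _, d in spec.state_sequence], dtype=float)
    n = int(round(durations.sum() * fs))

    # per-sample state index
    state_names = [s for s, _ in spec.state_sequence]
    bounds = np.concatenate(([0.0], np.cumsum(durations))) * fs
    state = np.empty(n, dtype=object)
    for i, name in enumerate(state_names):
        state[int(round(bounds[i])):int(round(bounds[i + 1]))] = name

    amp = {s: np.array(spec.band_amplitudes[s]) for s in set(state_names)}
    delta_amp = np.array([amp[s][0] for s in state])
    theta_amp = np.array([amp[s][1] for s in state])
    emg_amp = np.array([amp[s][2] for s in state])
    # ramp amplitudes across state boundaries (1 s Hann smoothing) so the
    # modulation steps do not inject broadband clicks into the EEG
    win = np.hanning(int(fs))
    win /= win.sum()
    delta_amp = np.convolve(delta_amp, win, mode="same")
    theta_amp = np.convolve(theta_amp, win, mode="same")
    emg_amp = np.convolve(emg_amp, win, mode="same")

    eeg = spec.noise_sd * _pink_noise(n, rng)
    eeg += delta_amp * _band_noise(n, fs, (1.0, 4.0), rng)
    eeg += theta_amp * _band_noise(n, fs, (6.0, 9.0), rng)
    emg = emg_amp * rng.standard_normal(n)
    movement = np.zeros(n)
    wake = state == "Wake"
    if wake.any():
        act = np.abs(_band_noise(n, fs, (0.1, 2.0), rng)) + 0.5
        movement[wake] = act[wake]

    # hypnogram from the epoch-midpoint state
    spe = int(round(spec.epoch_len * fs))
    n_epochs = n // spe
    hyp_states = [state[i * spe + spe // 2] for i in range(n_epochs)]
    hypnogram = Hypnogram(states=hyp_states, epoch_len=spec.epoch_len)

    nrem = state == "NREM"
    spindles: list[SpindleEvent] = []
    if spec.spindle_rate > 0 and nrem.any():
        band_sd = bandpass(eeg, fs, SPINDLE_BAND)[nrem].std()
        peak = spec.spindle_snr * band_sd
        nrem_minutes = nrem.sum() / fs / 60.0
        n_events = int(round(spec.spindle_rate * nrem_minutes))
        diff = np.diff(nrem.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        stops = list(np.flatnonzero(diff == -1) + 1)
        if nrem[0]:
            starts.insert(0, 0)
        if nrem[-1]:
            stops.append(n)
        runs = list(zip(starts, stops))
        durs = np.round(
            rng.uniform(*spec.spindle_duration_range, n_events) * fs
        ).astype(int)
        margin = int(round(0.25 * fs))
        min_gap = int(round(1.0 * fs))  # keep planted events un-mergeable
        for start, stop in _place_events(runs, durs, rng, margin, min_gap):
            length = stop - start
            tt = np.arange(length) / fs
            phase = rng.uniform(0, 2 * np.pi)
            # Tukey (tapered-cosine) window: flat envelope over the event
            # body, so onset/offset and duration ground truth are sharp
            wave = (peak * tukey(length, alpha=0.25)
                    * np.sin(2 * np.pi * spec.spindle_freq * tt + phase))
            eeg[start:stop] += wave
            spindles.append(
                SpindleEvent(onset=start / fs, duration=length / fs,
                             peak_amplitude=float(peak),
                             oscillation_frequency=spec.spindle_freq)
            )

    spike_times = np.array([])
    sleep = ~wake
    if spec.spike_rate > 0 and sleep.any():
        mad_sd = np.median(np.abs(eeg - np.median(eeg))) * 1.4826
        s_amp = spec.spike_amplitude_sd * mad_sd
        hours = sleep.sum() / fs / 3600.0
        n_spikes = int(round(spec.spike_rate * hours))
        if n_spikes > 0:
            diff = np.diff(sleep.astype(np.int8))
            starts = list(np.flatnonzero(diff == 1) + 1)
            stops = list(np.flatnonzero(diff == -1) + 1)
            if sleep[0]:
                starts.insert(0, 0)
            if sleep[-1]:
                stops.append(n)
            runs = list(zip(starts, stops))
            w = int(round(spec.spike_width_ms / 1000.0 * fs))
            # keep spikes clear of planted spindles so both truths stay exact
            occupied = [(int(e.onset * fs), int((e.onset + e.duration) * fs))
                        for e in spindles]
            placed = _place_events(runs, np.full(n_spikes, w), rng,
                                   margin=int(fs), min_gap=int(fs))
            times = []
            for start, stop in placed:
                if any(start < e and stop > b for b, e in occupied):
                    continue
                eeg[start:stop] += -s_amp * np.hanning(stop - start)
                times.append((start + (stop - start) // 2) / fs)
            spike_times = np.array(times)

    rec = Recording(eeg=eeg, emg=emg, movement=movement, sampling_rate=fs)
    return SimulatedEEG(recording=rec, hypnogram=hypnogram, spindles=spindles,
                        spike_times=spike_times,
                        state_per_sample=state)
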