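"""EEG/EMG recordings, epoch features, sleep staging, and REM architecture.

Vigilance states are scored per epoch (default 10 s) from four features:
delta (1-4 Hz) and theta (6-9 Hz) EEG band power, EMG RMS, and mean
locomotor activity. Wake is high EMG or movement; among the remaining
epochs REM is a high theta/delta ratio (and never directly follows Wake),
NREM is high delta, and the rest is quiet wakefulness (QW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

STATES = ("Wake", "QW", "NREM", "REM")

#: default band limits (Hz); the bands are named in the literature without
#: fixed limits, so these are explicit, configurable choices of this package
DELTA_BAND = (1.0, 4.0)
THETA_BAND = (6.0, 9.0)


@dataclass
class Recording:
    """Aligned EEG (uV), EMG (uV) and movement-activity series."""

    eeg: np.ndarray = field(repr=False)
    emg: np.ndarray = field(repr=False)
    movement: np.ndarray = field(repr=False)
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.movement = np.asarray(self.movement, dtype=float)
        if not (self.eeg.shape == self.emg.shape == self.movement.shape):
            raise ValueError("eeg, emg and movement must have equal length")
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")

    @property
    def duration(self) -> float:
        return self.eeg.size / self.sampling_rate


@dataclass
class Hypnogram:
    """One vigilance state per scoring epoch."""

    states: list
    epoch_len: float = 10.0

    def __post_init__(self) -> None:
        self.states = list(self.states)
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown states {sorted(bad)}; allowed: {STATES}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    def __len__(self) -> int:
        return len(self.states)

    def state_mask(self, state: str, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of epochs scored as ``state``."""
        spe = int(round(self.epoch_len * sampling_rate))
        mask = np.zeros(n_samples, dtype=bool)
        for i, s in enumerate(self.states):
            if s == state:
                mask[i * spe:min((i + 1) * spe, n_samples)] = True
        return mask

    def total_time(self, state: str) -> float:
        return self.states.count(state) * self.epoch_len


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Average PSD power (uV^2) in a frequency band via Welch's method."""
    nperseg = min(x.size, int(2 * fs))
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def epoch_features(
    rec: Recording,
    epoch_len: float = 10.0,
    delta_band: tuple[float, float] = DELTA_BAND,
    theta_band: tuple[float, float] = THETA_BAND,
) -> pd.DataFrame:
    """Per-epoch delta power, theta power, EMG RMS and mean movement."""
    fs = rec.sampling_rate
    spe = int(round(epoch_len * fs))
    if abs(spe - epoch_len * fs) > 1e-9:
        raise ValueError("epoch_len must be a multiple of the sample interval")
    n_epochs = rec.eeg.size // spe
    if n_epochs == 0:
        raise ValueError("epoch longer than the recording")
    rows = []
    for i in range(n_epochs):
        sl = slice(i * spe, (i + 1) * spe)
        eeg = rec.eeg[sl]
        rows.append(
            (
                i,
                band_power(eeg, fs, delta_band),
                band_power(eeg, fs, theta_band),
                float(np.sqrt(np.mean(rec.emg[sl] ** 2))),
                float(np.mean(rec.movement[sl])),
            )
        )
    return pd.DataFrame(
        rows, columns=["epoch", "delta_power", "theta_power", "emg_rms",
                       "movement_mean"]
    ).set_index("epoch")


@dataclass
class StagingThresholds:
    """Staging cut-offs; any field left None is auto-derived per recording.

    Auto-derivation uses feature percentiles: EMG and movement at the 60th
    percentile over all epochs, theta/delta ratio at the 85th percentile
    over non-Wake epochs, and delta at the median over non-Wake, non-REM
    epochs. These defaults make staging self-calibrating per recording.
    """

    emg: float | None = None
    movement: float | None = None
    theta_delta_ratio: float | None = None
    delta: float | None = None


def stage_sleep(
    features: pd.DataFrame,
    thresholds: StagingThresholds | None = None,
    epoch_len: float = 10.0,
) -> Hypnogram:
    """Score Wake/QW/NREM/REM from epoch features.

    Rules, in order: Wake iff EMG or movement above threshold; among the
    remaining epochs, REM iff theta/delta ratio above threshold and the
    previous epoch was not Wake (a REM-signature epoch straight after Wake
    is scored QW); NREM iff delta above threshold; otherwise QW.
    """
    thr = thresholds or StagingThresholds()
    emg = features["emg_rms"].to_numpy()
    mov = features["movement_mean"].to_numpy()
    delta = features["delta_power"].to_numpy()
    theta = features["theta_power"].to_numpy()
    auto = (thr.emg is None and thr.movement is None
            and thr.theta_delta_ratio is None and thr.delta is None)
    if auto and (emg.std() == 0 and mov.std() == 0 and delta.std() == 0
                 and theta.std() == 0):
        # percentile thresholds are meaningless on constant features
        warnings.warn("all epoch features identical; staging everything QW")
        return Hypnogram(states=["QW"] * len(features), epoch_len=epoch_len)

    emg_thr = np.percentile(emg, 60) if thr.emg is None else thr.emg
    mov_thr = np.percentile(mov, 60) if thr.movement is None else thr.movement
    wake = (emg > emg_thr) | (mov > mov_thr)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
    if thr.theta_delta_ratio is None:
        nonwake = ratio[~wake]
        ratio_thr = np.percentile(nonwake, 85) if nonwake.size else np.inf
    else:
        ratio_thr = thr.theta_delta_ratio

    rem_candidate = ~wake & (ratio > ratio_thr)
    if thr.delta is None:
        rest = delta[~wake & ~rem_candidate]
        delta_thr = np.median(rest) if rest.size else np.inf
    else:
        delta_thr = thr.delta

    states: list[str] = []
    for i in range(len(features)):
        if wake[i]:
            states.append("Wake")
        elif rem_candidate[i] and i > 0 and states[i - 1] != "Wake":
            states.append("REM")
        elif delta[i] > delta_thr:
            states.append("NREM")
        else:
            states.append("QW")
    return Hypnogram(states=states, epoch_len=epoch_len)


def _bouts(states: list) -> list[tuple[str, int, int]]:
    """Maximal runs as (state, start_epoch, length)."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((states[start], start, i - start))
            start = i
    return out


def rem_metrics(
    h: Hypnogram, phase_labels: list | None = None
) -> pd.DataFrame:
    """REM %time, %bouts, and NREM->REM transition counts, split by phase.

    Percent time is REM epochs over all epochs; percent bouts is REM bouts
    over bouts of all states (bouts attributed to the phase of their first
    epoch); transitions are NREM->REM boundaries, attributed to the phase
    of the REM-entry epoch. A row labelled "all" covers the whole
    recording; per-phase counts partition the totals exactly.
    """
    states = h.states
    n = len(states)
    if n == 0:
        raise ValueError("empty hypnogram")
    if phase_labels is not None and len(phase_labels) != n:
        raise ValueError("phase_labels must align with epochs")

    bouts = _bouts(states)
    transitions = [i for i in range(1, n)
                   if states[i - 1] == "NREM" and states[i] == "REM"]

    def row(sel_epochs, sel_bouts, sel_trans) -> dict:
        n_epochs = len(sel_epochs)
        rem_epochs = sum(1 for i in sel_epochs if states[i] == "REM")
        rem_bouts = sum(1 for b in sel_bouts if b[0] == "REM")
        return {
            "n_epochs": n_epochs,
            "rem_percent_time": 100.0 * rem_epochs / n_epochs if n_epochs else 0.0,
            "rem_bouts": rem_bouts,
            "total_bouts": len(sel_bouts),
            "rem_percent_bouts": (100.0 * rem_bouts / len(sel_bouts)
                                  if sel_bouts else 0.0),
            "nrem_rem_transitions": len(sel_trans),
        }

    rows = {"all": row(range(n), bouts, transitions)}
    if phase_labels is not None:
        for ph in dict.fromkeys(phase_labels):  # preserve order
            epochs = [i for i in range(n) if phase_labels[i] == ph]
            ph_bouts = [b for b in bouts if phase_labels[b[1]] == ph]
            ph_trans = [i for i in transitions if phase_labels[i] == ph]
            rows[ph] = row(epochs, ph_bouts, ph_trans)
    return pd.DataFrame(rows).T
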