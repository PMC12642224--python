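"""Synthetic fEPSP sweeps with a known linear rising phase.

Each sweep has a 5 ms flat baseline, a brief stimulus artifact, a linear
descent at the planted slope to the negative peak, a short plateau (so the
sampled minimum equals the planted amplitude exactly), and an exponential
recovery. With zero noise the slope and amplitude estimators recover the
planted values exactly.
"""

from __future__ import annotations

import numpy as np

from ..ephys import Sweep


def simulate_fepsp(
    true_slope: float,
    peak_amplitude: float,
    noise_sd: float,
    n_sweeps: int,
    seed: int | None = None,
    *,
    sample_interval_ms: float = 0.1,
    total_ms: float = 30.0,
    stimulus_time: float = 5.0,
    recovery_tau_ms: float = 8.0,
    intensity: float | None = None,
) -> list[Sweep]:
    """Simulate ``n_sweeps`` sweeps with a planted slope (mV/ms, negative)
    and negative-peak amplitude (mV, positive)."""
    if peak_amplitude <= 0:
        raise ValueError("peak_amplitude must be positive")
    if true_slope >= 0:
        raise ValueError("true_slope must be negative (negative-going fEPSP)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_ms + 1e-9, sample_interval_ms)
    onset = stimulus_time + 1.0  # response begins after the artifact window
    v = np.zeros_like(t)

    # stimulus artifact: short positive deflection right at the stimulus
    artifact = (t >= stimulus_time) & (t < stimulus_time + 0.4)
    v[artifact] = 2.0

    linear = t >= onset
    v[linear] = np.maximum(true_slope * (t[linear] - onset), -peak_amplitude)
    # 0.3 ms plateau at the peak, then exponential recovery toward 0
    t_reach = onset + peak_amplitude / abs(true_slope)
    t_rec = t_reach + 0.3
    rec = t >= t_rec
    v[rec] = -peak_amplitude * np.exp(-(t[rec] - t_rec) / recovery_tau_ms)

    sweeps = []
    for _ in range(n_sweeps):
        noise = rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0
        sweeps.append(Sweep(time=t.copy(), voltage=v + noise,
                            stimulus_time=stimulus_time, intensity=intensity))
    return sweeps
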