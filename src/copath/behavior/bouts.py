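"""Movement-state binarization and moving-bout structure metrics.

Open-field center-point tracking is reduced to 0.5 s bins; each bin is
scored moving (1) or not moving (0) by whether its displacement exceeds a
movement threshold. Consecutive identical states form bouts, whose counts,
durations and the moving speed quantify behavioral persistence versus
fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BoutSeries:
    """Binary movement states per time bin for one animal."""

    animal_id: str
    states: np.ndarray = field(repr=False)
    bin_width: float = 0.5
    #: per-bin displacement (same units as the threshold); used for speed
    displacements: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.states.size == 0:
            raise ValueError("empty state series")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")
        if self.displacements is not None:
            self.displacements = np.asarray(self.displacements, dtype=float)
            if self.displacements.shape != self.states.shape:
                raise ValueError("displacements must align with states")


@dataclass
class BoutMetrics:
    """Per-animal bout structure summary.

    Mean durations are NaN (undefined, not zero) when a state never occurs.
    ``moving_speed`` is total distance over total moving time, NaN when the
    animal never moves or displacements were not supplied.
    """

    animal_id: str
    n_moving_bouts: int
    n_still_bouts: int
    n_transitions: int
    mean_moving_duration: float
    mean_still_duration: float
    moving_speed: float


def binarize_movement(
    displacements,
    threshold: float,
    *,
    animal_id: str = "",
    bin_width: float = 0.5,
) -> BoutSeries:
    """Assign each bin state 1 iff its displacement strictly exceeds ``threshold``.

    The comparison is strict (>): a displacement exactly at the threshold is
    scored not-moving.
    """
    displacements = np.asarray(displacements, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if (displacements < 0).any():
        raise ValueError("negative displacement")
    states = (displacements > threshold).astype(np.int8)
    return BoutSeries(animal_id=animal_id, states=states, bin_width=bin_width,
                      displacements=displacements)


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state value, run length in bins) for each maximal run."""
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return states[starts], ends - starts


def bout_metrics(series: BoutSeries) -> BoutMetrics:
    """Bout counts, state transitions, mean bout durations and moving speed.

    Mean duration of a state = total time in that state / number of its
    bouts. Speed = total distance / total moving time, over moving bins only.
    """
    values, lengths = _run_lengths(series.states)
    moving = values == 1
    n_moving = int(moving.sum())
    n_still = int((~moving).sum())
    n_transitions = values.size - 1

    def mean_dur(mask: np.ndarray) -> float:
        n = int(mask.sum())
        if n == 0:
            return float("nan")
        return float(lengths[mask].sum() * series.bin_width / n)

    speed = float("nan")
    if series.displacements is not None:
        moving_bins = series.states == 1
        t_moving = moving_bins.sum() * series.bin_width
        if t_moving > 0:
            speed = float(series.displacements[moving_bins].sum() / t_moving)

    return BoutMetrics(
        animal_id=series.animal_id,
        n_moving_bouts=n_moving,
        n_still_bouts=n_still,
        n_transitions=n_transitions,
        mean_moving_duration=mean_dur(moving),
        mean_still_duration=mean_dur(~moving),
        moving_speed=speed,
    )
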