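"""Per-animal behavioral motif sequences.

A motif sequence is the frame-wise output of an unsupervised pose-sequence
segmentation (one motif label per video frame at a fixed frame rate), the
substrate of every behavior statistic in this subpackage.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MotifSequence:
    """Frame-wise motif labels for one animal.

    Parameters
    ----------
    animal_id : str
        Identifier of the animal (the unit of replication).
    genotype : str
        Group label (e.g. WT, E4, NLF, E4NLF).
    labels : list
        One motif id per frame, drawn from a finite vocabulary.
    frame_rate : float
        Frames per second of the underlying video.
    """

    animal_id: str
    genotype: str
    labels: list = field(repr=False)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if not self.labels:
            raise ValueError(f"empty motif sequence for animal {self.animal_id!r}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def vocabulary(self) -> list:
        """Sorted distinct motif ids present in this sequence."""
        return sorted(set(self.labels))
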