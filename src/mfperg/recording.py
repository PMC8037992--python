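"""Continuous ERG recording container.

A recording holds one repetition of the multifocal run: one full m-sequence
cycle of raw electrode samples at 1200 Hz, split into 32 equal segments for
artifact bookkeeping (segments contaminated by blinks or noise are flagged
and excluded from kernel averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_FS = 1200.0
N_SEGMENTS = 32


@dataclass
class ContinuousRecording:
    samples: np.ndarray            # µV
    fs: float                      # Hz
    n_states: int                  # m-sequence states covered (one full cycle)
    samples_per_state: int
    segment_boundaries: np.ndarray  # int array, len n_segments + 1
    artifact_flags: np.ndarray      # bool per segment
    repetition: int = 1
    eye: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.segment_boundaries = np.asarray(self.segment_boundaries, dtype=int)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if len(self.artifact_flags) != len(self.segment_boundaries) - 1:
            raise ValueError("artifact_flags must have one entry per segment")

    @property
    def n_segments(self) -> int:
        return len(self.artifact_flags)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def segment_of_sample(self) -> np.ndarray:
        """Segment index for every sample."""
        return (
            np.searchsorted(self.segment_boundaries, np.arange(len(self.samples)),
                            side="right") - 1
        )

    def copy(self) -> "ContinuousRecording":
        return replace(
            self,
            samples=self.samples.copy(),
            segment_boundaries=self.segment_boundaries.copy(),
            artifact_flags=self.artifact_flags.copy(),
        )


def make_segment_boundaries(n_samples: int, n_segments: int = N_SEGMENTS) -> np.ndarray:
    return np.round(np.linspace(0, n_samples, n_segments + 1)).astype(int)
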