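"""First-slice second-order kernel recovery from continuous recordings.

For a binary pattern-reversal m-sequence design the first slice of the
second-order kernel is the response component locked to stimulus state
transitions: epochs following reversal states (bit 1) enter with weight +1,
epochs following no-reversal states (bit 0) with weight −1.  Because the
per-element modulations are shifted copies of one maximal-length sequence,
the ±1-weighted epoch sum divided by the number of reversal states is an
*exact* inverse of the linear forward model whenever the shift separation
exceeds the epoch span: cross-element and overlap terms cancel identically
over one full cycle (two-level autocorrelation), so a noise-free synthesis
round-trips to the generating templates to numerical precision.

Acquisition-convention kernels arrive polarity-inverted and are flipped back
before waveform measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .msequence import ReversalSchedule
from .recording import ContinuousRecording

RAW = "raw"
FLIPPED_BACK = "flipped-back"


@dataclass
class KernelSet:
    """Per-element kernel epochs (µV, 0..epoch_ms post state onset)."""

    traces: np.ndarray          # (n_elements, n_samples)
    fs: float
    epoch_ms: float
    polarity_convention: str
    n_states_used: np.ndarray   # per element
    eye: str | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.n_states_used = np.asarray(self.n_states_used, dtype=int)
        if len(self.n_states_used) != self.traces.shape[0]:
            raise ValueError("n_states_used must have one entry per element")

    @property
    def n_elements(self) -> int:
        return self.traces.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) * 1000.0 / self.fs

    def copy(self) -> "KernelSet":
        return replace(self, traces=self.traces.copy(),
                       n_states_used=self.n_states_used.copy())


def reject_artifacts(
    recording: ContinuousRecording, threshold_uV: float = 100.0
) -> tuple[ContinuousRecording, int]:
    """Flag segments whose peak-to-peak amplitude exceeds the threshold.

    Returns the flagged recording (a copy) and the number of rejected
    segments.  Raises if every segment is rejected.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    rec = recording.copy()
    for s in range(rec.n_segments):
        lo, hi = rec.segment_boundaries[s], rec.segment_boundaries[s + 1]
        seg = rec.samples[lo:hi]
        if len(seg) and np.ptp(seg) > threshold_uV:
            rec.artifact_flags[s] = True
    n_rejected = int(rec.artifact_flags.sum())
    if n_rejected == rec.n_segments:
        raise ValueError("all segments rejected; recording unusable")
    return rec, n_rejected


def extract_first_slice(
    recording: ContinuousRecording,
    schedules: Sequence[ReversalSchedule],
    epoch_ms: float = 120.0,
) -> KernelSet:
    """Recover all per-element kernels from one recording.

    Epochs overlapping artifact-flagged segments are dropped.  The cycle is
    treated as circular (the m-sequence is periodic), so epochs started near
    the end of the cycle wrap around.
    """
    fs = recording.fs
    spp = recording.samples_per_state
    n_states = recording.n_states
    n_cycle = n_states * spp
    if len(recording.samples) < n_cycle:
        raise ValueError(
            f"recording has {len(recording.samples)} samples but one cycle "
            f"needs {n_cycle}: timing mismatch"
        )
    epoch_len = int(round(epoch_ms / 1000.0 * fs))
    samples = recording.samples[:n_cycle]

    bad_sample = np.zeros(n_cycle, dtype=bool)
    for s in np.flatnonzero(recording.artifact_flags):
        lo = recording.segment_boundaries[s]
        hi = min(recording.segment_boundaries[s + 1], n_cycle)
        bad_sample[lo:hi] = True

    onsets = np.arange(n_states) * spp
    idx = (onsets[:, None] + np.arange(epoch_len)[None, :]) % n_cycle
    epochs = samples[idx]                      # (n_states, epoch_len)
    good = ~bad_sample[idx].any(axis=1)        # epoch usable?

    n_el = len(schedules)
    traces = np.empty((n_el, epoch_len))
    used = np.empty(n_el, dtype=int)
    for e, sched in enumerate(schedules):
        if sched.n_states != n_states:
            raise ValueError(
                f"schedule for element {e} has {sched.n_states} states, "
                f"recording covers {n_states}: timing mismatch"
            )
        a = (2.0 * sched.state_values - 1.0)   # ±1 encoding
        w = np.where(good, a, 0.0)
        n_pos = int(np.sum(good & (sched.state_values == 1)))
        if n_pos == 0:
            raise ValueError(f"element {e}: no usable reversal epochs remain")
        traces[e] = w @ epochs / n_pos
        used[e] = int(good.sum())

    return KernelSet(
        traces=traces,
        fs=fs,
        epoch_ms=epoch_ms,
        polarity_convention=RAW,
        n_states_used=used,
        eye=recording.eye,
    )


def flip_polarity(kernels: KernelSet) -> KernelSet:
    """Negate all traces, restoring the conventional recording polarity."""
    if kernels.polarity_convention != RAW:
        raise ValueError(
            f"kernels already {kernels.polarity_convention}; refusing double flip"
        )
    out = kernels.copy()
    out.traces = -out.traces
    out.polarity_convention = FLIPPED_BACK
    return out


def average_repetitions(kernel_sets: Sequence[KernelSet]) -> KernelSet:
    """Pointwise mean across repetitions, weighted by states used per element."""
    if not kernel_sets:
        raise ValueError("no kernel sets to average")
    ref = kernel_sets[0]
    for ks in kernel_sets[1:]:
        if ks.traces.shape != ref.traces.shape:
            raise ValueError("mismatched epoch lengths or element counts")
        if ks.polarity_convention != ref.polarity_convention:
            raise ValueError("mixed polarity conventions")
    weights = np.stack([ks.n_states_used for ks in kernel_sets])  # (rep, el)
    traces = np.stack([ks.traces for ks in kernel_sets])          # (rep, el, t)
    wsum = weights.sum(axis=0)
    if np.any(wsum == 0):
        raise ValueError("element with zero usable states in every repetition")
    mean = np.einsum("re,ret->et", weights.astype(float), traces) / wsum[:, None]
    return KernelSet(
        traces=mean,
        fs=ref.fs,
        epoch_ms=ref.epoch_ms,
        polarity_convention=ref.polarity_convention,
        n_states_used=wsum,
        eye=ref.eye,
    )
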