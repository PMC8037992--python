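"""Maximal-length sequences and multifocal stimulus geometry.

The multifocal pattern-reversal stimulus is a dartboard of 36 checkerboard
elements in 4 eccentricity rings.  Each element follows its own binary
pseudo-random modulation (1 = pattern reversal, 0 = no reversal), one state
per two video frames.  All elements share one mother m-sequence; element k
plays the sequence delayed by ``k * shift_spacing`` states, the standard
multifocal construction that decorrelates elements over a full cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MSeq",
    "StimulusDesign",
    "ReversalSchedule",
    "DEFAULT_TAPS",
    "generate_msequence",
    "build_geometry",
    "build_schedule",
]

#: Feedback polynomials x^m + ... + 1 known to be primitive over GF(2),
#: given as exponent sets.  Each verified maximal by exhaustive state walk.
DEFAULT_TAPS: dict[int, frozenset[int]] = {
    2: frozenset({2, 1}),
    3: frozenset({3, 2}),
    4: frozenset({4, 3}),
    5: frozenset({5, 3}),
    6: frozenset({6, 5}),
    7: frozenset({7, 6}),
    8: frozenset({8, 6, 5, 4}),
    9: frozenset({9, 5}),
    10: frozenset({10, 7}),
    11: frozenset({11, 9}),
    12: frozenset({12, 11, 10, 4}),
    13: frozenset({13, 12, 11, 8}),
    14: frozenset({14, 13, 12, 2}),
    15: frozenset({15, 14}),
    16: frozenset({16, 15, 13, 4}),
}


@dataclass(frozen=True)
class MSeq:
    """One period of a maximal-length binary sequence.

    Attributes
    ----------
    register_length
        Number of stages m of the generating shift register.
    taps
        Exponents of the feedback polynomial (must include m).
    bits
        uint8 array of one full period, values in {0, 1}.
    period
        ``2**register_length - 1``.
    """

    register_length: int
    taps: frozenset[int]
    bits: np.ndarray
    period: int

    def as_pm1(self) -> np.ndarray:
        """Sequence in the ±1 encoding (bit 1 → +1, bit 0 → −1)."""
        return (2 * self.bits.astype(np.int8) - 1).astype(np.int8)


@dataclass(frozen=True)
class StimulusDesign:
    """Dartboard geometry plus per-element sequence shifts.

    Ring indexing is 1-based (ring 1 central); element indexing 0-based.
    ``element_angles`` holds each element's sector-center angle in degrees,
    counter-clockwise from the positive horizontal meridian, used by the
    left-right flip of right-eye data.
    """

    frame_rate: float = 75.0
    frames_per_state: int = 2
    ring_bounds: tuple[float, ...] = (0.0, 3.6, 7.6, 14.3, 22.7)
    elements_per_ring: tuple[int, ...] = (4, 8, 12, 12)
    element_ring_map: tuple[int, ...] = ()
    element_shifts: tuple[int, ...] = ()
    element_angles: tuple[float, ...] = ()
    checks_per_element: tuple[int, int] = (4, 4)
    mean_luminance_cd_m2: float = 56.0

    @property
    def state_duration_s(self) -> float:
        return self.frames_per_state / self.frame_rate

    @property
    def n_elements(self) -> int:
        return len(self.element_ring_map)

    def elements_in_ring(self, ring: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.element_ring_map) == ring)


@dataclass(frozen=True)
class ReversalSchedule:
    """Per-element reversal schedule: state onset times and binary states."""

    element: int
    state_times_s: np.ndarray
    state_values: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.state_values)

    def reversal_count(self) -> int:
        return int(self.state_values.sum())

    def mean_reversal_rate(self) -> float:
        """Reversals per second averaged over the schedule."""
        dt = self.state_times_s[1] - self.state_times_s[0] if self.n_states > 1 else 1.0
        return self.reversal_count() / (self.n_states * dt)


def generate_msequence(
    register_length: int,
    taps: frozenset[int] | set[int] | None = None,
    seed_state: int | None = None,
) -> MSeq:
    """Generate one period of a maximal-length sequence from a Fibonacci LFSR.

    Parameters
    ----------
    register_length
        Register size m; the sequence period is ``2**m - 1``.
    taps
        Feedback polynomial exponents; must contain ``register_length``.
        Defaults to a verified primitive polynomial for m in 2..16.
    seed_state
        Nonzero initial register contents; defaults to all ones.

    Raises
    ------
    ValueError
        If the seed is zero, the taps are malformed, or the taps are not
        primitive (detected by the state walk closing early).
    """
    m = int(register_length)
    if m < 2:
        raise ValueError("register_length must be >= 2")
    if taps is None:
        if m not in DEFAULT_TAPS:
            raise ValueError(f"no default taps for register_length={m}; pass taps")
        taps = DEFAULT_TAPS[m]
    taps = frozenset(int(t) for t in taps)
    if m not in taps:
        raise ValueError(f"taps must include the register length {m}")
    if not all(1 <= t <= m for t in taps):
        raise ValueError(f"tap positions must lie in 1..{m}, got {sorted(taps)}")

    full = (1 << m) - 1
    state = full if seed_state is None else int(seed_state)
    if state == 0:
        raise ValueError("seed_state must be nonzero")
    if not 0 < state <= full:
        raise ValueError(f"seed_state must fit in {m} bits")

    mask = 0
    for t in taps:
        mask |= 1 << (t - 1)

    period = full
    bits = np.empty(period, dtype=np.uint8)
    init = state
    for i in range(period):
        bits[i] = (state >> (m - 1)) & 1
        fb = (state & mask).bit_count() & 1
        state = ((state << 1) & full) | fb
        if state == init and i + 1 < period:
            raise ValueError(
                f"taps {sorted(taps)} are not primitive: period {i + 1} < {period}"
            )
    if state != init:
        raise ValueError(f"taps {sorted(taps)} are not primitive (no cycle closure)")
    return MSeq(register_length=m, taps=taps, bits=bits, period=period)


def build_geometry(
    ring_bounds: tuple[float, ...] = (0.0, 3.6, 7.6, 14.3, 22.7),
    elements_per_ring: tuple[int, ...] = (4, 8, 12, 12),
    shift_spacing: int = 400,
    *,
    period: int | None = None,
    epoch_states: int = 5,
    frame_rate: float = 75.0,
    frames_per_state: int = 2,
) -> StimulusDesign:
    """Assemble the dartboard design with per-element sequence shifts.

    Shifts are ``element_index * shift_spacing`` states.  When ``period`` is
    given, the spacing is validated: all pairwise shift separations (in both
    directions around the cycle) must exceed ``epoch_states``, otherwise the
    analysis epoch of one element would overlap the kernel of another
    (cross-contamination), and the total span must fit inside one period.
    """
    ring_bounds = tuple(float(b) for b in ring_bounds)
    elements_per_ring = tuple(int(n) for n in elements_per_ring)
    if len(elements_per_ring) != len(ring_bounds) - 1:
        raise ValueError("elements_per_ring must have len(ring_bounds) - 1 entries")
    if any(b2 <= b1 for b1, b2 in zip(ring_bounds, ring_bounds[1:])):
        raise ValueError("ring_bounds must be strictly increasing")
    if any(n < 1 for n in elements_per_ring):
        raise ValueError("each ring needs at least one element")

    n_elements = sum(elements_per_ring)
    ring_map: list[int] = []
    angles: list[float] = []
    for ring_idx, n in enumerate(elements_per_ring, start=1):
        ring_map.extend([ring_idx] * n)
        # sector centers, counter-clockwise, first sector straddling 0..360/n
        angles.extend(((i + 0.5) * 360.0 / n) % 360.0 for i in range(n))

    shift_spacing = int(shift_spacing)
    if shift_spacing < 1:
        raise ValueError("shift_spacing must be positive")
    shifts = tuple(i * shift_spacing for i in range(n_elements))
    if period is not None:
        if shift_spacing * n_elements >= period:
            raise ValueError(
                f"shift_spacing {shift_spacing} x {n_elements} elements >= period "
                f"{period}: kernels would cross-contaminate"
            )
        sep = _min_pairwise_separation(shifts, period)
        if sep <= epoch_states:
            raise ValueError(
                f"minimum shift separation {sep} states does not exceed the "
                f"analysis epoch ({epoch_states} states)"
            )

    return StimulusDesign(
        frame_rate=frame_rate,
        frames_per_state=frames_per_state,
        ring_bounds=ring_bounds,
        elements_per_ring=elements_per_ring,
        element_ring_map=tuple(ring_map),
        element_shifts=shifts,
        element_angles=tuple(angles),
    )


def _min_pairwise_separation(shifts: tuple[int, ...], period: int) -> int:
    s = np.asarray(shifts) % period
    d = np.abs(s[:, None] - s[None, :])
    d = np.minimum(d, period - d)
    d[np.diag_indices_from(d)] = period
    return int(d.min())


def build_schedule(mseq: MSeq, design: StimulusDesign, element: int) -> ReversalSchedule:
    """Reversal schedule of one element: the mother sequence delayed by its shift.

    State k of the element equals the mother sequence bit at
    ``(k + shift) mod period``; states start at t = 0 and are spaced
    ``frames_per_state / frame_rate`` seconds apart.
    """
    if not 0 <= element < design.n_elements:
        raise ValueError(f"element {element} outside 0..{design.n_elements - 1}")
    shift = design.element_shifts[element]
    values = np.roll(mseq.bits, -shift)
    times = np.arange(mseq.period) * design.state_duration_s
    return ReversalSchedule(element=element, state_times_s=times, state_values=values)


def build_all_schedules(mseq: MSeq, design: StimulusDesign) -> list[ReversalSchedule]:
    return [build_schedule(mseq, design, e) for e in range(design.n_elements)]


def design_to_frame(design: StimulusDesign):
    """Geometry as a tidy table (element, ring, shift, angle_deg)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "element": np.arange(design.n_elements),
            "ring": list(design.element_ring_map),
            "shift_states": list(design.element_shifts),
            "angle_deg": list(design.element_angles),
        }
    )
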