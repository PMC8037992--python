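"""Kernel extraction: artifact rejection, round trips, polarity, averaging."""

import numpy as np
import pytest

from mfperg.cohort import synthesize_recording
from mfperg.kernels import (
    FLIPPED_BACK,
    RAW,
    average_repetitions,
    extract_first_slice,
    flip_polarity,
    reject_artifacts,
)
from mfperg.msequence import build_all_schedules, build_geometry, generate_msequence
from mfperg.recording import ContinuousRecording, make_segment_boundaries


def quiet_recording(n_states=1023, spp=32, fs=1200.0):
    n = n_states * spp
    return ContinuousRecording(
        samples=np.zeros(n), fs=fs, n_states=n_states, samples_per_state=spp,
        segment_boundaries=make_segment_boundaries(n),
        artifact_flags=np.zeros(32, dtype=bool),
    )


class TestRejectArtifacts:
    def test_clean_recording_keeps_all_segments(self, rng):
        rec = quiet_recording()
        rec.samples += rng.normal(0, 3, len(rec.samples))
        _, n = reject_artifacts(rec, threshold_uV=100.0)
        assert n == 0

    def test_injected_blinks_flag_their_segments(self):
        rec = quiet_recording()
        hit = [3, 11, 27]
        for s in hit:
            lo = rec.segment_boundaries[s]
            rec.samples[lo + 50: lo + 170] += 300.0 * np.hanning(120)
        out, n = reject_artifacts(rec, threshold_uV=100.0)
        assert n == 3
        assert sorted(np.flatnonzero(out.artifact_flags)) == hit

    def test_rejected_count_non_increasing_in_threshold(self):
        rec = quiet_recording()
        for s, amp in enumerate(range(100, 900, 100)):   # 8 graded transients
            lo = rec.segment_boundaries[2 * s]
            rec.samples[lo + 40: lo + 160] += amp * np.hanning(120)
        counts = [reject_artifacts(rec, thr)[1]
                  for thr in (50, 150, 350, 550, 850)]
        assert counts == [8, 7, 5, 3, 0]
        assert counts == sorted(counts, reverse=True)

    def test_all_rejected_is_an_error(self):
        rec = quiet_recording()
        rec.samples += 1000.0 * np.sin(np.arange(len(rec.samples)))
        with pytest.raises(ValueError, match="all segments"):
            reject_artifacts(rec, threshold_uV=10.0)


class TestExtractFirstSlice:
    def test_single_element_round_trip(self, mseq10):
        """A known template inserted at every reversal is recovered exactly."""
        design = build_geometry(ring_bounds=(0, 5), elements_per_ring=(1,),
                                shift_spacing=1)
        sched = build_all_schedules(mseq10, design)
        t = np.arange(144) / 1200 * 1000
        template = np.exp(-0.5 * ((t - 50) / 8) ** 2) - 0.6 * np.exp(
            -0.5 * ((t - 80) / 10) ** 2)
        rec = synthesize_recording(template[None, :], design, sched,
                                   noise_sd=0.0, blink_rate_per_min=0.0,
                                   polarity=+1)
        ks = extract_first_slice(rec, sched)
        assert np.abs(ks.traces[0] - template).max() < 1e-9
        assert ks.n_states_used[0] == mseq10.period

    def test_full_design_round_trip_and_cross_talk(self, design10, schedules10, rng):
        """36 shifted elements, noise-free: every kernel equals its own
        template; cross-contamination is at numerical zero."""
        templates = rng.normal(0, 1, (36, 144))
        templates *= np.hanning(144)
        rec = synthesize_recording(templates, design10, schedules10,
                                   noise_sd=0.0, blink_rate_per_min=0.0,
                                   polarity=+1)
        ks = extract_first_slice(rec, schedules10)
        err = np.abs(ks.traces - templates).max()
        assert err < 1e-6
        peak = np.abs(templates).max()
        assert err < 0.01 * peak

    def test_extraction_is_linear(self, design10, schedules10, rng):
        t1 = rng.normal(0, 1, (36, 144)) * np.hanning(144)
        t2 = rng.normal(0, 1, (36, 144)) * np.hanning(144)
        recs = []
        for t in (t1, t2, t1 + t2):
            recs.append(synthesize_recording(t, design10, schedules10,
                                             noise_sd=0.0, blink_rate_per_min=0.0,
                                             polarity=+1))
        k1, k2, k12 = (extract_first_slice(r, schedules10).traces for r in recs)
        assert np.allclose(k1 + k2, k12, atol=1e-9)

    def test_noise_scaling_law(self, rng):
        """Kernel RMS from pure white noise shrinks like 1/sqrt(states used)."""
        rms = {}
        for m in (8, 10):
            seq = generate_msequence(m)
            design = build_geometry(ring_bounds=(0, 5), elements_per_ring=(1,),
                                    shift_spacing=1)
            sched = build_all_schedules(seq, design)
            vals = []
            for _ in range(6):
                rec = quiet_recording(n_states=seq.period)
                rec.samples = rng.normal(0, 5.0, len(rec.samples))
                vals.append(float(np.sqrt(
                    (extract_first_slice(rec, sched).traces ** 2).mean())))
            rms[m] = np.mean(vals)
        ratio = rms[8] / rms[10]
        expected = np.sqrt((2 ** 10 - 1) / (2 ** 8 - 1))
        assert ratio == pytest.approx(expected, rel=0.25)

    def test_rejected_segments_are_excluded(self, mseq10):
        design = build_geometry(ring_bounds=(0, 5), elements_per_ring=(1,),
                                shift_spacing=1)
        sched = build_all_schedules(mseq10, design)
        rec = quiet_recording(n_states=mseq10.period)
        rec.artifact_flags[5] = True
        ks = extract_first_slice(rec, sched)
        assert ks.n_states_used[0] < mseq10.period

    def test_timing_mismatch_is_an_error(self, schedules10):
        rec = quiet_recording(n_states=511)
        with pytest.raises(ValueError, match="mismatch"):
            extract_first_slice(rec, schedules10)


class TestFlipPolarity:
    def test_flip_negates_and_double_flip_errors(self, design10, schedules10):
        rec = quiet_recording()
        rec.samples[:] = 0.0
        ks = extract_first_slice(rec, schedules10)
        ks.traces = np.arange(36 * 144, dtype=float).reshape(36, 144)
        flipped = flip_polarity(ks)
        assert flipped.polarity_convention == FLIPPED_BACK
        assert np.array_equal(flipped.traces, -ks.traces)
        with pytest.raises(ValueError, match="double flip"):
            flip_polarity(flipped)

    def test_acquisition_polarity_gives_positive_p1_after_flip_back(
            self, design10, schedules10, control_ring1_template):
        """With the acquisition sign convention (polarity −1), raw kernels are
        inverted; flipping back restores a positive P1, as printed for the
        control group."""
        traces = np.tile(control_ring1_template.trace(), (36, 1))
        rec = synthesize_recording(traces, design10, schedules10,
                                   noise_sd=0.0, blink_rate_per_min=0.0,
                                   polarity=-1)
        ks = extract_first_slice(rec, schedules10)
        assert ks.polarity_convention == RAW
        i_p1 = np.argmin(ks.traces[0])   # raw P1 is a trough
        flipped = flip_polarity(ks)
        assert flipped.traces[0].max() > 0
        assert np.argmax(flipped.traces[0]) == i_p1   # peak times unchanged

    def test_flip_preserves_extremum_positions(self, rng, design10, schedules10):
        rec = quiet_recording()
        ks = extract_first_slice(rec, schedules10)
        ks.traces = rng.normal(size=(36, 144))
        flipped = flip_polarity(ks)
        assert np.array_equal(np.argmax(ks.traces, axis=1),
                              np.argmin(flipped.traces, axis=1))


class TestAverageRepetitions:
    def _kernel_set(self, traces, used, design10, schedules10):
        rec = quiet_recording()
        ks = extract_first_slice(rec, schedules10)
        ks.traces = traces
        ks.n_states_used = np.asarray(used)
        return ks

    def test_identical_repetitions_are_idempotent(self, rng, design10, schedules10):
        tr = rng.normal(size=(36, 144))
        reps = [self._kernel_set(tr.copy(), np.full(36, 1023), design10, schedules10)
                for _ in range(3)]
        avg = average_repetitions(reps)
        assert np.allclose(avg.traces, tr)
        assert np.array_equal(avg.n_states_used, np.full(36, 3069))

    def test_noise_variance_shrinks_by_repetition_count(self, rng, design10,
                                                        schedules10):
        single = rng.normal(size=(50, 36, 144))
        reps = [self._kernel_set(single[i], np.full(36, 1023), design10, schedules10)
                for i in range(3)]
        avg = average_repetitions(reps[:3])
        ratio = avg.traces.var() / single[0].var()
        assert ratio == pytest.approx(1 / 3, rel=0.15)

    def test_zero_weight_repetition_is_excluded(self, design10, schedules10):
        a = self._kernel_set(np.ones((36, 144)), np.full(36, 1000),
                             design10, schedules10)
        b = self._kernel_set(np.full((36, 144), 3.0), np.full(36, 1000),
                             design10, schedules10)
        dead = self._kernel_set(np.full((36, 144), 99.0), np.zeros(36),
                                design10, schedules10)
        avg = average_repetitions([a, b, dead])
        assert np.allclose(avg.traces, 2.0)   # mean of the two live repetitions

    def test_mismatched_epochs_rejected(self, design10, schedules10):
        a = self._kernel_set(np.ones((36, 144)), np.full(36, 10), design10, schedules10)
        b = self._kernel_set(np.ones((36, 100)), np.full(36, 10), design10, schedules10)
        b.traces = np.ones((36, 100))
        with pytest.raises(ValueError, match="mismatched"):
            average_repetitions([a, b])
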