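"""Synthetic cohort generators: sampling, templates, recordings, OCT data."""

import numpy as np
import pytest

from mfperg import calibration as cal
from mfperg.cohort import (
    calibrate_ring_template,
    draw_subject_params,
    sample_cohort,
    synthesize_layer_data,
    synthesize_recording,
)
from mfperg.oct_sectors import summarize_etdrs, summarize_prnfl
from mfperg.waveform import bandpass_filter, detect_peaks


class TestSampleCohort:
    def test_default_sizes_match_study(self):
        records = sample_cohort(seed=0)
        assert len(records) == 37
        by_group = {g: sum(r.group == g for r in records)
                    for g in ("Control", "NON", "HON")}
        assert by_group == {"Control": 14, "NON": 12, "HON": 11}

    def test_small_cohort_fields_populated(self):
        records = sample_cohort((2, 2, 2), seed=1)
        assert len(records) == 6
        for r in records:
            assert r.eye in ("OD", "OS")
            assert r.sex in ("M", "F")
            assert 18 <= r.age_y <= 65
            if r.group == "Control":
                assert r.duration_y is None
            else:
                assert r.duration_y is not None and r.duration_y > 0

    def test_deterministic_under_seed(self):
        a = sample_cohort(seed=7)
        b = sample_cohort(seed=7)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_non_durations_match_calibration(self):
        """Monte-Carlo: many sampled NON disease durations recover the
        calibrated 6.4 y mean (truncation keeps the check loose-ish)."""
        durs = [r.duration_y for r in sample_cohort((2, 1000, 2), seed=3)
                if r.group == "NON"]
        se = 4.6 / np.sqrt(len(durs))
        assert abs(np.mean(durs) - 6.4) < 3 * se + 0.6   # + truncation shift

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sample_cohort((1, 2, 2), seed=0)


class TestDrawSubjectParams:
    def test_zero_between_subject_sd_hits_group_means(self):
        p = draw_subject_params("Control", between_subject_sd=0.0, seed=0)
        assert p.template.targets[1]["N2"][0] == pytest.approx(-1.5)
        assert p.template.targets[1]["P1"][0] == pytest.approx(1.24)
        assert p.macular_targets["GCL"]["parafoveal"] == pytest.approx(51.75)
        assert p.disc_targets["PMB"] == pytest.approx(54.33)

    def test_control_ring1_n2_mean_recovers_calibration(self):
        """Monte-Carlo over draws: the ring-1 N2 parameter mean sits within
        3 SE of the control calibration mean −1.5 µV."""
        n = 400
        rng = np.random.default_rng(11)
        vals = [draw_subject_params("Control", seed=rng).template.targets[1]["N2"][0]
                for _ in range(n)]
        se = 0.39 / np.sqrt(n)
        assert abs(np.mean(vals) - (-1.5)) < 3 * se + 0.01

    def test_hon_parafoveal_gcl_mean(self):
        n = 600
        rng = np.random.default_rng(13)
        vals = [draw_subject_params("HON", seed=rng).macular_targets["GCL"]["parafoveal"]
                for _ in range(n)]
        se = 6.7 / np.sqrt(n)
        assert abs(np.mean(vals) - 40.14) < 3 * se

    def test_time_ordering_enforced(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = draw_subject_params("HON", seed=rng)
            for ring, comps in p.template.targets.items():
                assert comps["N1"][1] < comps["P1"][1] < comps["N2"][1]

    def test_missing_calibration_cell_named(self):
        mf = cal.load_mfperg_calibration()
        broken = mf[~((mf.group == "HON") & (mf.ring == 3) & (mf.component == "P1"))]
        with pytest.raises(KeyError, match="group=HON, ring=3, component=P1"):
            draw_subject_params("HON", mf_calibration=broken, seed=0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            draw_subject_params("Patients", seed=0)


class TestTemplateCalibration:
    def test_measured_conventions_match_targets(self):
        amp_t = (-2.02, 5.02, -4.52)    # control peripheral-ring parameters
        time_t = (25.0, 43.33, 70.42)
        tpl = calibrate_ring_template(amp_t, time_t)
        pk = detect_peaks(bandpass_filter(tpl.trace()))
        assert pk.n1_amp == pytest.approx(amp_t[0], abs=0.01)
        assert pk.p1_amp == pytest.approx(amp_t[1], abs=0.01)
        assert pk.n2_amp == pytest.approx(amp_t[2], abs=0.01)
        assert pk.n1_time == pytest.approx(time_t[0], abs=0.5)

    def test_sign_violations_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            calibrate_ring_template((0.5, 1.0, -1.0), (25, 50, 75))
        with pytest.raises(ValueError, match="N1 < P1 < N2"):
            calibrate_ring_template((-0.5, 1.0, -1.0), (50, 25, 75))


class TestSynthesizeRecording:
    def test_noise_free_single_element_superposition(self, mseq10):
        from mfperg.msequence import build_all_schedules, build_geometry
        design = build_geometry(ring_bounds=(0, 5), elements_per_ring=(1,),
                                shift_spacing=1)
        sched = build_all_schedules(mseq10, design)
        template = np.zeros(144)
        template[10] = 1.0
        rec = synthesize_recording(template[None, :], design, sched,
                                   noise_sd=0.0, blink_rate_per_min=0.0,
                                   polarity=+1)
        manual = np.zeros(mseq10.period * 32)
        for k in np.flatnonzero(sched[0].state_values == 1):
            manual[(k * 32 + 10) % len(manual)] += 1.0
        assert np.allclose(rec.samples, manual, atol=1e-9)

    def test_rms_grows_with_noise(self, design10, schedules10):
        p = draw_subject_params("Control", between_subject_sd=0.0, seed=0)
        rms = []
        for sd in (0.0, 2.0, 5.0, 10.0):
            rec = synthesize_recording(p.template, design10, schedules10,
                                       noise_sd=sd, blink_rate_per_min=0.0, seed=4)
            rms.append(float(np.sqrt((rec.samples ** 2).mean())))
        assert rms == sorted(rms)

    def test_total_reversal_rate_across_elements(self, design10, schedules10):
        total = sum(s.mean_reversal_rate() for s in schedules10)
        assert total == pytest.approx(18.75 * 36, rel=0.01)

    def test_segment_structure(self, design10, schedules10):
        p = draw_subject_params("NON", between_subject_sd=0.0, seed=0)
        rec = synthesize_recording(p.template, design10, schedules10, seed=0)
        assert rec.n_segments == 32
        assert rec.segment_boundaries[0] == 0
        assert rec.segment_boundaries[-1] == len(rec.samples)

    def test_blinks_appear_at_configured_rate(self, design10, schedules10):
        p = draw_subject_params("Control", between_subject_sd=0.0, seed=0)
        rec0 = synthesize_recording(p.template, design10, schedules10,
                                    noise_sd=0.0, blink_rate_per_min=0.0, seed=9)
        rec1 = synthesize_recording(p.template, design10, schedules10,
                                    noise_sd=0.0, blink_rate_per_min=20.0, seed=9)
        assert rec1.samples.max() > rec0.samples.max() + 100.0


class TestSynthesizeLayerData:
    def test_uniform_targets_give_constant_map(self):
        data = synthesize_layer_data(
            {"GCL": {"center": 50.0, "parafoveal": 50.0, "perifoveal": 50.0}},
            {"G": 90.0, "PMB": 90.0, "T": 90.0},
            texture_sd=0.0, seed=0)
        assert np.allclose(data.maps["GCL"], 50.0, atol=1e-6)
        # G/T/PMB are the profile's contract; S/I/N carry the double-hump shape
        sec = summarize_prnfl(data.profile, data.profile_angles_deg)
        # sub-sample blending at sector borders leaks ~0.01 µm, far inside
        # the generator's 0.5 µm contract
        assert sec.g == pytest.approx(90.0, abs=0.05)
        assert sec.t == pytest.approx(90.0, abs=0.05)
        assert sec.pmb == pytest.approx(90.0, abs=0.05)
        assert sec.s == pytest.approx(sec.i, abs=0.05)

    def test_region_means_recover_random_targets(self, rng):
        """Sector/region means recover the generating targets to <0.5 µm for
        many random target sets."""
        for _ in range(25):
            mt = {"GCL": {r: float(rng.uniform(20, 60))
                          for r in ("center", "parafoveal", "perifoveal")}}
            g = float(rng.uniform(80, 110))
            t = float(rng.uniform(50, 80))
            pmb = float(rng.uniform(35, 60))
            data = synthesize_layer_data(mt, {"G": g, "PMB": pmb, "T": t},
                                         seed=rng)
            et = summarize_etdrs(data)
            for region, want in mt["GCL"].items():
                assert abs(et.value("GCL", region) - want) < 0.5
            sec = summarize_prnfl(data.profile, data.profile_angles_deg)
            assert abs(sec.pmb - pmb) < 0.5
            assert abs(sec.t - t) < 0.5
            assert abs(sec.g - g) < 0.5

    def test_region_error_decreases_with_smoothness(self):
        mt = {"GCL": {"center": 20.0, "parafoveal": 50.0, "perifoveal": 35.0}}
        disc = {"G": 95.0, "PMB": 45.0, "T": 61.0}
        errs = []
        for sm in (0.15, 0.05, 0.005):
            data = synthesize_layer_data(mt, disc, smoothness_mm=sm,
                                         texture_sd=0.0, seed=0)
            et = summarize_etdrs(data)
            errs.append(abs(et.value("GCL", "parafoveal") - 50.0))
        assert errs[0] > errs[-1]
        assert errs[-1] < 0.5

    def test_positive_everywhere_and_gcipl_identity(self, rng):
        p = draw_subject_params("HON", seed=rng)
        data = synthesize_layer_data(p.macular_targets, p.disc_targets, seed=rng)
        for layer, m in data.maps.items():
            assert (m > 0).all(), layer
        assert (data.profile > 0).all()
        assert np.array_equal(data.gcipl(), data.maps["GCL"] + data.maps["IPL"])

    def test_non_positive_target_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            synthesize_layer_data({"GCL": {"center": -1.0, "parafoveal": 50.0,
                                           "perifoveal": 50.0}},
                                  {"G": 90.0, "PMB": 50.0, "T": 60.0})

    def test_bit_reproducible_under_seed(self):
        mt = {"GCL": {"center": 20.0, "parafoveal": 50.0, "perifoveal": 35.0}}
        disc = {"G": 95.0, "PMB": 45.0, "T": 61.0}
        a = synthesize_layer_data(mt, disc, seed=21)
        b = synthesize_layer_data(mt, disc, seed=21)
        assert np.array_equal(a.maps["GCL"], b.maps["GCL"])
        assert np.array_equal(a.profile, b.profile)
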