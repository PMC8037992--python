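"""Synthetic cohort generation.

Emulates the study's raw material with known ground truth: a three-group
cohort (healthy controls, MS without optic neuritis = NON, MS with a
history of optic neuritis = HON), per-subject multifocal PERG response
templates, continuous noisy electrode recordings produced by the linear
forward model, and segmented macular/peripapillary OCT thickness data.

All group-level distributions are calibrated to the packaged summary tables
(see :mod:`mfperg.calibration`): amplitudes and thicknesses are normal with
the printed group mean/SD, peak times are normal around the printed group
median with SD = printed range / 4 (only medians and ranges are available
for times).

Waveform templates are sums of three signed Gaussian lobes (N1, P1, N2).
Because the printed amplitudes are defined through the measurement chain
(baseline-referenced and trough-to-peak conventions, after 3-45 Hz
zero-phase filtering), lobe parameters are *calibrated*: a damped fixed
point adjusts lobe amplitudes and centers until the measured peaks of the
template equal the drawn targets.  Parameter recovery by the full pipeline
is then unbiased by construction, up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import calibration as cal
from .msequence import ReversalSchedule, StimulusDesign
from .recording import ContinuousRecording, make_segment_boundaries
from .waveform import DEFAULT_BAND, DEFAULT_BASELINE, DEFAULT_WINDOWS, bandpass_filter, detect_peaks

DEFAULT_FS = 1200.0
DEFAULT_EPOCH_MS = 120.0
#: Gaussian lobe widths (FWHM, ms) for N1/P1/N2; N2 is the broadest wave.
DEFAULT_LOBE_FWHM = (8.0, 12.0, 15.0)
#: Width of the late positive recovery lobe the calibration may use.
RECOVERY_FWHM = 18.0
#: Correlation between component amplitudes within a subject.
AMP_CORRELATION = 0.6
#: Emmetropic schematic-eye conversion for the macular grid.
DEGREES_PER_MM = 3.44

_GROUP_SIZES = {"Control": 14, "NON": 12, "HON": 11}


# --------------------------------------------------------------------------
# cohort table
# --------------------------------------------------------------------------

@dataclass
class CohortRecord:
    subject_id: str
    group: str
    age_y: float
    sex: str
    eye: str
    duration_y: float | None = None
    edss: float | None = None
    bcva_logmar: float | None = None


def _trunc_normal(rng, mean, sd, low, high, max_tries=1000):
    if sd == 0 or np.isnan(sd):
        return float(np.clip(mean, low, high))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def sample_cohort(
    n_per_group: tuple[int, int, int] = (14, 12, 11),
    demographics: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> list[CohortRecord]:
    """Draw a synthetic cohort table (one randomly selected eye per subject).

    Group sizes default to the study's 14 controls / 12 NON / 11 HON.
    Continuous demographics are truncated normals with the calibrated
    mean/SD/range; the analysis eye is Bernoulli(0.5).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demo = demographics if demographics is not None else cal.load_cohort_demographics()
    records: list[CohortRecord] = []
    for group, n in zip(cal.GROUPS, n_per_group):
        if n < 2:
            raise ValueError(f"need at least 2 subjects per group, got {n} for {group}")

        def row(var):
            sel = demo[(demo.group == group) & (demo.variable == var)]
            return sel.iloc[0] if len(sel) else None

        female_frac = row("female_frac")
        for i in range(n):
            age = _trunc_normal(rng, *row("age_y")[["mean", "sd", "low", "high"]])
            sex = "F" if rng.random() < (female_frac["mean"] if female_frac is not None else 0.5) else "M"
            eye = "OD" if rng.random() < 0.5 else "OS"
            dur = edss = None
            if group != "Control":
                dur = _trunc_normal(rng, *row("duration_y")[["mean", "sd", "low", "high"]])
                e = row("edss")
                edss = round(_trunc_normal(rng, *e[["mean", "sd", "low", "high"]]) * 2) / 2
            b = row("bcva_logmar")
            bcva = _trunc_normal(rng, *b[["mean", "sd", "low", "high"]]) if b is not None else None
            records.append(
                CohortRecord(
                    subject_id=f"{group}-{i + 1:02d}", group=group, age_y=age,
                    sex=sex, eye=eye, duration_y=dur, edss=edss, bcva_logmar=bcva,
                )
            )
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# --------------------------------------------------------------------------
# response templates
# --------------------------------------------------------------------------

@dataclass
class RingTemplate:
    """Three-lobe waveform of one eccentricity ring (µV vs ms)."""

    lobe_amps: np.ndarray       # absolute lobe amplitudes, signed
    lobe_times: np.ndarray      # centers, ms
    lobe_fwhm: np.ndarray       # widths, ms
    fs: float = DEFAULT_FS
    epoch_ms: float = DEFAULT_EPOCH_MS
    #: worst measured-amplitude residual left by calibration (µV)
    residual_uV: float = 0.0

    def trace(self) -> np.ndarray:
        n = int(round(self.epoch_ms / 1000.0 * self.fs))
        t = np.arange(n) * 1000.0 / self.fs
        sigma = self.lobe_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out = np.zeros(n)
        for a, mu, s in zip(self.lobe_amps, self.lobe_times, sigma):
            out += a * np.exp(-0.5 * ((t - mu) / s) ** 2)
        return out


@dataclass
class ResponseTemplate:
    """Per-subject mfPERG ground truth: one calibrated template per ring.

    ``element_scales`` multiply the ring template per element and average to
    one within each ring, so ring means reproduce the ring parameters.
    """

    ring_templates: dict[int, RingTemplate]
    targets: dict[int, dict[str, tuple[float, float]]]   # ring -> comp -> (amp, time)
    element_scales: np.ndarray | None = None

    def element_trace(self, element: int, design: StimulusDesign) -> np.ndarray:
        ring = design.element_ring_map[element]
        tr = self.ring_templates[ring].trace()
        if self.element_scales is not None:
            tr = tr * self.element_scales[element]
        return tr

    def element_traces(self, design: StimulusDesign) -> np.ndarray:
        return np.stack([self.element_trace(e, design) for e in range(design.n_elements)])


class TemplateCalibrationError(RuntimeError):
    pass


_FILTER_MATRICES: dict[tuple, np.ndarray] = {}


def _filter_matrix(band: tuple[float, float], fs: float, n: int) -> np.ndarray:
    """Matrix form of the zero-phase band-pass on length-n traces.

    Forward-backward filtering with odd-extension padding is linear in the
    input, so it is exactly a fixed matrix; applying it as a mat-vec is two
    orders of magnitude faster than per-call filtering, which matters inside
    the calibration solver.
    """
    key = (band, fs, n)
    if key not in _FILTER_MATRICES:
        _FILTER_MATRICES[key] = bandpass_filter(np.eye(n), *band, fs=fs).T
    return _FILTER_MATRICES[key]


def _measure_subsample(trace, fs, windows, baseline_window):
    """N1/P1/N2 measurement with parabolic sub-sample interpolation.

    Continuous in the trace (no sample quantization), which makes the
    calibration objective smooth enough for a derivative-based solver.
    Matches :func:`mfperg.waveform.detect_peaks` up to the interpolation.
    """
    t = np.arange(len(trace)) * 1000.0 / fs
    bmask = (t >= baseline_window[0]) & (t <= baseline_window[1])
    bl = trace[bmask].mean() if bmask.any() else 0.0
    dt = 1000.0 / fs

    def ext(lo, hi, kind, after=None):
        m = (t >= lo) & (t <= hi)
        if after is not None:
            m &= t > after
        idx = np.flatnonzero(m)
        if len(idx) < 3:
            return None
        seg = trace[idx]
        p = int(np.argmin(seg) if kind == "min" else np.argmax(seg))
        i = idx[p]
        if p == 0 or p == len(seg) - 1:
            return float(trace[i]), float(t[i]), False
        y0, y1, y2 = trace[i - 1], trace[i], trace[i + 1]
        denom = y0 - 2.0 * y1 + y2
        d = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5) if denom != 0 else 0.0
        return float(y1 - 0.25 * (y0 - y2) * d), float(t[i] + d * dt), True

    r1 = ext(*windows["N1"], "min")
    n1v, n1t, ok1 = r1 if r1 else (bl, windows["N1"][0], False)
    r2 = ext(*windows["P1"], "max", after=n1t if ok1 else None)
    p1v, p1t, ok2 = r2 if r2 else (n1v, windows["P1"][0], False)
    r3 = ext(*windows["N2"], "min", after=p1t if ok2 else None)
    n2v, n2t, ok3 = r3 if r3 else (p1v, windows["N2"][0], False)
    amps = np.array([n1v - bl, p1v - n1v, n2v - p1v])
    times = np.array([n1t, p1t, n2t])
    return amps, times, ok1 and ok2 and ok3


def calibrate_ring_template(
    amp_targets: tuple[float, float, float],
    time_targets: tuple[float, float, float],
    lobe_fwhm: tuple[float, float, float] = DEFAULT_LOBE_FWHM,
    fs: float = DEFAULT_FS,
    epoch_ms: float = DEFAULT_EPOCH_MS,
    filter_band: tuple[float, float] | None = DEFAULT_BAND,
    windows: Mapping[str, tuple[float, float]] | None = None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE,
    amp_tol: float = 5e-3,
    time_tol: float = 0.45,
    strict: bool = True,
) -> RingTemplate:
    """Fit lobe parameters so the *measured* peaks equal the targets.

    ``amp_targets`` are in measured conventions (N1 from baseline <= 0,
    P1 trough-to-peak >= 0, N2 peak-to-trough <= 0); ``time_targets`` are
    the N1/P1/N2 peak times in ms.  The measurement chain (optional
    band-pass, then windowed extremum detection) is exactly the one the
    analysis pipeline applies, so pipeline parameter recovery is unbiased
    by construction.

    Fitting is a bounded least-squares over the three component lobes plus
    a late positive "recovery" lobe outside the measured windows.  The
    recovery lobe matters under the 3 Hz high-pass: the filtered waveform
    has near-zero area, so a large P1 digs a trough into the N2 window
    that a shallow N2 target could not otherwise escape.  Lobe amplitudes
    are sign-bounded (the template always keeps N1/P1/N2 morphology) and
    centers stay within a few ms of their targets.

    A draw can still be infeasible (e.g. an N2 target far shallower than
    the filter's trough floor).  ``strict=True`` raises a
    :class:`TemplateCalibrationError` when the fit misses ``amp_tol`` or
    ``time_tol`` (about half the 0.83 ms sample spacing); ``strict=False``
    returns the best fit with its worst amplitude miss in ``residual_uV``.
    """
    from scipy.optimize import least_squares

    a_n1, a_p1, a_n2 = amp_targets
    if not (a_n1 <= 0 and a_p1 >= 0 and a_n2 <= 0):
        raise ValueError("amplitude targets violate sign conventions")
    t1, t2, t3 = time_targets
    if not t1 < t2 < t3:
        raise ValueError("time targets must satisfy N1 < P1 < N2")

    win = dict(DEFAULT_WINDOWS if windows is None else windows)
    fwhm = np.append(np.asarray(lobe_fwhm, float), RECOVERY_FWHM)
    target_a = np.array([a_n1, a_p1, a_n2])
    target_t = np.array([t1, t2, t3], dtype=float)

    n_samp = int(round(epoch_ms / 1000.0 * fs))
    fmat = (_filter_matrix(tuple(filter_band), fs, n_samp)
            if filter_band is not None else None)
    # largest target magnitude bounds the admissible lobe sizes: without it
    # the solver can satisfy the measured conventions with huge mutually
    # cancelling lobes, which would be unphysiological and inflate the raw
    # recording's amplitude out of proportion to the measured response
    amax = max(abs(a_n1), a_p1, abs(a_n2), 0.2)

    def residuals(x):
        tpl = RingTemplate(x[:4].copy(), x[4:].copy(), fwhm, fs, epoch_ms)
        tr = tpl.trace()
        if fmat is not None:
            tr = fmat @ tr
        ma, mt, _ = _measure_subsample(tr, fs, win, baseline_window)
        parsimony = 0.02 * x[:4] / amax
        return np.concatenate([(ma - target_a) / 0.005,
                               (mt - target_t) / 0.5, parsimony])

    lb = np.array([-2.0 * amax, 0.02, -2.0 * amax, 0.0,
                   t1 - 6.0, t2 - 6.0, t3 - 8.0, 100.0])
    ub = np.array([-0.02, 2.0 * amax, -0.02, 1.5 * amax,
                   t1 + 6.0, t2 + 6.0, t3 + 8.0, 112.0])
    # absolute peak values implied by the trough/peak conventions, clipped
    # to the admissible lobe signs (a shallow drawn N2 under a large P1
    # would otherwise initialize with an inverted N2 lobe)
    v = np.clip([a_n1, a_n1 + a_p1, a_n1 + a_p1 + a_n2],
                [-2.0 * amax, 0.02, -2.0 * amax], [-0.02, 2.0 * amax, -0.02])
    starts = [
        np.array([*v, 0.1, t1, t2, t3, 106.0]),
        np.array([min(v[0], -0.3), max(v[1], 0.5), min(v[2], -0.3), 1.0,
                  t1, t2, t3, 104.0]),
    ]

    best: tuple[float, float, RingTemplate] | None = None
    for x0 in starts:
        sol = least_squares(residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                            diff_step=1e-3, xtol=1e-4, ftol=1e-6, max_nfev=400)
        tpl = RingTemplate(sol.x[:4].copy(), sol.x[4:].copy(), fwhm, fs, epoch_ms)
        # score with the pipeline's sample-quantized detector
        tr = tpl.trace()
        if filter_band is not None:
            tr = bandpass_filter(tr, *filter_band, fs=fs)
        pk = detect_peaks(tr, fs=fs, windows=win, baseline_window=baseline_window)
        if pk.unmeasurable:
            continue
        amp_miss = float(np.max(np.abs(
            np.array([pk.n1_amp, pk.p1_amp, pk.n2_amp]) - target_a)))
        time_miss = float(np.max(np.abs(
            np.array([pk.n1_time, pk.p1_time, pk.n2_time]) - target_t)))
        if best is None or amp_miss < best[0]:
            tpl.residual_uV = amp_miss
            best = (amp_miss, time_miss, tpl)
        if amp_miss < amp_tol and time_miss <= time_tol:
            break

    if best is None:
        if strict:
            raise TemplateCalibrationError(
                f"no measurable template found for targets amp={amp_targets}, "
                f"time={time_targets}"
            )
        # infeasible draw: fall back to the untuned initial morphology; the
        # affected component may measure as unmeasurable downstream, which
        # the pipeline records rather than hides
        x0 = np.clip(starts[0], lb, ub)
        tpl = RingTemplate(x0[:4].copy(), x0[4:].copy(), fwhm, fs, epoch_ms)
        tpl.residual_uV = np.inf
        return tpl
    amp_miss, time_miss, tpl = best
    if strict and (amp_miss >= amp_tol or time_miss > time_tol):
        raise TemplateCalibrationError(
            f"calibration missed targets (amp miss {amp_miss:.4f} uV, "
            f"time miss {time_miss:.2f} ms) for amp={amp_targets}, "
            f"time={time_targets}"
        )
    return tpl


# --------------------------------------------------------------------------
# per-subject parameter draws
# --------------------------------------------------------------------------

@dataclass
class SubjectParams:
    """Ground-truth generating parameters of one synthetic subject."""

    group: str
    template: ResponseTemplate
    macular_targets: dict[str, dict[str, float]]   # layer -> region -> µm
    disc_targets: dict[str, float]                 # sector -> µm


def _draw_times(rng, medians, ranges, scale, windows):
    """Ordered N1/P1/N2 time draw, clipped 2 ms inside the search windows
    and at least 8 ms apart."""
    names = ("N1", "P1", "N2")
    t = [rng.normal(m, r / 4.0 * scale) if scale > 0 else m
         for m, r in zip(medians, ranges)]
    lo = [windows[c][0] + 2.0 for c in names]
    # N2 keeps a wider top margin: a broad late lobe pushed against the
    # window edge has its filtered trough outside the search range
    hi = [windows[c][1] - m for c, m in zip(names, (2.0, 2.0, 8.0))]
    t[0] = float(np.clip(t[0], lo[0], hi[0]))
    t[1] = float(np.clip(t[1], max(lo[1], t[0] + 8.0), hi[1]))
    t[2] = float(np.clip(t[2], max(lo[2], t[1] + 8.0), hi[2]))
    return tuple(t)


def draw_subject_params(
    group: str,
    mf_calibration: pd.DataFrame | None = None,
    oct_calibration: pd.DataFrame | None = None,
    between_subject_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    lobe_fwhm: tuple[float, float, float] = DEFAULT_LOBE_FWHM,
    filter_band: tuple[float, float] | None = DEFAULT_BAND,
    windows: Mapping[str, tuple[float, float]] | None = None,
    fs: float = DEFAULT_FS,
    epoch_ms: float = DEFAULT_EPOCH_MS,
) -> SubjectParams:
    """Draw one subject's generating parameters from the group calibration.

    ``between_subject_sd`` scales all calibrated SDs (0 gives every subject
    the group mean exactly).  Amplitude draws are clipped to their sign
    conventions; time draws are kept ordered and inside the search windows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if group not in cal.GROUPS:
        raise ValueError(f"unknown group {group!r}")
    mf = mf_calibration if mf_calibration is not None else cal.load_mfperg_calibration()
    oc = oct_calibration if oct_calibration is not None else cal.load_oct_calibration()
    win = dict(DEFAULT_WINDOWS if windows is None else windows)
    s = float(between_subject_sd)

    # Component amplitudes share a subject-level response-strength factor
    # (rho = AMP_CORRELATION between any two components): stronger
    # responders have deeper troughs and higher peaks everywhere.  The
    # marginals stay Normal(group mean, group SD); jointly infeasible
    # combinations (huge P1 with a near-flat N2) become rare.
    strength = rng.normal()

    ring_templates: dict[int, RingTemplate] = {}
    targets: dict[int, dict[str, tuple[float, float]]] = {}
    n_rings = int(mf.ring.max())
    for ring in range(1, n_rings + 1):
        cells = {c: cal.mfperg_cell(mf, group, ring, c) for c in cal.COMPONENTS}
        amps = {}
        for c, cell in cells.items():
            sign = 1.0 if c == "P1" else -1.0
            z = (np.sqrt(AMP_CORRELATION) * sign * strength
                 + np.sqrt(1.0 - AMP_CORRELATION) * rng.normal())
            a = cell.amp_mean_uV + cell.amp_sd_uV * s * z
            if c == "P1":
                a = max(a, 0.1)
            else:
                a = min(a, -0.05)
            amps[c] = float(a)
        times = _draw_times(
            rng,
            [cells[c].time_median_ms for c in cal.COMPONENTS],
            [cells[c].time_range_ms for c in cal.COMPONENTS],
            s, win,
        )
        targets[ring] = {c: (amps[c], times[i]) for i, c in enumerate(cal.COMPONENTS)}
        ring_templates[ring] = calibrate_ring_template(
            (amps["N1"], amps["P1"], amps["N2"]), times,
            lobe_fwhm=lobe_fwhm, fs=fs, epoch_ms=epoch_ms,
            filter_band=filter_band, windows=win, strict=False,
        )

    macular: dict[str, dict[str, float]] = {}
    for layer in cal.MACULAR_LAYERS:
        macular[layer] = {}
        for region in cal.MACULAR_REGIONS:
            cell = cal.oct_cell(oc, group, layer, region)
            v = rng.normal(cell.mean_um, cell.sd_um * s) if s > 0 else cell.mean_um
            macular[layer][region] = float(max(v, 1.0))

    disc: dict[str, float] = {}
    for sector in cal.DISC_SECTORS:
        cell = cal.oct_cell(oc, group, "pRNFL", sector)
        v = rng.normal(cell.mean_um, cell.sd_um * s) if s > 0 else cell.mean_um
        disc[sector] = float(max(v, 5.0))
    # keep the profile constructible: temporal-outside-bundle value positive
    disc["PMB"] = float(min(disc["PMB"], 2.5 * disc["T"]))

    template = ResponseTemplate(ring_templates=ring_templates, targets=targets)
    return SubjectParams(group=group, template=template,
                         macular_targets=macular, disc_targets=disc)


# --------------------------------------------------------------------------
# continuous recording forward model
# --------------------------------------------------------------------------

def synthesize_recording(
    template: ResponseTemplate | np.ndarray,
    design: StimulusDesign,
    schedules: Sequence[ReversalSchedule],
    noise_sd: float = 5.0,
    blink_rate_per_min: float = 2.0,
    seed: int | np.random.Generator = 0,
    fs: float = DEFAULT_FS,
    polarity: int = -1,
    repetition: int = 1,
    eye: str | None = None,
) -> ContinuousRecording:
    """Linear, time-invariant forward model of one recording repetition.

    The recording is the superposition over elements and reversal events of
    the element's template inserted at the event time (circularly over one
    full cycle), plus white noise and sparse high-amplitude blink
    transients.  ``polarity`` encodes the acquisition sign convention: the
    default −1 produces raw kernels that are inverted and must be "flipped
    back", as in conventional multifocal practice; +1 gives the plain
    superposition of the templates themselves.

    ``template`` may be a :class:`ResponseTemplate` or a pre-built
    ``(n_elements, epoch_samples)`` trace array.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not schedules:
        raise ValueError("need at least one schedule")
    n_states = schedules[0].n_states
    dt = schedules[0].state_times_s[1] - schedules[0].state_times_s[0]
    spp_f = dt * fs
    spp = int(round(spp_f))
    if abs(spp_f - spp) > 1e-9:
        raise ValueError(f"state duration {dt}s is not an integer number of samples at {fs} Hz")
    n = n_states * spp

    traces = (template.element_traces(design)
              if isinstance(template, ResponseTemplate) else np.asarray(template, float))
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.shape[0] != len(schedules):
        raise ValueError("one template trace per schedule required")
    if traces.shape[1] > n:
        raise ValueError("template longer than one full cycle")

    sig = np.zeros(n)
    pad = np.zeros(n)
    for sched, tr in zip(schedules, traces):
        if sched.n_states != n_states:
            raise ValueError("schedules must share a common cycle length")
        train = np.zeros(n)
        train[np.flatnonzero(sched.state_values == 1) * spp] = 1.0
        pad[:] = 0.0
        pad[: len(tr)] = tr
        sig += np.fft.irfft(np.fft.rfft(train) * np.fft.rfft(pad), n)
    sig *= polarity

    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, n)
    if blink_rate_per_min > 0:
        duration_min = n / fs / 60.0
        for _ in range(rng.poisson(blink_rate_per_min * duration_min)):
            amp = rng.uniform(200.0, 500.0)
            blen = int(rng.uniform(0.1, 0.3) * fs)
            start = int(rng.integers(0, max(n - blen, 1)))
            sig[start:start + blen] += amp * np.hanning(blen)

    return ContinuousRecording(
        samples=sig, fs=fs, n_states=n_states, samples_per_state=spp,
        segment_boundaries=make_segment_boundaries(n),
        artifact_flags=np.zeros(32, dtype=bool),
        repetition=repetition, eye=eye,
    )


# --------------------------------------------------------------------------
# OCT layer-thickness forward model
# --------------------------------------------------------------------------

@dataclass
class LayerThicknessData:
    """Segmented macular thickness maps plus a peripapillary circle profile.

    Maps cover a 30° x 25° field centered on the fovea; the profile holds
    768 samples on the 3.5 mm disc circle, indexed by eye-relative angle
    from the temporal meridian (the device's sector frame, identical for
    both eyes).  Thickness in µm.
    """

    maps: dict[str, np.ndarray]
    x_deg: np.ndarray
    y_deg: np.ndarray
    profile: np.ndarray
    profile_angles_deg: np.ndarray
    degrees_per_mm: float = DEGREES_PER_MM
    fovea_center_deg: tuple[float, float] = (0.0, 0.0)
    eye: str | None = None

    def gcipl(self) -> np.ndarray:
        """Ganglion cell + inner plexiform complex, pointwise."""
        return self.maps["GCL"] + self.maps["IPL"]


#: ETDRS ring radii, mm (1 / 3 / 6 mm diameter circles).
ETDRS_RADII_MM = (0.5, 1.5, 3.0)
#: Spectralis-style disc sector spans, degrees about the temporal meridian.
DEFAULT_SECTORS: dict[str, tuple[float, float]] = {
    "T": (-45.0, 45.0),
    "S": (45.0, 135.0),
    "N": (135.0, 225.0),
    "I": (225.0, 315.0),
    "PMB": (-15.0, 15.0),
}


def _region_masks_macula(x_deg, y_deg, fovea_center, degrees_per_mm):
    xx, yy = np.meshgrid(x_deg - fovea_center[0], y_deg - fovea_center[1])
    r_mm = np.hypot(xx, yy) / degrees_per_mm
    return {
        "center": r_mm <= ETDRS_RADII_MM[0],
        "parafoveal": (r_mm > ETDRS_RADII_MM[0]) & (r_mm <= ETDRS_RADII_MM[1]),
        "perifoveal": (r_mm > ETDRS_RADII_MM[1]) & (r_mm <= ETDRS_RADII_MM[2]),
    }, r_mm


def _sector_mask(angles_deg, span):
    start, end = span
    width = (end - start) % 360.0 or 360.0
    return ((angles_deg - start) % 360.0) < width


def synthesize_layer_data(
    macular_targets: Mapping[str, Mapping[str, float]],
    disc_targets: Mapping[str, float],
    smoothness_mm: float = 0.005,
    texture_sd: float = 1.5,
    seed: int | np.random.Generator = 0,
    grid_step_deg: float = 0.25,
    field_deg: tuple[float, float] = (30.0, 25.0),
    degrees_per_mm: float = DEGREES_PER_MM,
    n_profile: int = 768,
    sectors: Mapping[str, tuple[float, float]] | None = None,
    si_hump_um: float = 15.0,
    eye: str | None = None,
) -> LayerThicknessData:
    """Generate segmented OCT data whose region means hit the given targets.

    Macular maps are radially piecewise-constant over the ETDRS regions
    (values continue outward beyond the 6 mm circle), blended over
    ``smoothness_mm`` and overlaid with a smooth zero-region-mean texture, so
    region means recover the targets up to the (sub-pixel, by default)
    smoothing error.  The peripapillary profile is built the same way over
    the disc sectors; S/I are raised and N lowered by ``si_hump_um`` (the
    double-hump shape of real circle scans) without moving the global mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sectors = dict(DEFAULT_SECTORS if sectors is None else sectors)

    for layer, regions in macular_targets.items():
        for region, v in regions.items():
            if not v > 0:
                raise ValueError(f"non-positive target {v} for {layer}/{region}")
    for sector, v in disc_targets.items():
        if not v > 0:
            raise ValueError(f"non-positive target {v} for pRNFL/{sector}")

    half_x, half_y = field_deg[0] / 2.0, field_deg[1] / 2.0
    x = np.arange(-half_x, half_x + grid_step_deg / 2, grid_step_deg)
    y = np.arange(-half_y, half_y + grid_step_deg / 2, grid_step_deg)
    masks, r_mm = _region_masks_macula(x, y, (0.0, 0.0), degrees_per_mm)
    outside = r_mm > ETDRS_RADII_MM[2]
    sigma_px = smoothness_mm * degrees_per_mm / grid_step_deg

    maps: dict[str, np.ndarray] = {}
    for layer, regions in macular_targets.items():
        base = np.full(r_mm.shape, regions["perifoveal"], dtype=float)
        base[masks["parafoveal"]] = regions["parafoveal"]
        base[masks["center"]] = regions["center"]
        if sigma_px > 0:
            base = ndimage.gaussian_filter(base, sigma_px, mode="nearest")
        if texture_sd > 0:
            noise = ndimage.gaussian_filter(rng.normal(size=r_mm.shape), 2.0,
                                            mode="nearest")
            sd = noise.std()
            noise *= texture_sd / sd if sd > 0 else 0.0
            for mask in (*masks.values(), outside):
                if mask.any():
                    noise[mask] -= noise[mask].mean()
            base = base + noise
        maps[layer] = np.clip(base, 0.5, None)

    angles = np.arange(n_profile) * 360.0 / n_profile
    angles = (angles + 180.0) % 360.0 - 180.0   # (-180, 180], 0 = temporal
    t_val, pmb_val, g_val = (disc_targets[k] for k in ("T", "PMB", "G"))
    pmb_width = (sectors["PMB"][1] - sectors["PMB"][0]) % 360.0
    t_width = (sectors["T"][1] - sectors["T"][0]) % 360.0
    t_out = (t_width * t_val - pmb_width * pmb_val) / (t_width - pmb_width)
    rest = (360.0 * g_val - t_width * t_val) / (360.0 - t_width)
    prof = np.full(n_profile, rest, dtype=float)
    prof[_sector_mask(angles, sectors["S"])] += si_hump_um
    prof[_sector_mask(angles, sectors["I"])] += si_hump_um
    prof[_sector_mask(angles, sectors["N"])] -= 2.0 * si_hump_um
    tmask = _sector_mask(angles, sectors["T"])
    pmask = _sector_mask(angles, sectors["PMB"])
    prof[tmask] = t_out
    prof[pmask] = pmb_val
    smooth_deg = smoothness_mm * 40.0  # ~0.2 deg of arc at the 0.005 mm default
    if smooth_deg > 0:
        prof = ndimage.gaussian_filter1d(prof, smooth_deg / (360.0 / n_profile),
                                         mode="wrap")
    if texture_sd > 0:
        pnoise = ndimage.gaussian_filter1d(rng.normal(size=n_profile), 3.0,
                                           mode="wrap")
        psd = pnoise.std()
        pnoise *= texture_sd / psd if psd > 0 else 0.0
        regions = [pmask, tmask & ~pmask,
                   _sector_mask(angles, sectors["S"]),
                   _sector_mask(angles, sectors["N"]),
                   _sector_mask(angles, sectors["I"])]
        for mask in regions:
            if mask.any():
                pnoise[mask] -= pnoise[mask].mean()
        prof = prof + pnoise
    prof = np.clip(prof, 1.0, None)

    return LayerThicknessData(
        maps=maps, x_deg=x, y_deg=y, profile=prof, profile_angles_deg=angles,
        degrees_per_mm=degrees_per_mm, eye=eye,
    )
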