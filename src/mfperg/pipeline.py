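"""End-to-end reproducible pipeline: simulate → extract → measure → summarize → test.

A :class:`PipelineConfig` plus a seed fully determines a run.  The stages:

1. sample the cohort and per-subject generating parameters;
2. synthesize continuous recordings (3 repetitions) and OCT data;
3. artifact rejection, kernel extraction, repetition averaging, polarity
   flip-back, right-eye left-right flipping, 3–45 Hz filtering, ring
   averaging, N1/P1/N2 measurement;
4. ETDRS and peripapillary sector summaries;
5. the omnibus/post hoc/correlation battery with Holm adjustment per family.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import kernels as kx
from . import stats as st
from . import waveform as wf
from .cohort import (
    CohortRecord,
    draw_subject_params,
    sample_cohort,
    synthesize_layer_data,
    synthesize_recording,
)
from .msequence import build_all_schedules, build_geometry, generate_msequence
from .oct_sectors import summarize_etdrs, summarize_prnfl


@dataclass
class PipelineConfig:
    """Serializable run configuration; a run is reproducible from this + seed."""

    seed: int = 0
    n_per_group: tuple[int, int, int] = (14, 12, 11)
    register_length: int = 14
    shift_spacing: int | None = None     # auto: min(400, period // (n_elements + 1))
    repetitions: int = 3
    noise_sd_uV: float = 5.0
    blink_rate_per_min: float = 2.0
    # the stimulus-locked superposition of 36 element responses alone spans
    # ~180 µV peak-to-peak per segment, so the working threshold sits above
    # it; blink transients (200-500 µV) still stand out
    artifact_threshold_uV: float = 250.0
    fs: float = 1200.0
    epoch_ms: float = 120.0
    filter_low_hz: float = 3.0
    filter_high_hz: float = 45.0
    between_subject_sd: float = 1.0
    smoothness_mm: float = 0.005
    texture_sd_um: float = 1.5
    n_missing_disc_scans: int = 2
    stats_policy: str = "paper"
    mfperg_calibration: str | None = None
    oct_calibration: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "n_per_group" in d:
            d["n_per_group"] = tuple(d["n_per_group"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    mfperg_measures: pd.DataFrame
    oct_measures: pd.DataFrame
    stats: dict
    log: list[str] = field(default_factory=list)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        super().__init__(f"stage {stage!r}"
                         + (f", subject {subject}" if subject else "")
                         + f": {cause}")
        self.stage, self.subject = stage, subject


def _measure_subject(rec_conf, subject: CohortRecord, params, design, schedules,
                     rng: np.random.Generator, log: list[str]) -> pd.DataFrame:
    reps = []
    for rep in range(1, rec_conf.repetitions + 1):
        rec = synthesize_recording(
            params.template, design, schedules,
            noise_sd=rec_conf.noise_sd_uV,
            blink_rate_per_min=rec_conf.blink_rate_per_min,
            seed=rng, fs=rec_conf.fs, polarity=-1,
            repetition=rep, eye=subject.eye,
        )
        rec, n_rej = kx.reject_artifacts(rec, rec_conf.artifact_threshold_uV)
        if n_rej:
            log.append(f"{subject.subject_id} rep {rep}: rejected {n_rej} segment(s)")
        reps.append(kx.extract_first_slice(rec, schedules, epoch_ms=rec_conf.epoch_ms))
    avg = kx.average_repetitions(reps)
    flipped = kx.flip_polarity(avg)
    oriented = wf.normalize_laterality(flipped, subject.eye, design)
    filtered = oriented.copy()
    filtered.traces = wf.bandpass_filter(
        filtered.traces, rec_conf.filter_low_hz, rec_conf.filter_high_hz, fs=rec_conf.fs
    )
    ra = wf.ring_average(filtered, design)
    meas = wf.measure_ring_averages(ra)
    for _, row in meas[meas.unmeasurable].iterrows():
        log.append(f"{subject.subject_id}: {row.component} unmeasurable in ring {row.ring}")
    meas.insert(0, "subject_id", subject.subject_id)
    meas.insert(1, "group", subject.group)
    return meas


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    log: list[str] = [f"config: {json.dumps(config.to_dict(), sort_keys=True)}"]
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_subjects, s_disc = ss.spawn(3)

    mf_cal = cal.load_mfperg_calibration(config.mfperg_calibration)
    oct_cal = cal.load_oct_calibration(config.oct_calibration)

    mseq = generate_msequence(config.register_length)
    n_el = 36
    spacing = config.shift_spacing
    if spacing is None:
        spacing = min(400, mseq.period // (n_el + 1))
    spp = int(round(config.fs * 2 / 75))   # samples per 2-frame state
    epoch_states = int(np.ceil(config.epoch_ms / 1000.0 * config.fs / spp)) * 2
    design = build_geometry(shift_spacing=spacing, period=mseq.period,
                            epoch_states=epoch_states)
    schedules = build_all_schedules(mseq, design)
    log.append(f"m-sequence period {mseq.period}, shift spacing {spacing} states")

    cohort = sample_cohort(config.n_per_group, seed=np.random.default_rng(s_cohort))
    subject_rngs = [np.random.default_rng(c) for c in s_subjects.spawn(len(cohort))]

    mf_rows, oct_rows = [], []
    for subject, rng in zip(cohort, subject_rngs):
        try:
            params = draw_subject_params(
                subject.group, mf_cal, oct_cal,
                between_subject_sd=config.between_subject_sd, seed=rng,
                filter_band=(config.filter_low_hz, config.filter_high_hz),
                fs=config.fs, epoch_ms=config.epoch_ms,
            )
        except Exception as exc:   # noqa: BLE001 - stage context added
            raise PipelineError("draw_subject_params", subject.subject_id, exc) from exc
        try:
            mf_rows.append(_measure_subject(config, subject, params, design,
                                            schedules, rng, log))
        except Exception as exc:
            raise PipelineError("mfperg", subject.subject_id, exc) from exc
        try:
            data = synthesize_layer_data(
                params.macular_targets, params.disc_targets,
                smoothness_mm=config.smoothness_mm,
                texture_sd=config.texture_sd_um, seed=rng, eye=subject.eye,
            )
            etdrs = summarize_etdrs(data)
            sectors = summarize_prnfl(data.profile, data.profile_angles_deg)
        except Exception as exc:
            raise PipelineError("oct", subject.subject_id, exc) from exc
        tab = etdrs.table.copy()
        tab.insert(0, "subject_id", subject.subject_id)
        tab.insert(1, "group", subject.group)
        oct_rows.append(tab)
        for sector, value in sectors.as_dict().items():
            if sector == "NT_ratio":
                continue
            oct_rows.append(pd.DataFrame([{
                "subject_id": subject.subject_id, "group": subject.group,
                "layer": "pRNFL", "region": sector, "mean_um": value,
            }]))

    mf = pd.concat(mf_rows, ignore_index=True)
    octm = pd.concat(oct_rows, ignore_index=True)

    # emulate missing disc scans (df(2, N-3-k) in the disc analyses)
    if config.n_missing_disc_scans > 0:
        drng = np.random.default_rng(s_disc)
        patients = [r.subject_id for r in cohort if r.group != "Control"]
        dropped = sorted(drng.choice(patients, size=config.n_missing_disc_scans,
                                     replace=False))
        octm = octm[~((octm.layer == "pRNFL") & octm.subject_id.isin(dropped))]
        log.append(f"dropped disc scans: {', '.join(dropped)}")

    stats = _run_battery(mf, octm, config, log)
    result = PipelineResult(
        cohort=pd.DataFrame([r.__dict__ for r in cohort]),
        mfperg_measures=mf, oct_measures=octm, stats=stats, log=log,
    )
    if outdir is not None:
        write_bundle(result, config, outdir)
    return result


def _groups_of(df, value_col):
    out = {}
    for g in cal.GROUPS:
        v = df[df.group == g][value_col].dropna().to_numpy()
        if len(v) >= 2:
            out[g] = v
    return out


def _omnibus_with_posthoc(values, family, measure, policy, skipped, log):
    """Run one omnibus + post hoc; measures with too little usable data
    (e.g. unmeasurable peaks in a tiny cohort) are recorded, not fatal."""
    try:
        res = st.omnibus_test(values, family=family, measure=measure, policy=policy)
    except ValueError as exc:
        skipped[measure] = {"test": "not testable", "reason": str(exc)}
        log.append(f"stats: {measure} not testable ({exc})")
        return None
    try:
        res.posthoc = st.posthoc_pairwise(values, parametric=res.test == "ANOVA")
    except ValueError as exc:
        log.append(f"stats: post hocs for {measure} not testable ({exc})")
    return res


def _result_to_dict(r: st.GroupComparisonResult) -> dict:
    return {
        "test": r.test, "statistic": round(r.statistic, 4),
        "df": [r.df1, r.df2], "p_raw": r.p_raw, "p_holm": r.p_holm,
        "posthoc": [
            {"pair": list(e.pair), "test": e.test, "statistic": round(e.statistic, 4),
             "df": e.df, "p_raw": e.p_raw, "p_holm": e.p_holm}
            for e in r.posthoc
        ],
    }


def _run_battery(mf: pd.DataFrame, octm: pd.DataFrame, config: PipelineConfig,
                 log: list[str]) -> dict:
    policy = config.stats_policy
    out: dict = {"mfperg_amplitude": {}, "mfperg_peak_time": {},
                 "macular_thickness": {}, "disc_thickness": {},
                 "correlations": {}}

    def run_family(fam_key, groups_iter):
        results, skipped = [], {}
        for label, family, values in groups_iter:
            res = _omnibus_with_posthoc(values, family, label, policy,
                                        skipped, log)
            if res is not None:
                results.append(res)
        st.adjust_family(results)
        out[fam_key] = {r.measure: _result_to_dict(r) for r in results}
        out[fam_key].update(skipped)

    for fam_key, col, family in [
        ("mfperg_amplitude", "amplitude_uV", "amplitude"),
        ("mfperg_peak_time", "peak_time_ms", st.PEAK_TIME_FAMILY),
    ]:
        run_family(fam_key, (
            (f"ring{ring}_{comp}" if ring else f"summed_{comp}", family,
             _groups_of(sub, col))
            for (ring, comp), sub in mf.groupby(["ring", "component"])
        ))

    mac = octm[octm.layer != "pRNFL"]
    run_family("macular_thickness", (
        (f"{layer}_{region}", "thickness", _groups_of(sub, "mean_um"))
        for (layer, region), sub in mac.groupby(["layer", "region"])
    ))

    disc = octm[octm.layer == "pRNFL"]
    run_family("disc_thickness", (
        (f"pRNFL_{region}", "thickness", _groups_of(sub, "mean_um"))
        for region, sub in disc.groupby("region")
    ))

    # structure-function panels: foveal N2 amplitude and parafoveal P1 peak
    # time against the structural measures that differed between groups
    struct = {
        "pRNFL_PMB": disc[disc.region == "PMB"],
        "pRNFL_T": disc[disc.region == "T"],
        "GCL_parafoveal": mac[(mac.layer == "GCL") & (mac.region == "parafoveal")],
        "GCL_perifoveal": mac[(mac.layer == "GCL") & (mac.region == "perifoveal")],
    }
    func = {
        "ring1_N2_amplitude": mf[(mf.ring == 1) & (mf.component == "N2")]
        .set_index("subject_id")["amplitude_uV"],
        "ring2_P1_peak_time": mf[(mf.ring == 2) & (mf.component == "P1")]
        .set_index("subject_id")["peak_time_ms"],
    }
    for fname, fseries in func.items():
        pairs = {}
        for sname, sdf in struct.items():
            s = sdf.set_index("subject_id")["mean_um"]
            common = s.index.intersection(fseries.index)
            x, y = s.loc[common], fseries.loc[common]
            ok = x.notna() & y.notna()
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if ok.sum() >= 3 and np.ptp(xv) > 0 and np.ptp(yv) > 0:
                pairs[sname] = (xv, yv)
        panel = st.correlation_panel(pairs)
        out["correlations"][fname] = {
            k: {"r": round(v.r, 4), "r2": round(v.r2, 4), "n": v.n,
                "p_raw": v.p_raw, "p_holm": v.p_holm}
            for k, v in panel.items()
        }
    log.append("statistics battery complete")
    return out


def group_table(measures: pd.DataFrame, value_col: str,
                by: list[str]) -> pd.DataFrame:
    """Group mean [SD] table mirroring the published summary layout."""
    g = measures.groupby([*by, "group"])[value_col].agg(["mean", "std", "count"])
    return g.reset_index()


def write_bundle(result: PipelineResult, config: PipelineConfig,
                 outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    result.cohort.to_csv(out / "cohort.csv", index=False)
    result.mfperg_measures.to_csv(out / "mfperg_measures.csv", index=False)
    result.oct_measures.to_csv(out / "oct_measures.csv", index=False)
    group_table(result.mfperg_measures, "amplitude_uV",
                ["ring", "component"]).to_csv(out / "table_mfperg_amplitudes.csv",
                                              index=False)
    group_table(result.mfperg_measures, "peak_time_ms",
                ["ring", "component"]).to_csv(out / "table_mfperg_peak_times.csv",
                                              index=False)
    group_table(result.oct_measures, "mean_um",
                ["layer", "region"]).to_csv(out / "table_oct_thickness.csv",
                                            index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, sort_keys=True)
    (out / "log.txt").write_text("\n".join(result.log) + "\n")
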