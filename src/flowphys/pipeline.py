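"""End-to-end orchestration: sessions -> minute variables -> baseline-corrected
cohort table -> curves and paired condition statistics, with audit logs.

Every exclusion (bad channel, unusable or incomplete series, screened
outlier) is recorded with a reason so a cohort run is fully auditable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import autonomic, eeg, motion, stats
from .session import (
    CONDITIONS,
    PHASES,
    PhaseSet,
    Session,
    SessionFormatError,
    SessionValidationError,
    partition_phases,
    read_session,
)

#: Condition pairs in reporting order.
CONDITION_PAIRS = (
    ("boredom", "flow"),
    ("flow", "frustration"),
    ("boredom", "frustration"),
)

_VARIABLE_DISPLAY = {
    "hr_mean": "HR AVG",
    "hr_sd": "HR SD",
    "spo2_mean": "SpO2 AVG",
    "spo2_sd": "SpO2 SD",
    "gsr_mean": "GSR AVG",
    "gsr_sd": "GSR SD",
    "acc_sd": "ACC",
    "gyro_sd": "AV",
}
_DEVICE_DISPLAY = {"headset": "HS", "armband": "AB"}


@dataclass
class PipelineConfig:
    """All analysis parameters; the defaults are the study's printed ones.

    250/50/500 Hz rates live in the session files; here: 0.5-30 Hz order-2
    Butterworth, delta/theta/alpha/beta band edges, [70, 100]% SpO2 validity,
    (30, 220) BPM default HR bounds and alpha = 0.05.
    """

    filter_low: float = 0.5
    filter_high: float = 30.0
    filter_order: int = 2
    band_edges: dict = field(
        default_factory=lambda: {
            "delta": [0.5, 4.0],
            "theta": [4.0, 7.0],
            "alpha": [8.0, 12.0],
            "beta": [13.0, 30.0],
        }
    )
    flat_sd: float = 0.1
    extreme_k: float = 10.0
    channel_overrides: dict = field(default_factory=dict)  # subject -> [ch]
    ica_seed: int = 0
    ica_corr_threshold: float = 0.8
    ica_kurtosis_gate: float = 2.0
    ica_kurtosis_threshold: float = 8.0
    hr_bounds: tuple = (30.0, 220.0)
    hr_robust_k: float = 4.0
    hr_bounds_overrides: dict = field(default_factory=dict)  # subject -> [lo, hi]
    max_repaired_fraction: float = 0.5
    eeg_baselines: tuple = ("closed", "open")
    alpha: float = 0.05

    def band_scheme(self) -> eeg.BandScheme:
        bands = {}
        last = max(self.band_edges, key=lambda b: self.band_edges[b][1])
        for name, (lo, hi) in self.band_edges.items():
            bands[name] = eeg.Band(lo, hi, inclusive_upper=(name == last))
        return eeg.BandScheme(bands=bands)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.hr_bounds = tuple(cfg.hr_bounds)
        cfg.eeg_baselines = tuple(cfg.eeg_baselines)
        return cfg


_MINUTE_COLS = ["phase", "variable", "channel", "band", "minute", "value"]


@dataclass
class SubjectData:
    """Per-subject minute variables plus audit records."""

    subject_id: str
    minutes: pd.DataFrame  # phase, variable, channel, band, minute, value
    _frames: list = field(default_factory=list)
    repairs: list = field(default_factory=list)
    channel_quality: eeg.ChannelQuality | None = None
    exclusions: list = field(default_factory=list)  # dicts with reasons
    ica_info: list = field(default_factory=list)
    #: (family, phase) pairs with complete usable data
    complete: set = field(default_factory=set)


@dataclass
class CohortTable:
    """Subject x condition x minute x variable table, baseline-corrected."""

    corrected: pd.DataFrame  # + baseline, minute, value (percent change)
    test_values: pd.DataFrame  # phase-level values used by the t-tests
    exclusions: pd.DataFrame
    subjects: list[str] = field(default_factory=list)


@dataclass
class AnalysisResult:
    cohort: CohortTable
    curves: pd.DataFrame
    full_table: pd.DataFrame
    significant_table: pd.DataFrame
    results: list
    logs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-subject analysis
# ---------------------------------------------------------------------------

def _analyze_eeg(
    phase_set: PhaseSet, config: PipelineConfig, subject: str, out: SubjectData
) -> None:
    rate = phase_set.rates["eeg"]
    filtered = [
        eeg.bandpass_filter(
            phase_set.block(p, "eeg"), rate,
            config.filter_low, config.filter_high, config.filter_order,
        )
        for p in PHASES
    ]
    try:
        quality = eeg.detect_bad_channels(
            np.concatenate(filtered, axis=0),
            phase_set.channels["eeg"],
            flat_sd=config.flat_sd,
            extreme_k=config.extreme_k,
            overrides=config.channel_overrides.get(subject),
        )
    except eeg.AllChannelsBadError:
        out.exclusions.append(
            {"subject": subject, "phase": "all", "variable": "eeg",
             "reason": "all EEG channels bad"}
        )
        return
    out.channel_quality = quality
    for ch in quality.bad:
        out.exclusions.append(
            {"subject": subject, "phase": "all", "variable": f"eeg:{ch}",
             "reason": f"bad channel ({quality.reasons[ch]})"}
        )
    df, infos = eeg.eeg_minute_powers(
        phase_set,
        quality,
        scheme=config.band_scheme(),
        filter_low=config.filter_low,
        filter_high=config.filter_high,
        filter_order=config.filter_order,
        ica_seed=config.ica_seed,
        ica_params={
            "corr_threshold": config.ica_corr_threshold,
            "kurtosis_gate": config.ica_kurtosis_gate,
            "kurtosis_threshold": config.ica_kurtosis_threshold,
        },
    )
    out.ica_info = infos
    df = df.rename(columns={"power": "value"})
    df["variable"] = "power"
    if len(df):
        out._frames.append(df[_MINUTE_COLS])
    for p in PHASES:
        out.complete.add(("eeg", p))


def _analyze_pulse(
    phase_set: PhaseSet, config: PipelineConfig, subject: str, out: SubjectData
) -> None:
    bounds = tuple(config.hr_bounds_overrides.get(subject, config.hr_bounds))
    for modality, family in (("hr", "hr"), ("spo2", "spo2")):
        rate = phase_set.rates[modality]
        for phase in PHASES:
            series = phase_set.block(phase, modality)[:, 0]
            sid = f"{subject}/{phase}/{modality}"
            try:
                if modality == "hr":
                    repaired, log = autonomic.repair_hr(
                        series, bounds=bounds, robust_k=config.hr_robust_k,
                        series_id=sid,
                    )
                else:
                    repaired, log = autonomic.repair_spo2(series, series_id=sid)
            except autonomic.UnusableSeriesError:
                out.exclusions.append(
                    {"subject": subject, "phase": phase, "variable": family,
                     "reason": "series unusable (no valid samples)"}
                )
                continue
            if log.n_replaced:
                out.repairs.append(log)
            usable = autonomic.minute_usability(
                len(series), rate, log.indices, config.max_repaired_fraction
            )
            if not autonomic.flag_incomplete(usable):
                out.exclusions.append(
                    {"subject": subject, "phase": phase, "variable": family,
                     "reason": f"incomplete ({int((~usable).sum())} unusable minutes)"}
                )
                continue
            means, sds = autonomic.minute_stats(repaired, rate)
            rows = []
            for i, (m, sd) in enumerate(zip(means, sds), start=1):
                rows.append({"phase": phase, "variable": f"{family}_mean",
                             "channel": "", "band": "", "minute": i, "value": m})
                rows.append({"phase": phase, "variable": f"{family}_sd",
                             "channel": "", "band": "", "minute": i, "value": sd})
            out._frames.append(pd.DataFrame(rows))
            out.complete.add((family, phase))


def _analyze_gsr_imu(
    phase_set: PhaseSet, config: PipelineConfig, subject: str, out: SubjectData
) -> None:
    rows = []
    for phase in PHASES:
        gsr = phase_set.block(phase, "gsr")[:, 0]
        means, sds = autonomic.minute_stats(gsr, phase_set.rates["gsr"])
        for i, (m, sd) in enumerate(zip(means, sds), start=1):
            rows.append({"phase": phase, "variable": "gsr_mean", "channel": "",
                         "band": "", "minute": i, "value": m})
            rows.append({"phase": phase, "variable": "gsr_sd", "channel": "",
                         "band": "", "minute": i, "value": sd})
        out.complete.add(("gsr", phase))
        for modality, device in (("imu_headset", "headset"), ("imu_armband", "armband")):
            block = phase_set.block(phase, modality)
            acc_sd, gyr_sd = motion.motion_minute_sd(block, phase_set.rates[modality])
            for i, (a, g) in enumerate(zip(acc_sd, gyr_sd), start=1):
                rows.append({"phase": phase, "variable": "acc_sd",
                             "channel": device, "band": "", "minute": i, "value": a})
                rows.append({"phase": phase, "variable": "gyro_sd",
                             "channel": device, "band": "", "minute": i, "value": g})
            out.complete.add((f"imu_{device}", phase))
    out._frames.append(pd.DataFrame(rows))


def analyze_session(session: Session, config: PipelineConfig) -> SubjectData:
    """Reduce one subject's recording to per-minute physiological variables."""
    phase_set = partition_phases(session)
    out = SubjectData(
        subject_id=session.subject_id,
        minutes=pd.DataFrame(columns=_MINUTE_COLS),
    )
    _analyze_eeg(phase_set, config, session.subject_id, out)
    _analyze_pulse(phase_set, config, session.subject_id, out)
    _analyze_gsr_imu(phase_set, config, session.subject_id, out)
    if out._frames:
        out.minutes = pd.concat(out._frames, ignore_index=True)[_MINUTE_COLS]
    out._frames = []
    out.minutes.insert(0, "subject", session.subject_id)
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _family(variable: str, channel: str) -> str:
    if variable == "power":
        return "eeg"
    if variable in ("acc_sd", "gyro_sd"):
        return f"imu_{channel}"
    return variable.split("_")[0]


_BASELINE_PHASE = {"closed": "baseline_closed", "open": "baseline_open"}


def build_cohort(
    subject_datas: list[SubjectData], config: PipelineConfig
) -> CohortTable:
    """Baseline-correct per-minute values and derive phase-level test values.

    EEG variables are corrected against both baselines (configurable); all
    other modalities against the eyes-closed baseline only.  A subject
    enters a condition cell only when both that condition and the needed
    baseline phase are complete for the variable's modality.  EEG test
    values are the per-subject mean over minutes of log(power / baseline
    power); the other variables use the mean percent change.
    """
    corrected_rows = []
    test_rows = []
    exclusion_rows = []
    for sd in subject_datas:
        exclusion_rows.extend(sd.exclusions)
        if sd.minutes.empty:
            continue
        df = sd.minutes
        for (variable, channel, band), grp in df.groupby(
            ["variable", "channel", "band"], sort=True
        ):
            family = _family(variable, channel)
            baselines = config.eeg_baselines if family == "eeg" else ("closed",)
            by_phase = {p: g for p, g in grp.groupby("phase")}
            for bl_name in baselines:
                bl_phase = _BASELINE_PHASE[bl_name]
                if (family, bl_phase) not in sd.complete or bl_phase not in by_phase:
                    exclusion_rows.append(
                        {"subject": sd.subject_id, "phase": bl_phase,
                         "variable": variable,
                         "reason": f"missing {bl_name} baseline; conditions dropped"}
                    )
                    continue
                bl_value = float(by_phase[bl_phase]["value"].iloc[0])
                if bl_value == 0:
                    exclusion_rows.append(
                        {"subject": sd.subject_id, "phase": bl_phase,
                         "variable": variable,
                         "reason": f"zero {bl_name} baseline; percent change undefined"}
                    )
                    continue
                for cond in CONDITIONS:
                    if (family, cond) not in sd.complete or cond not in by_phase:
                        continue
                    g = by_phase[cond].sort_values("minute")
                    pct = stats.baseline_correct(g["value"].to_numpy(), bl_value)
                    for minute, v in zip(g["minute"], pct):
                        corrected_rows.append(
                            {"subject": sd.subject_id, "condition": cond,
                             "variable": variable, "channel": channel,
                             "band": band, "baseline": bl_name,
                             "minute": int(minute), "value": float(v)}
                        )
                    if family == "eeg":
                        test_val = float(
                            np.mean(np.log(g["value"].to_numpy() / bl_value))
                        )
                    else:
                        test_val = float(np.mean(pct))
                    test_rows.append(
                        {"subject": sd.subject_id, "condition": cond,
                         "variable": variable, "channel": channel,
                         "band": band, "baseline": bl_name, "value": test_val}
                    )
    cols = ["subject", "condition", "variable", "channel", "band",
            "baseline", "minute", "value"]
    tcols = ["subject", "condition", "variable", "channel", "band",
             "baseline", "value"]
    return CohortTable(
        corrected=pd.DataFrame(corrected_rows, columns=cols),
        test_values=pd.DataFrame(test_rows, columns=tcols),
        exclusions=pd.DataFrame(
            exclusion_rows, columns=["subject", "phase", "variable", "reason"]
        ),
        subjects=[sd.subject_id for sd in subject_datas],
    )


def comparison_label(
    cond_a: str, cond_b: str, variable: str, channel: str, band: str,
) -> str:
    pair = f"{cond_a.capitalize()}-{cond_b}"
    if variable == "power":
        return f"{pair}, {channel}, {band}"
    name = _VARIABLE_DISPLAY.get(variable, variable)
    if variable in ("acc_sd", "gyro_sd"):
        return f"{pair}, {name}, {_DEVICE_DISPLAY.get(channel, channel)}"
    return f"{pair}, {name}"


def run_statistics(
    cohort: CohortTable, config: PipelineConfig
) -> tuple[list, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All condition-pair tests plus cohort mean curves.

    Returns (results, curves, curve outlier log, test outlier log); EEG
    tests run separately per baseline type, channel and band.
    """
    results = []
    outlier_frames = []
    tv = cohort.test_values
    measures = (
        tv[["variable", "channel", "band", "baseline"]]
        .drop_duplicates()
        .sort_values(["variable", "channel", "band", "baseline"])
    )
    for _, m in measures.iterrows():
        for cond_a, cond_b in CONDITION_PAIRS:
            label = comparison_label(
                cond_a, cond_b, m["variable"], m["channel"], m["band"]
            )
            if m["variable"] == "power":
                label = f"{label} [{m['baseline']}]"
            try:
                result, outliers = stats.paired_condition_test(
                    tv, cond_a, cond_b,
                    variable=m["variable"], channel=m["channel"],
                    band=m["band"], baseline=m["baseline"],
                    alpha=config.alpha, label=label,
                )
            except ValueError:
                continue  # insufficient complete pairs; already audited
            results.append(result)
            if len(outliers):
                outlier_frames.append(outliers)
    curves, curve_outliers = stats.aggregate_curves(
        cohort.corrected, alpha=config.alpha
    )
    test_outliers = (
        pd.concat(outlier_frames, ignore_index=True)
        if outlier_frames
        else pd.DataFrame(columns=["comparison", "subject", "reason"])
    )
    return results, curves, curve_outliers, test_outliers


def run_pipeline(
    sessions: list[Session], config: PipelineConfig | None = None
) -> AnalysisResult:
    """Full analysis of an in-memory cohort."""
    config = config or PipelineConfig()
    subject_datas = [analyze_session(s, config) for s in sessions]
    cohort = build_cohort(subject_datas, config)
    results, curves, curve_outliers, test_outliers = run_statistics(cohort, config)
    full, significant = stats.emit_results_table(results, alpha=config.alpha)
    repairs = pd.DataFrame(
        [
            {"series": log.series_id, "rule": log.rule,
             "n_replaced": log.n_replaced,
             "indices": ",".join(map(str, log.indices))}
            for sd in subject_datas
            for log in sd.repairs
        ],
        columns=["series", "rule", "n_replaced", "indices"],
    )
    channels = pd.DataFrame(
        [
            {"subject": sd.subject_id, "channel": ch, "status": st,
             "reason": sd.channel_quality.reasons.get(ch, ""),
             "source": sd.channel_quality.source.get(ch, "")}
            for sd in subject_datas
            if sd.channel_quality is not None
            for ch, st in sd.channel_quality.status.items()
        ],
        columns=["subject", "channel", "status", "reason", "source"],
    )
    return AnalysisResult(
        cohort=cohort,
        curves=curves,
        full_table=full,
        significant_table=significant,
        results=results,
        logs={
            "repairs": repairs,
            "channels": channels,
            "exclusions": cohort.exclusions,
            "curve_outliers": curve_outliers,
            "test_outliers": test_outliers,
        },
    )


# ---------------------------------------------------------------------------
# Disk-level entry points
# ---------------------------------------------------------------------------

def load_cohort(cohort_dir: str) -> tuple[list[Session], pd.DataFrame]:
    """Read every session subdirectory; skip unreadable ones with a log."""
    sessions = []
    skipped = []
    for name in sorted(os.listdir(cohort_dir)):
        path = os.path.join(cohort_dir, name)
        if not os.path.isdir(path):
            continue
        try:
            sessions.append(read_session(path))
        except (SessionFormatError, SessionValidationError, ValueError) as exc:
            skipped.append({"subject": name, "phase": "all", "variable": "all",
                            "reason": f"unreadable session: {exc}"})
    return sessions, pd.DataFrame(
        skipped, columns=["subject", "phase", "variable", "reason"]
    )


def write_outputs(result: AnalysisResult, out_dir: str) -> None:
    """Emit all tables and audit logs as TSV under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out_dir, name), sep="\t", index=False)

    emit(result.cohort.corrected, "cohort_minutes.tsv")
    emit(result.cohort.test_values, "test_values.tsv")
    emit(result.curves, "curves.tsv")
    emit(result.full_table, "results_full.tsv")
    emit(result.significant_table, "results_significant.tsv")
    for name, df in result.logs.items():
        emit(df, f"log_{name}.tsv")


def run_cohort_dir(
    cohort_dir: str, out_dir: str, config: PipelineConfig | None = None
) -> AnalysisResult:
    """Load, analyze and write a cohort directory; the CLI `run` backend."""
    config = config or PipelineConfig()
    sessions, skipped = load_cohort(cohort_dir)
    if not sessions:
        raise SessionFormatError(f"no usable sessions in {cohort_dir}")
    result = run_pipeline(sessions, config)
    if len(skipped):
        result.logs["exclusions"] = pd.concat(
            [skipped, result.logs["exclusions"]], ignore_index=True
        )
    write_outputs(result, out_dir)
    return result
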