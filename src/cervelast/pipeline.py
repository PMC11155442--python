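"""End-to-end pipeline: simulate cohort -> track -> fit -> cohort statistics.

All randomness is derived from one master seed via a documented counter
scheme (``SeedSequence((master, stage, subject, sector))``), so any stage
can be rerun independently and a full rerun reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cohortgen import CohortConfig, SPTB, VALIDATION_GROUPS, generate_cohort
from .stats import (delong_ci, filter_analysis_set, sens_spec_at_cutoff,
                    summarize_characteristics)
from .stress_strain import (FitError, QualityGates, StressStrainFit,
                            fit_stress_strain, subject_summary)
from .synthetic import (CompressionProtocol, ExamRecording, ProbeSpec,
                        TissueModel, adaptive_protocol, simulate_exam)
from .tracking import EnvelopeParams, TrackingError, track_exam

_STAGE_COHORT = 0
_STAGE_EXAMS = 1
_SECTOR_INDEX = {"anterior": 0, "posterior": 1}


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration for one reproducible pipeline run."""

    probe: ProbeSpec = ProbeSpec()
    base_protocol: CompressionProtocol = CompressionProtocol()
    envelope: EnvelopeParams = EnvelopeParams()
    quality: QualityGates = QualityGates()
    cohort: CohortConfig = CohortConfig()
    cutoff_kpa_mm: float = 1.0
    speed_of_sound: float = 1540.0
    snr_db: float | None = 20.0
    pressure_noise: bool = True
    master_seed: int = 0
    save_recordings: bool = False
    save_tracks: bool = False


def _exam_seed(master: int, subject_index: int, sector: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        (master, _STAGE_EXAMS, subject_index, _SECTOR_INDEX[sector]))


def measure_exam(tissue: TissueModel, config: PipelineConfig,
                 seed: np.random.SeedSequence, subject_id: str,
                 sector: str) -> tuple[ExamRecording, StressStrainFit | None]:
    """Simulate, track and fit a single sector exam; fit is None when unusable."""
    protocol = adaptive_protocol(tissue, config.base_protocol, config.probe)
    recording = simulate_exam(
        tissue, config.probe, protocol, seed,
        snr_db=config.snr_db, pressure_noise=config.pressure_noise,
        subject_id=subject_id, sector=sector,
    )
    try:
        track = track_exam(recording, config.envelope, config.speed_of_sound)
        fit = fit_stress_strain(track, config.quality, sector=sector)
    except (TrackingError, FitError):
        return recording, None
    return recording, fit


def measure_validation_subjects(cohort: pd.DataFrame, config: PipelineConfig,
                                out_dir: Path | None = None) -> pd.DataFrame:
    """Run the measurement chain for every subject with ground-truth tissue.

    Returns the cohort table with per-sector and averaged measured columns
    appended; subjects whose sectors both fail keep NaNs and are counted as
    fit failures downstream.
    """
    cohort = cohort.copy()
    new_cols = [
        "elasticity_anterior_kpa_mm", "elasticity_posterior_kpa_mm",
        "elasticity_avg_kpa_mm", "length_anterior_mm", "length_posterior_mm",
        "length_avg_mm", "r2_anterior", "r2_posterior", "single_sector",
    ]
    for col in new_cols:
        cohort[col] = np.nan
    for idx, row in cohort.iterrows():
        if row.get("group") not in VALIDATION_GROUPS:
            continue
        if not np.isfinite(row.get("true_elasticity_anterior_kpa_mm", np.nan)):
            continue
        fits: dict[str, StressStrainFit | None] = {}
        for sector in ("anterior", "posterior"):
            rest_length = float(row[f"true_length_{sector}_mm"])
            tissue = TissueModel(
                elasticity_kpa_mm=float(row[f"true_elasticity_{sector}_kpa_mm"]),
                rest_length_mm=rest_length,
                # unusually short cervices can still compress to half length
                min_compressed_length_mm=min(10.0, 0.5 * rest_length),
                speed_of_sound=config.speed_of_sound,
            )
            recording, fit = measure_exam(
                tissue, config, _exam_seed(config.master_seed, int(idx), sector),
                subject_id=str(row["subject_id"]), sector=sector)
            fits[sector] = fit if (fit is not None and fit.valid) else None
            if fit is not None:
                cohort.loc[idx, f"elasticity_{sector}_kpa_mm"] = fit.elasticity_kpa_mm
                cohort.loc[idx, f"length_{sector}_mm"] = fit.zero_pressure_length_mm
                cohort.loc[idx, f"r2_{sector}"] = fit.r_squared
            if out_dir is not None and config.save_recordings:
                rec_dir = out_dir / "recordings"
                rec_dir.mkdir(parents=True, exist_ok=True)
                cio.write_recording(rec_dir / f"{row['subject_id']}_{sector}.cmrec", recording)
        try:
            summary = subject_summary(fits["anterior"], fits["posterior"])
        except FitError:
            continue
        cohort.loc[idx, "elasticity_avg_kpa_mm"] = summary.avg_elasticity_kpa_mm
        cohort.loc[idx, "length_avg_mm"] = summary.avg_length_mm
        cohort.loc[idx, "single_sector"] = float(summary.single_sector)
    return cohort


def simulate_group_recovery(group: str, n_subjects: int, master_seed: int,
                            snr_db: float | None = 20.0) -> dict:
    """End-to-end elasticity recovery for one outcome group.

    Draws ``n_subjects`` subjects from the group's configured distributions,
    simulates both sector exams at the given noise level, runs tracking and
    stress-strain fitting, and summarises the recovered per-subject average
    elasticity (kPa/mm) against the ground truth.
    """
    if group == "sptb":
        counts = dict(n_sptb=n_subjects, n_term=0)
    elif group == "term":
        counts = dict(n_sptb=0, n_term=n_subjects)
    else:
        raise ValueError(f"unknown outcome group {group!r}")
    cohort_config = CohortConfig(**counts, n_indicated=0, n_development=0,
                                 n_no_show=0, n_lost_followup=0, n_operator_error=0)
    config = PipelineConfig(cohort=cohort_config, master_seed=master_seed, snr_db=snr_db)
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence((master_seed, _STAGE_COHORT)))
    cohort = generate_cohort(cohort_config, cohort_rng)
    measured = measure_validation_subjects(cohort, config)
    ok = measured[np.isfinite(measured["elasticity_avg_kpa_mm"])]
    return {
        "group": group,
        "n_subjects": n_subjects,
        "n_recovered": int(len(ok)),
        "mean_recovered_elasticity_kpa_mm": float(ok["elasticity_avg_kpa_mm"].mean()),
        "mean_true_elasticity_kpa_mm": float(ok["true_elasticity_avg_kpa_mm"].mean()),
        "mean_recovered_length_mm": float(ok["length_avg_mm"].mean()),
    }


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 out_dir: str | Path | None = None) -> dict:
    """Run the full study emulation and return the machine-readable report.

    Stages: synthetic cohort generation; per-sector exam simulation, echo
    tracking and stress-strain fitting; analysis-set filtering; group table;
    ROC/AUC with DeLong CI; cutoff sensitivity/specificity; ground-truth
    versus recovered elasticity comparison. With ``out_dir`` set, the cohort
    table, measurements, group table and results are written to disk.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    cohort_rng = np.random.default_rng(
        np.random.SeedSequence((config.master_seed, _STAGE_COHORT)))
    cohort = generate_cohort(config.cohort, cohort_rng)
    measured = measure_validation_subjects(cohort, config, out_path)
    analysis, accounting = filter_analysis_set(measured)

    usable = analysis[np.isfinite(analysis["elasticity_avg_kpa_mm"])]
    labels = (usable["group"] == SPTB).to_numpy()
    elasticity = usable["elasticity_avg_kpa_mm"].to_numpy(float)

    report: dict = {
        "master_seed": config.master_seed,
        "accounting": accounting,
        "n_measured": int(len(usable)),
        "n_fit_failures": int(len(analysis) - len(usable)),
        "cutoff_kpa_mm": config.cutoff_kpa_mm,
    }
    for group in ("sptb", "term"):
        sel = usable[usable["group"] == group]["elasticity_avg_kpa_mm"]
        report[f"recovered_mean_elasticity_{group}_kpa_mm"] = (
            float(sel.mean()) if len(sel) else None)

    truth_ok = usable[np.isfinite(usable["true_elasticity_avg_kpa_mm"])]
    if len(truth_ok) >= 2:
        t = truth_ok["true_elasticity_avg_kpa_mm"].to_numpy(float)
        m = truth_ok["elasticity_avg_kpa_mm"].to_numpy(float)
        ss_res = float(np.sum((m - t) ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        report["truth_recovery"] = {
            "n": len(truth_ok),
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "mean_abs_error_kpa_mm": float(np.mean(np.abs(m - t))),
        }

    if labels.any() and (~labels).any():
        roc = delong_ci(-elasticity, labels)
        cut = sens_spec_at_cutoff(elasticity, labels, config.cutoff_kpa_mm)
        report["roc"] = dataclasses.asdict(roc)
        report["cutoff_metrics"] = dataclasses.asdict(cut)

    char_table = summarize_characteristics(analysis) if accounting["analyzed"] >= 4 else None

    if out_path is not None:
        cio.write_cohort_csv(cohort, out_path / "cohort.csv")
        cio.write_cohort_csv(measured, out_path / "measurements.csv")
        if char_table is not None:
            char_table.to_csv(out_path / "characteristics.csv", index=False)
        cio.write_results_json(report, out_path / "results.json")
    if char_table is not None:
        report["characteristics_table"] = char_table.to_dict(orient="records")
    return report
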