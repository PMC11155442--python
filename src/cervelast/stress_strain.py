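"""Stress-strain maps and elasticity/length fitting from depth tracks.

The applied pressure (stress, kPa) is regressed on the tracked surface depth
(the "strain" axis is absolute shortening in mm, not a dimensionless ratio).
The absolute slope of that line is the cervical elasticity in kPa/mm; its
intersection with the zero-pressure axis is the cervical length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import ExamRecording
from .tracking import DepthTrack, EnvelopeParams, wavelet_envelope


class FitError(ValueError):
    """Track unusable for a stress-strain fit."""


@dataclass(frozen=True)
class QualityGates:
    """Validity thresholds for a stress-strain fit.

    A fit is only trusted when enough frames contributed, the pressure ramp
    actually spanned a usable range, and the points are close to a line —
    protection against the low-amplitude failure mode of very soft cervices.
    """

    min_frames: int = 20
    min_span_kpa: float = 5.0
    min_r2: float = 0.8


@dataclass(frozen=True)
class StressStrainFit:
    """Fitted elasticity (kPa/mm) and zero-pressure length (mm) for one exam."""

    elasticity_kpa_mm: float
    zero_pressure_length_mm: float
    r_squared: float
    n_frames_used: int
    pressure_span_kpa: float
    valid: bool
    reasons: tuple[str, ...] = ()
    sector: str | None = None


@dataclass(frozen=True)
class StressStrainMap:
    """Echo-amplitude image over (depth, applied pressure), linear grayscale."""

    depth_bins_mm: np.ndarray     # bin centres, horizontal axis
    pressure_bins_kpa: np.ndarray  # one value per frame row, vertical axis
    amplitude: np.ndarray         # (n_frames, n_depth_bins), >= 0


def _lad_line(d: np.ndarray, p: np.ndarray, slope0: float, intercept0: float) -> tuple[float, float]:
    """Least-absolute-deviation line p = c0 + c1 d, seeded from the OLS fit."""
    res = optimize.minimize(
        lambda c: np.sum(np.abs(p - (c[0] + c[1] * d))),
        x0=np.array([intercept0, slope0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return float(res.x[1]), float(res.x[0])


def fit_stress_strain(
    track: DepthTrack,
    quality: QualityGates = QualityGates(),
    method: str = "ols",
    sector: str | None = None,
) -> StressStrainFit:
    """Fit pressure against depth over the valid frames of a track.

    Ordinary least squares of ``p = c0 + c1 d`` (a robust least-absolute-
    deviation variant is available via ``method="lad"``; its validity gating
    still uses the OLS R^2). Elasticity is ``|c1|`` and the zero-pressure
    length is the depth-axis intersection ``-c0 / c1``. Degenerate tracks
    (no compression) come back with ``valid=False`` and a reason code rather
    than raising; fewer than two valid frames is an error.
    """
    mask = np.asarray(track.valid, dtype=bool)
    d = np.asarray(track.depth_mm, dtype=float)[mask]
    p = np.asarray(track.pressure_kpa, dtype=float)[mask]
    if len(d) < 2:
        raise FitError("need at least two valid frames to fit a slope")
    span = float(np.ptp(p))
    reasons: list[str] = []

    if np.ptp(d) < 1e-9:  # no measurable compression: vertical point cloud
        return StressStrainFit(
            elasticity_kpa_mm=np.nan, zero_pressure_length_mm=float(d.mean()),
            r_squared=0.0, n_frames_used=len(d), pressure_span_kpa=span,
            valid=False, reasons=("no_compression",), sector=sector,
        )

    ols = stats.linregress(d, p)
    slope, intercept = float(ols.slope), float(ols.intercept)
    r2 = float(ols.rvalue**2)
    if method == "lad":
        slope, intercept = _lad_line(d, p, slope, intercept)
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")

    if abs(slope) < 1e-9:
        return StressStrainFit(
            elasticity_kpa_mm=np.nan, zero_pressure_length_mm=np.nan,
            r_squared=r2, n_frames_used=len(d), pressure_span_kpa=span,
            valid=False, reasons=("no_compression",), sector=sector,
        )

    if len(d) < quality.min_frames:
        reasons.append("too_few_frames")
    if span < quality.min_span_kpa:
        reasons.append("pressure_span_too_small")
    if r2 < quality.min_r2:
        reasons.append("poor_linearity")
    return StressStrainFit(
        elasticity_kpa_mm=abs(slope),
        zero_pressure_length_mm=-intercept / slope,
        r_squared=r2,
        n_frames_used=len(d),
        pressure_span_kpa=span,
        valid=not reasons,
        reasons=tuple(reasons),
        sector=sector,
    )


def build_map(
    recording: ExamRecording,
    track: DepthTrack,
    params: EnvelopeParams | None = None,
    depth_bin_mm: float = 0.1,
) -> StressStrainMap:
    """Bin each frame's envelope by depth at its measured pressure.

    One row per frame (vertical axis: applied pressure), columns on a uniform
    depth grid; cell values are mean envelope amplitude on a linear scale,
    no log compression.
    """
    params = params or EnvelopeParams()
    matrix = recording.sample_matrix()
    if matrix.shape[0] != len(track):
        raise ValueError("recording and track have mismatched frame counts")
    env = wavelet_envelope(matrix, params, recording.probe.sampling_rate)
    quantum_mm = track.speed_of_sound / (2.0 * recording.probe.sampling_rate) * 1000.0
    sample_depths = np.arange(matrix.shape[1]) * quantum_mm
    edges = np.arange(0.0, sample_depths[-1] + depth_bin_mm, depth_bin_mm)
    idx = np.clip(np.digitize(sample_depths, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    amplitude = np.vstack([
        np.bincount(idx, weights=row, minlength=len(edges) - 1) / np.maximum(counts, 1)
        for row in env
    ])
    centers = (edges[:-1] + edges[1:]) / 2.0
    return StressStrainMap(depth_bins_mm=centers,
                           pressure_bins_kpa=np.asarray(track.pressure_kpa, float),
                           amplitude=amplitude)


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject average of the two sector fits (anterior, posterior)."""

    avg_elasticity_kpa_mm: float
    avg_length_mm: float
    n_sectors_used: int
    single_sector: bool
    sectors_used: tuple[str, ...]


def subject_summary(anterior: StressStrainFit | None,
                    posterior: StressStrainFit | None) -> SubjectSummary:
    """Arithmetic mean of the valid sector fits; flags single-sector fallback."""
    fits = {"anterior": anterior, "posterior": posterior}
    used = {name: f for name, f in fits.items() if f is not None and f.valid}
    if not used:
        raise FitError("no valid sector fit; subject unusable")
    elast = float(np.mean([f.elasticity_kpa_mm for f in used.values()]))
    length = float(np.mean([f.zero_pressure_length_mm for f in used.values()]))
    return SubjectSummary(
        avg_elasticity_kpa_mm=elast,
        avg_length_mm=length,
        n_sectors_used=len(used),
        single_sector=len(used) == 1,
        sectors_used=tuple(used),
    )
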