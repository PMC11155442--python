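"""Synthetic tactile-ultrasound exam recordings with known ground truth.

Emulates a pulse-echo probe pressed against the cervix: a 5 MHz transducer
sampled at 50 MHz records one A-line per frame at 100 frames/s while the
applied pressure ramps up. The internal cervical surface produces the
dominant echo; its depth shrinks linearly with pressure at the tissue's
true stress-to-strain ratio (kPa/mm). Diffuse scatterers inside the cervix
and additive white noise provide realistic clutter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .signal_model import add_gabors, attenuation_factor, gaussian_pulse_sigma

ANTERIOR = "anterior"
POSTERIOR = "posterior"
SECTORS = (ANTERIOR, POSTERIOR)


class SafetyLimitError(ValueError):
    """Commanded pressure exceeds the probe's safety limit."""


class ConfigError(ValueError):
    """Invalid probe/tissue/protocol configuration."""


@dataclass(frozen=True)
class ProbeSpec:
    """Acquisition characteristics of the tactile-ultrasound probe.

    Defaults reproduce the device as specified: 5 MHz pulse-echo transducer,
    20 ns acquisition resolution (50 MHz), 100 data frames per second,
    30 kPa operational pressure range with sub-30 Pa pressure noise.
    """

    center_frequency: float = 5.0e6          # Hz
    sampling_rate: float = 50.0e6            # Hz
    pulse_duration: float = 0.5e-6           # s, nominal burst length (< 1 us)
    fractional_bandwidth: float = 0.5        # spectral FWHM / f0 of the burst
    frame_rate: float = 100.0                # frames / s
    max_pressure_kpa: float = 30.0
    pressure_noise_sd_pa: float = 30.0
    record_depth_mm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("center_frequency", "sampling_rate", "pulse_duration",
                     "fractional_bandwidth", "frame_rate", "max_pressure_kpa",
                     "record_depth_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.pressure_noise_sd_pa < 0:
            raise ConfigError("pressure_noise_sd_pa must be non-negative")
        if self.sampling_rate < 2.0 * self.center_frequency:
            raise ConfigError("sampling_rate violates Nyquist for center_frequency")
        if self.pulse_duration >= 1e-6:
            raise ConfigError("pulse_duration must be below 1 us")
        if self.max_pressure_kpa > 30.0:
            raise ConfigError("max_pressure_kpa exceeds the 30 kPa device limit")

    def n_samples(self, speed_of_sound: float) -> int:
        """A-line length for a round trip to ``record_depth_mm``."""
        return int(round(2.0 * self.record_depth_mm / 1000.0 / speed_of_sound * self.sampling_rate))


@dataclass(frozen=True)
class TissueModel:
    """Ground-truth mechanical and acoustic description of one cervical sector.

    ``elasticity_kpa_mm`` is the stress-to-strain ratio: applied pressure
    change (kPa) per millimetre of cervical shortening. The compressed length
    follows the linear law ``L(p) = max(L_min, L0 - p / E)``.
    """

    elasticity_kpa_mm: float
    rest_length_mm: float
    speed_of_sound: float = 1540.0           # m/s, standard soft tissue
    attenuation_db_cm_mhz: float = 0.5
    surface_reflectivity: float = 1.0
    scatterer_density_per_mm: float = 1.5
    scatterer_amplitude: float = 0.05        # fraction of surface_reflectivity
    min_compressed_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.elasticity_kpa_mm <= 0:
            raise ConfigError("elasticity_kpa_mm must be positive")
        if self.rest_length_mm <= 0 or self.min_compressed_length_mm <= 0:
            raise ConfigError("lengths must be positive")
        if self.min_compressed_length_mm >= self.rest_length_mm:
            raise ConfigError("min_compressed_length_mm must be below rest_length_mm")
        if self.speed_of_sound <= 0:
            raise ConfigError("speed_of_sound must be positive")
        if not (0.0 <= self.surface_reflectivity <= 1.0):
            raise ConfigError("surface_reflectivity must lie in [0, 1]")
        if self.scatterer_density_per_mm < 0:
            raise ConfigError("scatterer_density_per_mm must be non-negative")
        if not (0.0 <= self.scatterer_amplitude < 1.0):
            raise ConfigError("scatterer_amplitude must lie in [0, 1)")

    def compressed_length_mm(self, pressure_kpa: float) -> float:
        """Cervical length under ``pressure_kpa`` (linear law with a hard floor)."""
        return max(self.min_compressed_length_mm,
                   self.rest_length_mm - pressure_kpa / self.elasticity_kpa_mm)


@dataclass(frozen=True)
class CompressionProtocol:
    """Commanded pressure program: linear ramp, optional hold at the peak."""

    contact_pressure_kpa: float = 1.0
    peak_pressure_kpa: float = 21.0
    ramp_duration_s: float = 3.0
    hold_frames: int = 0

    def __post_init__(self) -> None:
        if self.contact_pressure_kpa < 0:
            raise ConfigError("contact_pressure_kpa must be non-negative")
        if self.peak_pressure_kpa < self.contact_pressure_kpa:
            raise ConfigError("peak_pressure_kpa must be >= contact_pressure_kpa")
        if self.ramp_duration_s <= 0:
            raise ConfigError("ramp_duration_s must be positive")
        if self.hold_frames < 0:
            raise ConfigError("hold_frames must be non-negative")

    def n_frames(self, frame_rate: float) -> int:
        return int(round(self.ramp_duration_s * frame_rate)) + self.hold_frames

    def commanded_pressures(self, frame_rate: float) -> np.ndarray:
        n_ramp = int(round(self.ramp_duration_s * frame_rate))
        ramp = np.linspace(self.contact_pressure_kpa, self.peak_pressure_kpa, n_ramp)
        if self.hold_frames:
            return np.concatenate([ramp, np.full(self.hold_frames, self.peak_pressure_kpa)])
        return ramp


@dataclass(frozen=True)
class ScattererField:
    """Frozen diffuse-scatterer realisation in material (rest) coordinates."""

    positions_mm: np.ndarray     # in [0, rest_length_mm]
    amplitudes: np.ndarray       # absolute echo amplitudes before attenuation
    phases: np.ndarray           # carrier phase per scatterer


@dataclass(frozen=True)
class Frame:
    """One acquisition frame: measured pressure plus the raw RF A-line."""

    timestamp_s: float
    applied_pressure_kpa: float
    samples: np.ndarray


@dataclass(frozen=True)
class ExamRecording:
    """Time-ordered frames for one cervical sector of one subject."""

    subject_id: str
    sector: str
    probe: ProbeSpec
    frames: tuple[Frame, ...]
    ground_truth: TissueModel | None = None

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ConfigError(f"sector must be one of {SECTORS}")
        ts = self.timestamps_s()
        if len(ts) > 1 and np.any(np.diff(ts) <= 0):
            raise ConfigError("frame timestamps must be strictly increasing")

    def timestamps_s(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames])

    def pressures_kpa(self) -> np.ndarray:
        return np.array([f.applied_pressure_kpa for f in self.frames])

    def sample_matrix(self) -> np.ndarray:
        """Frame-major (n_frames, n_samples) float array of the raw A-lines."""
        return np.stack([f.samples for f in self.frames]) if self.frames else np.empty((0, 0))


def draw_scatterers(tissue: TissueModel, rng: np.random.Generator) -> ScattererField:
    """Poisson-placed diffuse scatterers along the uncompressed cervix."""
    count = rng.poisson(tissue.scatterer_density_per_mm * tissue.rest_length_mm)
    positions = rng.uniform(0.0, tissue.rest_length_mm, size=count)
    amplitudes = rng.uniform(0.0, tissue.scatterer_amplitude, size=count) * tissue.surface_reflectivity
    phases = rng.uniform(0.0, 2.0 * np.pi, size=count)
    return ScattererField(positions, amplitudes, phases)


def simulate_frame(
    tissue: TissueModel,
    probe: ProbeSpec,
    pressure_kpa: float,
    rng: np.random.Generator | int | None = None,
    *,
    scatterers: ScattererField | None = None,
    snr_db: float | None = None,
    pressure_noise: bool = True,
    timestamp_s: float = 0.0,
) -> Frame:
    """Simulate one A-line at a commanded pressure.

    The dominant echo is a Gabor burst at the round-trip delay of the internal
    surface, attenuated by the exponential tissue law. Scatterer echoes ride
    at material positions rescaled by the compression ratio so they move with
    the tissue. ``snr_db`` sets white-noise power relative to the (attenuated)
    surface-echo amplitude; ``None`` disables noise. The recorded pressure
    carries Gaussian sensor noise of ``probe.pressure_noise_sd_pa`` unless
    ``pressure_noise`` is off.
    """
    if pressure_kpa < 0:
        raise ConfigError("pressure must be non-negative")
    if pressure_kpa > probe.max_pressure_kpa:
        raise SafetyLimitError(
            f"commanded pressure {pressure_kpa} kPa exceeds the probe limit "
            f"of {probe.max_pressure_kpa} kPa"
        )
    rng = np.random.default_rng(rng)
    c = tissue.speed_of_sound
    n = probe.n_samples(c)
    sigma_t = gaussian_pulse_sigma(probe.center_frequency, probe.fractional_bandwidth)
    signal = np.zeros(n)

    depth_mm = tissue.compressed_length_mm(pressure_kpa)
    surface_amp = tissue.surface_reflectivity * attenuation_factor(
        depth_mm, probe.center_frequency, tissue.attenuation_db_cm_mhz
    )
    if scatterers is None and tissue.scatterer_density_per_mm > 0:
        scatterers = draw_scatterers(tissue, rng)
    depths = np.array([depth_mm])
    amps = np.array([surface_amp])
    phases = np.zeros(1)
    if scatterers is not None and len(scatterers.positions_mm):
        # scatterers ride at material positions rescaled by the compression ratio
        pos = scatterers.positions_mm * (depth_mm / tissue.rest_length_mm)
        att = attenuation_factor(pos, probe.center_frequency, tissue.attenuation_db_cm_mhz)
        depths = np.concatenate([depths, pos])
        amps = np.concatenate([amps, scatterers.amplitudes * att])
        phases = np.concatenate([phases, scatterers.phases])
    add_gabors(signal, probe.sampling_rate, 2.0 * depths / 1000.0 / c,
               amps, sigma_t, probe.center_frequency, phases)

    if snr_db is not None and surface_amp > 0:
        noise_sd = surface_amp / 10.0 ** (snr_db / 20.0)
        signal += rng.normal(0.0, noise_sd, size=n)

    measured = pressure_kpa
    if pressure_noise and probe.pressure_noise_sd_pa > 0:
        measured += rng.normal(0.0, probe.pressure_noise_sd_pa / 1000.0)
    return Frame(timestamp_s=timestamp_s, applied_pressure_kpa=max(measured, 0.0), samples=signal)


def simulate_exam(
    tissue: TissueModel,
    probe: ProbeSpec,
    protocol: CompressionProtocol,
    seed: np.random.Generator | np.random.SeedSequence | int | None,
    *,
    snr_db: float | None = 20.0,
    pressure_noise: bool = True,
    subject_id: str = "sim",
    sector: str = ANTERIOR,
) -> ExamRecording:
    """Simulate a full compression exam (linear ramp plus optional hold).

    All randomness (scatterer field, signal noise, pressure sensor noise)
    derives from ``seed``; identical inputs give bit-identical recordings.
    """
    if protocol.peak_pressure_kpa > probe.max_pressure_kpa:
        raise SafetyLimitError(
            f"protocol peak {protocol.peak_pressure_kpa} kPa exceeds the probe "
            f"limit of {probe.max_pressure_kpa} kPa"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scatterers = (draw_scatterers(tissue, rng)
                  if tissue.scatterer_density_per_mm > 0 else None)
    frames = []
    for k, p in enumerate(protocol.commanded_pressures(probe.frame_rate)):
        frames.append(simulate_frame(
            tissue, probe, float(p), rng,
            scatterers=scatterers, snr_db=snr_db, pressure_noise=pressure_noise,
            timestamp_s=k / probe.frame_rate,
        ))
    return ExamRecording(subject_id=subject_id, sector=sector, probe=probe,
                         frames=tuple(frames), ground_truth=tissue)


def adaptive_protocol(
    tissue: TissueModel,
    base: CompressionProtocol = CompressionProtocol(),
    probe: ProbeSpec = ProbeSpec(),
    compression_floor_fraction: float = 0.35,
) -> CompressionProtocol:
    """Per-subject pressure program as an operator would apply it.

    The operator ramps pressure while watching the echo in real time and
    stops where compression saturates: the peak is the pressure that shortens
    the cervix to ``compression_floor_fraction`` of its rest length (or to the
    tissue's hard floor, whichever is longer), capped at the base protocol's
    peak and the probe safety limit. Soft cervices therefore receive low peak
    pressures rather than a flat, uninformative over-compression segment.
    """
    floor_mm = max(tissue.min_compressed_length_mm,
                   compression_floor_fraction * tissue.rest_length_mm)
    usable_mm = max(tissue.rest_length_mm - floor_mm, 0.0)
    # L(p) = L0 - p/E, so pressure E * usable shortens the cervix to the floor
    peak = tissue.elasticity_kpa_mm * usable_mm
    peak = min(peak, base.peak_pressure_kpa, probe.max_pressure_kpa)
    peak = max(peak, base.contact_pressure_kpa + 1e-6)
    return replace(base, peak_pressure_kpa=peak)
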