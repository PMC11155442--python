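"""Shared pulse-shape primitives for the RF signal model and the envelope detector.

The transmit pulse and the detection wavelet are both Gaussian-windowed
5 MHz carriers; their time-domain width is set from a fractional bandwidth
(spectral FWHM / carrier frequency).
"""
from __future__ import annotations

import numpy as np

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def gaussian_pulse_sigma(center_frequency: float, fractional_bandwidth: float) -> float:
    """Time-domain standard deviation (s) of a Gaussian pulse envelope.

    ``fractional_bandwidth`` is the spectral full width at half maximum
    divided by the carrier frequency; the time/frequency widths obey
    ``sigma_t = 1 / (2 pi sigma_f)``.
    """
    sigma_f = fractional_bandwidth * center_frequency / _FWHM_TO_SIGMA
    return 1.0 / (2.0 * np.pi * sigma_f)


def add_gabor(
    signal: np.ndarray,
    sampling_rate: float,
    delay_s: float,
    amplitude: float,
    sigma_t: float,
    center_frequency: float,
    phase: float = 0.0,
    support_sigmas: float = 4.0,
) -> None:
    """Add a Gaussian-windowed cosine burst centred at ``delay_s`` in place.

    Only samples within ``support_sigmas`` envelope standard deviations of the
    centre are touched; outside that window the burst is below 4e-4 of its
    peak and is dropped.
    """
    n = signal.shape[-1]
    center = delay_s * sampling_rate
    half = support_sigmas * sigma_t * sampling_rate
    lo = max(int(np.floor(center - half)), 0)
    hi = min(int(np.ceil(center + half)) + 1, n)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / sampling_rate - delay_s
    signal[..., lo:hi] += (
        amplitude
        * np.exp(-(t**2) / (2.0 * sigma_t**2))
        * np.cos(2.0 * np.pi * center_frequency * t + phase)
    )


def add_gabors(
    signal: np.ndarray,
    sampling_rate: float,
    delays_s: np.ndarray,
    amplitudes: np.ndarray,
    sigma_t: float,
    center_frequency: float,
    phases: np.ndarray | None = None,
    support_sigmas: float = 4.0,
) -> None:
    """Vectorised form of :func:`add_gabor` for a batch of bursts."""
    delays_s = np.asarray(delays_s, dtype=float)
    if delays_s.size == 0:
        return
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.zeros_like(delays_s) if phases is None else np.asarray(phases, dtype=float)
    n = signal.shape[-1]
    half = int(np.ceil(support_sigmas * sigma_t * sampling_rate))
    centers = delays_s * sampling_rate
    k0 = np.floor(centers - half).astype(int)
    idx = k0[:, None] + np.arange(2 * half + 1)[None, :]
    t = idx / sampling_rate - delays_s[:, None]
    contrib = (amplitudes[:, None]
               * np.exp(-(t**2) / (2.0 * sigma_t**2))
               * np.cos(2.0 * np.pi * center_frequency * t + phases[:, None]))
    inside = (idx >= 0) & (idx < n)
    signal += np.bincount(idx[inside], weights=contrib[inside], minlength=n)


def attenuation_factor(depth_mm: float | np.ndarray, center_frequency: float, coeff_db_cm_mhz: float) -> float | np.ndarray:
    """Round-trip amplitude attenuation for an echo from ``depth_mm``.

    Standard exponential soft-tissue law: ``coeff`` dB per cm per MHz applied
    over the two-way path ``2 * depth``.
    """
    f_mhz = center_frequency / 1e6
    path_cm = 2.0 * np.asarray(depth_mm) / 10.0
    return 10.0 ** (-coeff_db_cm_mhz * f_mhz * path_cm / 20.0)
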