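"""Vital-sign estimation from 30-second pulse-oximeter waveforms (PPG).

Breathing modulates the photoplethysmogram in amplitude (mechanical effect
of respiration) and in frequency (respiratory sinus arrhythmia).  Because
sinus arrhythmia is attenuated in older adults, the respiratory rate is
estimated here from the amplitude-modulation route:

1. remove the mean and low-pass filter the waveform with a heart-rate
   adaptive filter whose transition band runs from 0.5x to 1.2x the
   cardiac frequency, suppressing the cardiac component while keeping the
   respiratory baseband;
2. decimate to ~4 Hz so the autoregressive poles concentrate in the
   respiratory band;
3. fit autoregressive (Burg) models at several orders, evaluate each power
   spectrum on a common frequency grid, and take the pointwise *median*
   spectrum across orders — robust to spurious poles of any single order;
4. report 60x the frequency of the median-spectrum peak within the
   respiratory band (default 4-40 breaths/min).

Pulse rate is normally reported by the oximeter itself; a beat-detection
fallback is provided for segments where it is absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

__all__ = [
    "PPGSegment",
    "RrEstimate",
    "estimate_pulse_rate",
    "adaptive_lowpass",
    "ar_median_spectrum",
    "estimate_respiratory_rate",
    "DEFAULT_AR_ORDERS",
    "DEFAULT_RR_BAND_BRPM",
]

logger = logging.getLogger(__name__)

DEFAULT_AR_ORDERS: tuple[int, ...] = tuple(range(4, 13))
DEFAULT_RR_BAND_BRPM: tuple[float, float] = (4.0, 40.0)
#: target sampling rate after decimation (Hz)
DECIMATED_FS_HZ = 4.0
#: spectral grid: 0 to 1 Hz in steps of 0.004 Hz (0.24 breaths/min)
SPECTRUM_GRID_HZ = np.arange(0.0, 1.0 + 1e-9, 0.004)


class PPGError(ValueError):
    """Raised for invalid PPG segments or estimator parameters."""


@dataclass
class PPGSegment:
    """A raw pulse-oximeter waveform segment."""

    samples: np.ndarray
    fs_hz: float
    rr_true_brpm: Optional[float] = None
    hr_true_bpm: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise PPGError("samples must be a non-empty 1-D array")
        if self.fs_hz < 25:
            raise PPGError(f"sampling rate must be at least 25 Hz, got {self.fs_hz}")
        if not 20.0 <= self.duration_s <= 60.0:
            logger.warning(
                "PPG segment duration %.1f s outside the expected [20, 60] s range",
                self.duration_s,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class RrEstimate:
    """Respiratory-rate estimate with a quality flag.

    quality: ``ok`` (in-band peak at least 3 dB above the band's median
    power), ``low_confidence`` (peak present but weak) or ``failed``.
    ``candidates`` holds the per-order spectral peak frequencies (Hz).
    """

    rr_brpm: Optional[float]
    hr_bpm_used: Optional[float]
    quality: str
    candidates: dict[int, float] = field(default_factory=dict)


def estimate_pulse_rate(ppg: PPGSegment) -> RrEstimate:
    """Pulse rate from systolic-peak detection on the band-passed waveform.

    The signal is band-passed to the cardiac band (0.5-3 Hz) and peaks are
    detected with a refractory distance corresponding to 200 beats/min.
    Returns the rate as 60 / median inter-beat interval; quality is
    ``failed`` when fewer than 10 beats are found.
    """
    x = ppg.samples - ppg.samples.mean()
    if np.allclose(x, 0.0):
        return RrEstimate(rr_brpm=None, hr_bpm_used=None, quality="failed")
    sos = sps.butter(4, [0.5, 3.0], btype="bandpass", fs=ppg.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, x)
    min_dist = max(1, int(round(ppg.fs_hz * 60.0 / 200.0)))
    peaks, _ = sps.find_peaks(y, distance=min_dist, prominence=0.5 * np.std(y))
    if peaks.size < 10:
        return RrEstimate(rr_brpm=None, hr_bpm_used=None, quality="failed")
    ibi = np.diff(peaks) / ppg.fs_hz
    hr = 60.0 / float(np.median(ibi))
    return RrEstimate(rr_brpm=None, hr_bpm_used=hr, quality="ok")


def _design_lowpass(fs_hz: float, hr_bpm: float) -> np.ndarray:
    """Linear-phase FIR with transition band 0.5x-1.2x the cardiac frequency.

    Kaiser design for >=40 dB stopband attenuation; the corresponding
    passband ripple is well under 1 dB.
    """
    f_hr = hr_bpm / 60.0
    pass_edge, stop_edge = 0.5 * f_hr, 1.2 * f_hr
    width = stop_edge - pass_edge
    nyq = fs_hz / 2.0
    if stop_edge >= nyq:
        raise PPGError(
            f"stopband edge {stop_edge:.2f} Hz exceeds Nyquist {nyq:.2f} Hz; "
            "sampling rate too low for this heart rate"
        )
    numtaps, beta = sps.kaiserord(ripple=40.0, width=width / nyq)
    numtaps |= 1  # odd length -> exactly symmetric, integer group delay
    cutoff = 0.5 * (pass_edge + stop_edge)
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_hz)


def adaptive_lowpass(ppg: PPGSegment, hr_bpm: float) -> np.ndarray:
    """Zero-phase heart-rate-adaptive low-pass filtering of the waveform.

    The passband edge sits at 0.5x and the stopband edge at 1.2x the
    cardiac frequency.  The mean is removed before filtering; the
    symmetric FIR is applied with its group delay compensated, so the
    output is zero-phase.
    """
    if not 30.0 <= hr_bpm <= 200.0:
        raise PPGError(f"heart rate {hr_bpm} bpm outside the supported [30, 200] range")
    taps = _design_lowpass(ppg.fs_hz, hr_bpm)
    x = ppg.samples - ppg.samples.mean()
    # 'same' convolution with an odd symmetric kernel centres the output,
    # i.e. compensates the (numtaps-1)/2 group delay.
    return np.convolve(x, taps, mode="same")


def ar_median_spectrum(
    x: np.ndarray,
    fs_hz: float,
    orders: Sequence[int] = DEFAULT_AR_ORDERS,
    grid_hz: np.ndarray = SPECTRUM_GRID_HZ,
) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """Pointwise median of AR power spectra across model orders.

    Each order is fitted by Burg's method and its spectrum evaluated on
    ``grid_hz``; the median across orders is robust to a single order
    placing a spurious pole.  Returns (grid, median spectrum, per-order
    peak frequency).  Raises ``PPGError`` on degenerate (constant) input
    or if the signal is shorter than 4x the largest order.
    """
    x = np.asarray(x, dtype=float)
    orders = sorted(set(int(p) for p in orders))
    if not orders or min(orders) < 1:
        raise PPGError(f"invalid AR orders {orders}")
    if x.size < 4 * max(orders):
        raise PPGError(f"signal length {x.size} < 4 x max order {max(orders)}")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise PPGError("degenerate (constant) signal")
    grid_hz = np.asarray(grid_hz, dtype=float)
    if grid_hz.max() > fs_hz / 2 + 1e-9:
        raise PPGError("spectral grid extends beyond Nyquist")

    x = x - x.mean()
    omega = 2.0 * np.pi * grid_hz / fs_hz
    spectra = np.empty((len(orders), grid_hz.size))
    peaks: dict[int, float] = {}
    for i, p in enumerate(orders):
        rho, sigma2 = burg(x, order=p, demean=False)
        # S(f) = sigma^2 / |1 - sum_k rho_k e^{-j w k}|^2
        k = np.arange(1, p + 1)
        denom = np.abs(1.0 - np.exp(-1j * np.outer(omega, k)) @ rho) ** 2
        spectra[i] = sigma2 / np.maximum(denom, 1e-300)
        peaks[p] = float(grid_hz[np.argmax(spectra[i])])
    return grid_hz, np.median(spectra, axis=0), peaks


def _decimate(x: np.ndarray, fs_hz: float, target_fs: float = DECIMATED_FS_HZ) -> tuple[np.ndarray, float]:
    frac = Fraction(target_fs / fs_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    y = sps.resample_poly(x, up, down)
    return y, fs_hz * up / down


def estimate_respiratory_rate(
    ppg: PPGSegment,
    hr_bpm: Optional[float] = None,
    band_brpm: tuple[float, float] = DEFAULT_RR_BAND_BRPM,
    orders: Sequence[int] = DEFAULT_AR_ORDERS,
) -> RrEstimate:
    """Respiratory rate (breaths/min) from one PPG segment.

    Pipeline: mean removal -> heart-rate-adaptive low-pass -> decimation to
    ~4 Hz -> median AR spectrum -> 60x the in-band peak frequency.  The
    heart rate may come from the device; when absent it is estimated with
    :func:`estimate_pulse_rate`.  The result is ``low_confidence`` when the
    in-band peak rises less than 3 dB above the band's median power, and
    ``failed`` when any upstream stage fails.
    """
    lo, hi = band_brpm
    if not 0 < lo < hi:
        raise PPGError(f"invalid respiratory band {band_brpm}")
    if hr_bpm is None:
        pr = estimate_pulse_rate(ppg)
        if pr.quality == "failed" or pr.hr_bpm_used is None:
            return RrEstimate(rr_brpm=None, hr_bpm_used=None, quality="failed")
        hr_bpm = pr.hr_bpm_used

    try:
        filtered = adaptive_lowpass(ppg, hr_bpm)
        dec, fs_dec = _decimate(filtered, ppg.fs_hz)
        grid, spec, cands = ar_median_spectrum(dec, fs_dec, orders=orders)
    except PPGError as exc:
        logger.info("respiratory-rate estimation failed: %s", exc)
        return RrEstimate(rr_brpm=None, hr_bpm_used=hr_bpm, quality="failed")

    in_band = (grid >= lo / 60.0) & (grid <= hi / 60.0)
    if not np.any(in_band):
        return RrEstimate(rr_brpm=None, hr_bpm_used=hr_bpm, quality="failed")
    band_spec = spec[in_band]
    band_grid = grid[in_band]
    i_peak = int(np.argmax(band_spec))
    rr = 60.0 * float(band_grid[i_peak])

    # quality: the peak must stand >= 3 dB above the band's median power and
    # be interior to the band — a maximum at the band edge is usually the
    # skirt of an out-of-band component (residual cardiac power), not a
    # respiratory peak.
    peak_db = 10.0 * math.log10(band_spec[i_peak] / max(np.median(band_spec), 1e-300))
    interior = 0 < i_peak < band_spec.size - 1
    quality = "ok" if (peak_db >= 3.0 and interior) else "low_confidence"
    return RrEstimate(rr_brpm=rr, hr_bpm_used=hr_bpm, quality=quality, candidates=cands)
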