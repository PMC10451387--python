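"""The ten CoP sway variables computed from one preprocessed trial.

Operationalizations
-------------------
The variable set is the classical i-CTSIB one: four time-domain magnitudes,
the 95% confidence sway ellipse area, a signed mean acceleration, and four
spectral descriptors of the resultant power spectrum. Where the field's
verbal definitions are ambiguous, this module fixes one concrete definition
and uses it everywhere (generator calibration included):

* ``mean_cm`` - mean resultant distance of the CoP from the trial centroid.
* ``mean_path_cm_s`` - total path length divided by the recorded duration
  ``(n-1)/fs``. Note this coincides with ``mean_velocity_cm_s`` under
  uniform sampling; both are kept for schema compatibility with the
  conventional ten-variable table.
* ``mean_velocity_cm_s`` - mean per-sample speed (chord length times fs).
* ``mean_distance_cm`` - mean inter-sample chord length.
* ``mean_acc_cm_s2`` - signed mean of the second difference of the resultant
  displacement, times fs^2 (a signed definition; the magnitude is tiny for
  stationary sway, matching reported elderly-cohort norms).
* ``ellipse_area_cm2`` - pi * chi2(2 df, 95%) * sqrt(lambda1*lambda2) with
  lambda_i the eigenvalues of the x-y sample covariance (the principal-axes
  construction of the 95% confidence ellipse).
* spectral percentiles at 5/50/95% of cumulative band power (linear
  interpolation of the trapezoid cumulative) and the spectral centroid,
  all on the resultant (x+y) Welch spectrum within the analysis band.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal, stats

from .errors import InsufficientDataError, UndefinedSpectrumError
from .preprocessing import FilterSpec, bandpass_cop, detrend_cop
from .types import CopTrial, SwayFeatures

#: chi-square quantile (2 df, 95%) used by the confidence ellipse.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, 2))

#: Welch settings: Hann window, ~8 s segments, 50% overlap. An 8 s segment
#: resolves the 0.1 Hz band edge (bin width 0.125 Hz) within a 30 s trial.
WELCH_SEGMENT_S = 8.0
WELCH_WINDOW = "hann"


def time_domain_features(trial: CopTrial) -> SwayFeatures:
    """Compute the five time-domain sway magnitudes of a preprocessed trial."""
    if trial.n_samples < 3:
        raise InsufficientDataError(
            f"time-domain features need >= 3 samples, got {trial.n_samples}"
        )
    x, y, fs = trial.x, trial.y, trial.fs
    cx, cy = x - x.mean(), y - y.mean()
    r = np.hypot(cx, cy)
    chords = np.hypot(np.diff(x), np.diff(y))
    duration = trial.duration_s
    feats = SwayFeatures()
    feats.mean_cm = float(r.mean())
    feats.mean_path_cm_s = float(chords.sum() / duration)
    feats.mean_velocity_cm_s = float(np.mean(chords * fs))
    feats.mean_distance_cm = float(chords.mean())
    feats.mean_acc_cm_s2 = float(np.mean(np.diff(r, n=2)) * fs**2)
    return feats


def ellipse_area_95(trial: CopTrial) -> float:
    """Area of the 95% confidence sway ellipse, in cm^2.

    Returns 0 (with a warning) for a degenerate, collinear trajectory whose
    covariance is rank-deficient.
    """
    if trial.n_samples < 3:
        raise InsufficientDataError(
            f"ellipse area needs >= 3 samples, got {trial.n_samples}"
        )
    cov = np.cov(np.vstack([trial.x, trial.y]))
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or not np.isfinite(eigvals).all():
        if eigvals[0] < -1e-12 or eigvals[1] > 1e-12:
            warnings.warn(
                "rank-deficient CoP covariance (collinear trajectory); "
                "ellipse area set to 0",
                stacklevel=2,
            )
        return 0.0
    return float(np.pi * CHI2_95_2DF * math.sqrt(eigvals[0] * eigvals[1]))


@dataclass(frozen=True)
class PowerSpectrum:
    """Welch power spectral density of a trial, restricted to the analysis band."""

    freqs: np.ndarray
    power_x: np.ndarray
    power_y: np.ndarray
    power: np.ndarray  # resultant: power_x + power_y
    window: str
    nperseg: int
    noverlap: int
    band: tuple[float, float]


def power_spectrum(
    trial: CopTrial,
    band: tuple[float, float] = (FilterSpec.f_low, FilterSpec.f_high),
    segment_s: float = WELCH_SEGMENT_S,
) -> PowerSpectrum:
    """Welch-averaged periodogram per axis plus the resultant spectrum.

    The output is restricted to the analysis band ``band``.
    """
    if trial.n_samples < 64:
        raise InsufficientDataError(
            f"power spectrum needs >= 64 samples, got {trial.n_samples}"
        )
    nperseg = min(trial.n_samples, int(round(segment_s * trial.fs)))
    noverlap = nperseg // 2
    f, pxx = signal.welch(
        trial.x, fs=trial.fs, window=WELCH_WINDOW, nperseg=nperseg, noverlap=noverlap
    )
    _, pyy = signal.welch(
        trial.y, fs=trial.fs, window=WELCH_WINDOW, nperseg=nperseg, noverlap=noverlap
    )
    keep = (f >= band[0]) & (f <= band[1])
    return PowerSpectrum(
        freqs=f[keep],
        power_x=pxx[keep],
        power_y=pyy[keep],
        power=pxx[keep] + pyy[keep],
        window=WELCH_WINDOW,
        nperseg=nperseg,
        noverlap=noverlap,
        band=band,
    )


def frequency_features(spectrum: PowerSpectrum) -> SwayFeatures:
    """Spectral percentile frequencies and centroid of the resultant spectrum.

    ``freq_low5 / freq_median / freq_high5`` are the frequencies at which the
    cumulative band power reaches 5% / 50% / 95% (linear interpolation of the
    trapezoid cumulative); ``freq_center`` is the power-weighted mean
    frequency (spectral centroid) over the band.
    """
    f, p = spectrum.freqs, spectrum.power
    total = integrate.trapezoid(p, f)
    if not (total > 0):
        raise UndefinedSpectrumError("zero total band power; percentile frequencies undefined")
    cum = integrate.cumulative_trapezoid(p, f, initial=0.0)
    feats = SwayFeatures()
    feats.freq_low5_hz = float(np.interp(0.05 * total, cum, f))
    feats.freq_median_hz = float(np.interp(0.50 * total, cum, f))
    feats.freq_high5_hz = float(np.interp(0.95 * total, cum, f))
    feats.freq_center_hz = float(integrate.trapezoid(f * p, f) / total)
    return feats


def compute_sway_features(
    trial: CopTrial, spec: FilterSpec | None = None
) -> SwayFeatures:
    """Full feature pipeline on a raw trial.

    Runs ``detrend -> bandpass`` then assembles all ten variables. If the
    preprocessed signal has no band power (e.g. a constant input) the
    frequency features are flagged missing (NaN) rather than raising.
    """
    spec = spec or FilterSpec()
    pre = bandpass_cop(detrend_cop(trial), spec)
    feats = time_domain_features(pre)
    feats.ellipse_area_cm2 = ellipse_area_95(pre)
    # a numerically-null residual (e.g. a constant raw input after filtering)
    # has no meaningful spectrum even though float noise makes it nonzero
    raw_amp = float(max(np.max(np.abs(trial.x)), np.max(np.abs(trial.y)), 1.0))
    pre_amp = float(max(np.max(np.abs(pre.x)), np.max(np.abs(pre.y))))
    if pre_amp < 1e-12 * raw_amp:
        return feats
    try:
        spectrum = power_spectrum(pre, band=(spec.f_low, spec.f_high))
        feats.update(frequency_features(spectrum))
    except (InsufficientDataError, UndefinedSpectrumError):
        pass  # frequency features stay NaN (flagged missing)
    return feats
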