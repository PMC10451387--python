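"""CoP signal conditioning: linear detrending and Butterworth bandpass.

The standard stabilometry preprocessing chain applied before feature
extraction is ``detrend -> bandpass(0.1-4 Hz)``. The bandpass is a 4th-order
Butterworth (a 2nd-order lowpass prototype transformed to a bandpass, i.e. a
4th-order transfer function), designed digitally via the bilinear transform
at the trial's sampling rate, so the half-power (-3 dB) points of the
single-pass response fall exactly on the configured band edges. By default
the filter is applied forward-backward (zero phase), which preserves the
timing of sway excursions at the cost of squaring the magnitude response.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DomainError, InsufficientDataError, NyquistError
from .types import CopTrial


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass filter configuration.

    ``order`` is the order of the bandpass transfer function and must be
    even (the lowpass prototype has order ``order // 2``).
    """

    order: int = 4
    f_low: float = 0.1
    f_high: float = 4.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2 != 0:
            raise DomainError(f"bandpass order must be a positive even integer, got {self.order}")
        if not (0 < self.f_low < self.f_high):
            raise DomainError(
                f"need 0 < f_low < f_high, got f_low={self.f_low}, f_high={self.f_high}"
            )

    def design_sos(self, fs: float) -> np.ndarray:
        """Second-order sections of the digital filter for sampling rate ``fs``."""
        if self.f_high >= fs / 2:
            raise NyquistError(
                f"f_high={self.f_high} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        return signal.butter(
            self.order // 2,
            [self.f_low, self.f_high],
            btype="bandpass",
            fs=fs,
            output="sos",
        )


def detrend_cop(trial: CopTrial) -> CopTrial:
    """Remove the least-squares straight line from each CoP axis.

    The output has (numerically) zero mean and zero linear trend per axis.
    """
    if trial.n_samples < 3:
        raise InsufficientDataError(
            f"detrending needs at least 3 samples, got {trial.n_samples}"
        )
    x = signal.detrend(trial.x, type="linear")
    y = signal.detrend(trial.y, type="linear")
    return trial.replace_signal(x, y)


def bandpass_cop(trial: CopTrial, spec: FilterSpec | None = None) -> CopTrial:
    """Bandpass-filter both CoP axes.

    With ``spec.zero_phase`` (the default) the filter is applied forward and
    backward with odd-reflection edge padding; otherwise a single causal pass
    is used. Output length equals input length.
    """
    spec = spec or FilterSpec()
    sos = spec.design_sos(trial.fs)
    if spec.zero_phase:
        x = signal.sosfiltfilt(sos, trial.x, padtype="odd")
        y = signal.sosfiltfilt(sos, trial.y, padtype="odd")
    else:
        x = signal.sosfilt(sos, trial.x)
        y = signal.sosfilt(sos, trial.y)
    return trial.replace_signal(x, y)


def filter_gain(spec: FilterSpec, fs: float, f: float | np.ndarray) -> float | np.ndarray:
    """Single-pass magnitude response of the designed digital filter, in dB.

    Note that zero-phase application squares the magnitude response, so the
    effective two-pass attenuation at the band edges is twice this value.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any((f_arr <= 0) | (f_arr >= fs / 2)):
        raise DomainError(f"frequency must lie in (0, {fs / 2}) Hz")
    sos = spec.design_sos(fs)
    _, h = signal.sosfreqz(sos, worN=f_arr, fs=fs)
    gain_db = 20.0 * np.log10(np.abs(h))
    return float(gain_db[0]) if np.isscalar(f) or np.ndim(f) == 0 else gain_db


def halfpower_crossings(spec: FilterSpec, fs: float, n_grid: int = 200_001) -> tuple[float, float]:
    """Locate the lower and upper half-power (-3 dB) crossings of the response.

    The single-pass magnitude is evaluated on a fine geometric frequency grid
    and the two crossings of 10*log10(1/2) dB are found by linear
    interpolation of the dB response.
    """
    f = np.geomspace(1e-3, fs / 2 * 0.999, n_grid)
    g = filter_gain(spec, fs, f)
    target = 10.0 * np.log10(0.5)
    above = g > target
    idx = np.nonzero(np.diff(above.astype(int)))[0]
    if len(idx) < 2:
        raise DomainError("response does not have two half-power crossings")

    # linear interpolation in (gain, frequency) between bracketing grid points
    def cross(i: int) -> float:
        g0, g1 = g[i], g[i + 1]
        f0, f1 = f[i], f[i + 1]
        return float(f0 + (target - g0) * (f1 - f0) / (g1 - g0))

    return cross(idx[0]), cross(idx[-1])
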