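"""Condition-calibrated synthetic sway generator and dual-device emulation.

Sway model
----------
Each CoP axis is an independent, stationary, band-limited Gaussian process
with a power-law spectrum ``S(f) ~ f**(-alpha)`` on the analysis band
(0.1-4 Hz by default), synthesized exactly on the trial's FFT grid (circular
embedding), so every spectral moment of a generated trial is known in closed
form. The generator is calibrated per CTSIB condition so that the *expected
value of the features the package itself computes* - after detrending,
zero-phase bandpass filtering and Welch spectral estimation - matches the
condition's calibration targets. The expectation accounts for:

* the two-pass filter power response ``|H(f)|**4``;
* the chord (finite-difference) velocity estimator, including its implicit
  sinc attenuation;
* the variance removed by linear detrending (projection of the circulant
  covariance onto the {1, t} span);
* the Hann-window smoothing of the Welch spectrum (exact expected Welch
  periodogram of the synthesized process);
* the finite-sample downward bias of ``sqrt(det(sample covariance))`` for an
  autocorrelated series (first-order correction ``1 - q/2`` with
  ``q = sum(v_k^2) / (sum v_k)^2`` the spectral concentration).

Calibration targets
-------------------
A condition is calibrated to its mean sway velocity plus *either* the median
sway frequency *or* the 95% ellipse area. For a stationary Gaussian process
the three quantities are linked by a spectral-moment bound
(``f_rms >= f_median / sqrt(2)``), and published elderly-cohort norms for
the CTSIB conditions violate that bound jointly, so all three cannot be
requested at once; doing so raises :class:`~ictsib.errors.CalibrationError`
naming the conflicting targets. The default configuration matches velocity
and median frequency for the firm / dual-task / single-foam conditions, and
velocity and ellipse area for the double-foam conditions where sway
amplitude is the defining characteristic of the task.

The stability-index link
------------------------
Ground-truth SI for a synthetic cohort is an affine function of the sway
features plus Gaussian noise. By default the noise level is derived per
condition from a declared R^2 (0.95), i.e. the linear link explains 95% of
the SI variance across the cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, signal, special, stats
from scipy.optimize import brentq

from .cop import MM_PER_CM, CornerLoadSeries, GridGeometry, PressureFrameSeries
from .errors import CalibrationError, DomainError
from .features import CHI2_95_2DF, WELCH_SEGMENT_S, WELCH_WINDOW, compute_sway_features
from .preprocessing import FilterSpec
from .types import Condition, CopTrial, SwayFeatures

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ConditionCalibration:
    """Calibration targets for one CTSIB condition.

    ``target_mean_velocity_cm_s`` is always required. Exactly which of the
    two remaining targets are set determines the spectrum shape solve; see
    the module docstring. ``amplitude_ratio_xy`` is the AP:ML amplitude
    ratio (1 = isotropic sway).
    """

    target_mean_velocity_cm_s: float
    target_ellipse_area_cm2: float | None = None
    target_freq_median_hz: float | None = None
    amplitude_ratio_xy: float = 1.0
    band_hz: tuple[float, float] = (0.1, 4.0)

    def __post_init__(self) -> None:
        if self.target_mean_velocity_cm_s <= 0:
            raise DomainError("target mean velocity must be positive")
        if self.amplitude_ratio_xy <= 0:
            raise DomainError("amplitude ratio must be positive")
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise DomainError(f"invalid band {self.band_hz}")


@dataclass(frozen=True)
class SiLink:
    """Affine link from sway features to the reference stability index.

    ``si = intercept + sum_i weights[name_i] * feature_i + noise``. If
    ``noise_sd`` is None, it is derived per condition as
    ``sd(link) * sqrt(1/target_r2 - 1)`` across the generated cohort so the
    link explains ``target_r2`` of the SI variance.
    """

    weights: dict[str, float]
    intercept: float = 0.4
    noise_sd: float | None = None
    target_r2: float = 0.95

    def apply(self, features: SwayFeatures) -> float:
        return self.intercept + sum(
            w * getattr(features, name) for name, w in self.weights.items()
        )


#: Default SI link: sway magnitude (velocity, area, mean excursion) drives
#: the index; intercept keeps SI strictly positive for realistic sway.
DEFAULT_SI_LINK = SiLink(
    weights={"mean_velocity_cm_s": 1.0, "ellipse_area_cm2": 0.25, "mean_cm": 0.8},
    intercept=0.4,
)

#: Per-condition calibration targets (elderly-cohort norms): mean velocity
#: in cm/s for every condition; median frequency in Hz for the firm,
#: dual-task and single-foam conditions; 95% ellipse area in cm^2 for the
#: double-foam conditions.
DEFAULT_CONDITION_CALIBRATIONS: dict[Condition, ConditionCalibration] = {
    Condition.EO_FIRM: ConditionCalibration(1.20, target_freq_median_hz=1.44),
    Condition.EO_FIRM_DC: ConditionCalibration(1.69, target_freq_median_hz=1.44),
    Condition.EO_FOAM1: ConditionCalibration(1.59, target_freq_median_hz=1.44),
    Condition.EO_FOAM2: ConditionCalibration(2.04, target_ellipse_area_cm2=3.58),
    Condition.EC_FIRM: ConditionCalibration(1.64, target_freq_median_hz=1.48),
    Condition.EC_FOAM1: ConditionCalibration(2.26, target_freq_median_hz=1.49),
    Condition.EC_FOAM2: ConditionCalibration(2.94, target_ellipse_area_cm2=6.28),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator."""

    conditions: dict[Condition, ConditionCalibration] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_CALIBRATIONS)
    )
    si_link: SiLink = DEFAULT_SI_LINK
    duration_s: float = 30.0
    fs: float = 23.0
    #: log-sd of the per-subject log-normal sway-severity multiplier (mean 1),
    #: chosen so between-subject feature dispersion approximates cohort norms.
    severity_sigma: float = 0.3
    filter_spec: FilterSpec = FilterSpec()

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def default_generator_config() -> GeneratorConfig:
    return GeneratorConfig()


# ---------------------------------------------------------------------------
# calibration machinery


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Solved per-axis synthesis spectrum for one condition."""

    freqs: np.ndarray  # rfft grid, Hz
    var_x: np.ndarray  # per-bin variance contributions of the x axis, cm^2
    var_y: np.ndarray
    alpha: float
    expected: dict[str, float]  # expected pipeline features at this scale


class _PipelineExpectation:
    """Expected pipeline features of a circular Gaussian process.

    Everything is per unit total axis variance; amplitude scaling is applied
    analytically afterwards. Instances are cached per (n, fs, filter, band).
    """

    def __init__(self, n: int, fs: float, filter_spec: FilterSpec, band: tuple[float, float]):
        self.n, self.fs, self.band = n, fs, band
        self.freqs = np.fft.rfftfreq(n, 1.0 / fs)
        sos = filter_spec.design_sos(fs)
        _, h = signal.sosfreqz(sos, worN=self.freqs, fs=fs)
        self.h4 = np.abs(h) ** 4  # zero-phase (two-pass) power response
        self.in_band = (self.freqs >= band[0]) & (self.freqs <= band[1])
        self.chord_gain = 2.0 * (1.0 - np.cos(2.0 * np.pi * self.freqs / fs))
        self._detrend_quad = self._detrend_quadform()
        self._welch = None  # lazy: (welch_freqs, kernel over in-band bins)

    def _detrend_quadform(self) -> np.ndarray:
        """Quadratic-form weights of the variance removed by linear detrending.

        For the circular synthesis ``x_t = sum_k sqrt(v_k)(a_k cos w_k t -
        b_k sin w_k t)`` with a, b standard normal, the expected squared
        projection onto a unit vector b is ``sum_k v_k |B_k|^2`` with B the
        DFT of b; the expected mean-square removed by projecting onto
        span{1, t} is therefore ``sum_k v_k w_k / n`` with the weights
        returned here.
        """
        n = self.n
        b1 = np.ones(n) / math.sqrt(n)
        t = np.arange(n) - (n - 1) / 2.0
        b2 = t / np.linalg.norm(t)
        return sum(np.abs(np.fft.rfft(b)) ** 2 for b in (b1, b2))

    def _welch_setup(self):
        if self._welch is None:
            nperseg = min(self.n, int(round(WELCH_SEGMENT_S * self.fs)))
            win = signal.get_window(WELCH_WINDOW, nperseg)
            fw = np.fft.rfftfreq(nperseg, 1.0 / self.fs)
            keep = (fw >= self.band[0]) & (fw <= self.band[1])
            fw = fw[keep]
            fk = self.freqs[self.in_band]
            t = np.arange(nperseg)
            # |DTFT of window|^2 at fw -+ fk (both spectral images of a real process)
            def k2(df):
                ph = np.exp(-2j * np.pi * df[..., None] * t / self.fs)
                return np.abs((win * ph).sum(axis=-1)) ** 2
            kernel = 0.5 * (k2(fw[:, None] - fk[None, :]) + k2(fw[:, None] + fk[None, :]))
            self._welch = (fw, kernel)
        return self._welch

    def stats(self, v: np.ndarray) -> dict[str, float]:
        """Expected features for per-axis raw-spectrum variance contributions v.

        Assumes both axes share the shape of ``v`` (scaled versions); returns
        per-axis quantities for unit input.
        """
        p = v * self.h4  # post-filter contributions
        m0 = float(p.sum())
        detrend_loss = float((p * self._detrend_quad).sum() / self.n)
        m0_eff = max(m0 - detrend_loss, 0.0)
        chord_var = float((p * self.chord_gain).sum())
        q = float((p**2).sum() / m0**2) if m0 > 0 else 0.0
        fw, kernel = self._welch_setup()
        pw = kernel @ p[self.in_band]
        # same quantile rule as features.frequency_features: trapezoid cumulative
        cum = integrate.cumulative_trapezoid(pw, fw, initial=0.0)
        median = float(np.interp(0.5 * cum[-1], cum, fw)) if cum[-1] > 0 else math.nan
        return {
            "m0_eff": m0_eff,
            "chord_var": chord_var,
            "q": q,
            "freq_median_hz": median,
        }


def _mean_norm_2d(sd_a: float, sd_b: float) -> float:
    """E[sqrt(A^2+B^2)] for independent zero-mean normals with sds sd_a, sd_b."""
    hi, lo = max(sd_a, sd_b), min(sd_a, sd_b)
    if hi == 0:
        return 0.0
    m = 1.0 - (lo / hi) ** 2
    return math.sqrt(2.0 / math.pi) * hi * float(special.ellipe(m))


_EXPECTATION_CACHE: dict[tuple, _PipelineExpectation] = {}
_CALIBRATION_CACHE: dict[tuple, CalibratedSpectrum] = {}


def _expectation(config: GeneratorConfig, band: tuple[float, float]) -> _PipelineExpectation:
    key = (config.n_samples, config.fs, config.filter_spec, band)
    if key not in _EXPECTATION_CACHE:
        _EXPECTATION_CACHE[key] = _PipelineExpectation(
            config.n_samples, config.fs, config.filter_spec, band
        )
    return _EXPECTATION_CACHE[key]


def _shape_spectrum(exp: _PipelineExpectation, alpha: float) -> np.ndarray:
    """Unit-variance power-law variance contributions on the rfft grid."""
    v = np.zeros_like(exp.freqs)
    fb = exp.freqs[exp.in_band]
    v[exp.in_band] = fb ** (-alpha)
    return v / v.sum()


def _expected_at_scale(
    exp: _PipelineExpectation, alpha: float, sx: float, sy: float, fs: float
) -> dict[str, float]:
    """Expected pipeline features for axis sds (sx, sy) at spectrum shape alpha."""
    v = _shape_spectrum(exp, alpha)
    s = exp.stats(v)
    chord_sd = math.sqrt(s["chord_var"])
    sigma_eff = math.sqrt(s["m0_eff"])
    vel = fs * _mean_norm_2d(sx * chord_sd, sy * chord_sd)
    area = (
        math.pi * CHI2_95_2DF * (sx * sigma_eff) * (sy * sigma_eff) * (1.0 - s["q"] / 2.0)
    )
    mean_cm = _mean_norm_2d(sx * sigma_eff, sy * sigma_eff)
    return {
        "mean_velocity_cm_s": vel,
        "ellipse_area_cm2": area,
        "freq_median_hz": s["freq_median_hz"],
        "mean_cm": mean_cm,
    }


_ALPHA_BRACKET = (-10.0, 10.0)
#: Relative slack when a redundant third target is supplied explicitly.
_REDUNDANT_TARGET_RTOL = 0.05


def calibrate_condition(
    config: GeneratorConfig, condition: Condition
) -> CalibratedSpectrum:
    """Solve spectrum shape and amplitude for one condition's targets.

    Raises :class:`CalibrationError` when the requested target combination is
    infeasible for a stationary Gaussian process under the package's feature
    definitions.
    """
    cal = config.conditions[condition]
    key = (cal, config.n_samples, config.fs, config.filter_spec)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    exp = _expectation(config, cal.band_hz)
    if exp.freqs[exp.in_band].size < 3:
        raise CalibrationError(f"band {cal.band_hz} contains too few FFT bins")
    rho = cal.amplitude_ratio_xy
    # unit scale: sy = 1, sx = rho (relative axis sds)
    V = cal.target_mean_velocity_cm_s
    A = cal.target_ellipse_area_cm2
    M = cal.target_freq_median_hz

    def at(alpha: float) -> dict[str, float]:
        return _expected_at_scale(exp, alpha, rho, 1.0, config.fs)

    if M is not None:
        g = lambda a: at(a)["freq_median_hz"] - M
        lo, hi = _ALPHA_BRACKET
        if g(lo) * g(hi) > 0:
            raise CalibrationError(
                f"{condition.value}: target_freq_median_hz={M} is outside the "
                f"range achievable within band {cal.band_hz}"
            )
        alpha = brentq(g, lo, hi, xtol=1e-9)
    elif A is not None:
        # scale-invariant shape condition: velocity / sqrt(area)
        target_ratio = V / math.sqrt(A)
        g = lambda a: (lambda e: e["mean_velocity_cm_s"] / math.sqrt(e["ellipse_area_cm2"]))(
            at(a)
        ) - target_ratio
        lo, hi = _ALPHA_BRACKET
        if g(lo) * g(hi) > 0:
            raise CalibrationError(
                f"{condition.value}: targets mean_velocity={V} cm/s and "
                f"ellipse_area={A} cm^2 are jointly infeasible in band {cal.band_hz}"
            )
        alpha = brentq(g, lo, hi, xtol=1e-9)
    else:
        alpha = 1.0  # default mildly low-frequency-weighted sway spectrum

    unit = at(alpha)
    scale = V / unit["mean_velocity_cm_s"]
    expected = _expected_at_scale(exp, alpha, rho * scale, scale, config.fs)

    if M is not None and A is not None:
        ach = expected["ellipse_area_cm2"]
        if abs(ach - A) > _REDUNDANT_TARGET_RTOL * A:
            raise CalibrationError(
                f"{condition.value}: target_mean_velocity_cm_s={V}, "
                f"target_ellipse_area_cm2={A} and target_freq_median_hz={M} are "
                f"jointly infeasible for a stationary Gaussian process (the "
                f"spectral-moment bound f_rms >= f_median/sqrt(2) forces an "
                f"ellipse area of {ach:.3g} cm^2 at these velocity/median "
                f"targets); drop one of the three targets"
            )

    v_shape = _shape_spectrum(exp, alpha)
    spec = CalibratedSpectrum(
        freqs=exp.freqs,
        var_x=v_shape * (rho * scale) ** 2,
        var_y=v_shape * scale**2,
        alpha=float(alpha),
        expected=expected,
    )
    _CALIBRATION_CACHE[key] = spec
    return spec


def expected_features(config: GeneratorConfig, condition: Condition) -> dict[str, float]:
    """Expected pipeline features of trials generated for ``condition``."""
    return dict(calibrate_condition(config, condition).expected)


# ---------------------------------------------------------------------------
# trial / cohort generation


def _synthesize_axis(v: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one circular Gaussian series with per-bin variance contributions v."""
    amp = np.sqrt(v * n**2 / 4.0)
    z = amp * (rng.standard_normal(len(v)) + 1j * rng.standard_normal(len(v)))
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = math.sqrt(v[-1]) * n * rng.standard_normal() if v[-1] > 0 else 0.0
    return np.fft.irfft(z, n)


def generate_cop_trial(
    config: GeneratorConfig,
    condition: Condition,
    seed: int | np.random.Generator,
    subject_id: str = "",
    amplitude_multiplier: float = 1.0,
) -> CopTrial:
    """Generate one condition-calibrated synthetic CoP trial.

    Deterministic given ``seed``. ``amplitude_multiplier`` scales both axes
    (used for per-subject sway severity); the calibration targets refer to a
    multiplier of 1.
    """
    spec = calibrate_condition(config, condition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_samples
    x = _synthesize_axis(spec.var_x * amplitude_multiplier**2, n, rng)
    y = _synthesize_axis(spec.var_y * amplitude_multiplier**2, n, rng)
    return CopTrial.from_signals(x, y, config.fs, condition, subject_id)


@dataclass
class CohortRow:
    subject_id: str
    condition: Condition
    features: SwayFeatures
    si_reference: float
    noise_draw: float
    severity: float


@dataclass
class SyntheticCohort:
    """A generated cohort: trials, features, ground-truth SI and its link."""

    rows: list[CohortRow]
    trials: dict[tuple[str, Condition], CopTrial]
    si_link: SiLink
    noise_sd_by_condition: dict[Condition, float]
    config: GeneratorConfig

    def training_table(self):
        """View as a :class:`~ictsib.model.TrainingTable`."""
        from .model import TrainingRow, TrainingTable

        return TrainingTable(
            rows=[
                TrainingRow(r.subject_id, r.condition, r.features, r.si_reference)
                for r in self.rows
            ],
            source="ictsib.synth",
        )


def generate_cohort(
    config: GeneratorConfig, n_subjects: int, seed: int
) -> SyntheticCohort:
    """Generate a full synthetic cohort (``n_subjects`` x all conditions).

    Per subject a latent log-normal sway-severity multiplier (mean 1) scales
    the sway amplitude in every condition; features are computed through the
    real preprocessing/feature pipeline; the reference SI is the affine link
    applied to the features plus Gaussian noise (floored at zero, which for
    the default link is a measure-zero event).
    """
    if n_subjects < 2:
        raise DomainError(f"a cohort needs at least 2 subjects, got {n_subjects}")
    root = np.random.default_rng(seed)
    sev_sigma = config.severity_sigma
    severities = np.exp(root.normal(-0.5 * sev_sigma**2, sev_sigma, size=n_subjects))
    subject_ids = [f"S{i + 1:03d}" for i in range(n_subjects)]

    rows: list[CohortRow] = []
    trials: dict[tuple[str, Condition], CopTrial] = {}
    link_values: dict[Condition, list[float]] = {c: [] for c in config.conditions}
    for sid, sev in zip(subject_ids, severities):
        for cond in config.conditions:
            trial = generate_cop_trial(
                config, cond, root, subject_id=sid, amplitude_multiplier=float(sev)
            )
            feats = compute_sway_features(trial, config.filter_spec)
            rows.append(CohortRow(sid, cond, feats, math.nan, math.nan, float(sev)))
            trials[(sid, cond)] = trial
            link_values[cond].append(config.si_link.apply(feats))

    noise_sd: dict[Condition, float] = {}
    for cond in config.conditions:
        if config.si_link.noise_sd is not None:
            noise_sd[cond] = config.si_link.noise_sd
        else:
            sd_link = float(np.std(link_values[cond], ddof=1))
            noise_sd[cond] = sd_link * math.sqrt(1.0 / config.si_link.target_r2 - 1.0)

    for row in rows:
        link = config.si_link.apply(row.features)
        draw = float(root.normal(0.0, noise_sd[row.condition]))
        si = max(link + draw, 0.0)
        row.si_reference = si
        row.noise_draw = si - link  # equals draw unless floored at zero
    return SyntheticCohort(rows, trials, config.si_link, noise_sd, config)


# ---------------------------------------------------------------------------
# dual-device emulation


@dataclass(frozen=True)
class FootprintModel:
    """Bivariate-Gaussian two-foot pressure footprint on the mat."""

    foot_sd_x_cm: float = 4.0  # AP spread of one foot's pressure blob
    foot_sd_y_cm: float = 2.0  # ML spread
    foot_offset_y_cm: float = 8.0  # half the ML stance width


#: Sensor-noise defaults (kgf), checked by Monte Carlo: with these levels,
#: dual-device SI agreement across an emulated cohort stays above the 0.96
#: Pearson r benchmark of mat-on-force-plate validation studies.
DEFAULT_GRID_NOISE_SD_KGF = 0.02
DEFAULT_CORNER_NOISE_SD_KGF = 0.05


def _cell_weights(centers_edges: np.ndarray, mu: np.ndarray, sd: float) -> np.ndarray:
    """Integral of N(mu, sd^2) over consecutive cell intervals, per frame."""
    z = (centers_edges[None, :] - mu[:, None]) / (sd * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + special.erf(z))
    return np.diff(cdf, axis=1)


def emulate_devices(
    trial: CopTrial,
    grid: GridGeometry | None = None,
    board: CornerLoadSeries | None = None,
    load_kgf: float = 60.0,
    grid_noise_sd: float = DEFAULT_GRID_NOISE_SD_KGF,
    corner_noise_sd: float = DEFAULT_CORNER_NOISE_SD_KGF,
    seed: int | np.random.Generator = 0,
    footprint: FootprintModel = FootprintModel(),
) -> tuple[PressureFrameSeries, CornerLoadSeries]:
    """Emulate both measurement devices observing the same CoP trajectory.

    The pressure grid sees two foot-shaped Gaussian pressure blobs whose
    combined centroid tracks the CoP exactly (cell values are exact integrals
    of the footprint over each cell); cells below three noise standard
    deviations after adding sensor noise read zero (sensor dead band). The
    corner board solves the lever equations for the same CoP and total load,
    with additive load-cell noise.
    """
    grid = grid or GridGeometry()
    board_L = board.board_length_cm if board is not None else 43.3
    board_W = board.board_width_cm if board is not None else 22.8
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = trial.x, trial.y
    half_x = grid.n_cols * grid.pitch_x_mm / MM_PER_CM / 2.0
    half_y = grid.n_rows * grid.pitch_y_mm / MM_PER_CM / 2.0
    off = footprint.foot_offset_y_cm
    if (
        np.any(np.abs(x) > min(half_x, board_L / 2.0))
        or np.any(np.abs(y) + off > half_y)
        or np.any(np.abs(y) > board_W / 2.0)
    ):
        raise DomainError("CoP trajectory leaves the active area of a device")

    # grid: separable Gaussian cell integrals, two feet at CoP -+ ML offset
    cx = grid.cell_x_cm
    cy = grid.cell_y_cm
    x_edges = np.concatenate([cx - grid.pitch_x_mm / MM_PER_CM / 2.0,
                              [cx[-1] + grid.pitch_x_mm / MM_PER_CM / 2.0]])
    y_edges_desc = np.concatenate([cy + grid.pitch_y_mm / MM_PER_CM / 2.0,
                                   [cy[-1] - grid.pitch_y_mm / MM_PER_CM / 2.0]])
    wx = _cell_weights(x_edges, x, footprint.foot_sd_x_cm)  # (n_t, n_cols)
    # row weights: integrate over descending y edges, take -diff; both feet
    # share wx, so the frame tensor is one outer product (wy_sum x wx)
    wy_sum = np.zeros((trial.n_samples, grid.n_rows))
    for sign in (+1.0, -1.0):
        wy_sum -= _cell_weights(y_edges_desc, y + sign * off, footprint.foot_sd_y_cm)
    # footprint support window: outside it cell weights are < 1e-14, so those
    # cells carry pure sensor noise and can be sampled from the dead-band
    # survivor distribution directly instead of drawing the full dense grid
    tiny = 1e-14
    row_mask = wy_sum.max(axis=0) > tiny
    col_mask = wx.max(axis=0) > tiny
    win_rows = np.nonzero(row_mask)[0]
    win_cols = np.nonzero(col_mask)[0]
    sub = (load_kgf / 2.0) * (
        wy_sum[:, win_rows, None] * wx[:, None, win_cols]
    )
    frames = np.zeros((trial.n_samples, grid.n_rows, grid.n_cols))
    if grid_noise_sd > 0:
        sub += rng.normal(0.0, grid_noise_sd, size=sub.shape)
        sub[sub < 3.0 * grid_noise_sd] = 0.0
        # background cells: value = noise, kept only above the 3-sigma dead
        # band; equivalent to drawing the survivor count per frame and the
        # surviving values from the upper-tail conditional distribution
        # (duplicate draws of one cell are merged, a <0.1% count distortion)
        bg_r, bg_c = np.nonzero(~(row_mask[:, None] & col_mask[None, :]))
        n_bg = len(bg_r)
        if n_bg:
            p_tail = float(stats.norm.sf(3.0))
            k = rng.binomial(n_bg, p_tail, size=trial.n_samples)
            t_idx = np.repeat(np.arange(trial.n_samples), k)
            pos = rng.integers(0, n_bg, size=int(k.sum()))
            _, uniq = np.unique(t_idx * n_bg + pos, return_index=True)
            t_idx, pos = t_idx[uniq], pos[uniq]
            frames[t_idx, bg_r[pos], bg_c[pos]] = grid_noise_sd * special.ndtri(
                1.0 - rng.random(len(pos)) * p_tail
            )
    frames[np.ix_(np.arange(trial.n_samples), win_rows, win_cols)] = np.clip(
        sub, 0.0, None
    )
    grid_series = PressureFrameSeries(geometry=grid, frames=frames, time=trial.time.copy())

    # corners: bilinear load split reproducing the lever equations
    px = 0.5 + x / board_L
    py = 0.5 + y / board_W
    def corner(fx, fy):
        c = load_kgf * fx * fy
        if corner_noise_sd > 0:
            c = c + rng.normal(0.0, corner_noise_sd, size=c.shape)
        return c
    corners = CornerLoadSeries(
        tl=corner(1 - px, py),
        tr=corner(px, py),
        bl=corner(1 - px, 1 - py),
        br=corner(px, 1 - py),
        board_length_cm=board_L,
        board_width_cm=board_W,
        time=trial.time.copy(),
    )
    return grid_series, corners
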