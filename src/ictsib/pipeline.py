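"""End-to-end session scoring, device-agreement analysis and study sizing."""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyReportError,
    UndefinedCorrelationError,
)
from .features import compute_sway_features
from .io import read_cop_trial
from .model import ConditionModel, predict_si
from .preprocessing import FilterSpec
from .types import Condition, CopTrial, SessionReport, SwayFeatures


def run_ictsib_session(
    trials: dict[Condition, CopTrial | str | Path],
    models: dict[Condition, ConditionModel],
    filter_spec: FilterSpec | None = None,
    subject_id: str | None = None,
) -> SessionReport:
    """Score one subject's i-CTSIB session.

    For each supplied condition the trial is read (if given as a path),
    preprocessed, reduced to sway features and mapped to an SI estimate by
    that condition's model. The overall SI is the mean over the scored
    conditions. A condition whose feature vector is incomplete (e.g. a flat
    trial with an undefined spectrum) is reported as missing rather than
    scored; negative model outputs are floored at zero, since the stability
    index is nonnegative by construction.
    """
    if not trials:
        raise EmptyReportError("no conditions supplied for the session")
    missing_models = [c for c in trials if c not in models]
    if missing_models:
        raise ConfigurationError(
            f"no model available for condition(s): {[c.value for c in missing_models]}"
        )
    per_condition: dict[Condition, float] = {}
    feature_table: dict[Condition, SwayFeatures] = {}
    missing: list[Condition] = []
    sid = subject_id or ""
    for cond, trial in trials.items():
        if not isinstance(trial, CopTrial):
            trial = read_cop_trial(trial, condition=cond)
        if not sid and trial.subject_id:
            sid = trial.subject_id
        feats = compute_sway_features(trial, filter_spec)
        feature_table[cond] = feats
        if not feats.is_complete():
            missing.append(cond)
            continue
        per_condition[cond] = max(predict_si(models[cond], feats), 0.0)
    if not per_condition:
        raise EmptyReportError("no condition could be scored in this session")
    return SessionReport(
        subject_id=sid,
        per_condition_si=per_condition,
        feature_table=feature_table,
        missing_conditions=missing,
    )


def device_agreement(si_a, si_b) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-subject SI vectors
    measured by two devices."""
    a = np.asarray(si_a, dtype=float)
    b = np.asarray(si_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("SI vectors must be one-dimensional and equally long")
    if len(a) < 3:
        raise DomainError(f"agreement needs >= 3 subjects, got {len(a)}")
    if float(np.std(a)) < 1e-15 or float(np.std(b)) < 1e-15:
        raise UndefinedCorrelationError("constant SI vector; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def sample_size_finite_population(
    population: float,
    confidence: float = 0.95,
    margin: float = 0.05,
    p: float = 0.5,
) -> int:
    """Minimum sample size with finite-population correction.

    ``n0 = z^2 p (1-p) / margin^2`` (infinite-population normal
    approximation, z the two-sided standard-normal quantile for the
    confidence level), corrected as ``n = ceil(n0 / (1 + (n0 - 1) /
    population))``. The ceiling is used because the result is a minimum
    ("this many or more"); the corrected value never exceeds the population.
    ``population=math.inf`` gives the uncorrected size.
    """
    if not population >= 1:
        raise DomainError(f"population must be >= 1, got {population}")
    if not 0 < margin < 1:
        raise DomainError(f"margin must be in (0, 1), got {margin}")
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    if not 0 < p < 1:
        raise DomainError(f"p must be in (0, 1), got {p}")
    z = float(stats.norm.ppf(1 - (1 - confidence) / 2))
    n0 = z**2 * p * (1 - p) / margin**2
    if math.isinf(population):
        return math.ceil(n0)
    return math.ceil(n0 / (1 + (n0 - 1) / population))
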