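"""Individual survival curves: interpolation, medians, counterfactual edits.

An :class:`ISDCurve` is a subject-specific cancer-free probability function
on a finite time grid starting at S(0) = 1.  Because the follow-up horizon
of the emulated cohort is 207 months while clinically interesting medians
can lie well beyond it, curves carry a tail rule: ``linear_last_segment``
extends the final segment's slope past the grid (the default), ``none``
holds the last value.

The counterfactual procedure edits a single *actionable* feature of one
subject on the raw questionnaire scale, re-runs the fitted pipeline, and
reports the change in predicted median cancer-free time.  These are model
counterfactuals, not causal claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ISDCurve", "InterventionReport", "BEYOND_HORIZON", "survival_at",
           "median_event_time", "counterfactual_delta", "months_to_age"]

#: Sentinel for a median that never crosses 0.5 (flat or rising tail).
BEYOND_HORIZON = math.inf


@dataclass
class ISDCurve:
    """A survival function on a strictly increasing grid with S(0) = 1."""

    times: np.ndarray
    probs: np.ndarray
    tail_rule: str = "linear_last_segment"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.probs = np.asarray(self.probs, float)
        if self.tail_rule not in ("linear_last_segment", "none"):
            raise ValueError(f"unknown tail_rule {self.tail_rule!r}")
        if self.times.ndim != 1 or self.times.shape != self.probs.shape:
            raise ValueError("times and probs must be 1-d and equal length")
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("curve must start at t=0")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if abs(self.probs[0] - 1.0) > 1e-9:
            raise ValueError("S(0) must equal 1")
        if (np.diff(self.probs) > 1e-9).any():
            raise ValueError("survival probabilities must be non-increasing")
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        self.probs = np.minimum.accumulate(np.clip(self.probs, 0.0, 1.0))

    def survival_at(self, t):
        return survival_at(self, t)

    def median(self):
        return median_event_time(self)


def survival_at(curve: ISDCurve, t) -> float:
    """S(t) by linear interpolation; the tail rule governs t beyond the grid."""
    t_arr = np.asarray(t, float)
    if (t_arr < 0).any():
        raise ValueError("t must be >= 0")
    out = np.interp(t_arr, curve.times, curve.probs)
    last_t, last_p = curve.times[-1], curve.probs[-1]
    beyond = t_arr > last_t
    if np.any(beyond) and curve.tail_rule == "linear_last_segment" and len(curve.times) > 1:
        slope = (curve.probs[-1] - curve.probs[-2]) / (curve.times[-1] - curve.times[-2])
        out = np.where(beyond, last_p + slope * (t_arr - last_t), out)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def median_event_time(curve: ISDCurve) -> float:
    """First time the curve crosses survival 0.5, in months.

    Linear interpolation between grid points; if the curve ends above 0.5
    and the tail rule is ``linear_last_segment``, the final segment's slope
    is extended until it crosses.  A flat (or absent) tail that never
    crosses yields the :data:`BEYOND_HORIZON` sentinel.
    """
    t, p = curve.times, curve.probs
    below = np.nonzero(p <= 0.5)[0]
    if len(below):
        i = below[0]
        if p[i] == 0.5 or i == 0:
            return float(t[i])
        # interpolate within segment [i-1, i]
        return float(t[i - 1] + (p[i - 1] - 0.5) * (t[i] - t[i - 1]) / (p[i - 1] - p[i]))
    if curve.tail_rule == "linear_last_segment" and len(t) > 1:
        slope = (p[-1] - p[-2]) / (t[-1] - t[-2])
        if slope < 0:
            return float(t[-1] + (p[-1] - 0.5) / (-slope))
    return BEYOND_HORIZON


@dataclass
class InterventionReport:
    """Outcome of one single-feature counterfactual edit."""

    feature: str
    old_value: object
    new_value: object
    baseline_median: float
    counterfactual_median: float
    delta_months: float
    baseline_attained_age: int | None = None
    counterfactual_attained_age: int | None = None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "old_value": self.old_value,
            "new_value": self.new_value,
            "baseline_median_months": self.baseline_median,
            "counterfactual_median_months": self.counterfactual_median,
            "delta_months": self.delta_months,
            "baseline_attained_age": self.baseline_attained_age,
            "counterfactual_attained_age": self.counterfactual_attained_age,
        }


def counterfactual_delta(model, metadata, x, feature, new_value,
                         age_at_recruitment=None) -> InterventionReport:
    """Predicted gain (months) from editing one actionable feature.

    Parameters
    ----------
    model : object
        Fitted pipeline exposing ``predict_curve(raw_row) -> ISDCurve``;
        the edit is applied on the raw questionnaire scale and re-passed
        through the pipeline's own fitted transform.
    metadata : sequence of FeatureMeta
        Schema carrying the actionable/intrinsic taxonomy and admissible
        ranges.  Editing an intrinsic feature (age, menarche age, hormone
        history, ...) is refused.
    x : mapping or pandas Series
        The subject's raw feature values.
    feature, new_value :
        The single edit; all other features are left untouched.
    """
    meta = {m.name: m for m in metadata}
    if feature not in meta:
        raise KeyError(f"unknown feature {feature!r}")
    m = meta[feature]
    if not m.actionable:
        raise ValueError(
            f"{feature!r} is an intrinsic feature and cannot be intervened on; "
            "counterfactual edits are restricted to actionable lifestyle features")
    if m.dtype == "numeric":
        lo, hi = m.admissible_range
        if not (lo - 1e-9 <= float(new_value) <= hi + 1e-9):
            raise ValueError(f"new value {new_value} outside admissible range [{lo}, {hi}]")
    elif new_value not in m.admissible_range:
        raise ValueError(f"new value {new_value!r} not an admissible category")

    import pandas as pd
    row = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x.copy()
    base_curve = model.predict_curve(row)
    cf_row = row.copy()
    cf_row[feature] = new_value
    cf_curve = model.predict_curve(cf_row)

    base_med = median_event_time(base_curve)
    cf_med = median_event_time(cf_curve)
    delta = cf_med - base_med
    if math.isnan(delta):          # inf - inf: both beyond horizon
        delta = 0.0
    rep = InterventionReport(feature, row.get(feature), new_value,
                             base_med, cf_med, delta)
    if age_at_recruitment is not None:
        if math.isfinite(base_med):
            rep.baseline_attained_age = months_to_age(age_at_recruitment, base_med)
        if math.isfinite(cf_med):
            rep.counterfactual_attained_age = months_to_age(age_at_recruitment, cf_med)
    return rep


def months_to_age(age_at_recruitment, months_from_recruitment) -> int:
    """Attained age in whole years: ceiling of recruitment age + months/12."""
    if age_at_recruitment < 0 or months_from_recruitment < 0:
        raise ValueError("ages and durations must be non-negative")
    return int(math.ceil(age_at_recruitment + months_from_recruitment / 12.0))
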