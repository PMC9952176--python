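"""Detector performance calibration: recall, detection range, monitored area.

Two distinct detector properties are calibrated, matching their two
distinct uses downstream:

* **algorithmic recall** — the fraction of verified gunshots the template
  detector finds; its reciprocal adjusts detected counts upward;
* **audible radius** — the distance out to which gunshots are detectable
  at all (assessed with control shots fired at known distances), whose
  circle gives the effective monitored area used when choosing posta
  fractions.

The detection-probability-vs-distance relationship is modelled as a
Bernoulli logit, p(d) = 1 / (1 + exp(-(b0 + b1 d))), fitted by maximum
likelihood. Control-shot data can be completely separated (every shot
detected out to the maximum distance tried, as happens with a human
reviewer), in which case the slope is capped and flagged instead of
letting the fit diverge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "MatchResult",
    "RecallEstimate",
    "RangeModel",
    "EffectiveArea",
    "match_detections",
    "estimate_recall",
    "fit_logistic_range",
    "effective_radius",
    "monitored_area",
    "write_calibration_report",
]

DEFAULT_SLOPE_CAP = 0.05  # |b1| bound (per metre) applied on separation


@dataclass(frozen=True)
class MatchResult:
    """Tally of a detector run against verified ground truth."""

    true_positives: int
    false_negatives: int
    false_positives: int

    def __post_init__(self) -> None:
        if min(self.true_positives, self.false_negatives, self.false_positives) < 0:
            raise ValueError("match counts must be non-negative")


@dataclass(frozen=True)
class RecallEstimate:
    """Recall (sensitivity) and its reciprocal adjustment factor."""

    recall: float
    adjustment_factor: float

    def __post_init__(self) -> None:
        if not 0.0 < self.recall <= 1.0:
            raise ValueError("recall must lie in (0, 1]")
        if abs(self.recall * self.adjustment_factor - 1.0) > 1e-12:
            raise ValueError("adjustment_factor must be the exact reciprocal of recall")


@dataclass(frozen=True)
class RangeModel:
    """Logistic detection-probability-vs-distance curve.

    ``separation_flag`` marks a fit on completely separated data, where
    the slope magnitude was capped rather than allowed to diverge.
    """

    beta0: float
    beta1: float
    separation_flag: bool = False

    def prob(self, distance_m) -> np.ndarray | float:
        eta = self.beta0 + self.beta1 * np.asarray(distance_m, dtype=float)
        p = expit(eta)
        return p if p.ndim else float(p)


@dataclass(frozen=True)
class EffectiveArea:
    """Monitored circle: radius and its area in km^2."""

    radius_m: float
    area_km2: float

    def __post_init__(self) -> None:
        expected = math.pi * (self.radius_m / 1000.0) ** 2
        if abs(self.area_km2 - expected) > 0.05:
            raise ValueError("area_km2 inconsistent with radius_m")


def match_detections(
    detections,
    truth,
    tolerance_s: float = 1.0,
) -> MatchResult:
    """Match detection times to ground-truth times, one to one.

    Candidate pairs within ``tolerance_s`` are accepted greedily in
    order of increasing absolute time difference, so each detection and
    each truth event is used at most once. Unmatched truth events are
    false negatives, unmatched detections false positives.

    Both inputs are sequences of event times in seconds (or anything
    orderable and subtractable, e.g. timestamps converted to seconds).
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be non-negative")
    det = np.asarray(list(detections), dtype=float)
    tru = np.asarray(list(truth), dtype=float)

    pairs = []
    for i, d in enumerate(det):
        dt = np.abs(tru - d)
        for j in np.nonzero(dt <= tolerance_s)[0]:
            pairs.append((dt[j], i, j))
    pairs.sort(key=lambda p: p[0])

    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return MatchResult(
        true_positives=tp,
        false_negatives=len(tru) - tp,
        false_positives=len(det) - tp,
    )


def estimate_recall(match: MatchResult) -> RecallEstimate:
    """Recall = TP / (TP + FN); adjustment factor is its reciprocal."""
    denom = match.true_positives + match.false_negatives
    if denom <= 0:
        raise ValueError("recall undefined: no ground-truth events (TP + FN = 0)")
    if match.true_positives == 0:
        raise ValueError("degenerate recall: zero true positives, adjustment factor undefined")
    recall = match.true_positives / denom
    return RecallEstimate(recall=recall, adjustment_factor=1.0 / recall)


def _separation_check(distance: np.ndarray, detected: np.ndarray) -> bool:
    """True when a distance threshold perfectly splits the outcomes.

    Covers single-class data (all detected or none) and the monotone
    split where every detected shot is nearer than every missed one.
    """
    hits = distance[detected == 1]
    misses = distance[detected == 0]
    if hits.size == 0 or misses.size == 0:
        return True
    return hits.max() < misses.min() or misses.max() < hits.min()


def fit_logistic_range(
    control: pd.DataFrame,
    slope_cap: float = DEFAULT_SLOPE_CAP,
) -> RangeModel:
    """Fit the detection-probability-vs-distance logistic model.

    Parameters
    ----------
    control
        Control-shot table with columns ``distance_m`` and ``detected``
        (0/1), one row per shot.
    slope_cap
        Magnitude bound on the slope applied when the data are
        completely separated (the maximum-likelihood slope would
        otherwise diverge).

    Returns
    -------
    RangeModel, with ``separation_flag`` set when the cap was applied.
    """
    d = np.asarray(control["distance_m"], dtype=float)
    y = np.asarray(control["detected"], dtype=int)
    if d.size == 0:
        raise ValueError("control table is empty")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")

    if _separation_check(d, y):
        # detection should fall with distance; place the midpoint of the
        # capped curve at the boundary between the two classes, or past
        # the farthest shot when only one class is present
        hits = d[y == 1]
        misses = d[y == 0]
        if misses.size == 0:
            midpoint = d.max()
        elif hits.size == 0:
            midpoint = 0.0
        else:
            midpoint = 0.5 * (hits.max() + misses.min())
        beta1 = -abs(slope_cap)
        beta0 = -beta1 * midpoint
        return RangeModel(beta0=beta0, beta1=beta1, separation_flag=True)

    X = sm.add_constant(d)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-8)
    return RangeModel(beta0=float(fit.params[0]), beta1=float(fit.params[1]))


def effective_radius(
    model: RangeModel,
    p_cut: float = 0.5,
    max_observed_m: float = 1100.0,
) -> float:
    """Distance out to which detection probability stays >= ``p_cut``.

    Solved in closed form from the logistic curve and truncated at
    ``max_observed_m``: the farthest distance actually tried bounds any
    claim about the detection range. If the curve never falls below
    ``p_cut`` within the observed range (the separated all-detected
    case), the radius is ``max_observed_m`` itself.
    """
    if not 0.0 < p_cut < 1.0:
        raise ValueError("p_cut must lie strictly between 0 and 1")
    if max_observed_m < 0:
        raise ValueError("max_observed_m must be non-negative")
    if model.beta1 > 0:
        raise ValueError("positive-slope model: detection probability must not grow with distance")
    if model.beta1 == 0:
        return max_observed_m if model.prob(0.0) >= p_cut else 0.0
    d_cut = (math.log(p_cut / (1.0 - p_cut)) - model.beta0) / model.beta1
    return float(min(max(d_cut, 0.0), max_observed_m))


def monitored_area(radius_m: float, ndigits: int | None = 1) -> float:
    """Area of the monitored circle in km^2, pi * (r/1000)^2.

    Reported to 1 decimal by default; pass ``ndigits=None`` for full
    precision.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    area = math.pi * (radius_m / 1000.0) ** 2
    return area if ndigits is None else round(area, ndigits)


def write_calibration_report(
    path: str | Path,
    recall: RecallEstimate | None = None,
    model: RangeModel | None = None,
    radius_m: float | None = None,
) -> dict:
    """Assemble and write the calibration summary JSON; returns the dict."""
    report: dict = {}
    if recall is not None:
        report["recall"] = recall.recall
        report["adjustment_factor"] = recall.adjustment_factor
    if model is not None:
        report["beta0"] = model.beta0
        report["beta1"] = model.beta1
        report["separation_flag"] = model.separation_flag
    if radius_m is not None:
        report["radius_m"] = radius_m
        report["area_km2"] = monitored_area(radius_m)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report
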