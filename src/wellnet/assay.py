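"""qPCR quantification and mono- vs co-culture interaction classification.

Composition of a two-member co-culture is quantified with genus-specific
qPCR: a standard curve Cq = slope * log10(copies) + intercept fitted on a
plasmid dilution series converts Cq to 16S gene copies, and dividing by the
strain's rrn copy number (rrnDB) converts copies to cells. Amplification
efficiency is E = 10^(-1/slope) - 1 (slope -3.3219 <=> 100%).

The interaction of an isolate pair is called from the divergence of its
co-culture trajectory from the axenic one. The effect on partner x within a
time window is the difference in trapezoidal area under log10(density):

    delta_x = auc_log(co_x) - auc_log(mono_x)

thresholded at +/- epsilon * window_length into {+, 0, -}; the effect pair
maps onto the classical interaction taxonomy (mutualism (+,+),
commensalism (+,0), exploitation (+,-), amensalism (-,0), competition
(-,-), neutralism (0,0)). Windowed calls capture biphasic interactions that
switch regime mid-course.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GrowthCurveSet

__all__ = [
    "StandardCurve",
    "Quantification",
    "InteractionCall",
    "EFFECT_LABELS",
    "fit_standard_curve",
    "quantify",
    "growth_metrics",
    "classify_interaction",
    "collapse_to_plate_readout",
    "write_calls",
]

EFFECT_LABELS = {
    ("+", "+"): "mutualism",
    ("+", "0"): "commensalism",
    ("0", "+"): "commensalism",
    ("+", "-"): "exploitation",
    ("-", "+"): "exploitation",
    ("-", "0"): "amensalism",
    ("0", "-"): "amensalism",
    ("-", "-"): "competition",
    ("0", "0"): "neutralism",
}


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid qPCR standard curve has negative slope")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1 (1.0 == 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class Quantification:
    target: str
    cq: float
    copies_per_ul: float
    cells_per_ul: float


@dataclass(frozen=True)
class InteractionCall:
    pair_id: str
    window: tuple[float, float]
    effect_a: str
    effect_b: str
    label: str
    delta_a: float
    delta_b: float
    epsilon: float


def fit_standard_curve(log10_copies, cq_values) -> StandardCurve:
    """OLS of Cq on log10(copies) over the plasmid dilution series."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(cq_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("log10_copies and cq_values must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct dilution points")
    if not np.all(np.isfinite(y)):
        raise ValueError("cq values must be finite")
    fit = stats.linregress(x, y)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=float(fit.rvalue**2))


def quantify(
    cq: float,
    curve: StandardCurve,
    rrn_copies: float,
    target: str = "",
    cq_range: tuple[float, float] | None = None,
) -> Quantification:
    """Cq -> 16S copies/ul -> cells/ul (copies / rrn copy number).

    A Cq outside the calibrated range still yields a value but warns: the
    extrapolation is outside the region where the curve was validated.
    """
    if rrn_copies < 1:
        raise ValueError("rrn_copies must be >= 1")
    if cq_range is not None and not (cq_range[0] <= cq <= cq_range[1]):
        warnings.warn(f"cq {cq} outside calibrated range {cq_range}; extrapolating", stacklevel=2)
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return Quantification(target=target, cq=cq, copies_per_ul=copies, cells_per_ul=copies / rrn_copies)


def growth_metrics(
    times,
    densities,
    window: tuple[float, float] | None = None,
    detection_limit: float = 1.0,
) -> tuple[float, float, float]:
    """(auc_log, max_density, end_density) within a time window.

    auc_log is the trapezoidal area under log10(density) vs time; densities
    below ``detection_limit`` (default 1 cell/ml) are floored before the log.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(densities, dtype=float)
    if t.shape != d.shape:
        raise ValueError("times and densities must have equal length")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, d = t[mask], d[mask]
    if t.size < 2:
        raise ValueError("window contains fewer than 2 time points")
    if d.min() < 0:
        raise ValueError("densities must be >= 0")
    logd = np.log10(np.maximum(d, detection_limit))
    auc = float(np.trapezoid(logd, t))
    return auc, float(d.max()), float(d[-1])


def _effect(delta: float, threshold: float) -> str:
    if delta > threshold:
        return "+"
    if delta < -threshold:
        return "-"
    return "0"


def classify_interaction(
    curves: GrowthCurveSet,
    windows: Sequence[tuple[float, float]] | None = None,
    epsilon: float = 0.2,
    pair_id: str = "",
    detection_limit: float = 1.0,
) -> list[InteractionCall]:
    """One interaction call per time window from log-AUC divergence.

    ``epsilon`` is in log10-units (per hour of window): the call threshold
    on delta_x is epsilon * window_length, so a sustained 10-fold density
    shift over the whole window scores as 1.0 log10-unit/h and epsilon=0.2
    demands a fifth of that on average. Reported with every call.
    """
    t = curves.times
    if windows is None:
        windows = [(float(t[0]), float(t[-1]))]
    for (a0, a1), (b0, b1) in itertools.combinations(windows, 2):
        if max(a0, b0) < min(a1, b1):
            raise ValueError(f"windows ({a0},{a1}) and ({b0},{b1}) overlap")

    calls = []
    for window in windows:
        length = window[1] - window[0]
        if length <= 0:
            raise ValueError(f"empty window {window}")
        threshold = epsilon * length
        auc_mono_a, _, _ = growth_metrics(t, curves.mono_a, window, detection_limit)
        auc_mono_b, _, _ = growth_metrics(t, curves.mono_b, window, detection_limit)
        auc_co_a, _, _ = growth_metrics(t, curves.co_a, window, detection_limit)
        auc_co_b, _, _ = growth_metrics(t, curves.co_b, window, detection_limit)
        delta_a = auc_co_a - auc_mono_a
        delta_b = auc_co_b - auc_mono_b
        effect_a = _effect(delta_a, threshold)
        effect_b = _effect(delta_b, threshold)
        calls.append(
            InteractionCall(
                pair_id=pair_id,
                window=(float(window[0]), float(window[1])),
                effect_a=effect_a,
                effect_b=effect_b,
                label=EFFECT_LABELS[(effect_a, effect_b)],
                delta_a=delta_a,
                delta_b=delta_b,
                epsilon=epsilon,
            )
        )
    return calls


def collapse_to_plate_readout(label: str) -> str:
    """Collapse the six-way taxonomy to the on-plate three-way readout.

    Mutual requires facilitation of both partners; any suppressed partner
    reads as competitive; everything else is neutral.
    """
    if label == "mutualism":
        return "mutual"
    if label in ("competition", "amensalism", "exploitation"):
        return "competitive"
    return "neutral"


def write_calls(calls: Sequence[InteractionCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pair": c.pair_id,
                "window_start_h": c.window[0],
                "window_end_h": c.window[1],
                "effect_a": c.effect_a,
                "effect_b": c.effect_b,
                "label": c.label,
                "delta_a": c.delta_a,
                "delta_b": c.delta_b,
                "epsilon": c.epsilon,
            }
            for c in calls
        ],
        columns=[
            "pair", "window_start_h", "window_end_h", "effect_a", "effect_b",
            "label", "delta_a", "delta_b", "epsilon",
        ],
    ).to_csv(path, sep="\t", index=False)
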