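"""Enslaving and mirroring patterns as robust origin-constrained log-slopes.

For every (instructed finger, uninstructed finger) pair, the peak force of
the instructed finger (x) and the peak force of the uninstructed finger (y)
across all trials are related by a regression line constrained to pass
through the origin: pressing with zero force cannot enslave anything.  The
slope — newtons of involuntary force per newton of instructed force — is
estimated by iteratively reweighted least squares with Tukey bisquare
weights so single aberrant trials do not dominate, and is log-transformed
(natural log, with a small floor for non-positive slopes) before any
averaging or parametric statistics.

Within one hand the 20 off-diagonal pairs form the *enslaving pattern*; the
25 pairs from the active to the passive hand form the *mirroring pattern*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FINGERS, HANDS, channel_index
from .preprocess import PeakTable

__all__ = [
    "BISQUARE_C",
    "LOG_SLOPE_FLOOR",
    "SlopePattern",
    "robust_origin_slope",
    "log_slope",
    "enslaving_pattern",
    "mirroring_pattern",
    "mean_pattern_strength",
]

logger = logging.getLogger(__name__)

#: Tukey bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_C = 4.685
#: Slopes at or below zero are floored here before taking logs (N per N);
#: far below any physiologically observed coupling.
LOG_SLOPE_FLOOR = 1e-4
# The IRLS fixed point can contract slowly when outliers sit near the
# bisquare cutoff; a loose step tolerance would leave the slope several
# orders of magnitude further from the fixed point than the step size.
MAX_ITER = 500
TOL = 1e-11


class InsufficientDataError(ValueError):
    """Too few usable trials to estimate a slope."""


def robust_origin_slope(x: np.ndarray, y: np.ndarray, *,
                        c: float = BISQUARE_C, max_iter: int = MAX_ITER,
                        tol: float = TOL) -> float:
    """Origin-constrained robust regression slope of y on x.

    Iteratively reweighted least squares with Tukey bisquare weights
    ``w = (1 - (r / (c s))^2)^2`` for ``|r| < c s`` (else 0), where the
    scale ``s`` is the median absolute residual divided by 0.6745,
    re-estimated each iteration.  Starts from the ordinary least-squares
    origin slope and falls back to it when the residual MAD is zero
    (e.g. an exact linear fit).

    Parameters
    ----------
    x, y : array-like
        Peak forces; ``x`` must contain positive values, at least 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    if not np.any(x > 0):
        raise ValueError("all x <= 0: no instructed force to regress on")

    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    for _ in range(max_iter):
        r = y - slope * x
        scale = np.median(np.abs(r)) / 0.6745
        if scale <= 0 or not np.isfinite(scale):
            return slope  # exact fit: bisquare weights are all 1
        u = r / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        swx = float((w * x) @ x)
        if swx <= 0:
            return slope
        new = float((w * x) @ y) / swx
        if abs(new - slope) < tol:
            return new
        slope = new
    return slope


def log_slope(slope: float, floor: float = LOG_SLOPE_FLOOR) -> float:
    """Natural log of a slope, floored at ``floor`` N/N to stay finite."""
    return float(np.log(max(slope, floor)))


@dataclass
class SlopePattern:
    """A 5x5 matrix of pair-wise log-slopes for one context.

    Rows index the instructed finger, columns the uninstructed finger
    (D1..D5).  ``kind`` is ``"enslaving"`` (context = the instructed hand;
    diagonal invalid) or ``"mirroring"`` (context = active->passive
    direction, e.g. ``"R->L"``; all 25 cells valid).
    """

    kind: str
    context: str
    cells: np.ndarray
    valid: np.ndarray
    n_points: np.ndarray = field(default_factory=lambda: np.zeros((5, 5), int))

    @property
    def values(self) -> np.ndarray:
        """Valid-cell log-slopes, row-major order."""
        return self.cells[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, fi in enumerate(FINGERS):
            for j, fj in enumerate(FINGERS):
                if self.valid[i, j]:
                    rows.append({
                        "kind": self.kind, "context": self.context,
                        "instructed": fi, "uninstructed": fj,
                        "log_slope": self.cells[i, j],
                        "n_points": int(self.n_points[i, j]),
                    })
        return pd.DataFrame(rows)


def _pattern(peaks: PeakTable, kind: str, instructed_hand: str,
             uninstructed_hand: str, context: str,
             exclude_diagonal: bool, min_points: int = 3) -> SlopePattern:
    cells = np.full((5, 5), np.nan)
    valid = np.zeros((5, 5), bool)
    n_points = np.zeros((5, 5), int)
    for i, fi in enumerate(FINGERS):
        sub = peaks.filter(hand=instructed_hand, finger=fi)
        x = np.array([r.peak[channel_index(instructed_hand, fi)] for r in sub])
        for j, fj in enumerate(FINGERS):
            if exclude_diagonal and i == j:
                continue
            y = np.array([r.peak[channel_index(uninstructed_hand, fj)] for r in sub])
            usable = x > 0
            n_points[i, j] = int(usable.sum())
            if n_points[i, j] < min_points:
                logger.warning(
                    "%s %s: pair %s->%s has %d usable trials (< %d); cell invalid",
                    kind, context, fi, fj, n_points[i, j], min_points,
                )
                continue
            slope = robust_origin_slope(x[usable], y[usable])
            cells[i, j] = log_slope(slope)
            valid[i, j] = True
    return SlopePattern(kind=kind, context=context, cells=cells,
                        valid=valid, n_points=n_points)


def enslaving_pattern(peaks: PeakTable, hand: str) -> SlopePattern:
    """Enslaving pattern of one hand: 20 off-diagonal pairs, all three
    target levels pooled into one regression per pair."""
    if hand not in HANDS:
        raise ValueError(f"hand must be one of {HANDS}")
    return _pattern(peaks, "enslaving", hand, hand, hand, exclude_diagonal=True)


def mirroring_pattern(peaks: PeakTable, active_hand: str) -> SlopePattern:
    """Mirroring pattern for presses of ``active_hand``: all 25 pairs onto
    the passive hand."""
    if active_hand not in HANDS:
        raise ValueError(f"active_hand must be one of {HANDS}")
    passive = "L" if active_hand == "R" else "R"
    return _pattern(peaks, "mirroring", active_hand, passive,
                    f"{active_hand}->{passive}", exclude_diagonal=False)


def mean_pattern_strength(pattern: SlopePattern) -> tuple[float, float]:
    """Overall coupling strength: mean log-slope over valid cells and its
    back-transform (the geometric-mean slope, N per N)."""
    if pattern.n_valid == 0:
        raise InsufficientDataError(
            f"{pattern.kind} {pattern.context}: no valid cells to average")
    mean_log = float(pattern.values.mean())
    return mean_log, float(np.exp(mean_log))
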